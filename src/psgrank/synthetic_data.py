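"""Synthetic polysomnography and feature-table generators.

The signal generator emulates the gross spectral signatures that sleep
scorers rely on — delta-dominant slow-wave sleep, alpha-rich wake, spindle
bursts in stage 2, mixed-frequency S1/REM, stage-dependent muscle tone and
eye movement — without claiming physiological realism. Its purpose is to
give every downstream stage (filtering, feature extraction, ranking,
evaluation) inputs with known ground truth so the whole pipeline is
testable without any recorded data.

The EEG model is a sum of independent band-limited Gaussian noise
processes, one per clinical rhythm band (delta 0-4 Hz, theta 4-8 Hz, alpha
8-13 Hz, beta >13 Hz), each rescaled to a prescribed share of the epoch
power, plus broadband white noise 20 dB below the total. Stage-2 epochs
additionally carry Hann-windowed 13-Hz tone bursts of 1 s (sleep
spindles). EOG is modelled as sub-1-Hz filtered noise (slow rolling eye
movements) plus smoothed step deflections (rapid eye movements), EMG as
white noise scaled by the stage's muscle tone.

Within a stage, epochs are not identically scaled: the band-power mix is
jittered around the stage profile (Dirichlet resampling) and the EEG, EMG
and EOG amplitudes are modulated by per-epoch log-normal factors. Real
sleep stages overlap in every single feature — muscle tone in light sleep
ranges from near-wake to near-REM values — and without this overlap a
single feature would separate all five stages perfectly and any
feature-selection comparison on the cohort would be vacuous.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence` spawning; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import STAGES, EpochSignal, FeatureTable, Recording

#: Rhythm band edges in Hz used by the synthesis model (upper beta edge is
#: a synthesis cut-off, not a clinical definition).
SYNTH_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class StageSpec:
    """Synthesis parameters of one sleep stage.

    band_powers: relative EEG power per rhythm band (delta/theta/alpha/
        beta); must sum to 1.
    spindle_rate: expected number of 1-s spindle bursts per epoch.
    emg_tone: EMG white-noise amplitude scale.
    eog_activity: EOG slow/rapid eye-movement amplitude scale.
    """

    stage: str
    band_powers: dict[str, float]
    spindle_rate: float = 0.0
    emg_tone: float = 1.0
    eog_activity: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if set(self.band_powers) != set(SYNTH_BANDS):
            raise ValueError("band_powers must cover delta/theta/alpha/beta")
        total = sum(self.band_powers.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band_powers must sum to 1, got {total}")
        if any(v < 0 for v in self.band_powers.values()):
            raise ValueError("band powers must be non-negative")
        if self.spindle_rate < 0 or self.emg_tone <= 0 or self.eog_activity < 0:
            raise ValueError("scales must be non-negative (emg_tone positive)")


def default_stage_specs() -> dict[str, StageSpec]:
    """Default per-stage synthesis parameters.

    Chosen so the stages differ the way they do on a sleep montage: wake
    is alpha-rich with high muscle tone, S1 and REM share mixed
    theta-dominant EEG and are told apart by muscle atonia and rapid eye
    movements, S2 carries spindles, SWS is strongly delta-dominant with
    low tone.
    """
    return {
        "W": StageSpec("W", {"delta": 0.15, "theta": 0.15, "alpha": 0.50, "beta": 0.20},
                       emg_tone=1.0, eog_activity=0.4),
        "S1": StageSpec("S1", {"delta": 0.30, "theta": 0.40, "alpha": 0.20, "beta": 0.10},
                        emg_tone=0.6, eog_activity=0.5),
        "S2": StageSpec("S2", {"delta": 0.45, "theta": 0.30, "alpha": 0.15, "beta": 0.10},
                        spindle_rate=2.0, emg_tone=0.45, eog_activity=0.1),
        "SWS": StageSpec("SWS", {"delta": 0.80, "theta": 0.12, "alpha": 0.05, "beta": 0.03},
                         emg_tone=0.3, eog_activity=0.05),
        "REM": StageSpec("REM", {"delta": 0.30, "theta": 0.40, "alpha": 0.20, "beta": 0.10},
                         emg_tone=0.15, eog_activity=1.0),
    }


#: Per-subject per-stage epoch counts of the magnitude observed in real
#: overnight telemetry recordings (order W, REM, S1, S2, SWS).
DEFAULT_STAGE_COUNTS: list[dict[str, int]] = [
    {"W": 146, "REM": 122, "S1": 101, "S2": 527, "SWS": 136},
    {"W": 41, "REM": 159, "S1": 71, "S2": 351, "SWS": 284},
    {"W": 85, "REM": 226, "S1": 120, "S2": 392, "SWS": 180},
    {"W": 40, "REM": 143, "S1": 47, "S2": 266, "SWS": 152},
    {"W": 149, "REM": 80, "S1": 102, "S2": 428, "SWS": 218},
    {"W": 131, "REM": 142, "S1": 135, "S2": 378, "SWS": 198},
]


@dataclass
class SyntheticCohortConfig:
    """Configuration of a synthetic multi-subject cohort."""

    n_subjects: int = 6
    stage_counts: list[dict[str, int]] = field(
        default_factory=lambda: [dict(c) for c in DEFAULT_STAGE_COUNTS]
    )
    fs: float = 100.0
    epoch_len: float = 30.0
    seed: int = 0
    stage_specs: dict[str, StageSpec] = field(default_factory=default_stage_specs)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if len(self.stage_counts) != self.n_subjects:
            raise ValueError("stage_counts must have one entry per subject")
        for counts in self.stage_counts:
            if any(v < 0 for v in counts.values()):
                raise ValueError("stage counts must be non-negative")


# ---------------------------------------------------------------------------
# signal synthesis


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-power band-limited Gaussian noise (4th-order Butterworth)."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    sos = sps.butter(4, [low / nyq, high / nyq], btype="band", output="sos")
    x = sps.sosfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


#: Within-stage variability: Dirichlet concentration of the per-epoch
#: band-power jitter and log-normal sigmas of the amplitude modulations.
BAND_JITTER_CONCENTRATION = 25.0
EEG_AMP_SIGMA = 0.25
EMG_TONE_SIGMA = 0.5
EOG_ACTIVITY_SIGMA = 0.5


def generate_stage_epoch(
    spec: StageSpec,
    fs: float = 100.0,
    epoch_len: float = 30.0,
    seed: int | np.random.Generator = 0,
    within_stage_jitter: bool = True,
) -> tuple[EpochSignal, EpochSignal, EpochSignal]:
    """Generate one synchronized (EEG, EOG, EMG) epoch for a stage.

    With ``within_stage_jitter`` (the default) the stage profile is
    resampled per epoch: band powers from a Dirichlet centered on
    ``spec.band_powers`` and channel amplitudes from log-normal
    modulations, so stages overlap the way they do in recordings.
    Deterministic: identical ``spec`` and ``seed`` give bitwise-identical
    output.
    """
    if fs <= 0 or epoch_len <= 0:
        raise ValueError("fs and epoch_len must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(fs * epoch_len))

    band_names = list(SYNTH_BANDS)
    powers = np.array([spec.band_powers[b] for b in band_names])
    if within_stage_jitter:
        nz = powers > 0
        if nz.sum() > 1:
            powers[nz] = rng.dirichlet(BAND_JITTER_CONCENTRATION * powers[nz])
        eeg_amp = rng.lognormal(0.0, EEG_AMP_SIGMA)
        emg_tone = spec.emg_tone * rng.lognormal(0.0, EMG_TONE_SIGMA)
        eog_act = spec.eog_activity * rng.lognormal(0.0, EOG_ACTIVITY_SIGMA)
    else:
        eeg_amp = 1.0
        emg_tone = spec.emg_tone
        eog_act = spec.eog_activity

    # EEG: band-noise mixture with prescribed per-band sample powers.
    eeg = np.zeros(n)
    for band, p in zip(band_names, powers):
        if p > 0:
            low, high = SYNTH_BANDS[band]
            eeg += np.sqrt(p) * _band_noise(rng, n, fs, low, high)
    # broadband floor at -20 dB relative to the rhythm mixture
    eeg += 0.1 * rng.standard_normal(n)
    eeg *= eeg_amp
    # sleep spindles: 1-s Hann-windowed 13 Hz bursts
    n_spindles = int(rng.poisson(spec.spindle_rate)) if spec.spindle_rate > 0 else 0
    burst_len = int(round(fs))
    for _ in range(n_spindles):
        if n <= burst_len:
            break
        start = int(rng.integers(0, n - burst_len))
        t = np.arange(burst_len) / fs
        burst = np.hanning(burst_len) * np.sin(2 * np.pi * 13.0 * t)
        eeg[start:start + burst_len] += 1.5 * burst

    # EOG: slow (<1 Hz) rolling component plus rapid step deflections
    nyq = fs / 2.0
    sos = sps.butter(2, 0.8 / nyq, btype="low", output="sos")
    slow = sps.sosfilt(sos, rng.standard_normal(n))
    sd = slow.std()
    slow = slow / sd if sd > 0 else slow
    eog = eog_act * slow
    n_steps = int(rng.poisson(3.0 * eog_act)) if eog_act > 0 else 0
    edge = max(int(0.1 * fs), 1)
    for _ in range(n_steps):
        start = int(rng.integers(0, max(n - 4 * edge, 1)))
        width = int(rng.integers(2 * edge, 4 * edge))
        amp = 2.0 * eog_act * rng.choice([-1.0, 1.0])
        pulse = np.zeros(n)
        stop = min(start + width, n)
        pulse[start:stop] = amp
        # smooth the edges so the deflection is step-like, not impulsive
        kernel = np.hanning(2 * edge + 1)
        kernel /= kernel.sum()
        eog += np.convolve(pulse, kernel, mode="same")
    eog += 0.05 * rng.standard_normal(n)

    # EMG: broadband noise scaled by muscle tone
    emg = emg_tone * rng.standard_normal(n)

    return (
        EpochSignal(eeg, fs, "EEG"),
        EpochSignal(eog, fs, "EOG"),
        EpochSignal(emg, fs, "EMG"),
    )


# ---------------------------------------------------------------------------
# hypnogram and recording


#: Off-diagonal transition affinities of the cosmetic sleep-cycle model.
_TRANSITIONS: dict[str, dict[str, float]] = {
    "W": {"S1": 0.70, "S2": 0.10, "SWS": 0.05, "REM": 0.15},
    "S1": {"W": 0.15, "S2": 0.60, "SWS": 0.05, "REM": 0.20},
    "S2": {"W": 0.05, "S1": 0.15, "SWS": 0.50, "REM": 0.30},
    "SWS": {"W": 0.05, "S1": 0.10, "S2": 0.70, "REM": 0.15},
    "REM": {"W": 0.25, "S1": 0.40, "S2": 0.30, "SWS": 0.05},
}

_SELF_TRANSITION = 0.9


def generate_hypnogram(stage_counts: dict[str, int],
                       rng: np.random.Generator) -> list[str]:
    """Arrange the requested stage counts into a sleep-cycle-like sequence.

    A first-order Markov chain with self-transition probability 0.9 biases
    the order toward realistic-looking bouts while the exact per-stage
    counts are preserved. Purely cosmetic; not a physiological model.
    """
    remaining = {s: int(stage_counts.get(s, 0)) for s in STAGES}
    total = sum(remaining.values())
    if total == 0:
        raise ValueError("total epoch count must be positive")
    current = "W" if remaining.get("W", 0) > 0 else max(remaining, key=remaining.get)
    seq = [current]
    remaining[current] -= 1
    for _ in range(total - 1):
        avail = [s for s in STAGES if remaining[s] > 0]
        if not avail:
            break
        weights = []
        for s in avail:
            if s == current:
                w = _SELF_TRANSITION
            else:
                w = (1 - _SELF_TRANSITION) * _TRANSITIONS[current].get(s, 0.01)
            weights.append(max(w, 1e-6))
        weights = np.array(weights) / np.sum(weights)
        current = str(rng.choice(avail, p=weights))
        seq.append(current)
        remaining[current] -= 1
    return seq


def generate_recording(config: SyntheticCohortConfig) -> list[Recording]:
    """Generate one synthetic :class:`Recording` per subject."""
    recordings = []
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    for i in range(config.n_subjects):
        counts = config.stage_counts[i]
        if sum(counts.values()) == 0:
            raise ValueError(f"subject {i + 1} has zero total epochs")
        sub_ss = subject_seeds[i]
        hyp_rng = np.random.default_rng(sub_ss.spawn(1)[0])
        hyp = generate_hypnogram(counts, hyp_rng)
        epoch_seeds = sub_ss.spawn(len(hyp))
        chans: dict[str, list[EpochSignal]] = {"EEG": [], "EOG": [], "EMG": []}
        for stage, ess in zip(hyp, epoch_seeds):
            rng = np.random.default_rng(ess)
            eeg, eog, emg = generate_stage_epoch(
                config.stage_specs[stage], config.fs, config.epoch_len, rng
            )
            chans["EEG"].append(eeg)
            chans["EOG"].append(eog)
            chans["EMG"].append(emg)
        recordings.append(
            Recording(subject_id=f"subject{i + 1}", epochs=chans, hypnogram=hyp)
        )
    return recordings


# ---------------------------------------------------------------------------
# direct feature-table generator


def generate_feature_table(
    n: int,
    k_informative: int,
    k_redundant: int,
    k_noise: int,
    effect: float = 2.0,
    n_classes: int = 5,
    seed: int = 0,
    redundant_noise: float = 0.5,
) -> tuple[FeatureTable, dict[str, list[int]]]:
    """Generate a feature table with known informative/redundant/noise roles.

    Informative columns are unit-variance Gaussians whose class-conditional
    means are separated by ``effect`` standard deviations between adjacent
    class levels (level-to-class assignment randomly permuted per column).
    Redundant columns are noisy linear copies of randomly chosen informative
    parents (additive noise SD ``redundant_noise``). Noise columns are
    class-independent standard Gaussians.

    Returns the table and a role map with keys ``informative``,
    ``redundant``, ``noise`` and ``redundant_parents``.
    """
    if effect < 0:
        raise ValueError("effect must be non-negative")
    if n < n_classes:
        raise ValueError("need at least one sample per class")
    if k_redundant > 0 and k_informative == 0:
        raise ValueError("redundant columns require informative parents")
    rng = np.random.default_rng(seed)
    k = k_informative + k_redundant + k_noise
    stage_labels = list(STAGES)[:n_classes] if n_classes <= len(STAGES) else [
        f"C{c}" for c in range(n_classes)
    ]
    y = rng.integers(0, n_classes, size=n)

    X = np.empty((n, k))
    col = 0
    informative = list(range(k_informative))
    levels = np.arange(n_classes, dtype=float) - (n_classes - 1) / 2.0
    for _ in range(k_informative):
        perm = rng.permutation(n_classes)
        means = effect * levels[perm]
        X[:, col] = means[y] + rng.standard_normal(n)
        col += 1
    redundant = list(range(col, col + k_redundant))
    parents = []
    for _ in range(k_redundant):
        parent = int(rng.integers(0, k_informative))
        parents.append(parent)
        X[:, col] = X[:, parent] + redundant_noise * rng.standard_normal(n)
        col += 1
    noise = list(range(col, col + k_noise))
    for _ in range(k_noise):
        X[:, col] = rng.standard_normal(n)
        col += 1

    names = (
        [f"inf{i + 1}" for i in range(k_informative)]
        + [f"red{i + 1}" for i in range(k_redundant)]
        + [f"noise{i + 1}" for i in range(k_noise)]
    )
    table = FeatureTable(
        values=X,
        feature_names=names,
        labels=np.array([stage_labels[c] for c in y], dtype=object),
        subject_ids=np.array(["synthetic"] * n, dtype=object),
    )
    roles = {
        "informative": informative,
        "redundant": redundant,
        "noise": noise,
        "redundant_parents": parents,
    }
    return table, roles
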