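"""Per-epoch feature extraction: the 49-dimensional PSG feature vector.

The vector spans time-domain statistics, Hjorth parameters, wavelet-packet
band energies and ratios, entropy measures (spectral, Renyi, approximate,
permutation), nonlinear descriptors (Petrosian fractal dimension, Teager
energy, curve length, Hurst exponent, Itakura spectral distance against a
per-subject wake autoregressive model) on the EEG channel, amplitude
statistics and energy on the EOG channel, and spectral/energy features on
the EMG channel.

Layout (F-codes):

====== ======= ==================================================
F1-F8   EEG    min, max, mean, SD, variance, skewness, kurtosis, median
F9      EEG    zero-crossing rate
F10-F12 EEG    Hjorth activity, mobility, complexity
F13-F26 EEG    wavelet-packet: band energies (alpha, delta, beta1, beta2,
               theta, spindle), total energy, five band-energy ratios,
               mean and SD of in-band coefficients
F27-F30 EEG    spectral, Renyi, approximate, permutation entropy
F31-F36 EEG    Petrosian FD, Teager energy, energy, mean curve length,
               Hurst exponent, Itakura spectral distance to wake model
F37-F42 EOG    mean, max, SD, skewness, kurtosis, energy
F43-F46 EMG    total spectral power; max, mean, SD of the PSD
F47-F49 EMG    energy; energy ratio to previous / next epoch
====== ======= ==================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.linalg import solve_toeplitz, toeplitz
from scipy.spatial import cKDTree
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .types import ARModel, EpochSignal, FeatureTable, Recording

FEATURE_NAMES: list[str] = [f"F{i}" for i in range(1, 50)]

FEATURE_DESCRIPTIONS: dict[str, str] = {
    "F1": "EEG minimum", "F2": "EEG maximum", "F3": "EEG mean",
    "F4": "EEG standard deviation", "F5": "EEG variance",
    "F6": "EEG skewness", "F7": "EEG kurtosis", "F8": "EEG median",
    "F9": "EEG zero-crossing rate", "F10": "EEG Hjorth activity",
    "F11": "EEG Hjorth mobility", "F12": "EEG Hjorth complexity",
    "F13": "EEG WP alpha energy", "F14": "EEG WP delta energy",
    "F15": "EEG WP beta1 energy", "F16": "EEG WP beta2 energy",
    "F17": "EEG WP theta energy", "F18": "EEG WP spindle energy",
    "F19": "EEG WP total energy", "F20": "EEG WP alpha/(delta+theta)",
    "F21": "EEG WP delta/(alpha+theta)", "F22": "EEG WP theta/(alpha+delta)",
    "F23": "EEG WP delta/theta", "F24": "EEG WP alpha/theta",
    "F25": "EEG WP coefficient mean", "F26": "EEG WP coefficient SD",
    "F27": "EEG spectral entropy", "F28": "EEG Renyi entropy",
    "F29": "EEG approximate entropy", "F30": "EEG permutation entropy",
    "F31": "EEG Petrosian fractal dimension", "F32": "EEG Teager energy",
    "F33": "EEG energy", "F34": "EEG mean curve length",
    "F35": "EEG Hurst exponent", "F36": "EEG Itakura spectral distance",
    "F37": "EOG mean", "F38": "EOG maximum", "F39": "EOG SD",
    "F40": "EOG skewness", "F41": "EOG kurtosis", "F42": "EOG energy",
    "F43": "EMG total spectral power", "F44": "EMG PSD maximum",
    "F45": "EMG PSD mean", "F46": "EMG PSD SD", "F47": "EMG energy",
    "F48": "EMG energy ratio to previous epoch",
    "F49": "EMG energy ratio to next epoch",
}

#: Default wavelet-packet band edges (Hz) at fs = 100, depth 7
#: (128 leaves of ~0.39 Hz each).
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.39, 3.91),
    "theta": (3.91, 8.20),
    "alpha": (8.20, 12.89),
    "spindle": (11.72, 14.06),
    "beta1": (12.89, 21.88),
    "beta2": (21.88, 35.16),
}


@dataclass
class FeatureConfig:
    """Tunable parameters of the feature extractors.

    apen_m / apen_r: approximate-entropy pattern length and similarity
        threshold (r is a multiple of the epoch SD). Defaults m=2, r=0.2.
    apen_literal: if True, evaluate the printed approximate-entropy
        difference with length-m patterns in both averages instead of the
        standard phi_m - phi_{m+1}.
    renyi_alpha: Renyi entropy order (alpha=2, collision entropy).
    perm_m: permutation-entropy embedding dimension (m-sample windows,
        delay 1).
    wp_level / wp_wavelet: wavelet-packet depth and mother wavelet.
    band_edges: Hz edges of the six wavelet-packet bands.
    ar_order: autoregressive model order for the Itakura distance.
    spectral_entropy_band: [f1, f2] Hz range of the spectral entropy.
    n_hist_bins: amplitude-histogram bins for the Renyi entropy.
    hurst_regression: if True, estimate the Hurst exponent by regressing
        log(R/S) on log(window size) over dyadic windows instead of the
        default single-window ratio.
    """

    apen_m: int = 2
    apen_r: float = 0.2
    apen_literal: bool = False
    renyi_alpha: float = 2.0
    perm_m: int = 3
    wp_level: int = 7
    wp_wavelet: str = "db20"
    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )
    ar_order: int = 8
    spectral_entropy_band: tuple[float, float] = (0.3, 35.0)
    n_hist_bins: int = 16
    hurst_regression: bool = False

    def __post_init__(self) -> None:
        if self.apen_m < 1 or self.apen_r <= 0:
            raise ValueError("apen_m >= 1 and apen_r > 0 required")
        if self.renyi_alpha <= 0 or self.renyi_alpha == 1:
            raise ValueError("renyi_alpha must be positive and != 1")
        if self.perm_m < 2:
            raise ValueError("perm_m >= 2 required")
        for band, (lo, hi) in self.band_edges.items():
            if not lo < hi:
                raise ValueError(f"band {band} edges must increase")


# ---------------------------------------------------------------------------
# time-domain


def statistical_features(x: EpochSignal | np.ndarray) -> np.ndarray:
    """(min, max, mean, SD, variance, skewness, kurtosis, median).

    Population (biased) moments; raw (non-excess) kurtosis; skewness and
    kurtosis of a constant signal are 0 by convention.
    """
    x = _samples(x)
    if x.size == 0:
        raise ValueError("empty epoch")
    var = float(np.var(x))
    if var == 0:
        sk = kt = 0.0
    else:
        sk = float(_skew(x, bias=True))
        kt = float(_kurtosis(x, fisher=False, bias=True))
    return np.array([
        float(np.min(x)), float(np.max(x)), float(np.mean(x)),
        float(np.sqrt(var)), var, sk, kt, float(np.median(x)),
    ])


def zero_crossing_rate(x: EpochSignal | np.ndarray) -> int:
    """Number of sign changes in the epoch."""
    x = _samples(x)
    if x.size == 0:
        raise ValueError("empty epoch")
    s = np.signbit(x)
    return int(np.sum(s[1:] != s[:-1]))


def hjorth(x: EpochSignal | np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility, complexity.

    With sigma_k the variance of the k-th difference: activity =
    sigma_0, mobility = sqrt(sigma_1/sigma_0), complexity =
    sqrt(sigma_2/sigma_1) / sqrt(sigma_1/sigma_0). A zero-variance
    signal maps to (0, 0, 0).
    """
    x = _samples(x)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    s0 = float(np.var(x))
    if s0 == 0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    d2 = np.diff(d1)
    s1 = float(np.var(d1))
    s2 = float(np.var(d2))
    mobility = float(np.sqrt(s1 / s0))
    if s1 == 0:
        return s0, mobility, 0.0
    complexity = float(np.sqrt(s2 / s1) / np.sqrt(s1 / s0))
    return s0, mobility, complexity


# ---------------------------------------------------------------------------
# wavelet packet


def _wp_leaf_coefficients(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Frequency-ordered leaf coefficient arrays of the full WP tree."""
    # periodization keeps the transform (near-)orthogonal: leaf energies
    # sum to the signal energy instead of being inflated by boundary
    # extension coefficients (a 40-tap wavelet at depth 7 would otherwise
    # more than double the coefficient count of a 30-s epoch)
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="periodization",
                            maxlevel=level)
    return [node.data for node in wp.get_level(level, order="freq")]


def _band_leaf_indices(band: tuple[float, float], fs: float, level: int) -> range:
    width = (fs / 2.0) / 2 ** level
    lo = int(round(band[0] / width))
    hi = int(round(band[1] / width))
    return range(lo, hi)


def wavelet_packet_features(x: EpochSignal, cfg: FeatureConfig) -> np.ndarray:
    """The 14 wavelet-packet features (band energies, ratios, statistics).

    Leaves of a depth-``wp_level`` tree are assigned to bands by their
    frequency-ordered index; band energy is the sum of squared
    coefficients over the band's leaves. A zero-energy denominator band
    makes the corresponding ratio 0 (with a warning).
    """
    fs = x.fs
    data = x.samples
    leaves = _wp_leaf_coefficients(data, cfg.wp_wavelet, cfg.wp_level)
    leaf_energy = np.array([float(np.sum(c * c)) for c in leaves])
    bands = {}
    pooled = []
    # canonical band order so results do not depend on dict ordering
    for band in sorted(cfg.band_edges):
        idx = _band_leaf_indices(cfg.band_edges[band], fs, cfg.wp_level)
        bands[band] = float(leaf_energy[list(idx)].sum())
        pooled.extend(leaves[i] for i in idx)
    total = float(leaf_energy.sum())
    pooled_arr = np.concatenate(pooled) if pooled else np.zeros(1)

    def ratio(num: float, den: float) -> float:
        if den == 0:
            if num != 0:
                warnings.warn("zero-energy denominator band; ratio set to 0",
                              RuntimeWarning, stacklevel=2)
            return 0.0
        return num / den

    a, d, t = bands["alpha"], bands["delta"], bands["theta"]
    return np.array([
        a, d, bands["beta1"], bands["beta2"], t, bands["spindle"], total,
        ratio(a, d + t), ratio(d, a + t), ratio(t, a + d),
        ratio(d, t), ratio(a, t),
        float(pooled_arr.mean()), float(pooled_arr.std()),
    ])


# ---------------------------------------------------------------------------
# entropies


def spectral_entropy(x: EpochSignal, cfg: FeatureConfig | None = None) -> float:
    """Normalized Shannon entropy of the power spectrum in [f1, f2].

    The periodogram (Hann window) restricted to the band is normalized to
    a probability vector P; the result is -sum P log P / log(N_f), in
    [0, 1]. An all-zero spectrum returns 0.
    """
    cfg = cfg or FeatureConfig()
    f1, f2 = cfg.spectral_entropy_band
    freqs, psd = sps.periodogram(x.samples, fs=x.fs, window="hann")
    mask = (freqs >= f1) & (freqs <= f2)
    p = psd[mask]
    n_f = p.size
    if n_f < 2:
        raise ValueError("need at least 2 frequency bins in the band")
    total = p.sum()
    if total == 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / np.log(n_f)


def renyi_entropy(x: EpochSignal, cfg: FeatureConfig | None = None) -> float:
    """Renyi entropy of order alpha of the epoch's amplitude distribution.

    The distribution is a ``n_hist_bins``-bin equal-width histogram over
    the epoch's amplitude range. Natural logarithm.
    """
    cfg = cfg or FeatureConfig()
    data = _samples(x)
    if np.ptp(data) == 0:
        return 0.0
    counts, _ = np.histogram(data, bins=cfg.n_hist_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(np.log(np.sum(p ** cfg.renyi_alpha)) / (1.0 - cfg.renyi_alpha))


def _pattern_counts(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """C_i(r): per-window counts of Chebyshev-similar length-m windows."""
    w = np.lib.stride_tricks.sliding_window_view(x, m)
    tree = cKDTree(w)
    return tree.query_ball_point(w, r, p=np.inf, return_length=True)


def approximate_entropy(x: EpochSignal | np.ndarray,
                        cfg: FeatureConfig | None = None) -> float:
    """Approximate entropy ApEn(m, r) with r = apen_r * SD(epoch).

    Computed as phi_m(r) - phi_{m+1}(r) where phi_m is the average log
    fraction of windows within Chebyshev distance r (self-matches
    included, <= r inclusive). With ``apen_literal`` the second average
    also uses length-m counts, restricted to the first N-m windows,
    reproducing the printed difference verbatim.
    """
    cfg = cfg or FeatureConfig()
    data = _samples(x)
    m = cfg.apen_m
    n = data.size
    if n <= m + 1:
        raise ValueError("epoch too short for the chosen pattern length")
    if np.ptp(data) == 0:
        return 0.0
    r = cfg.apen_r * float(np.std(data))
    c_m = _pattern_counts(data, m, r)
    phi_m = float(np.mean(np.log(c_m / (n - m + 1))))
    if cfg.apen_literal:
        phi_next = float(np.mean(np.log(c_m[: n - m] / (n - m + 1))))
    else:
        c_m1 = _pattern_counts(data, m + 1, r)
        phi_next = float(np.mean(np.log(c_m1 / (n - m))))
    return phi_m - phi_next


def permutation_entropy(x: EpochSignal | np.ndarray,
                        cfg: FeatureConfig | None = None) -> float:
    """Bandt-Pompe permutation entropy, m-sample windows, delay 1.

    Ordinal patterns from a stable argsort (ties resolved by order of
    appearance); relative frequencies over the T-m+1 windows; natural
    logarithm. Bounded by log(m!).
    """
    cfg = cfg or FeatureConfig()
    data = _samples(x)
    m = cfg.perm_m
    if data.size < m:
        raise ValueError("epoch shorter than the embedding dimension")
    w = np.lib.stride_tricks.sliding_window_view(data, m)
    patterns = np.argsort(w, axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# nonlinear


def petrosian_fd(x: EpochSignal | np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the derivative."""
    data = _samples(x)
    n = data.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(data)
    s = np.sign(d)
    n_delta = int(np.sum(s[1:] * s[:-1] < 0))
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def teager_energy(x: EpochSignal | np.ndarray) -> float:
    """Mean discrete Teager energy x[n]^2 - x[n-1] x[n+1] over the interior."""
    data = _samples(x)
    if data.size < 3:
        raise ValueError("need at least 3 samples")
    psi = data[1:-1] ** 2 - data[:-2] * data[2:]
    return float(np.mean(psi))


def energy(x: EpochSignal | np.ndarray) -> float:
    """Average of squared samples."""
    data = _samples(x)
    if data.size == 0:
        raise ValueError("empty epoch")
    return float(np.mean(data * data))


def energy_ratio(current: float, neighbor: float | None) -> float:
    """Ratio of the current epoch's energy to a neighbor's.

    Boundary epochs (no neighbor) and zero neighbor energy both yield 1.
    """
    if neighbor is None or neighbor == 0:
        return 1.0
    return current / neighbor


def mean_curve_length(x: EpochSignal | np.ndarray) -> float:
    """Sum of absolute successive differences over the epoch."""
    data = _samples(x)
    if data.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(np.abs(np.diff(data))))


def hurst_exponent(x: EpochSignal | np.ndarray,
                   cfg: FeatureConfig | None = None) -> float:
    """Hurst exponent H = log(R/S) / log(T) from the rescaled range.

    Default: single-window R/S over the mean-centered epoch with T = N.
    With ``hurst_regression`` the slope of log(R/S) against log(window)
    over dyadic window sizes is returned instead. Zero-SD epochs map
    to 0.
    """
    cfg = cfg or FeatureConfig()
    data = _samples(x)
    n = data.size
    if n < 20:
        raise ValueError("need at least 20 samples")
    if not cfg.hurst_regression:
        rs = _rescaled_range(data)
        if rs == 0:
            return 0.0
        return float(np.log(rs) / np.log(n))
    sizes, ratios = [], []
    w = n
    while w >= 20:
        vals = [
            _rescaled_range(data[i: i + w]) for i in range(0, n - w + 1, w)
        ]
        vals = [v for v in vals if v > 0]
        if vals:
            sizes.append(w)
            ratios.append(np.mean(vals))
        w //= 2
    if len(sizes) < 2:
        rs = _rescaled_range(data)
        return float(np.log(rs) / np.log(n)) if rs > 0 else 0.0
    slope = np.polyfit(np.log(sizes), np.log(ratios), 1)[0]
    return float(slope)


def _rescaled_range(x: np.ndarray) -> float:
    s = float(np.std(x))
    if s == 0:
        return 0.0
    z = np.cumsum(x - x.mean())
    r = float(z.max() - z.min())
    return r / s


# ---------------------------------------------------------------------------
# autoregressive modelling / Itakura spectral distance


def yule_walker(x: np.ndarray, order: int) -> np.ndarray:
    """AR(p) coefficients a_1..a_p by the Yule-Walker equations.

    Biased autocovariance estimates (divide by N); returns a with the
    convention x[t] = sum_k a_k x[t-k] + e[t].
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    if n <= order:
        raise ValueError("epoch too short for the AR order")
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] == 0:
        raise ValueError("zero-variance epoch cannot be AR-modelled")
    return solve_toeplitz(r[:-1], r[1:])


def ar_autocovariance(coeffs: np.ndarray, n_lags: int,
                      noise_var: float = 1.0) -> np.ndarray:
    """Theoretical autocovariances r_0..r_{n_lags} of an AR process.

    Solves the linear Yule-Walker system r_k = sum_j a_j r_{|k-j|} +
    noise_var * delta_{k0} exactly.
    """
    a = np.asarray(coeffs, dtype=float)
    p = a.size
    size = max(n_lags, p) + 1
    m = np.eye(size)
    for k in range(size):
        for j in range(1, p + 1):
            m[k, abs(k - j)] -= a[j - 1]
    b = np.zeros(size)
    b[0] = noise_var
    r = np.linalg.solve(m, b)
    return r[: n_lags + 1]


def fit_wake_ar_model(
    wake_epochs: list[EpochSignal],
    cfg: FeatureConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[ARModel, np.ndarray]:
    """Representative wake AR model from a random half of the wake epochs.

    Selects floor(n/2) wake epochs uniformly at random (seeded), fits an
    AR model of order ``ar_order`` to each and averages the coefficients
    elementwise. Returns the model and the selected epoch indices.
    """
    cfg = cfg or FeatureConfig()
    n = len(wake_epochs)
    if n < 2:
        raise ValueError("need at least 2 wake epochs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = n // 2
    selected = np.sort(rng.permutation(n)[:k])
    coefs = np.mean(
        [yule_walker(wake_epochs[i].samples, cfg.ar_order) for i in selected], axis=0
    )
    return ARModel(coefficients=coefs, order=cfg.ar_order, source="wake"), selected


def itakura_spectral_distance(model: ARModel, x: EpochSignal,
                              cfg: FeatureConfig | None = None) -> float:
    """Itakura distance between the reference AR model and an epoch.

    d = log( (a_test' R_ref a_test) / (a_ref' R_ref a_ref) ) with R_ref
    the autocorrelation matrix implied by the reference model and a =
    [1, -a_1, ..., -a_p]. Non-negative because the reference
    coefficients minimize the prediction-error quadratic form of their
    own process.
    """
    data = _samples(x)
    if np.ptp(data) == 0:
        raise ValueError("degenerate (constant) epoch")
    a_test = yule_walker(data, model.order)
    r = ar_autocovariance(model.coefficients, model.order)
    big_r = toeplitz(r)
    u_ref = np.concatenate(([1.0], -model.coefficients))
    u_test = np.concatenate(([1.0], -a_test))
    num = float(u_test @ big_r @ u_test)
    den = float(u_ref @ big_r @ u_ref)
    return float(np.log(num / den))


# ---------------------------------------------------------------------------
# EMG spectral features


def emg_spectral_features(x: EpochSignal) -> np.ndarray:
    """(total power, PSD max, PSD mean, PSD SD) of the EMG periodogram."""
    freqs, psd = sps.periodogram(x.samples, fs=x.fs)
    total = float(np.trapezoid(psd, freqs))
    return np.array([total, float(psd.max()), float(psd.mean()), float(psd.std())])


# ---------------------------------------------------------------------------
# assembly


def extract_epoch_features(
    eeg: EpochSignal | None,
    eog: EpochSignal | None,
    emg: EpochSignal | None,
    neighbors: tuple[float | None, float | None] = (None, None),
    wake_model: ARModel | None = None,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """The ordered 49-feature vector for one synchronized epoch.

    ``neighbors`` holds the EMG energies of the previous and next epoch
    (None at recording boundaries). Raises if a channel is missing.
    """
    cfg = cfg or FeatureConfig()
    for name, ch in (("EEG", eeg), ("EOG", eog), ("EMG", emg)):
        if ch is None:
            raise ValueError(f"missing channel {name}")
    if wake_model is None:
        raise ValueError("missing wake AR model for the Itakura distance")

    stats = statistical_features(eeg)
    act, mob, comp = hjorth(eeg)
    wp = wavelet_packet_features(eeg, cfg)
    eog_stats = statistical_features(eog)
    emg_spec = emg_spectral_features(emg)
    emg_energy = energy(emg)
    prev_e, next_e = neighbors
    vec = np.concatenate([
        stats,                                             # F1-F8
        [zero_crossing_rate(eeg), act, mob, comp],         # F9-F12
        wp,                                                # F13-F26
        [
            spectral_entropy(eeg, cfg),                    # F27
            renyi_entropy(eeg, cfg),                       # F28
            approximate_entropy(eeg, cfg),                 # F29
            permutation_entropy(eeg, cfg),                 # F30
            petrosian_fd(eeg),                             # F31
            teager_energy(eeg),                            # F32
            energy(eeg),                                   # F33
            mean_curve_length(eeg),                        # F34
            hurst_exponent(eeg, cfg),                      # F35
            itakura_spectral_distance(wake_model, eeg, cfg),  # F36
        ],
        [eog_stats[2], eog_stats[1], eog_stats[3],
         eog_stats[5], eog_stats[6], energy(eog)],         # F37-F42
        emg_spec,                                          # F43-F46
        [emg_energy,
         energy_ratio(emg_energy, prev_e),
         energy_ratio(emg_energy, next_e)],                # F47-F49
    ])
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.where(~np.isfinite(vec))[0]]
        raise FloatingPointError(f"non-finite features: {bad}")
    return vec


def extract_features(
    recordings: list[Recording] | Recording,
    cfg: FeatureConfig | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Extract the full feature table for one or more recordings.

    Per subject, a representative wake AR model is fitted on a random
    (seeded) half of the wake epochs before the per-epoch pass. Assumes
    zero-energy epochs were already removed.
    """
    cfg = cfg or FeatureConfig()
    if isinstance(recordings, Recording):
        recordings = [recordings]
    root = np.random.SeedSequence(seed)
    sub_seeds = root.spawn(len(recordings))
    rows, labels, subjects = [], [], []
    for rec, ss in zip(recordings, sub_seeds):
        eeg, eog, emg = rec.channel("EEG"), rec.channel("EOG"), rec.channel("EMG")
        wake_idx = [i for i, s in enumerate(rec.hypnogram) if s == "W"]
        if len(wake_idx) < 2:
            raise ValueError(
                f"subject {rec.subject_id} has fewer than 2 wake epochs"
            )
        model, _ = fit_wake_ar_model(
            [eeg[i] for i in wake_idx], cfg, np.random.default_rng(ss)
        )
        emg_energies = [energy(e) for e in emg]
        n = rec.n_epochs
        for i in range(n):
            prev_e = emg_energies[i - 1] if i > 0 else None
            next_e = emg_energies[i + 1] if i < n - 1 else None
            rows.append(
                extract_epoch_features(
                    eeg[i], eog[i], emg[i], (prev_e, next_e), model, cfg
                )
            )
            labels.append(rec.hypnogram[i])
            subjects.append(rec.subject_id)
    return FeatureTable(
        values=np.array(rows),
        feature_names=list(FEATURE_NAMES),
        labels=np.array(labels, dtype=object),
        subject_ids=np.array(subjects, dtype=object),
    )


def standardize(t: FeatureTable) -> FeatureTable:
    """Scale each column to zero mean and unit variance (population SD).

    Constant columns map to all zeros. Idempotent.
    """
    if t.n_epochs < 2:
        raise ValueError("need at least 2 epochs to standardize")
    mean = t.values.mean(axis=0)
    sd = t.values.std(axis=0)
    out = np.zeros_like(t.values)
    nz = sd > 0
    out[:, nz] = (t.values[:, nz] - mean[nz]) / sd[nz]
    return FeatureTable(
        values=out,
        feature_names=list(t.feature_names),
        labels=t.labels.copy(),
        subject_ids=t.subject_ids.copy(),
    )


def _samples(x: EpochSignal | np.ndarray) -> np.ndarray:
    return x.samples if isinstance(x, EpochSignal) else np.asarray(x, dtype=float)
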