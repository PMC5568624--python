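"""Pipeline orchestration, configuration, I/O and hypnogram utilities.

``run_benchmark`` executes the complete comparison protocol on a
synthetic cohort (or previously extracted feature table): preprocessing,
49-feature extraction, standardization, the seven filter rankers, the
two rank aggregators, and the stability / similarity / accuracy
evaluation with Kneedle optimum selection. All outputs are CSV files in
the configured output directory, together with a YAML run manifest from
which the run can be replayed byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import borda, rra
from .evaluation import (DEFAULT_ACCURACY_D, DEFAULT_STABILITY_D,
                         accuracy_curve, balanced_subject_sampling,
                         similarity_matrix, stability_from_rankings)
from .features import FeatureConfig, extract_features, standardize
from .preprocessing import remove_zero_energy_epochs, segment, wavelet_bandpass
from .ranking import default_rankers
from .synthetic_data import (DEFAULT_STAGE_COUNTS, SyntheticCohortConfig,
                             generate_recording)
from .types import (AccuracyCurve, EpochSignal, FeatureTable, RankedList,
                    Recording, StabilityProfile)

logger = logging.getLogger(__name__)

#: Marker for movement-time epochs that are excluded from analysis.
EXCLUDED = "EXCLUDED"

_RK_TO_AASM = {
    "W": "W", "S1": "S1", "S2": "S2", "S3": "SWS", "S4": "SWS",
    "REM": "REM", "MT": EXCLUDED,
}


def map_rk_to_aasm(stage: str) -> str:
    """Map an R&K hypnogram label to its AASM equivalent.

    Stages 3 and 4 merge into slow-wave sleep; movement time maps to the
    exclusion marker. Unknown labels raise.
    """
    try:
        return _RK_TO_AASM[stage]
    except KeyError:
        raise ValueError(f"unknown R&K stage label {stage!r}") from None


def map_hypnogram(labels: list[str]) -> tuple[list[str], list[int]]:
    """Map a whole R&K hypnogram; returns (AASM labels, excluded indices)."""
    mapped = [map_rk_to_aasm(s) for s in labels]
    excluded = [i for i, s in enumerate(mapped) if s == EXCLUDED]
    if excluded:
        logger.info("excluding %d movement-time epochs", len(excluded))
    return mapped, excluded


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a benchmark run."""

    seed: int = 0
    cohort: SyntheticCohortConfig = field(
        default_factory=lambda: SyntheticCohortConfig()
    )
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    rankers: tuple[str, ...] = (
        "ReliefF", "Fisher", "Chi2", "IG", "CMIM", "MRMR-MID", "MRMR-MIQ"
    )
    aggregators: tuple[str, ...] = ("Borda", "RRA")
    relieff_k: int = 10
    n_bins: int = 10
    filter_band: tuple[float, float] = (0.3, 35.0)
    quota: int = 100
    n_boot: int = 50
    stability_d: tuple[int, ...] = DEFAULT_STABILITY_D
    accuracy_d: tuple[int, ...] = DEFAULT_ACCURACY_D
    n_runs: int = 200
    train_frac: float = 0.7
    classifiers: tuple[str, ...] = ("knn", "mlfn")
    mlfn_hidden: int = 12
    mlfn_max_iter: int = 30
    similarity_d: int = 29
    output_dir: str = "psgrank_output"

    def __post_init__(self) -> None:
        if not self.rankers:
            raise ValueError("at least one ranker must be enabled")
        known = {"ReliefF", "Fisher", "Chi2", "IG", "CMIM", "MRMR-MID", "MRMR-MIQ"}
        unknown = set(self.rankers) - known
        if unknown:
            raise ValueError(f"unknown rankers: {sorted(unknown)}")
        if set(self.aggregators) - {"Borda", "RRA"}:
            raise ValueError("aggregators must be among Borda, RRA")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # stage specs are nested frozen dataclasses; asdict handles them
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synthetic_data import StageSpec
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cd = dict(d["cohort"])
            if "stage_specs" in cd:
                cd["stage_specs"] = {
                    k: StageSpec(**v) if isinstance(v, dict) else v
                    for k, v in cd["stage_specs"].items()
                }
            d["cohort"] = SyntheticCohortConfig(**cd)
        if "feature" in d and isinstance(d["feature"], dict):
            fd = dict(d["feature"])
            if "band_edges" in fd:
                fd["band_edges"] = {
                    k: tuple(v) for k, v in fd["band_edges"].items()
                }
            if "spectral_entropy_band" in fd:
                fd["spectral_entropy_band"] = tuple(fd["spectral_entropy_band"])
            d["feature"] = FeatureConfig(**fd)
        for key in ("rankers", "aggregators", "stability_d", "accuracy_d",
                    "classifiers", "filter_band"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# I/O


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    return FeatureTable.from_frame(pd.read_csv(path))


def write_ranked_list(lst: RankedList, path: str | Path) -> None:
    lst.to_frame().to_csv(path, index=False)


def read_ranked_list(path: str | Path) -> RankedList:
    df = pd.read_csv(path)
    order = df.sort_values("rank")["feature_index"].to_numpy()
    scores = np.empty(len(df))
    scores[df["feature_index"].to_numpy()] = df["score"].to_numpy()
    names_by_idx = dict(zip(df["feature_index"], df["feature_name"]))
    names = [str(names_by_idx[i]) for i in range(len(df))]
    return RankedList(order, scores, str(df["method"].iloc[0]), names)


def read_psg(
    channel_paths: dict[str, str | Path],
    hypnogram_path: str | Path,
    fs: float = 100.0,
    epoch_len: float = 30.0,
    subject_id: str = "subject",
) -> Recording:
    """Assemble a Recording from per-channel sample CSVs and a hypnogram CSV.

    Channel CSVs hold one sample per row (column ``value``); the
    hypnogram CSV has columns ``epoch_index,stage``. The hypnogram length
    must match the epoch count of every channel.
    """
    hyp_df = pd.read_csv(hypnogram_path)
    hyp = [str(s) for s in hyp_df["stage"]]
    epochs: dict[str, list[EpochSignal]] = {}
    for ch, path in channel_paths.items():
        df = pd.read_csv(path)
        col = "value" if "value" in df.columns else df.columns[0]
        x = df[col].to_numpy(dtype=float)
        eps = segment(x, fs, epoch_len, channel=ch)
        if len(eps) != len(hyp):
            raise ValueError(
                f"channel {ch}: {len(eps)} epochs but hypnogram has {len(hyp)} "
                "(unsynchronized signal and hypnogram)"
            )
        epochs[ch] = eps
    return Recording(subject_id=subject_id, epochs=epochs, hypnogram=hyp)


def write_recording(rec: Recording, out_dir: str | Path) -> None:
    """Write a Recording as per-channel sample CSVs plus a hypnogram CSV.

    Inverse of :func:`read_psg` for equal-length epochs: channel files
    ``<subject>_<CH>.csv`` with a ``value`` column, hypnogram
    ``<subject>_hypnogram.csv`` with ``epoch_index,stage``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ch, eps in rec.epochs.items():
        samples = np.concatenate([e.samples for e in eps]) if eps else np.array([])
        pd.DataFrame({"value": samples}).to_csv(
            out_dir / f"{rec.subject_id}_{ch}.csv", index=False
        )
    pd.DataFrame({
        "epoch_index": np.arange(rec.n_epochs),
        "stage": rec.hypnogram,
    }).to_csv(out_dir / f"{rec.subject_id}_hypnogram.csv", index=False)


def read_edf(path: str | Path, channel_map: dict[str, str],
             fs: float = 100.0) -> dict[str, np.ndarray]:
    """Load raw channel arrays from an EDF file (optional dependency).

    ``channel_map`` maps roles (EEG/EOG/EMG) to EDF channel names,
    matched case-insensitively.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    lower = {name.lower(): name for name in raw.ch_names}
    out = {}
    for role, ch in channel_map.items():
        if ch.lower() not in lower:
            raise ValueError(f"channel {ch!r} not found in {path}")
        data = raw.get_data(picks=[lower[ch.lower()]])[0]
        out[role] = np.asarray(data, dtype=float)
    return out


# ---------------------------------------------------------------------------
# pipeline stages


def preprocess_recording(rec: Recording, low: float = 0.3, high: float = 35.0,
                         wavelet: str = "db20") -> tuple[Recording, list[int]]:
    """Zero-energy removal, then wavelet band-pass of EEG and EOG.

    The surviving epochs of each filtered channel are concatenated,
    filtered as one continuous signal and re-segmented, preserving
    epoch/hypnogram alignment. EMG is not band-pass filtered.
    """
    rec, removed = remove_zero_energy_epochs(rec)
    if rec.n_epochs == 0:
        return rec, removed
    fs = rec.epochs["EEG"][0].fs if "EEG" in rec.epochs else list(
        rec.epochs.values())[0][0].fs
    epoch_len = list(rec.epochs.values())[0][0].duration
    new_epochs = {}
    for ch, eps in rec.epochs.items():
        if ch in ("EEG", "EOG"):
            full = np.concatenate([e.samples for e in eps])
            filtered = wavelet_bandpass(full, fs, low, high, wavelet)
            new_epochs[ch] = segment(filtered, fs, epoch_len, channel=ch)
        else:
            new_epochs[ch] = list(eps)
    return Recording(rec.subject_id, new_epochs, list(rec.hypnogram)), removed


@dataclass
class BenchmarkResult:
    """Everything the benchmark computed, plus where it was written."""

    config: PipelineConfig
    ranked_lists: dict[str, RankedList]
    stability: dict[str, StabilityProfile]
    similarity: pd.DataFrame
    curves: dict[tuple[str, str], AccuracyCurve]
    analysis_table: FeatureTable
    output_dir: Path


def _build_lists(tables_rankings: dict[str, RankedList],
                 aggregators: tuple[str, ...]) -> dict[str, RankedList]:
    base = list(tables_rankings.values())
    out = dict(tables_rankings)
    if "Borda" in aggregators:
        out["Borda"] = borda(base)
    if "RRA" in aggregators:
        out["RRA"] = rra(base)
    return out


def run_benchmark(config: PipelineConfig,
                  recordings: list[Recording] | None = None) -> BenchmarkResult:
    """Execute the full comparison pipeline and write the report bundle.

    Stages: synthesize (or accept) recordings -> preprocess -> extract
    the 49 features -> standardize -> balanced per-subject sampling ->
    rank (7 methods) -> aggregate (Borda, RRA) -> stability, similarity
    and accuracy evaluation with Kneedle optima. Fully deterministic
    given the config.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    seed_of = {name: int(s.generate_state(1)[0] % (2 ** 31))
               for name, s in zip(
                   ("features", "sampling", "stability", "accuracy", "extra"),
                   seeds)}

    stage = "synthesis"
    try:
        if recordings is None:
            recordings = generate_recording(config.cohort)

        stage = "preprocessing"
        low, high = config.filter_band
        processed = []
        for rec in recordings:
            clean, removed = preprocess_recording(
                rec, low, high, config.feature.wp_wavelet
            )
            if removed:
                logger.info("%s: removed %d zero-energy epochs",
                            rec.subject_id, len(removed))
            processed.append(clean)

        stage = "feature extraction"
        full_table = extract_features(processed, config.feature,
                                      seed=seed_of["features"])

        stage = "standardization"
        std_table = standardize(full_table)
        write_feature_table(std_table, out_dir / "features.csv")

        stage = "balanced sampling"
        per_subject = [
            std_table.subset_rows(np.where(std_table.subject_ids == sid)[0])
            for sid in dict.fromkeys(std_table.subject_ids)
        ]
        analysis = balanced_subject_sampling(
            per_subject, config.quota, seed=seed_of["sampling"]
        )

        stage = "ranking"
        rankers = {
            name: r for name, r in default_rankers(
                config.relieff_k, config.n_bins).items()
            if name in config.rankers
        }
        base_lists = {name: r(analysis) for name, r in rankers.items()}
        lists = _build_lists(base_lists, config.aggregators)
        lists_dir = out_dir / "ranked_lists"
        lists_dir.mkdir(exist_ok=True)
        for name, lst in lists.items():
            write_ranked_list(lst, lists_dir / f"{name}.csv")

        stage = "stability"
        rng = np.random.default_rng(seed_of["stability"])
        n = analysis.n_epochs
        replicate_lists: dict[str, list[RankedList]] = {k: [] for k in lists}
        for _ in range(config.n_boot):
            idx = rng.integers(0, n, size=n)
            rep = standardize(analysis.subset_rows(idx))
            rep_base = {name: r(rep) for name, r in rankers.items()}
            for name, lst in _build_lists(rep_base, config.aggregators).items():
                replicate_lists[name].append(lst)
        d_stab = config.stability_d
        stability = {
            name: StabilityProfile(
                method=name,
                d_values=np.asarray(d_stab, dtype=int),
                stability=stability_from_rankings(reps, d_stab),
            )
            for name, reps in replicate_lists.items()
        }
        pd.concat([p.to_frame() for p in stability.values()]).to_csv(
            out_dir / "stability.csv", index=False
        )
        summary = pd.DataFrame({
            name: {
                f"mean_up_to_{dmax}": prof.mean_up_to(dmax)
                for dmax in (5, 13, 29)
            }
            for name, prof in stability.items()
        })
        summary.to_csv(out_dir / "stability_summary.csv")

        stage = "similarity"
        names = list(lists)
        sim = similarity_matrix([lists[k] for k in names],
                                d=config.similarity_d)
        sim_df = pd.DataFrame(sim, index=names, columns=names)
        sim_df.to_csv(out_dir / "similarity.csv")

        stage = "accuracy"
        curves: dict[tuple[str, str], AccuracyCurve] = {}
        acc_seed = seed_of["accuracy"]
        for name, lst in lists.items():
            for clf in config.classifiers:
                curves[(name, clf)] = accuracy_curve(
                    analysis, lst, classifier=clf,
                    d_values=config.accuracy_d, n_runs=config.n_runs,
                    train_frac=config.train_frac, seed=acc_seed,
                    mlfn_kwargs={"n_hidden": config.mlfn_hidden,
                                 "max_iter": config.mlfn_max_iter},
                )
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out_dir / "accuracy_curves.csv", index=False
        )
        top10 = pd.DataFrame({
            name: [lst.feature_names[i] if lst.feature_names else f"F{i + 1}"
                   for i in lst.order[:10]]
            for name, lst in lists.items()
        })
        top10.index = [f"top{i + 1}" for i in range(10)]
        optima = pd.DataFrame({
            name: {
                f"optimum_d_{clf}": curves[(name, clf)].optimum_d
                for clf in config.classifiers
            } | {
                f"accuracy_at_optimum_{clf}":
                    curves[(name, clf)].accuracy_at(curves[(name, clf)].optimum_d)
                for clf in config.classifiers
            }
            for name in lists
        })
        top10.to_csv(out_dir / "top10.csv")
        optima.to_csv(out_dir / "optima.csv")

        stage = "manifest"
        import pywt
        import scipy
        import sklearn
        manifest = {
            "config": _plain(config.to_dict()),
            "package_version": __version__,
            "library_versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "pywavelets": pywt.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    except Exception:
        logger.error("pipeline failed during stage: %s", stage)
        raise

    return BenchmarkResult(
        config=config,
        ranked_lists=lists,
        stability=stability,
        similarity=sim_df,
        curves=curves,
        analysis_table=analysis,
        output_dir=out_dir,
    )


def replay_manifest(manifest_path: str | Path,
                    output_dir: str | Path | None = None) -> BenchmarkResult:
    """Re-run a benchmark from its manifest; reproduces outputs exactly."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    if output_dir is not None:
        config.output_dir = str(output_dir)
    return run_benchmark(config)
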