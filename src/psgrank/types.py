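"""Core data containers shared across the pipeline.

All containers are plain dataclasses around numpy arrays; the feature
matrix additionally round-trips to/from :class:`pandas.DataFrame` for CSV
interchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical sleep-stage labels (AASM naming, SWS = N3).
STAGES: tuple[str, ...] = ("W", "S1", "S2", "SWS", "REM")

#: Channel roles handled by the pipeline.
CHANNELS: tuple[str, ...] = ("EEG", "EOG", "EMG")


@dataclass(frozen=True)
class EpochSignal:
    """One channel's samples for a single 30-s epoch."""

    samples: np.ndarray
    fs: float
    channel: str = "EEG"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass
class Recording:
    """Per-subject synchronized multi-channel epochs plus hypnogram.

    ``epochs`` maps a channel role ("EEG"/"EOG"/"EMG") to a list of
    :class:`EpochSignal`, all index-aligned with ``hypnogram``.
    """

    subject_id: str
    epochs: dict[str, list[EpochSignal]]
    hypnogram: list[str]

    def __post_init__(self) -> None:
        n = len(self.hypnogram)
        for ch, eps in self.epochs.items():
            if len(eps) != n:
                raise ValueError(
                    f"channel {ch!r} has {len(eps)} epochs but hypnogram has {n}"
                )

    @property
    def n_epochs(self) -> int:
        return len(self.hypnogram)

    def channel(self, name: str) -> list[EpochSignal]:
        if name not in self.epochs:
            raise KeyError(f"missing channel {name!r}")
        return self.epochs[name]


@dataclass
class FeatureTable:
    """Epochs x features numeric matrix with stage labels and subject ids."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("labels length must match row count")
        if self.values.shape[0] != self.subject_ids.size:
            raise ValueError("subject_ids length must match row count")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["stage"] = self.labels
        df["subject"] = self.subject_ids
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        meta = [c for c in ("stage", "subject") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        return cls(
            values=df[feats].to_numpy(dtype=float),
            feature_names=list(feats),
            labels=df["stage"].to_numpy() if "stage" in meta else np.array([""] * len(df)),
            subject_ids=df["subject"].to_numpy() if "subject" in meta else np.array([""] * len(df)),
        )


@dataclass
class RankedList:
    """An ordering of feature indices, best first, with per-feature scores.

    ``order[0]`` is the index of the top-ranked feature. ``scores`` is
    indexed by feature (not by rank position).
    """

    order: np.ndarray
    scores: np.ndarray
    method: str
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.order.size
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of feature indices")
        if self.scores.size != n:
            raise ValueError("scores must have one entry per feature")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_features(self) -> int:
        return self.order.size

    def top(self, d: int) -> set[int]:
        if d > self.n_features:
            raise ValueError(f"d={d} exceeds feature count {self.n_features}")
        return set(self.order[:d].tolist())

    def position(self, feature: int) -> int:
        """1-based rank position of ``feature`` (1 = best)."""
        return int(np.where(self.order == feature)[0][0]) + 1

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"F{i + 1}" for i in range(self.n_features)]
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_features + 1),
                "feature_index": self.order,
                "feature_name": [names[i] for i in self.order],
                "score": self.scores[self.order],
                "method": self.method,
            }
        )


@dataclass
class ARModel:
    """Monic autoregressive model a(z) = 1 - a_1 z^-1 - ... - a_p z^-p."""

    coefficients: np.ndarray
    order: int
    source: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != self.order:
            raise ValueError("order must equal number of coefficients")


@dataclass
class StabilityProfile:
    """Mean pairwise Tanimoto overlap of top-d sets per subset size d."""

    method: str
    d_values: np.ndarray
    stability: np.ndarray

    def __post_init__(self) -> None:
        self.d_values = np.asarray(self.d_values, dtype=int)
        self.stability = np.asarray(self.stability, dtype=float)
        if np.any((self.stability < -1e-12) | (self.stability > 1 + 1e-12)):
            raise ValueError("stability values must lie in [0, 1]")

    def mean_up_to(self, d_max: int) -> float:
        mask = self.d_values <= d_max
        return float(self.stability[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"method": self.method, "d": self.d_values, "stability": self.stability}
        )


@dataclass
class AccuracyCurve:
    """Mean validation accuracy as a function of the number of top features."""

    method: str
    classifier: str
    d_values: np.ndarray
    accuracy: np.ndarray
    optimum_d: int | None = None

    def __post_init__(self) -> None:
        self.d_values = np.asarray(self.d_values, dtype=int)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracy values must lie in [0, 1]")

    def accuracy_at(self, d: int) -> float:
        return float(self.accuracy[self.d_values == d][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "classifier": self.classifier,
                "d": self.d_values,
                "accuracy": self.accuracy,
                "optimum_d": self.optimum_d,
            }
        )
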