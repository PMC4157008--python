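"""Conjunctive threshold rule classifier and the Gmean fitness.

A rule model is a 14-bit feature mask plus one decision threshold per
feature. A candidate is a predicted peak iff every *selected* feature value
is greater than or equal to its threshold. An empty mask is a vacuous
conjunction and predicts peak for everything (self-penalizing through the
true-non-peak rate during training).

Fitness is the geometric mean of the true-peak rate and the true-non-peak
rate, sqrt(TPR * TNR); zero-denominator rates are defined as 0 so the fitness
is total. ``literal_gmean=True`` returns the plain product TPR * TNR instead
(a monotone-equivalent variant).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from peakswarm.candidates import PeakCandidate
from peakswarm.features import FEATURE_NAMES, N_FEATURES
from peakswarm.signal_io import AnnotationSet

__all__ = [
    "RuleModel",
    "ConfusionCounts",
    "classify",
    "classify_matrix",
    "label_candidates",
    "confusion",
    "gmean",
]


@dataclass(frozen=True)
class RuleModel:
    """A decoded particle: feature mask + per-feature decision thresholds."""

    mask: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool).reshape(-1)
        th = np.asarray(self.thresholds, dtype=float).reshape(-1)
        if mask.size != N_FEATURES or th.size != N_FEATURES:
            raise ValueError(f"mask and thresholds must have length {N_FEATURES}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "thresholds", th)

    @property
    def selected(self) -> tuple[int, ...]:
        """Selected features as 1-based feature numbers."""
        return tuple(int(i) + 1 for i in np.flatnonzero(self.mask))

    def to_dict(self, config: dict | None = None) -> dict:
        d = {
            "mask": self.mask.astype(int).tolist(),
            "thresholds": self.thresholds.tolist(),
            "selected_features": [FEATURE_NAMES[i - 1] for i in self.selected],
        }
        if config:
            d["config"] = dict(config)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RuleModel":
        return cls(np.asarray(d["mask"]), np.asarray(d["thresholds"]))

    def save(self, path: str | Path, config: dict | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(config), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RuleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def classify(fv: Sequence[float] | np.ndarray, model: RuleModel) -> bool:
    """Peak iff ``fv[i] >= threshold[i]`` for every selected feature i."""
    fv = np.asarray(fv, dtype=float)
    return bool(np.all(fv[model.mask] >= model.thresholds[model.mask]))


def classify_matrix(features: np.ndarray, model: RuleModel) -> np.ndarray:
    """Vectorized :func:`classify` over a (n, 14) feature matrix."""
    features = np.asarray(features, dtype=float)
    if not model.mask.any():
        return np.ones(features.shape[0], dtype=bool)
    return (features[:, model.mask] >= model.thresholds[model.mask]).all(axis=1)


def label_candidates(
    candidates: Sequence[PeakCandidate],
    annotations: AnnotationSet,
    tolerance: int = 0,
) -> np.ndarray:
    """Binary ground-truth labels for candidates against annotated peaks.

    A candidate is positive iff some annotation lies within ``tolerance``
    samples of its peak point; each annotation is consumed by at most one
    candidate (the nearest peak point wins, earlier index breaks ties).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pps = np.asarray([c.pp for c in candidates], dtype=np.int64)
    labels = np.zeros(pps.size, dtype=np.int8)
    for a in annotations.indices.tolist():
        if pps.size == 0:
            break
        dist = np.abs(pps - a)
        best = int(np.argmin(dist))  # argmin takes the earliest on ties
        if dist[best] <= tolerance:
            labels[best] = 1
    return labels


def confusion(predictions: Sequence[int] | np.ndarray, labels: Sequence[int] | np.ndarray) -> ConfusionCounts:
    """Standard 2x2 tally of binary predictions against binary labels."""
    preds = np.asarray(predictions, dtype=bool).reshape(-1)
    labs = np.asarray(labels, dtype=bool).reshape(-1)
    if preds.size != labs.size:
        raise ValueError(f"length mismatch: {preds.size} predictions vs {labs.size} labels")
    return ConfusionCounts(
        tp=int(np.count_nonzero(preds & labs)),
        tn=int(np.count_nonzero(~preds & ~labs)),
        fp=int(np.count_nonzero(preds & ~labs)),
        fn=int(np.count_nonzero(~preds & labs)),
    )


def gmean(counts: ConfusionCounts, literal: bool = False) -> float:
    """sqrt(TPR * TNR), with zero-denominator rates defined as 0.

    ``literal=True`` returns the plain product TPR * TNR.
    """
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    tpr = counts.tp / pos if pos else 0.0
    tnr = counts.tn / neg if neg else 0.0
    prod = tpr * tnr
    return prod if literal else math.sqrt(prod)
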