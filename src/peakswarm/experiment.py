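"""Multi-run training/testing experiments and their aggregate reports.

An experiment splits a labelled recording into train/test partitions, runs
candidate detection + feature extraction once, then trains a rule model per
independent run (re-seeding only the optimizer) and scores it on the test
partition. Two modes exist: ``fixed-model`` freezes the feature mask to a
named peak-model subset and optimizes thresholds only; ``select`` optimizes
mask and thresholds jointly. Aggregates are average / max / min / sample
standard deviation of the per-run Gmean values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from peakswarm.candidates import detect_candidates
from peakswarm.classifier import (
    ConfusionCounts,
    RuleModel,
    classify_matrix,
    confusion,
    gmean,
    label_candidates,
)
from peakswarm.features import (
    DEFAULT_MAC_WINDOW,
    N_FEATURES,
    extract_feature_matrix,
    model_subset,
)
from peakswarm.pso import SwarmConfig, run_rapso, run_standard_pso
from peakswarm.signal_io import AnnotationSet, Signal, split_recording

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "ExperimentReport",
    "PAPER_BUDGET",
    "aggregate",
    "run_experiment",
]

ALGORITHMS = ("pso", "rapso")
MODES = ("dumpala", "acir", "liu", "dingle", "select")

#: The reference full-scale budget (10 runs of 30 particles x 1000 iterations).
PAPER_BUDGET = {"n_runs": 10, "n_particles": 30, "k_max": 1000}


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment-level knobs; defaults are the desk-scale CI budget."""

    algorithm: str = "pso"
    mode: str = "select"
    n_runs: int = 3
    n_particles: int = 30
    k_max: int = 200
    boundary: Optional[int] = None
    tolerance: int = 0
    mac_window: int = DEFAULT_MAC_WINDOW
    literal_f12: bool = False
    literal_gmean: bool = False
    literal_ranges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class RunResult:
    run: int
    algorithm: str
    model: RuleModel
    train_counts: ConfusionCounts
    train_gmean: float
    test_counts: ConfusionCounts
    test_gmean: float
    history: np.ndarray


def aggregate(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(average, max, min, sample standard deviation) of run-level scores.

    Uses the n-1 (sample) convention; a single run has stdev 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty sequence of runs")
    stdev = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), float(v.max()), float(v.min()), stdev


@dataclass(frozen=True)
class ExperimentReport:
    config: ExperimentConfig
    runs: tuple[RunResult, ...]
    n_train_candidates: int
    n_test_candidates: int

    @property
    def train_gmeans(self) -> np.ndarray:
        return np.asarray([r.train_gmean for r in self.runs])

    @property
    def test_gmeans(self) -> np.ndarray:
        return np.asarray([r.test_gmean for r in self.runs])

    def aggregates(self) -> dict[str, tuple[float, float, float, float]]:
        return {
            "train": aggregate(self.train_gmeans),
            "test": aggregate(self.test_gmeans),
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-run rows followed by AVG/MAX/MIN/STDEV aggregate rows."""
        rows = []
        for r in self.runs:
            rows.append(
                {
                    "run": str(r.run),
                    "algorithm": r.algorithm,
                    "selected_features": "+".join(f"f{i}" for i in r.model.selected) or "-",
                    "thresholds": ";".join(
                        f"th{i}={r.model.thresholds[i - 1]:.4g}" for i in r.model.selected
                    )
                    or "-",
                    "train_gmean": r.train_gmean,
                    "train_tp": r.train_counts.tp,
                    "train_tn": r.train_counts.tn,
                    "train_fp": r.train_counts.fp,
                    "train_fn": r.train_counts.fn,
                    "test_gmean": r.test_gmean,
                    "test_tp": r.test_counts.tp,
                    "test_tn": r.test_counts.tn,
                    "test_fp": r.test_counts.fp,
                    "test_fn": r.test_counts.fn,
                }
            )
        agg = self.aggregates()
        for stat_i, stat in enumerate(("AVG", "MAX", "MIN", "STDEV")):
            rows.append(
                {
                    "run": stat,
                    "algorithm": self.config.algorithm,
                    "selected_features": "-",
                    "thresholds": "-",
                    "train_gmean": agg["train"][stat_i],
                    "test_gmean": agg["test"][stat_i],
                }
            )
        return pd.DataFrame(rows)


def _score(model: RuleModel, features: np.ndarray, labels: np.ndarray,
           literal_gmean: bool) -> tuple[ConfusionCounts, float]:
    counts = confusion(classify_matrix(features, model), labels)
    return counts, gmean(counts, literal=literal_gmean)


def run_experiment(
    signal: Signal,
    annotations: AnnotationSet,
    cfg: ExperimentConfig,
) -> ExperimentReport:
    """Run ``cfg.n_runs`` independently seeded training runs and score each
    trained model on the held-out test partition."""
    boundary = cfg.boundary if cfg.boundary is not None else len(signal) // 2
    (tr_sig, tr_ann), (te_sig, te_ann) = split_recording(signal, annotations, boundary)

    tr_cands = detect_candidates(tr_sig)
    if not tr_cands:
        raise ValueError("no peak candidates in the training partition")
    te_cands = detect_candidates(te_sig)
    tr_F = extract_feature_matrix(tr_sig, tr_cands, cfg.mac_window, cfg.literal_f12)
    te_F = extract_feature_matrix(te_sig, te_cands, cfg.mac_window, cfg.literal_f12)
    tr_y = label_candidates(tr_cands, tr_ann, cfg.tolerance)
    te_y = label_candidates(te_cands, te_ann, cfg.tolerance)

    fixed_mask = None
    if cfg.mode != "select":
        subset = model_subset(cfg.mode)
        fixed_mask = np.zeros(N_FEATURES, dtype=bool)
        fixed_mask[[i - 1 for i in subset]] = True

    runner = run_standard_pso if cfg.algorithm == "pso" else run_rapso
    algo_name = "synchronous" if cfg.algorithm == "pso" else "random_asynchronous"

    results = []
    for r in range(cfg.n_runs):
        swarm_cfg = SwarmConfig(
            n_particles=cfg.n_particles,
            k_max=cfg.k_max,
            literal_ranges=cfg.literal_ranges,
            fixed_mask=fixed_mask,
            seed=cfg.seed + r,  # fixed per-run seed increments
            algorithm=algo_name,
        )
        model, history = runner(tr_F, tr_y, swarm_cfg, literal_gmean=cfg.literal_gmean)
        tr_counts, tr_g = _score(model, tr_F, tr_y, cfg.literal_gmean)
        te_counts, te_g = _score(model, te_F, te_y, cfg.literal_gmean)
        results.append(
            RunResult(
                run=r + 1,
                algorithm=cfg.algorithm,
                model=model,
                train_counts=tr_counts,
                train_gmean=tr_g,
                test_counts=te_counts,
                test_gmean=te_g,
                history=history,
            )
        )
    return ExperimentReport(
        config=cfg,
        runs=tuple(results),
        n_train_candidates=len(tr_cands),
        n_test_candidates=len(te_cands),
    )
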