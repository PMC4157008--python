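"""Hybrid binary/continuous particle swarm optimization.

A particle holds 14 binary dimensions (the feature mask) followed by 14
continuous dimensions (the decision thresholds). Binary dimensions move by
the v-shaped transfer rule — flip the bit with probability |tanh(v)| — and
continuous dimensions by plain position addition clipped into their search
ranges. Two update schedules are provided:

* synchronous ("standard"): evaluate the whole population, update all
  personal/global bests, then move every particle;
* random-asynchronous ("RA"): per iteration draw N particle indices
  uniformly with replacement (some particles may be picked repeatedly, others
  not at all); each drawn particle is evaluated and moved immediately using
  the continuously updated global best.

Both variants start from uniform random positions, zero velocities and
best-score sentinels of 0, record the global best fitness once per iteration,
and replace the global best only on strict improvement (ties keep the
incumbent), so the recorded history is non-decreasing and seeded runs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from peakswarm.classifier import RuleModel
from peakswarm.features import N_FEATURES

__all__ = [
    "AMPLITUDE_RANGE",
    "WIDTH_RANGE",
    "SLOPE_RANGE",
    "SwarmConfig",
    "SwarmState",
    "threshold_ranges",
    "inertia",
    "transfer",
    "velocity_update",
    "position_update_continuous",
    "position_update_binary",
    "make_gmean_fitness",
    "run_swarm",
    "run_standard_pso",
    "run_rapso",
]

# Threshold search ranges per feature category.
AMPLITUDE_RANGE = (0.0, 30.0)
WIDTH_RANGE = (0.0, 781.25)
SLOPE_RANGE = (0.0, 24.16)

#: ``fitness(bits, thresholds) -> float`` over a decoded particle.
Fitness = Callable[[np.ndarray, np.ndarray], float]


def threshold_ranges(literal: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-threshold (lo, hi) arrays of length 14.

    Default assignment is by feature category: amplitudes th1–th5, widths
    th6–th10, slopes th11–th14. ``literal=True`` instead maps the width range
    onto th6–th12 and the slope range onto th13–th14 (the published index
    layout, physically incoherent for th11/th12 but kept reproducible).
    """
    lo = np.zeros(N_FEATURES)
    hi = np.empty(N_FEATURES)
    hi[0:5] = AMPLITUDE_RANGE[1]
    if literal:
        hi[5:12] = WIDTH_RANGE[1]
        hi[12:14] = SLOPE_RANGE[1]
    else:
        hi[5:10] = WIDTH_RANGE[1]
        hi[10:14] = SLOPE_RANGE[1]
    return lo, hi


@dataclass
class SwarmConfig:
    """Swarm hyperparameters and search-space definition.

    The defaults reproduce the reference setup: 30 particles, 1000
    iterations, c1 = c2 = 2, inertia 0.9 -> 0.4, binary v_max = 6.
    Continuous velocity clamping is 0.2x the range width per dimension.
    ``fixed_mask`` freezes the binary half (threshold-only optimization of a
    named peak model); ``n_bits`` / explicit ranges support generic harnesses.
    """

    n_particles: int = 30
    k_max: int = 1000
    c1: float = 2.0
    c2: float = 2.0
    w_max: float = 0.9
    w_min: float = 0.4
    v_max_binary: float = 6.0
    v_max_fraction: float = 0.2
    n_bits: int = N_FEATURES
    lo: Optional[np.ndarray] = None
    hi: Optional[np.ndarray] = None
    literal_ranges: bool = False
    per_dimension_r: bool = False
    fixed_mask: Optional[np.ndarray] = None
    seed: Optional[int] = None
    algorithm: str = "synchronous"

    def __post_init__(self) -> None:
        if self.lo is None or self.hi is None:
            if self.n_bits != N_FEATURES:
                raise ValueError("explicit lo/hi ranges required when n_bits != 14")
            self.lo, self.hi = threshold_ranges(self.literal_ranges)
        self.lo = np.asarray(self.lo, dtype=float).reshape(-1)
        self.hi = np.asarray(self.hi, dtype=float).reshape(-1)
        if self.lo.size != self.hi.size or np.any(self.hi < self.lo):
            raise ValueError("invalid threshold ranges")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if not (0 < self.w_min <= self.w_max):
            raise ValueError("need 0 < w_min <= w_max")
        if self.algorithm not in ("synchronous", "random_asynchronous"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.fixed_mask is not None:
            mask = np.asarray(self.fixed_mask, dtype=bool).reshape(-1)
            if mask.size != self.n_bits:
                raise ValueError(f"fixed_mask must have length {self.n_bits}")
            self.fixed_mask = mask

    @property
    def n_cont(self) -> int:
        return int(self.lo.size)

    @property
    def v_max(self) -> np.ndarray:
        """Per-dimension velocity clamp over [binary | continuous] dims."""
        return np.concatenate(
            [
                np.full(self.n_bits, self.v_max_binary),
                self.v_max_fraction * (self.hi - self.lo),
            ]
        )


@dataclass
class SwarmState:
    """Mutable swarm state: positions, velocities, bests and history."""

    bits: np.ndarray            # (N, n_bits) in {0, 1}
    cont: np.ndarray            # (N, n_cont) within [lo, hi]
    vel: np.ndarray             # (N, n_bits + n_cont)
    pbest_bits: np.ndarray
    pbest_cont: np.ndarray
    pbest_score: np.ndarray     # (N,)
    gbest_bits: np.ndarray
    gbest_cont: np.ndarray
    gbest_score: float
    iteration: int
    history: list[float] = field(default_factory=list)


def inertia(k: int, cfg: SwarmConfig) -> float:
    """Linearly decreasing inertia weight: w_max at k=0, w_min at k=k_max."""
    if cfg.k_max == 0:
        return cfg.w_max
    return cfg.w_max - (cfg.w_max - cfg.w_min) / cfg.k_max * k


def transfer(v: float | np.ndarray) -> float | np.ndarray:
    """V-shaped transfer function |tanh(v)|, mapping velocity to [0, 1)."""
    return np.abs(np.tanh(v))


def velocity_update(
    v: np.ndarray,
    x: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    w: float,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
    c1: float = 2.0,
    c2: float = 2.0,
    v_max: Optional[np.ndarray] = None,
) -> np.ndarray:
    """w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x), clamped to +/- v_max."""
    out = w * np.asarray(v, dtype=float) + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
    if v_max is not None:
        np.clip(out, -v_max, v_max, out=out)
    return out


def position_update_continuous(
    x: float | np.ndarray,
    v: float | np.ndarray,
    lo: float | np.ndarray,
    hi: float | np.ndarray,
) -> float | np.ndarray:
    """x + v, clipped into [lo, hi]."""
    return np.clip(x + v, lo, hi)


def position_update_binary(
    bit: int | np.ndarray,
    v: float | np.ndarray,
    u: float | np.ndarray,
) -> int | np.ndarray:
    """Flip the bit when u < |tanh(v)|; keep it otherwise."""
    return np.where(u < transfer(v), 1 - np.asarray(bit), bit)


def make_gmean_fitness(
    features: np.ndarray,
    labels: np.ndarray,
    literal_gmean: bool = False,
) -> Fitness:
    """Fitness closure: decode (bits, thresholds), classify all rows, Gmean."""
    F = np.ascontiguousarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool).reshape(-1)
    if F.shape[0] != y.size:
        raise ValueError("feature matrix and labels disagree in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos

    def fitness(bits: np.ndarray, thresholds: np.ndarray) -> float:
        mask = bits.astype(bool)
        if mask.any():
            preds = (F[:, mask] >= thresholds[mask]).all(axis=1)
        else:
            preds = np.ones(y.size, dtype=bool)
        tp = int(np.count_nonzero(preds & y))
        fp = int(np.count_nonzero(preds)) - tp
        tn = n_neg - fp
        tpr = tp / n_pos if n_pos else 0.0
        tnr = tn / n_neg if n_neg else 0.0
        prod = tpr * tnr
        return prod if literal_gmean else math.sqrt(prod)

    return fitness


def _init_state(cfg: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    n, nb, nc = cfg.n_particles, cfg.n_bits, cfg.n_cont
    if cfg.fixed_mask is not None:
        bits = np.tile(cfg.fixed_mask.astype(np.int8), (n, 1))
    else:
        bits = rng.integers(0, 2, size=(n, nb), dtype=np.int8)
    cont = rng.uniform(cfg.lo, cfg.hi, size=(n, nc))
    return SwarmState(
        bits=bits,
        cont=cont,
        vel=np.zeros((n, nb + nc)),
        pbest_bits=bits.copy(),
        pbest_cont=cont.copy(),
        pbest_score=np.zeros(n),
        gbest_bits=bits[0].copy(),
        gbest_cont=cont[0].copy(),
        gbest_score=0.0,
        iteration=0,
    )


def _evaluate(state: SwarmState, i: int, fitness: Fitness) -> None:
    score = float(fitness(state.bits[i], state.cont[i]))
    if score > state.pbest_score[i]:
        state.pbest_score[i] = score
        state.pbest_bits[i] = state.bits[i]
        state.pbest_cont[i] = state.cont[i]
    if score > state.gbest_score:  # strict: ties keep the incumbent
        state.gbest_score = score
        state.gbest_bits = state.bits[i].copy()
        state.gbest_cont = state.cont[i].copy()


def _move(state: SwarmState, i: int, w: float, cfg: SwarmConfig, rng: np.random.Generator) -> None:
    nb = cfg.n_bits
    d = nb + cfg.n_cont
    if cfg.per_dimension_r:
        r1, r2 = rng.random(d), rng.random(d)
    else:
        r1, r2 = float(rng.random()), float(rng.random())
    x = np.concatenate([state.bits[i], state.cont[i]])
    p = np.concatenate([state.pbest_bits[i], state.pbest_cont[i]])
    g = np.concatenate([state.gbest_bits, state.gbest_cont])
    v = velocity_update(state.vel[i], x, p, g, w, r1, r2, cfg.c1, cfg.c2, cfg.v_max)
    state.vel[i] = v
    state.cont[i] = position_update_continuous(state.cont[i], v[nb:], cfg.lo, cfg.hi)
    if cfg.fixed_mask is None and nb:
        u = rng.random(nb)
        state.bits[i] = position_update_binary(state.bits[i], v[:nb], u).astype(np.int8)


def run_swarm(fitness: Fitness, cfg: SwarmConfig) -> SwarmState:
    """Run the configured swarm and return its final state.

    Iteration 0 evaluates the freshly initialized population without moving
    it (so ``k_max=0`` returns the best of the initial population); each of
    the following ``k_max`` iterations evaluates and moves particles per the
    configured schedule. The global best fitness is appended to
    ``state.history`` once per iteration.
    """
    rng = np.random.default_rng(cfg.seed)
    state = _init_state(cfg, rng)
    n = cfg.n_particles
    synchronous = cfg.algorithm == "synchronous"
    for i in range(n):
        _evaluate(state, i, fitness)
    state.history.append(state.gbest_score)
    for k in range(cfg.k_max):
        w = inertia(k, cfg)
        if synchronous:
            for i in range(n):
                _move(state, i, w, cfg, rng)
            for i in range(n):
                _evaluate(state, i, fitness)
        else:
            drawn = rng.integers(0, n, size=n)
            for i in drawn.tolist():
                _evaluate(state, i, fitness)
                _move(state, i, w, cfg, rng)
        state.iteration = k + 1
        state.history.append(state.gbest_score)
    return state


def _decode(state: SwarmState) -> RuleModel:
    return RuleModel(state.gbest_bits.astype(bool), state.gbest_cont)


def _run_named(features: np.ndarray, labels: np.ndarray, cfg: SwarmConfig,
               algorithm: str, literal_gmean: bool) -> tuple[RuleModel, np.ndarray]:
    features = np.asarray(features, dtype=float)
    if features.size == 0:
        raise ValueError("empty training set")
    if cfg.algorithm != algorithm:
        raise ValueError(f"config algorithm is {cfg.algorithm!r}, expected {algorithm!r}")
    fitness = make_gmean_fitness(features, labels, literal_gmean=literal_gmean)
    state = run_swarm(fitness, cfg)
    return _decode(state), np.asarray(state.history)


def run_standard_pso(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: SwarmConfig,
    literal_gmean: bool = False,
) -> tuple[RuleModel, np.ndarray]:
    """Synchronous-update swarm; returns (best rule model, gbest history)."""
    return _run_named(features, labels, cfg, "synchronous", literal_gmean)


def run_rapso(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: SwarmConfig,
    literal_gmean: bool = False,
) -> tuple[RuleModel, np.ndarray]:
    """Random-asynchronous swarm; returns (best rule model, gbest history)."""
    return _run_named(features, labels, cfg, "random_asynchronous", literal_gmean)
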