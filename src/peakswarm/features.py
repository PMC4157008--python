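"""Model-based peak parameters and the fourteen-feature peak catalogue.

Each candidate peak is described by eight model parameters — the peak point
(PP), flanking valleys (VP1/VP2), turning points (TP1/TP2), half points
(HP1/HP2) and the moving-average-curve value at the peak (MAC) — from which
fourteen features are computed: five amplitudes (f1–f5, µV), five widths
(f6–f10, samples) and four slopes (f11–f14, µV/sample). All features are
absolute values, hence non-negative.

Four named peak models expose fixed feature subsets: ``dumpala``
{f1,f6,f11,f12}, ``acir`` {f1,f2,f7,f8,f13,f14}, ``liu``
{f1,f2,f3,f4,f6,f9,f10,f11,f12,f13,f14} and ``dingle`` {f5,f6,f11,f12}.

Notes
-----
* The slope of the second half wave (f12) is computed with denominator
  ``PP - VP2`` by default; ``literal_f12=True`` reproduces a published
  variant that reuses ``PP - VP1``.
* The moving-average window length defaults to 257 samples (~1 s at 256 Hz),
  centered and truncated at signal boundaries; it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from peakswarm.candidates import PeakCandidate
from peakswarm.signal_io import Signal

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "PEAK_MODELS",
    "DEFAULT_MAC_WINDOW",
    "ModelParams",
    "moving_average_value",
    "moving_average_curve",
    "find_turning_point",
    "find_half_point",
    "model_params",
    "extract_features",
    "extract_feature_matrix",
    "model_subset",
]

N_FEATURES = 14
FEATURE_NAMES = tuple(f"f{i}" for i in range(1, N_FEATURES + 1))
DEFAULT_MAC_WINDOW = 257

#: Named peak models as sets of 1-based feature numbers.
PEAK_MODELS: dict[str, frozenset[int]] = {
    "dumpala": frozenset({1, 6, 11, 12}),
    "acir": frozenset({1, 2, 7, 8, 13, 14}),
    "liu": frozenset({1, 2, 3, 4, 6, 9, 10, 11, 12, 13, 14}),
    "dingle": frozenset({5, 6, 11, 12}),
}


@dataclass(frozen=True)
class ModelParams:
    """The eight model-based parameters of one candidate peak."""

    pp: int
    vp1: int
    vp2: int
    tp1: int
    tp2: int
    hp1: int
    hp2: int
    mac: float

    def __post_init__(self) -> None:
        if not (self.vp1 <= self.tp1 <= self.pp <= self.tp2 <= self.vp2):
            raise ValueError("turning points must lie between the peak and its valleys")
        if not (self.vp1 <= self.hp1 <= self.pp <= self.hp2 <= self.vp2):
            raise ValueError("half points must lie between the peak and its valleys")


def _as_samples(signal: Union[Signal, Sequence[float], np.ndarray]) -> np.ndarray:
    return np.asarray(getattr(signal, "samples", signal), dtype=float)


def moving_average_value(
    signal: Union[Signal, Sequence[float], np.ndarray],
    center: int,
    window: int = DEFAULT_MAC_WINDOW,
) -> float:
    """Centered moving average at ``center``, truncated at signal boundaries."""
    x = _as_samples(signal)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if not (0 <= center < x.size):
        raise ValueError(f"center {center} out of range for signal of length {x.size}")
    half = window // 2
    lo = max(0, center - half)
    hi = min(x.size, center + half + 1)
    return float(x[lo:hi].mean())


def moving_average_curve(
    signal: Union[Signal, Sequence[float], np.ndarray],
    window: int = DEFAULT_MAC_WINDOW,
) -> np.ndarray:
    """Boundary-truncated centered moving average of the whole signal.

    Equals ``moving_average_value`` evaluated at every sample, computed in one
    pass via cumulative sums.
    """
    x = _as_samples(signal)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def find_turning_point(
    signal: Union[Signal, Sequence[float], np.ndarray],
    pp: int,
    vp: int,
) -> int:
    """First point, walking from ``pp`` toward ``vp``, where the one-sample
    slope magnitude drops by more than 50% relative to the preceding segment.

    Returns ``vp`` when no such drop occurs before the valley is reached.
    """
    x = _as_samples(signal)
    if vp == pp:
        raise ValueError("valley index must differ from peak index")
    step = 1 if vp > pp else -1
    prev_slope = abs(x[pp + step] - x[pp])
    i = pp + step
    while i != vp:
        nxt = i + step
        slope = abs(x[nxt] - x[i])
        if slope < 0.5 * prev_slope:
            return nxt
        prev_slope = slope
        i = nxt
    return vp


def find_half_point(
    signal: Union[Signal, Sequence[float], np.ndarray],
    pp: int,
    vp: int,
) -> int:
    """First sample, walking from ``pp`` toward ``vp``, at or below the
    midpoint level between peak and valley amplitudes (no interpolation)."""
    x = _as_samples(signal)
    if vp == pp:
        raise ValueError("valley index must differ from peak index")
    h = 0.5 * (x[pp] + x[vp])
    step = 1 if vp > pp else -1
    i = pp + step
    while i != vp:
        if x[i] <= h:
            return i
        i += step
    return vp


def model_params(
    signal: Union[Signal, Sequence[float], np.ndarray],
    candidate: PeakCandidate,
    mac_window: int = DEFAULT_MAC_WINDOW,
    mac: np.ndarray | None = None,
) -> ModelParams:
    """Compute the eight model parameters for one candidate.

    ``mac`` may be a precomputed :func:`moving_average_curve` to avoid
    recomputation across candidates.
    """
    x = _as_samples(signal)
    pp, vp1, vp2 = candidate.pp, candidate.vp1, candidate.vp2
    if not (0 <= vp1 < pp < vp2 < x.size):
        raise ValueError(f"candidate {candidate} invalid for signal of length {x.size}")
    mac_at_pp = float(mac[pp]) if mac is not None else moving_average_value(x, pp, mac_window)
    return ModelParams(
        pp=pp,
        vp1=vp1,
        vp2=vp2,
        tp1=find_turning_point(x, pp, vp1),
        tp2=find_turning_point(x, pp, vp2),
        hp1=find_half_point(x, pp, vp1),
        hp2=find_half_point(x, pp, vp2),
        mac=mac_at_pp,
    )


def _safe_slope(dy: float, dx: float) -> float:
    # zero denominator (possible only after turning-point fallback) -> 0
    return abs(dy / dx) if dx != 0 else 0.0


def extract_features(
    signal: Union[Signal, Sequence[float], np.ndarray],
    candidate: PeakCandidate,
    mac_window: int = DEFAULT_MAC_WINDOW,
    literal_f12: bool = False,
    mac: np.ndarray | None = None,
) -> np.ndarray:
    """Compute the fourteen features of one candidate as a length-14 array.

    f1..f5 amplitudes, f6..f10 widths, f11..f14 slopes (see module docstring
    for definitions). All entries are non-negative and finite.
    """
    x = _as_samples(signal)
    p = model_params(x, candidate, mac_window=mac_window, mac=mac)
    xpp = x[p.pp]
    f = np.empty(N_FEATURES)
    f[0] = abs(xpp - x[p.vp1])
    f[1] = abs(xpp - x[p.vp2])
    f[2] = abs(xpp - x[p.tp1])
    f[3] = abs(xpp - x[p.tp2])
    f[4] = abs(xpp - p.mac)
    f[5] = abs(p.vp1 - p.vp2)
    f[6] = abs(p.pp - p.vp1)
    f[7] = abs(p.pp - p.vp2)
    f[8] = abs(p.tp1 - p.tp2)
    f[9] = abs(p.hp1 - p.hp2)
    f[10] = _safe_slope(xpp - x[p.vp1], p.pp - p.vp1)
    f12_den = (p.pp - p.vp1) if literal_f12 else (p.pp - p.vp2)
    f[11] = _safe_slope(xpp - x[p.vp2], f12_den)
    f[12] = _safe_slope(xpp - x[p.tp1], p.pp - p.tp1)
    f[13] = _safe_slope(xpp - x[p.tp2], p.pp - p.tp2)
    return f


def extract_feature_matrix(
    signal: Union[Signal, Sequence[float], np.ndarray],
    candidates: Iterable[PeakCandidate],
    mac_window: int = DEFAULT_MAC_WINDOW,
    literal_f12: bool = False,
) -> np.ndarray:
    """Feature matrix of shape (n_candidates, 14), one row per candidate."""
    x = _as_samples(signal)
    mac = moving_average_curve(x, mac_window)
    rows = [
        extract_features(x, c, mac_window=mac_window, literal_f12=literal_f12, mac=mac)
        for c in candidates
    ]
    return np.asarray(rows, dtype=float).reshape(-1, N_FEATURES)


def model_subset(name: str) -> frozenset[int]:
    """The feature subset (1-based feature numbers) of a named peak model."""
    try:
        return PEAK_MODELS[name.lower()]
    except KeyError:
        valid = ", ".join(sorted(PEAK_MODELS))
        raise ValueError(f"unknown peak model {name!r}; valid names: {valid}") from None
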