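"""Three-point sliding-window peak candidate detection.

A candidate is a strict interior local maximum ``x(pp-1) < x(pp) > x(pp+1)``
flanked on both sides by strict interior local minima (valleys). Plateaus
(equal adjacent samples) never produce candidates because the inequalities are
strict; an optional jitter pre-pass can break ties, OFF by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from peakswarm.signal_io import Signal

__all__ = ["PeakCandidate", "detect_candidates", "break_plateaus"]


@dataclass(frozen=True, order=True)
class PeakCandidate:
    """A peak point ``pp`` with its flanking valley points ``vp1 < pp < vp2``."""

    pp: int
    vp1: int
    vp2: int

    def __post_init__(self) -> None:
        if not (self.vp1 < self.pp < self.vp2):
            raise ValueError(f"valleys must flank the peak: {self.vp1}, {self.pp}, {self.vp2}")


def _as_samples(signal: Union[Signal, Sequence[float], np.ndarray]) -> np.ndarray:
    return np.asarray(getattr(signal, "samples", signal), dtype=float)


def break_plateaus(samples: np.ndarray, eps_scale: float = 1e-9) -> np.ndarray:
    """Add an infinitesimal index-ordered ramp so no two samples are equal.

    The ramp magnitude is ``eps_scale`` times the signal's amplitude range per
    sample, small enough to leave all strict orderings intact.
    """
    x = np.asarray(samples, dtype=float)
    span = float(np.ptp(x)) or 1.0
    return x + np.arange(x.size) * (eps_scale * span)


def detect_candidates(
    signal: Union[Signal, Sequence[float], np.ndarray],
    jitter_plateaus: bool = False,
) -> list[PeakCandidate]:
    """Find all peak candidates, ordered by peak index.

    For each strict local maximum the nearest strict local minimum on each
    side is taken as the valley; maxima lacking either flanking valley (e.g.
    near the signal boundaries) are discarded. Signals too short to admit a
    peak with two interior valleys yield an empty list.
    """
    x = _as_samples(signal)
    if jitter_plateaus:
        x = break_plateaus(x)
    n = x.size
    if n < 5:
        return []
    mid = x[1:-1]
    maxima = np.flatnonzero((mid > x[:-2]) & (mid > x[2:])) + 1
    minima = np.flatnonzero((mid < x[:-2]) & (mid < x[2:])) + 1
    if maxima.size == 0 or minima.size < 2:
        return []
    out: list[PeakCandidate] = []
    pos = np.searchsorted(minima, maxima)
    for pp, j in zip(maxima.tolist(), pos.tolist()):
        if j == 0 or j == minima.size:
            continue
        out.append(PeakCandidate(pp=pp, vp1=int(minima[j - 1]), vp2=int(minima[j])))
    return out
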