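"""Seed-deterministic generator of labelled EEG-like test signals.

A generated recording is band-limited oscillatory background plus white
noise, with sharp transients (Gaussian or triangular bumps) planted at
annotated positions. Each annotation marks the exact apex sample of its
transient and the generator guarantees the apex is a strict local maximum of
the summed signal (an event whose apex gets broken by noise is re-drawn),
so tolerance-0 labelling is exact and every annotated peak is found by
candidate detection.

Defaults emulate a 40 s single-channel recording: 10240 samples at 256 Hz
with 40 annotated peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from peakswarm.candidates import detect_candidates
from peakswarm.classifier import RuleModel, classify_matrix, confusion, gmean, label_candidates
from peakswarm.features import DEFAULT_MAC_WINDOW, N_FEATURES, extract_feature_matrix
from peakswarm.signal_io import AnnotationSet, Signal, split_recording

__all__ = ["SynthConfig", "generate", "SeparableFixture", "make_separable_fixture"]

_N_OSC = 12  # sinusoid components in the background band


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic labelled recording.

    ``snr_knob``, when set, raises the lower bound of the transient amplitude
    range to ``snr_knob`` times the 99th-percentile prominence of the
    background's own local maxima, guaranteeing planted peaks stand out from
    background fluctuations by that factor.

    ``n_decoys`` plants additional sharp *downward* transients. Each decoy
    carves a deep valley, so its neighbouring (non-annotated) local maxima get
    large peak-to-valley amplitudes and slopes while keeping a small
    deviation from the moving-average curve — confounders that make the
    peak-vs-MAC amplitude (f5) the only cleanly separating feature.
    """

    n_samples: int = 10240
    fs: float = 256.0
    n_peaks: int = 40
    amp_range: tuple[float, float] = (12.0, 25.0)
    half_width_range: tuple[float, float] = (2.0, 6.0)
    min_separation: int = 160
    osc_amplitude: float = 2.0
    osc_band: tuple[float, float] = (1.0, 12.0)
    noise_std: float = 0.4
    snr_knob: Optional[float] = None
    edge_margin: int = 200
    n_decoys: int = 0
    decoy_amp_range: tuple[float, float] = (5.0, 29.0)
    decoy_half_width_range: tuple[float, float] = (1.0, 3.0)
    seed: Optional[object] = None

    def __post_init__(self) -> None:
        if self.n_peaks < 0 or self.n_decoys < 0:
            raise ValueError("n_peaks and n_decoys must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_peaks and self.min_separation * self.n_peaks >= self.n_samples:
            raise ValueError("min_separation * n_peaks must be < n_samples")
        for name, (lo, hi) in (
            ("amp_range", self.amp_range),
            ("half_width_range", self.half_width_range),
            ("osc_band", self.osc_band),
        ):
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be a non-degenerate positive range")


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.n_samples) / cfg.fs
    freqs = rng.uniform(cfg.osc_band[0], cfg.osc_band[1], _N_OSC)
    phases = rng.uniform(0.0, 2.0 * np.pi, _N_OSC)
    amp = cfg.osc_amplitude / np.sqrt(_N_OSC)
    x = np.zeros(cfg.n_samples)
    for f, ph in zip(freqs, phases):
        x += amp * np.sin(2.0 * np.pi * f * t + ph)
    x += rng.normal(0.0, cfg.noise_std, cfg.n_samples)
    return x


def _draw_event(cfg: SynthConfig, rng: np.random.Generator,
                amp_lo: float, amp_hi: float) -> tuple[float, float, bool]:
    amp = rng.uniform(amp_lo, amp_hi)
    hw = rng.uniform(*cfg.half_width_range)
    gaussian = bool(rng.integers(0, 2))
    return amp, hw, gaussian


def _bump(amp: float, hw: float, gaussian: bool) -> np.ndarray:
    """Symmetric transient with apex value ``amp`` at the center sample."""
    if gaussian:
        half = max(1, int(round(3.0 * hw)))
        k = np.arange(-half, half + 1)
        return amp * np.exp(-0.5 * (k / hw) ** 2)
    half = max(1, int(round(2.0 * hw)))
    k = np.arange(-half, half + 1)
    return amp * np.clip(1.0 - np.abs(k) / (half + 0.5), 0.0, None)


def _add_at(x: np.ndarray, center: int, bump: np.ndarray, sign: float = 1.0) -> None:
    """Add ``bump`` (odd length, apex at its middle) centered at ``center``,
    truncating whatever falls outside the signal."""
    half = bump.size // 2
    lo = max(0, center - half)
    hi = min(x.size, center + half + 1)
    x[lo:hi] += sign * bump[lo - (center - half) : bump.size - ((center + half + 1) - hi)]


def _place(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n, sep, margin = cfg.n_samples, cfg.min_separation, cfg.edge_margin
    span = n - 2 * margin - (cfg.n_peaks - 1) * sep - 1
    if span <= 0:
        raise ValueError(
            "infeasible placement: separation/margin constraints leave no room "
            f"for {cfg.n_peaks} peaks in {n} samples"
        )
    offsets = np.sort(rng.uniform(0.0, span, cfg.n_peaks))
    return margin + np.round(offsets).astype(np.int64) + np.arange(cfg.n_peaks) * sep


def _place_decoys(
    cfg: SynthConfig, rng: np.random.Generator, peak_positions: np.ndarray
) -> np.ndarray:
    """Decoy positions kept >= 30 samples from every annotated apex and
    >= 10 samples from each other (rejection sampling)."""
    if cfg.n_decoys == 0:
        return np.empty(0, dtype=np.int64)
    taken = list(peak_positions.tolist())
    decoys: list[int] = []
    lo, hi = cfg.edge_margin, cfg.n_samples - cfg.edge_margin
    for _ in range(50 * cfg.n_decoys):
        if len(decoys) == cfg.n_decoys:
            break
        d = int(rng.integers(lo, hi))
        if all(abs(d - p) >= 30 for p in taken[: len(peak_positions)]) and all(
            abs(d - q) >= 10 for q in decoys
        ):
            decoys.append(d)
    if len(decoys) < cfg.n_decoys:
        raise ValueError("infeasible placement: could not fit the requested decoys")
    return np.asarray(sorted(decoys), dtype=np.int64)


def _amp_bounds(cfg: SynthConfig, background: np.ndarray) -> tuple[float, float]:
    lo, hi = cfg.amp_range
    if cfg.snr_knob is not None:
        proms = [
            background[c.pp] - 0.5 * (background[c.vp1] + background[c.vp2])
            for c in detect_candidates(background)
        ]
        p99 = float(np.percentile(proms, 99)) if proms else cfg.noise_std
        lo = max(lo, cfg.snr_knob * p99)
        hi = max(hi, 1.5 * lo)
    return lo, hi


def generate(cfg: SynthConfig) -> tuple[Signal, AnnotationSet]:
    """Generate a labelled recording; bit-identical for identical seeds."""
    rng = np.random.default_rng(cfg.seed)
    last_error = "generation failed"
    for _attempt in range(5):
        background = _background(cfg, rng)
        if cfg.n_peaks == 0:
            return Signal(background, cfg.fs), AnnotationSet(np.empty(0, dtype=np.int64))
        amp_lo, amp_hi = _amp_bounds(cfg, background)
        positions = _place(cfg, rng)
        x = background.copy()
        bumps: list[np.ndarray] = []
        for p in positions:
            b = _bump(*_draw_event(cfg, rng, amp_lo, amp_hi))
            _add_at(x, int(p), b)
            bumps.append(b)
        for d in _place_decoys(cfg, rng, positions):
            amp = rng.uniform(*cfg.decoy_amp_range)
            hw = rng.uniform(*cfg.decoy_half_width_range)
            _add_at(x, int(d), _bump(amp, hw, bool(rng.integers(0, 2))), sign=-1.0)
        # repair apexes whose strictness was broken by noise or overlap
        ok = True
        for j, p in enumerate(positions):
            tries = 0
            while not (x[p - 1] < x[p] > x[p + 1]):
                if tries >= 20:
                    ok = False
                    break
                # re-draw this event's parameters (fresh jitter) and re-add
                _add_at(x, int(p), bumps[j], sign=-1.0)
                b = _bump(*_draw_event(cfg, rng, amp_lo, amp_hi))
                _add_at(x, int(p), b)
                bumps[j] = b
                tries += 1
            if not ok:
                break
        if not ok:
            last_error = "could not keep all transient apexes strict local maxima"
            continue
        found = {c.pp for c in detect_candidates(x)}
        if not all(int(p) in found for p in positions):
            last_error = "an annotated apex was not recovered by candidate detection"
            continue
        return Signal(x, cfg.fs), AnnotationSet(positions)
    raise RuntimeError(f"synthetic generation failed after 5 attempts: {last_error}")


@dataclass(frozen=True)
class SeparableFixture:
    """A recording whose planted single-feature rule separates the classes."""

    signal: Signal
    annotations: AnnotationSet
    boundary: int
    train_features: np.ndarray
    train_labels: np.ndarray
    test_features: np.ndarray
    test_labels: np.ndarray
    planted_model: RuleModel


def make_separable_fixture(
    seed: int,
    snr_knob: float = 4.0,
    mac_window: int = DEFAULT_MAC_WINDOW,
    boundary: Optional[int] = None,
    max_attempts: int = 5,
) -> SeparableFixture:
    """Build a train/test fixture separable by a planted f5 threshold.

    The recording is generated with a high signal-to-background knob; the
    planted rule {mask = {f5}, th5 = midpoint of the class gap} must reach
    Gmean = 1 on both partitions, otherwise the recording is re-drawn (up to
    ``max_attempts`` times). ``snr_knob < 1`` is refused outright: it
    produces overlapping f5 distributions by construction.
    """
    if snr_knob < 1.0:
        raise ValueError(
            "snr_knob must be >= 1: lower values produce overlapping f5 distributions"
        )
    for attempt in range(max_attempts):
        cfg = SynthConfig(
            seed=np.random.SeedSequence([int(seed), attempt]),
            snr_knob=snr_knob,
            amp_range=(22.0, 29.0),
            half_width_range=(1.0, 3.0),
            n_decoys=300,
        )
        signal, annotations = generate(cfg)
        b = boundary if boundary is not None else len(signal) // 2
        (tr_sig, tr_ann), (te_sig, te_ann) = split_recording(signal, annotations, b)
        parts = []
        for sig, ann in ((tr_sig, tr_ann), (te_sig, te_ann)):
            cands = detect_candidates(sig)
            F = extract_feature_matrix(sig, cands, mac_window=mac_window)
            y = label_candidates(cands, ann, tolerance=0)
            parts.append((F, y, len(ann)))
        (trF, trY, n_tr), (teF, teY, n_te) = parts
        if int(trY.sum()) != n_tr or int(teY.sum()) != n_te:
            continue  # some annotation missed a candidate at tolerance 0
        allF = np.vstack([trF, teF])
        y = np.concatenate([trY, teY]).astype(bool)
        f5 = allF[:, 4]
        pos_min = float(f5[y].min())
        neg_max = float(f5[~y].max())
        if pos_min <= neg_max:
            continue  # classes overlap on f5; re-draw
        theta = 0.5 * (pos_min + neg_max)
        if not (0.0 < theta < 30.0):
            continue  # threshold must be recoverable within the search range
        # f5 must be the *only* single feature that separates the classes,
        # otherwise recovering the planted feature is not identifiable
        others_overlap = all(
            float(allF[y, j].min()) <= float(allF[~y, j].max())
            for j in range(N_FEATURES)
            if j != 4
        )
        if not others_overlap:
            continue
        mask = np.zeros(N_FEATURES, dtype=bool)
        mask[4] = True
        thresholds = np.zeros(N_FEATURES)
        thresholds[4] = theta
        model = RuleModel(mask, thresholds)
        for F, lab in ((trF, trY), (teF, teY)):
            if gmean(confusion(classify_matrix(F, model), lab)) != 1.0:
                raise AssertionError("separability check failed despite class gap")
        return SeparableFixture(
            signal=signal,
            annotations=annotations,
            boundary=b,
            train_features=trF,
            train_labels=trY,
            test_features=teF,
            test_labels=teY,
            planted_model=model,
        )
    raise RuntimeError(
        f"could not build a separable fixture in {max_attempts} attempts (seed={seed})"
    )
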