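# peakswarm

Peak detection for sampled biosignals (EEG-style transients) built from four
stages:

1. **Candidate detection** — three-point sliding window: strict local maxima
   flanked by strict local minima (valleys).
2. **Feature extraction** — fourteen per-candidate features computed from
   eight model parameters (peak, valleys, turning points, half points, and
   the moving-average-curve value at the peak): five amplitudes, five widths,
   four slopes. Four classic fixed feature subsets are available by name
   (`dumpala`, `acir`, `liu`, `dingle`).
3. **Rule classification** — a candidate is a predicted peak iff every
   selected feature is ≥ its decision threshold (hard conjunction).
4. **Optimization** — the 14-bit feature mask and the 14 thresholds are
   searched jointly by hybrid binary/continuous PSO (v-shaped `|tanh|`
   transfer for the bits), in either the standard synchronous schedule or the
   random-asynchronous variant (particles drawn with replacement, each moving
   immediately after its own evaluation). Fitness is the geometric mean of
   the true-peak and true-non-peak rates, robust to heavy class imbalance.

A seed-deterministic synthetic generator produces labelled EEG-like
recordings (default: 10240 samples at 256 Hz with 40 annotated transient
peaks) so the whole pipeline is testable end to end, including a
parameter-recovery fixture whose classes are separable only through the
peak-vs-moving-average amplitude feature (f5).

## CLI

```sh
# generate a labelled synthetic recording
peakswarm simulate --out signal.txt --annotations-out ann.txt --seed 0

# candidate table (pp, vp1, vp2, amplitude), feature matrix with labels
peakswarm detect signal.txt --out candidates.tsv
peakswarm features signal.txt --annotations ann.txt --out features.tsv

# train: first half of the recording is the training partition by default
peakswarm train signal.txt ann.txt --algo rapso --mode select \
    --runs 3 --particles 30 --iters 200 --seed 0 \
    --model-out model.json --report-out report.tsv

# fixed peak model (thresholds only): --mode {dumpala,acir,liu,dingle}
peakswarm train signal.txt ann.txt --algo pso --mode dingle --report-out dingle.tsv

# score a saved model on a labelled recording; re-aggregate a report
peakswarm evaluate signal.txt ann.txt model.json
peakswarm report report.tsv
```

`--config cfg.yaml` presets any `train` option (keys mirror the
`ExperimentConfig` fields, e.g. `n_runs`, `n_particles`, `k_max`,
`tolerance`); explicit flags win. The reference full-scale budget is 10 runs
of 30 particles × 1000 iterations (`peakswarm.experiment.PAPER_BUDGET`);
defaults are a desk-scale budget.

Signal files are delimited text, one sample per row, with an optional
`# fs: <Hz>` header (otherwise pass `--fs`). Annotation files hold one
0-based sample index per row. All files and APIs are 0-based; only console
summaries print 1-based indices.

## Notable behavioural switches

- `literal_f12` — reproduce the published second-half-wave slope formula
  whose denominator reuses the first half wave (default corrects it).
- `gmean(..., literal=True)` — plain `TPR×TNR` product instead of the
  geometric mean.
- `SwarmConfig(literal_ranges=True)` — the published threshold-range index
  layout instead of per-category ranges.
- `detect_candidates(..., jitter_plateaus=True)` — optional tie-breaking
  pre-pass; by default plateaus never produce candidates (the three-point
  inequalities are strict).
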