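# Methods

This note documents the models, estimators and numerical choices behind
`sparklet`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the underlying measurement procedure leaves
the implementation open.

## 1. Signal model and detection

### Pixel model

A recording is a stack `F(t, x)` of `n_frames` frames at `frame_rate` Hz
(defaults 2000 and 150: a 13.33 s recording) with `pixel_size` µm pixels
(default 0.4 µm, a fixture choice for a 60× TIRF objective). The synthetic
generator renders

```
F(t, x) = B(x) · [ bleach(t) · (1 + Σ_e k_e(t, x)) + ε(t, x) ]
```

* `B(x)` — resting intensity: 1000 camera units inside cells, 100 on
  background (arbitrary; the analysis self-normalizes).
* `bleach(t) = exp(−λt)` — global mono-exponential photobleach, default
  λ = 0 (bleaching is usually minimized procedurally during acquisition).
* `ε ~ N(0, noise_sd)` i.i.d. per pixel and frame, in ΔF/F₀ units (default
  0.01). This is a shot-noise approximation at a fixed operating point;
  Poisson noise is available behind `poisson_noise=True`.
* Each sparklet kernel `k_e` is separable: a spatial Gaussian
  `exp(−r²/2σ²)` centred on its site and clipped to the owning cell's
  footprint, times a temporal pulse with **instantaneous rise and
  single-exponential decay**. "Duration" is defined as the time above half
  of peak, so the decay constant is `τ = duration / ln 2`. The measurement
  procedure constrains only durations (with a 3-frame detectable floor),
  not kinetics; the instant-rise/exponential-decay pulse is the simplest
  shape consistent with a channel-opening transient.
* Whole-cell transients ("global" events) are spatially uniform over one
  cell, amplitude 0.3 ΔF/F₀, so that they *must* be caught by the
  simultaneity filter. They occur at `global_event_rate` (default 0.0375 /s
  ≈ 0.5 per recording: occasional).

### Generator defaults as study conditions

* `footprint_sigma = 2.1 µm`: the ~2σ disc then covers π(4.2 µm)² ≈ 55 µm²,
  the middle of the 50–60 µm² footprint band reported for these events.
* `amplitude_band = (0.05, 0.27)` ΔF/F₀, uniform: the reported amplitude
  range; the uniform law is a neutral choice over that band.
* Durations: exponential with scale `duration_mean` (default 0.10 s)
  **left-truncated** at the 3-frame floor (20 ms at 150 Hz). By
  memorylessness this is `floor + Exp(duration_mean)`, and the truncated
  MLE below recovers `duration_mean` exactly in expectation.
* `site_rate = 0.1 events/s` per site: sites then fire 1.33 times per
  13.3 s recording on average, i.e. a site that fired at all repeats at
  least once about half the time — matching the qualitative observation
  that sparklet sites fire repetitively within a recording, though not
  always.
* Sites are placed uniformly inside each cell with a **minimum separation
  of 16 px (two ROI diameters)**. One ROI diameter is not enough: with a
  5.25 px footprint σ, a site 8 px away receives up to 0.086 ΔF/F₀ of
  disk-averaged crosstalk — above the 0.05 peak criterion — so genuine
  sparklets at adjacent sites would systematically co-classify and be
  falsely excluded as "simultaneous". At 16 px the worst-case crosstalk is
  0.004 ΔF/F₀.
* Cells are rectangles tiled on a grid (4 cells of ~120×120 px on a 256×256
  frame ⇒ 2.3·10⁻³ mm² each). A frame too small for the requested
  cells/sites raises a sizing error.

What the generator does **not** emulate: optical sectioning physics of the
evanescent field, stage drift or motion, indicator kinetics and buffering,
spatially correlated noise, cell-shape irregularity, and the absolute
frequency scale of real preparations. Tests passing on this generator
therefore demonstrate the correctness and calibration of the *pipeline*,
not performance claims about any particular instrument or tissue.

### ROI detector

The automated picker plants an ROI wherever a significant, persistent
baseline change occurs:

1. Per-pixel noise scale: `1.4826/√2 × median|ΔF|` over up to 512 evenly
   strided temporal first differences (robust to the sparse events; floored
   at 10⁻⁶ of the local baseline so noise-free synthetic movies remain
   detectable while a constant movie yields exactly z = 0 everywhere).
2. Per-pixel baseline: 20th percentile over 2 s blocks, linearly
   interpolated between block centres (static percentile when the window
   covers the recording). Tracks slow bleaching while ignoring events.
3. z-score each voxel, smooth with a 3×3 spatial mean, threshold at
   `z ≥ 3`. Because the smoothing leaves the (broad) event signal intact
   but divides independent pixel noise by 3, this is a ~9σ cut on pure
   noise: over 20 seeded null movies the detector produces ≤ 0.5 ROIs per
   movie, while a 0.05 ΔF/F₀ event at 0.01 noise sits at smoothed z ≈ 5.
4. Require persistence for 3 consecutive frames, label the surviving
   voxels as 26-connected spatio-temporal components, and take each
   component's z-weighted spatial centroid as a candidate site.
5. Drop candidates on background or whose 8-px disk would cross the frame
   edge; greedily accept candidates by decreasing strength subject to a
   centre separation of ≥ one ROI diameter (this both merges repeated
   firings of one site and resolves overlaps to the stronger site).

"ROI size of 8 pixels" is read as a *circular ROI of 8 px diameter* (the
conventional parameter of automated pickers); diameter, z-threshold,
persistence, percentile and window are all configurable. The ROI's cell is
the mask label under its centre pixel.

### Traces and classification

The per-ROI trace is the disk mean (49 px at diameter 8) per frame,
normalized by F₀ = median of the series; baseline mean is the median of the
normalized trace and baseline SD is `1.4826 × MAD` (falling back to the
plain SD when the MAD degenerates). Robust statistics are essential: the
events under study would inflate a whole-trace SD and bias the 2.5 SD
criterion against detection.

An event is a maximal run of frames with `value ≥ mean + 2.5·SD`; it is a
sparklet iff the run lasts ≥ 3 frames and `max(value − mean) ≥ 0.05`.
`peak_area` integrates `value − mean` over the run (ΔF/F₀·s); runs
truncated by the recording edge are kept if they qualify within the
observed span (13.3 s windows make edge losses non-negligible; the small
downward bias on their durations is accepted and documented).

Events in *separate* ROIs whose spans overlap or whose onsets differ by ≤ 2
frames (13 ms; configurable) are excluded transitively — detection in more
than one ROI implies a signal too large to be a sparklet. Two properties
follow by construction: exclusion is symmetric, and every whole-cell
transient detected in ≥ 2 ROIs is excluded. A documented side effect on
clean synthetic traces: the baseline SD is so small that supra-threshold
decay tails are long, and unrelated sparklets in different ROIs often
overlap by chance, removing both. Detector accuracy is therefore measured
*before* this filter (see §4).

## 2. Quantification

`frequency = n_events / recording_duration / membrane_area` in Hz/mm²,
with `membrane_area` the full masked footprint of the cell (pixel count ×
pixel_size²) — the area correction that compensates cell-to-cell variation
in TIRF-zone membrane. Excluded events never count; mask cells with zero
events are reported at frequency 0 with an undefined (NaN) amplitude, and
amplitude comparisons drop zero-sparklet cells rather than treating them
as zero-amplitude observations. No automatic segmentation is attempted:
masks are an input (synthetic or user-supplied). Note that with single-cell
footprint areas of ~10⁻³ mm², per-cell frequencies on synthetic data sit in
the tens-to-hundreds of Hz/mm²; the formula is the literal definition and
no attempt is made to reproduce any particular absolute scale.

## 3. Statistics

* **Wilcoxon matched-pairs signed-rank** (paired frequencies): zero
  differences dropped, midranks on ties; exact two-sided p by convolution
  over all 2^m sign assignments for m ≤ 12 nonzero differences, else a
  tie-corrected normal approximation with continuity correction. The
  reported statistic is the conventional smaller rank sum.
* **Mann–Whitney** (unpaired frequencies, e.g. designs where paired
  controls are impossible): exact by dynamic programming over the
  C(n, n_a) group labelings for n ≤ 14, else tie-corrected normal.
* **Student t, pooled variance** (amplitudes, zero-sparklet cells
  removed): delegated to `scipy.stats.ttest_ind(equal_var=True)`.
* **Spearman dependence**: rs from midranks; two-sided p by full n!
  permutation enumeration for n ≤ 8, else 10⁴ seeded random permutations
  with the add-one estimator `(1 + hits)/(1 + N)` (exactly valid, slightly
  conservative) and a reported Monte-Carlo SE. "Statistically dependent"
  means p < 0.05.
* Mean ± SEM summaries report SD/√n, with SEM 0 and a flag at n = 1.

All p-values are two-sided; no multiple-testing correction is applied
(matching the measurement procedure being reimplemented). The exact-regime
cutoffs (2^12 sign vectors, C(14,7) labelings, 8! permutations) keep every
exact computation well under a second. Exact and approximate regimes agree
to < 0.03 for 5 ≤ n ≤ 12 (regression-guarded).

Paired-frequency scenarios are generated through a **Gaussian copula** with
gamma marginals (shape 2, a realistic cell-to-cell heterogeneity with
CV ≈ 0.7): with copula correlation `ρ = 2 sin(π ρ_s / 6)` the *population*
Spearman correlation equals the requested `ρ_s` exactly; `ρ_s = 0` gives
the independent model and `ρ_s = 1` an exact monotone relation. Under the
independent model the permutation test rejects at 4.9% over 1000
replicates; at `ρ_s = 0.8`, n = 25 pairs, dependence is declared in ≥ 85%
of replicates — the qualitative pattern in which every intervention except
store depletion leaves paired frequencies rank-dependent.

## 4. Validation against ground truth

A classified event matches a truth sparklet when its ROI centre lies within
4 px (one ROI radius) of the true site and onsets agree within ±3 frames
(one-to-one, greedy by onset). Matching is computed on classified events
**before** simultaneity exclusion: the filter deliberately discards
whole-cell signals and, on synthetic data, both partners of chance
cross-ROI tail overlaps — design behaviour that is validated by its own
tests, not a detection failure. Consistently, (a) recall is computed over
*observable* truth sparklets — those whose occupancy window (decay to
0.002 ΔF/F₀) does not overlap a whole-cell transient in the same cell —
and (b) detections caused by an injected whole-cell transient count as
correct detections of that transient, not as false positives.

Benchmark problem sizes, chosen to exercise the full acquisition geometry
while keeping a desk-scale runtime: detector accuracy on ten 256×256 ×
2000-frame movies (20 sites, amplitudes uniform on [0.08, 0.27], noise
0.01); rate recovery through the quantification bookkeeping on five
128×128 movies (20 cells, ~650 true events); 500/100 replicates for
Spearman calibration/power; 1000 events for duration recovery. Typical
results: recall ≈ 0.92–0.96 (residual misses are same-site events whose
runs merge into a predecessor's supra-threshold tail), precision ≈ 0.98,
pooled-rate error within 2 Poisson SE, duration MLE within 10%.

### Duration law

The classification floor left-truncates observed durations, so the
exponential mean is estimated by the truncated-exponential MLE
`mean = sample_mean − truncation` (exact by memorylessness), with a
one-sample KS statistic against the fitted law as a goodness summary (its
p-value is approximate, the scale having been estimated from the same
sample). All-equal durations yield a valid MLE with a `degenerate`
goodness flag; fits are recommended from ~10 events upward.

## 5. Known limitations

* The detector has no sub-pixel localization, no drift tracking, and no
  adaptive ROI sizing; two sites closer than one ROI diameter resolve to
  the stronger one.
* Same-site events closer than a supra-threshold tail merge into one run;
  at the default site rate this costs a few percent of recall and biases
  per-site counts slightly downward.
* The baseline-SD estimator on nearly noise-free traces makes the 2.5 SD
  criterion extremely permissive (the 0.05 ΔF/F₀ peak criterion then does
  all the work) and event spans generous; on realistic noise the two
  criteria are both active.
* Permutation p-values below 1/(N+1) ≈ 10⁻⁴ are not resolvable at the
  default 10⁴ permutations.
* The Hz/mm² scale depends entirely on the mask's area convention; only
  within-convention comparisons are meaningful.
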