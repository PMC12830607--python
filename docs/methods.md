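# Methods

## Problem setting

In limbal stem cell deficiency (LSCD) the corneal epithelium loses its
renewal source; histologically the injured surface shows focal regions of
extreme thinning (few cell layers, keratinized surface) and thickening
(hyperplasia), while the *mean* epithelial thickness can stay close to
normal. A useful quantitative readout must therefore measure the
*irregularity* of the thickness profile, not its average. This package
implements that readout for the standard paired design: one injured
(study, right) eye and one control (left) eye per animal.

## Profile morphometry

An eye's profile is the ordered sequence of thickness samples along the
sectioned contour, with slides (physically separate strips) concatenated
in slide order. Metrics:

* **Standardization.** z = (t − μ)/σ with μ, σ computed per animal,
  pooling that animal's measured eye series (both eyes). Pooling is what
  makes the metric comparable across animals with different baseline
  thickness while preserving the within-animal contrast: a focal lesion
  in the study eye produces large |z| against the animal's own scale.
  Per-eye scope is available for sensitivity analysis. z-scores use the
  population SD (divisor n), the usual z-score convention; σ = 0
  (constant data) maps to z ≡ 0.
* **Ra** = mean(|z − mean(z)|); **Rz** = max(z) − min(z). Rz is
  deliberately the plain amplitude, not the ISO-4287 five-peak Rz: it is
  the statistic that responds to a single extreme hot spot. Rz ≥ Ra
  always (the extreme deviation bounds the mean absolute deviation).
  Default grouping computes Ra/Rz on the eye-level standardized profile;
  a per-slide-averaged mode exists because real sectioning protocols
  sometimes warrant treating strips separately.
* **Rolling SD**: sample SD (divisor n − 1) in every full window of 5
  consecutive measurements, averaged; computed on the raw µm scale by
  default so the value is interpretable in micrometres. Optionally
  windows break at slide boundaries (off by default; the boundary windows
  are a negligible fraction and both modes are exposed).
* **Skewness**: Fisher–Pearson g₁ = m₃/m₂^{3/2}, bias-uncorrected — the
  default of the standard scientific-Python skewness routine. Undefined
  on zero variance; reported as missing, not raised.
* **σ-exceedance**: fraction of samples with |z| strictly greater than
  1, 2, 3. Strict inequality matters only on ties, which have measure
  zero for continuous data.
* **Smoothing** (centered moving average, odd window, shrunken at the
  edges) is a display aid for profile plots; metrics are computed on
  unsmoothed data unless a sensitivity flag is set, since smoothing
  attenuates exactly the local extremes the metrics target.

Missing samples (extraction gaps) are dropped, never imputed or zeroed —
zeros would register as catastrophic thinning in every metric.

## Group statistics

One table row per metric. The pooled per-measurement mean thickness is
tested with an unpaired two-sample t-test (pooled variance; Welch by
flag) treating measurements as units — per-eye units are available, and
the choice is recorded in the output. All per-eye metrics are tested with
a paired t-test matched on animal id. Zero-variance paired differences
are flagged degenerate: t = 0, p = 1 when all differences are zero,
otherwise p is pinned below machine resolution rather than invented.
Raw p-values are reported without multiplicity correction, matching how
such tables are conventionally presented; a Holm-adjusted column can be
enabled. No modeling beyond t-tests (no mixed models) is attempted: with
n = 4 animals per group the paired t is the defensible test.

## Thickness extraction from labeled rasters

Input is a calibrated label raster (0 background, 1 stroma, 2 epithelium,
3 nucleus). Pixels are 0-based row-major; pixel (r, c) covers the
half-open unit square centered on (r, c), so an h-pixel band has
thickness exactly h px.

1. The epithelium mask is the largest connected component (components
   below `min_component_px` are logged and discarded; more than one large
   component aborts with the component sizes — the section is likely
   folded). Nucleus pixels are reassigned to their host tissue by
   nearest-non-nucleus-pixel (Euclidean distance transform), which also
   handles nuclei touching the image border where hole-filling fails.
2. The basal contour is the set of epithelium pixels 4-adjacent to
   stroma, ordered by angle around the stroma centroid and cut at the
   largest angular gap. This ordering is exact for the open bands and
   arcs this pipeline measures; strongly re-entrant (S-shaped) interfaces
   are out of scope and would need a chaining-based ordering.
3. The contour is smoothed with a moving average of width
   `normal_window_um` (raw pixel normals are unstable), resampled at
   `sampling_step_um` of arc length, and the outward normal (away from
   the stroma centroid) is taken from central-difference tangents.
4. Thickness at each site is measured by marching the normal ray in
   half-pixel steps offset by a quarter pixel (so samples never sit on
   pixel edges): thickness runs from the stroma-side edge of the basal
   pixel to the far edge of the farthest epithelium pixel of the
   contiguous run, bridging gaps up to `gap_tolerance_um` (nuclei,
   keratin flakes). Rays leaving the image while still inside epithelium
   yield missing samples, logged. The half-pixel bookkeeping makes
   axis-aligned bands exact (an 80 px band reads 80.0, not 79.5 or 80.5)
   and keeps oblique/curved geometries within about a pixel.

Positions are cumulative arc length in µm from the start of the contour.

## Cellularity

A nucleus is a connected component of the nucleus label (4-connectivity,
so separately placed nuclei that approach within a diagonal step stay
distinct); components under 4 px are discarded as noise. Membership is
by centroid-in-compartment with a majority-of-pixels fallback when the
centroid pixel lands exactly on a compartment boundary. Density =
count / area, with area the compartment mask including its embedded
nuclei, in mm². Touching nuclei are not split (no watershed): the
synthetic ground truth controls overlap, and on real H&E this
undercounts dense infiltrates — a documented limitation. Densities are
reported per mm², the scale on which such results are tabulated.

## OCT longitudinal analysis

Series carry (animal, region, day, thickness) with day −1 the
pre-procedure baseline. Percent-of-baseline is 100·t(day)/t(−1) (the
baseline maps to exactly 100). Each post-baseline day is tested against
baseline with a two-sided paired t across animals; significance bands
0.05/0.01/0.001 are annotated as stars. The swelling peak is the argmax
of the cohort mean over post-injury days (ties to the earlier day); the
residual fraction (final − baseline)/(peak − baseline) measures how much
swelling persists at the end of follow-up. A peak on the schedule
boundary is flagged (the series may be monotone). No multiple-testing
correction across days, mirroring per-day star annotation; noted in the
report metadata. The module does not decide which corneal layer the
series quantifies — outputs carry the thickness field they were given.

## Synthetic data: what it emulates, and what it does not

The generator produces the three data streams with the structure the
analysis assumes, at defaults chosen to mirror the emulated study:

* **Cohort**: 4 animals, right eye study / left eye control, ~190
  samples per eye at 10 µm spacing split into two slides (A/B, positions
  restarting per slide), control baseline 77.7 µm.
* **Noise**: i.i.d. Gaussian on thickness, SD 4.6 µm. No within-profile
  noise magnitude is published for this kind of data; 4.6 µm is set so
  the control five-point rolling SD lands near the observed control
  value (E[S] for n = 5 i.i.d. normals is c₄(5) ≈ 0.94 of σ, and
  4.36/0.94 ≈ 4.6).
* **Hot spots**: per study eye, 3 Gaussian-shaped bumps in arc length
  (amplitude ±40 µm with random sign, width SD 40 µm), centers drawn on
  the sampling grid away from the profile ends so each peak is sampled
  exactly — which is what makes amplitude-recovery-from-range testable
  to 1%. Amplitudes match the observed scale of focal
  thinning/thickening (≈ 40–50 µm off an 80 µm baseline). Thickness is
  clipped at a 5 µm floor; a spec whose profile would sit at the floor
  everywhere is rejected.
* **Histology rasters**: a flat or annular epithelium band of prescribed
  per-column thickness above stroma; nuclei as disks placed uniformly in
  a compartment with a hard-core minimum separation (one diameter plus a
  pixel) and Poisson-distributed count (mean density × area), clipped to
  the compartment so boundary disks never leak labels. The placed count
  is the ground truth, so counting can be tested exactly; the hard core
  thins nothing because the count is fixed before placement.
* **OCT**: piecewise-linear rise from baseline (day −1) to
  multiplier × baseline at the peak day, then linear decline to
  baseline + (1 − recovery) × excess at day 28; central peaks at day 8
  with multiplier 1.5, limbal earlier (day 6) and lower — swelling that
  resolves only partially. Noise is added after the curve.

Everything is driven by one seed per artifact and is bit-reproducible.

What the generator does **not** emulate: spatial correlation of
measurement noise, the slow anatomical thickness trend along real
sections (central → limbal), staining variability, nucleus size/shape
heterogeneity, overlapping nuclei, and OCT segmentation failures.
Passing tests therefore demonstrate correctness of the *computations*
and recoverability of *injected* effects under the stated noise model —
not performance on real slides, where the extraction and counting
limitations above apply.

## Numerical choices

* z-scores: population SD; rolling SD: sample SD; both configurable.
* Strict inequalities in exceedance; ties broken to the earlier day in
  peak detection; argmax takes the first maximum.
* Degenerate inputs: constant profiles give z ≡ 0, Ra = Rz = 0,
  skewness missing; zero-variance paired differences give the flagged
  degenerate test above.
* Float round trips: tables are written with full repr precision, so
  write → read reproduces values bit-for-bit.
* Monte-Carlo checks in the tests use fixed seeds and problem sizes
  (200 cohorts for detection/null rates, 10⁵ samples for Gaussian
  calibration, images of a few mm² for density recovery) chosen to keep
  the whole suite under a minute on one CPU while leaving the binomial /
  Poisson error bands well inside the asserted tolerances.
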