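# Methods

## Measurement model

### Coverage from disclosed images

A disclosed-plaque frame is an 8-bit RGB raster in which stained plaque
is red-dominant and clean enamel green-dominant. The measurement chain
is: optional deinterlacing → per-pixel integer ratio `floor(R/G)` →
threshold at ratio ≥ 1 → intersection with the rasterized tooth ROI →
histogram count. With floor division, "plaque" at the default threshold
is exactly the set of pixels where R ≥ G, and on realistic frames the
ratio image takes only small values (0–3). Division rounding is
configurable (`floor` | `round`) for sensitivity analysis; floor is the
default because it makes the plaque criterion the clean inequality
R ≥ G. Where the green channel is zero, a pixel with red signal
saturates to 255 (maximally plaque-like: red with no green reference)
and a fully dark pixel maps to 0 (no evidence). These zero-green rules
are a package convention; dark pixels occur essentially only outside the
tooth ROI, so they have no practical effect on per-tooth results.

### ΔR% from undisclosed images

Mature plaque fluoresces red without disclosure. With `r = R/G`
real-valued per pixel and `r₀` the mean of `r` over a plaque-free
reference ellipse on the same tooth, each ROI pixel gets
`ΔR = 100·(r − r₀)/r₀`; pixels with ΔR at or above the detection
threshold (default 20%, configurable) are "red-fluorescent", and the
reported ΔR% is the mean of ΔR over detected pixels (0 when nothing is
detected). Being a ratio of ratios, ΔR% is invariant to global
multiplicative illumination changes up to 8-bit quantization. Averaging
over *detected* pixels (rather than the whole ROI, or a maximum) is the
implemented convention; with defaults it produces values on the scale of
65–70% for realistic red-fluorescing plaque. G = 0 pixels are excluded
from both the reference mean and detection. A detection comparison
tolerance of 1e-9 keeps pixels sitting exactly at the threshold detected
despite float round-off.

### Geometry

Pixel (row *i*, col *j*) occupies `[j, j+1)×[i, i+1)` with centre
`(j+0.5, i+0.5)`; a pixel belongs to a region iff its centre does.
Polygons use the even-odd (ray-crossing) rule with centres exactly on an
edge excluded; ellipses use the rotated-ellipse inequality ≤ 1. Both
rules are deterministic and exactly checkable against per-pixel oracles;
integer-aligned rectangles rasterize to their exact area.
Self-intersection is rejected (via a robust geometric simplicity check);
fully collinear rings are accepted and rasterize to an empty mask.

### Deinterlacing

Interlaced video sensors can leave alternating-row brightness artifacts.
The pre-filter replaces every row of one parity (default odd rows),
channel by channel, with the integer mean of its two vertical
neighbours, rounded half up (`(a+b+1)//2`); boundary rows of that parity
copy their single neighbour. Constant images are fixed points. This
neighbour-mean filter is the package's own choice of the simplest
artifact-removing kernel; it is applied before the ratio image.

## Cohort layer

Exclusions run in a fixed order, each subject logged once under the
first rule that fires: (1) fewer than 10 natural anterior teeth,
(2) recent antibiotics (a supplied boolean; no time-window logic),
(3) missing BMI/smoking/age, (4) withdrawn or no images. Repeat visits
(visit_index > 1) are dropped and logged, keeping only each subject's
first imaging session to avoid Hawthorne-effect bias. The order affects
only the log, not the retained set; the filter is idempotent and
conserves counts. Subject summaries are arithmetic means over measured
teeth. Gestational age at delivery is binned half-open: <28 weeks
extreme, 28–<34 moderate, 34–<37 mild, ≥37 term; missing outcomes are
"unknown" and excluded from tabulations.

## Statistics

* Two-sample *t*: Student's pooled-variance variant (not Welch),
  df = n₁+n₂−2, two-sided, computable directly from published group
  means/sds — the pooled form is what reproduces summary-table p-values
  recomputed from group statistics.
* Chi-squared: Pearson, no Yates continuity correction.
* Logistic regression: maximum likelihood (Newton-Raphson, tolerance
  1e-8, ≤100 iterations, intercept always included) via statsmodels;
  Wald SEs from the inverse observed information; OR = exp(β) with the
  1.96-multiplier normal-approximation 95% CI. Complete separation is
  reported as an error naming the separating predictor. Coefficients are
  reported per unit of each predictor (unstandardised).
* Smoking enters as a single ordinal code 0/1/2 (nonsmoker / stopped
  during pregnancy / smoker during pregnancy) by default — one degree of
  freedom — with a binary any-smoking-in-pregnancy option. Age and BMI
  are continuous.
* Relative difference between group means is reported as a percentage of
  the larger mean.
* The descriptive table rounds means/sds to 2 dp, p to 3 dp, categorical
  percentages to whole percent; delivery outcome is tabulated without a
  test (descriptive only).

## Synthetic data

### Images

A tooth is an axis-aligned ellipse (default semi-axes 80×110 px in a
256×256 frame) of green-fluorescing enamel (G = 150, R/G = 0.55) on a
dark background, outlined by a 72-gon ROI. Plaque occupies a contiguous
band grown row by row from the gingival (lower) edge — where plaque
accrues in vivo — containing exactly `ceil(f · tooth_area)` pixels for
areal fraction `f`; a scattered-speckle mode exists for robustness
testing. Disclosed mode sets the band's ratio to `r_plaque` (default
1.6 > 1); undisclosed mode elevates it by a configured ΔR (default 70%)
over enamel, in which case the band's absolute ratio may stay below 1 —
undisclosed plaque is not red-dominant, only relatively elevated.
Optional Gaussian channel noise and an odd-row brightness offset emulate
the sensor chain. The exact plaque mask is returned as ground truth;
generation is byte-deterministic given the seed.

What the generator does **not** emulate: specular highlights, gingival
tissue in frame, uneven illumination, motion blur, partial disclosure,
curved 3-D tooth surfaces. Passing tests therefore show the algorithm is
internally correct and robust to the modelled artifacts — not that it
matches clinical inter-operator variability.

### Cohorts

Default parameters describe an antenatal case-control sample of 91
(51 cases at clinical risk of preterm delivery / 40 controls): coverage
normal (25.50, sd 17.45) in cases vs (20.58, 14.39) in controls
truncated to [0,100]; age (28.69, 5.91) vs (30.78, 6.41); BMI ≈ 26 in
both; smoking multinomial (61/10/29% vs 75/10/15%). ΔR% is linked
linearly to coverage with slope/intercept/noise calibrated to a
population Pearson r of 0.55 (mean ≈ 66.6, sd ≈ 16.5). Truncation pulls
the coverage mean up and sd down relative to the parent moments;
`realized_coverage_moments` gives the achieved moments and the
calibration helper uses them, so the target correlation is met on
average (verified by Monte Carlo). Per-tooth values scatter normally
(sd 5) around the subject mean over 10–12 teeth. Delivery follows
`P(<37 wk) = expit(−2.75 + 0.05·coverage)` with gestational age drawn
from truncated normals within the preterm/term ranges.

Two generation modes resolve the two natural directions of the model:
`stratified` fixes group sizes and draws coverage per group (its fitted
coverage coefficient is positive, since cases are generated with higher
coverage); `logistic` draws covariates from the pooled distributions and
assigns case status through `expit(intercept + β·x)` with configured
coefficients (defaults β = (−0.042, 0.036, −0.822, 0.005, 0.030),
intercept −1.75, chosen so the expected case fraction is ≈ 51/91).
`stratified` is for descriptive-table fixtures; `logistic` is the
correctly specified model used for coefficient-recovery and
type-I-error calibration.

A fixed accounting fixture (`study_accounting_cohort`) composes 109
recruited subjects: the 91 analyzable plus 7 with <10 natural anterior
teeth, 5 with recent antibiotics, 4 with missing covariates and 2
withdrawn; among the 91, delivery outcomes are fixed at 17 preterm
(<37 wk) of which 6 before 34 weeks, with one control outcome missing.

## Numerical and design choices

* Monte-Carlo problem sizes: coefficient recovery uses 200 replicates of
  n = 5000 (vectorized subject-level draws); type-I calibration uses
  1000 replicates of n = 400; correlation consistency uses one n = 9000
  draw and 500 replicate n = 91 draws. These sizes give binomial /
  sampling error comfortably below the asserted tolerances.
* The vectorized `simulate_cohort_frame` is the generator's core;
  `simulate_cohort` adds per-tooth measurement objects on top. Large
  simulations use the frame directly.
* Degenerate inputs are errors, not silent defaults: empty ROIs,
  references outside the ROI or without green signal, zero contingency
  marginals, one-class outcomes, duplicate subject-visits.
* The end-to-end pipeline degrades gracefully in exactly one place: on
  cohorts too small to support the 5-predictor logistic model (or with
  separation) it writes the descriptive report and skips the regression
  with a note, so small smoke-test runs still complete.

## Limitations

* The ΔR% definition (detected-pixel mean over a ratio-based per-pixel
  elevation) is a reasoned reconstruction of what proprietary QLF
  analysis software reports, not a byte-level emulation.
* mm² areas require a user-supplied mm-per-pixel calibration; without it
  areas are reported in pixels and mm² fields are null.
* No automatic tooth detection: ROIs come from files.
* Published summary statistics are printed rounded (2–3 dp); quantities
  recomputed from them (p-values, CI endpoints) carry a propagation
  error of order 1e-3, which is the precision at which such
  recomputations are asserted.
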