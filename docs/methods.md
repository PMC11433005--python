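# Methods

This note documents the models behind `husphen`'s synthetic-data
generators, the derived-index conventions, the numerical choices, and what
the test suite does and does not establish about real data.

## Synthetic cohort model

The cohort generator emulates a two-arm longitudinal DIO design: standard
diet (SD) vs Western diet (WD), male and female, eight mice per sex per
arm, weekly records from 8 to 24 weeks of age. Every effect size is a
(mean, SD) pair in the variable's own units, drawn per mouse, and WD
effects are additive deltas on the sex-specific base — zeroing them makes
the arms exchangeable, which is what the type-I-calibration tests exploit.

* **Body weight**: per-mouse linear trend, baseline ~23 g (males) / 18 g
  (females), base slope 0.30 / 0.20 g·week⁻¹ with a WD extra of
  0.25 / 0.15 g·week⁻¹, plus 0.4 g Gaussian measurement noise. The linear
  trend is deliberately simple; it reproduces the monotone separation of
  the arms without modelling growth-curve saturation.
* **Food intake**: per-mouse base (3.3 / 2.9 g·day⁻¹) with a transient
  hyperphagic window on WD (+0.5 g·day⁻¹ during weeks 8–12) followed by a
  mild compensatory reduction (−0.3 g·day⁻¹), matching the
  hyperphagia-then-normalization feeding pattern such diets produce.
  Caloric intake uses the diet densities 3.150 (SD) and 4.2594 (WD)
  kcal/g.
* **Biochemistry**: sampled at 8, 16 and 24 weeks (the final draw marked
  fasting); WD shifts are timepoint-specific (endpoint hyperglycemia,
  progressive hypercholesterolemia, an early triglyceride rise that
  reverses at 16 weeks, higher transaminases and insulin, lower BUN).
  Values are clipped at zero.
* **Attrition** is missing-at-random truncation of whole mice after a
  uniformly drawn timepoint (default probability 0.03 ≈ 1/32, the scale of
  losing one animal per study), exercising the unbalanced-data path of the
  mixed ANOVA.

## Speckle phantoms

A phantom is a set of disjoint labeled regions (liver, renal cortex, …) on
a 550 × 650 grid at 0.02 mm/px (≈ 11 × 13 mm field). The continuous image
is `base × blur(multiplier)`:

* `base` holds the regional target means (a.u. in [0, 255]) plus optional
  i.i.d. Gaussian heterogeneity;
* the multiplier is fully developed multiplicative Rayleigh speckle with
  its scale set so E[multiplier] = 1 (regional means are preserved in
  expectation), blurred by a Gaussian point-spread function of σ = 1.5 px
  to mimic the finite resolution cell.

Blurring the multiplier field rather than the composed image keeps region
boundaries out of the mean-preservation argument and makes the degenerate
no-speckle phantom exactly piecewise-constant. Intensities are quantized
to 8 bits by round-half-even. The texture parameters of "coarsened"
parenchyma grades are free: no texture statistics are published for them,
so heterogeneity SDs are exposed as knobs with a 6 a.u. default.

What this does **not** model: physical wave propagation (no k-space or
Field-II simulation), attenuation with depth, anisotropic resolution,
log-compression curves of specific scanners. Passing phantom tests shows
the ROI estimators are unbiased under multiplicative mean-one speckle —
not that they are robust to scanner-specific artifacts.

## Doppler waveforms and index extraction

Each cardiac cycle is piecewise: a linear systolic upstroke from EDV to
PSV over 15% of the period; an exponential run-off `PSV·e^{−k u}` over
70%; a linear late-diastolic recovery to EDV over 8%; an end-diastolic
hold for the final 7%. Without a mean-velocity target, k is set so the
run-off lands exactly on EDV (monotone decay, trace minimum = EDV). With
`mv_target`, k is solved by bisection on the closed-form cycle mean
(strictly decreasing in k; relative tolerance 10⁻⁹, verified against
trapezoidal integration to < 0.1%). A cycle mean below EDV — which the
printed index pair RI ≈ 0.5, PI = 1.18 with PSV − EDV = 15 mm/s implies —
is attainable because the run-off may undershoot EDV before the recovery;
this is also why EDV is defined at the **foot of the systolic upstroke**
(true end-diastole) rather than the global cycle minimum.

Extraction: systolic peaks are local maxima separated by ≥ 60% of the
expected period (heart rate from the caller's hint or the dominant
spectral peak in 2–20 Hz) with prominence ≥ 50% of the trace excursion.
PSV and EDV are averaged over min(4, detected) cycles (floor 3); MV and
VTI come from the median-PSV cycle (peak-to-peak spans cover one full
period), or all cycles behind a flag. On clean traces extraction is exact.
When the first-difference residual indicates noise (> 0.5% of the
excursion), the trace is smoothed with a moving average of 2% of the
period, the foot detector uses lag-window slopes anchored at the
maximum-slope point of the upstroke (searched within the 20% of the period
adjacent to the peak, which excludes the recovery limb), and the EDV read
is the median over the pre-upstroke span clear of the smoothed corner.
These choices hold the RI error below 0.02 in ≥ 95% of traces at noise up
to 5% of PSV. The default sampling rate (8 kHz) places the waveform's
corner points on the sample grid at 400 bpm, so the noiseless RI is exact
rather than grid-limited.

Whether a clinical "MV" traces the envelope maximum or the mean spectral
velocity is instrument-dependent; here the trace itself is the envelope,
with an optional 5-sample moving-maximum for spectral-envelope input.

## Echocardiographic indices

Derived indices are computed from beat-averaged calipers (≥ 3 beats
enforced) and only then normalized: 1-D measures by BW^(1/3), 3-D measures
(Teichholz volumes, corrected LV mass, SV, CO) by BW. FS, RWT are
ratio indices and commute with normalization; EF does **not** commute
exactly, because the 2.4 mm offset in V(D) = (7.0/(2.4 + D))·D³ breaks
scale homogeneity — the scale-invariance property is therefore asserted
for FS and RWT only. Similarly, group indices computed from group-mean
diameters differ from per-animal-then-averaged indices (mean-of-ratios vs
ratio-of-means): for the 8-week male-control row this is < 0.05 percentage
points for FS and < 2% for RWT, but ≈ 10% for EF, and published normalized
LV-volume magnitudes are not reconstructible from the printed exponents at
all; the formula-consistency tests are therefore restricted to FS and RWT.
A systolic diameter exceeding the diastolic one yields a negative FS with
an attached warning rather than an error, so QC review remains possible.

## Liver ROI analysis

ROIs are circles (the protocol's hand-drawn ROIs are near-circular) with
hard area tolerances: 0.1 ± 0.02 mm² for the HR/HPV ratios, 1 ± 0.02 mm²
for gray-level-histogram analysis; a minimum of 30 pixels guards the SD
estimate. Depth matching of ratio ROIs is enforced at 10% of depth (the
protocol says "same distance from the probe" without a number). Anisotropy
uses the population SD (n denominator) over exactly the three protocol
planes; the SD convention is not published, and the choice is recorded
here rather than asserted as "the" published convention. Visual steatosis
grading is operator-entered data: the module validates, stores and
aggregates grades; it never classifies pixels.

## Scoring conventions

NAS is the unweighted sum of a steatosis term, hypertrophy and
inflammation, each 0–3, hence 0–9. Macro- and micro-vesicular steatosis
are graded separately, and how they combine into the single steatosis term
is unspecified in the source scoring system (a plain sum would give 0–12);
the default takes max(macro, micro), which preserves the 0–9 range under
mixed-pattern steatosis, with a sum-capped-at-3 variant behind a flag.
Renal glomerular grades use closed lower bounds (exactly 30% → grade 1,
exactly 70% → grade 2) because the verbal rule's strict inequalities leave
the boundaries unassigned. Frequency percentages are truncated (not
rounded) to two decimals, matching the sevenths-style printing of
small-group tables (1/7 → 14.28). Published per-text percentages that
conflict with their own table counts (e.g. a 48.85% where counts give
42.85%) are not reproduced; the package reproduces count arithmetic only.

## Statistics

* **Mann–Whitney**: for combined n ≤ 16 the two-sided p comes from the
  full permutation distribution of U over tie-averaged ranks (exact with
  ties); beyond that, the normal approximation with tie-corrected variance
  and continuity correction. Exactness is property-tested against a
  rank-free enumeration oracle.
* **Mixed repeated-measures ANOVA**: complete-case split-plot fit (subjects
  missing any timepoint are dropped) via `pingouin.mixed_anova`, with the
  Greenhouse–Geisser epsilon applied to both the within and interaction
  dfs, yielding the fractional dfs conventional in repeated-measures
  reporting. This mirrors, but is not identical to, the REML "mixed
  effects" fit of commercial software; it is documented as an
  approximation. Degenerate inputs (zero residual variance) fall back to
  classical sums of squares with F = 0, p = 1 for absent effects and
  p reported below 10⁻¹² for structured noiseless effects. Per-timepoint
  contrasts are pooled-variance t tests, Sidak-adjusted with
  p_adj = 1 − (1 − p)^m, family size m = number of timepoints by default
  (the published family is not stated; m is configurable).
* **Sample size**: the z-based normal-approximation formula
  n = ⌈2·SD²·(z_{1−α/2} + z_{power})²/δ²⌉, which reproduces the 7-per-group
  (8 after 10% attrition inflation) design at δ = 30, SD = 20, α = 0.05,
  power = 0.80. An iterative t-based formula would give n = 8 before
  inflation; the z form matches the published calculator's behavior.
* **Significance stars** at p < 0.05/0.01/0.001/0.0001.

Type-I calibration runs use 1000 seeded null cohorts (single sex, 8 per
arm, three imaging timepoints) for the endpoint Mann–Whitney, and 1000
seeded Gaussian null datasets (8 subjects per arm, 3 timepoints) for the
ANOVA diet effect; both rejection rates are required to sit in
0.05 ± 0.02.

## Problem sizes and determinism

Monte-Carlo sizes follow the quantities they estimate: 100 seeded phantoms
per hepatic-renal-ratio configuration (SE of the mean ≈ 0.004, against an
acceptance band of ±0.02), 200 seeds for slope recovery, 1000 for type-I
calibration. All generators are pure functions of (spec, seed); tests use
fixed seed lists, and `scripts/acceptance.py` derives independent child
seeds (< 2³¹) from its single `--seed` argument via `SeedSequence`.

## Known limitations

* The cohort model is additive-Gaussian; it does not emulate growth-curve
  saturation, heteroscedasticity, litter effects or covariance between
  analytes.
* Phantoms validate estimator logic under an idealized speckle model, not
  scanner physics.
* The ANOVA is a split-plot approximation of a REML mixed model; with
  heavy attrition the complete-case fit loses information a true mixed
  model would keep.
* Visual and histological grading are modeled as given ordinal data;
  automated grading from images is out of scope.
* HOMA2 (%B/%S) values are pass-through columns: the structural HOMA2
  model is not implemented.
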