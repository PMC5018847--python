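# Methods note

What the pipeline computes, which algorithm dialects are pinned and why,
how the synthetic generators were calibrated, and what the validation
does and does not establish.

## 1. Color and calibration

Photographs are assumed scale-calibrated (pixels/cm known; the study
standard is 37.6 px/cm) and in a known colorspace. Decoding:

- **sRGB**: the piecewise IEC 61966-2-1 transfer function.
- **Adobe RGB (1998)**: pure power law with exponent 563/256 ≈ 2.1992.

Linear RGB maps to XYZ through the standard primaries' matrices with one
deliberate numerical choice: each matrix row is rescaled so that
RGB = (1,1,1) maps *exactly* to the D65 2° white (0.95047, 1, 1.08883).
Published 7-digit matrices miss the white point by ~2e-5, which would
make a pure-white image come out faintly chromatic; the rescale removes
that artifact without visibly changing any other color. XYZ → CIELAB is
the CIE 1976 formula with the 6/29 linear toe. Color difference is CIE76
(plain Euclidean ΔE in Lab) — adequate for the large (ΔE > 5) egg-substrate
differences at stake here.

The analysis window is a square of side `round(13.3 cm × px_per_cm)`
pixels (500 px at the standard scale) centered on the clutch centroid,
clamped to the image with a warning if it does not fit.

## 2. Regions

From the binary clutch mask: **internal** = mask eroded by a radius-4
disk; **dilated** = mask dilated by a radius-8 disk; **contour band** =
dilated ∧ ¬internal (a ~12 px band straddling the outline); **background**
= ¬dilated. Structuring elements are single disks (skimage's default
decomposition is disabled so the footprint is the exact Euclidean disk);
a square element is available as a sensitivity knob. The three regions
partition the window by construction. Erosion that empties the clutch
warns; dilation that swallows the whole window raises.

## 3. Edge detection

The camouflage metrics are defined in terms of one particular Canny
dialect, so the detector is implemented in-house rather than borrowed
from scikit-image (whose threshold semantics and interpolated
non-maximum suppression differ):

- Gradient: derivative-of-Gaussian (`gaussian_filter` order 1,
  `mode="nearest"`), σ = 3 px by default.
- The gradient magnitude is normalized by its maximum, so the hysteresis
  thresholds (high 0.2, low = 0.4·high by default) are *fractions of the
  per-image maximum* — the MATLAB toolbox convention. This makes the
  edge map invariant to affine luminance rescaling.
- Non-maximum suppression: interpolation-free, the gradient direction
  quantized to 4 sectors; a pixel survives if strictly greater than its
  negative-direction neighbor and ≥ its positive-direction neighbor
  (the asymmetric tie-break keeps plateau edges one pixel wide).
- Hysteresis: 8-connected components of above-low pixels are kept if
  they contain an above-high pixel.

A per-pixel loop re-implementation of the same dialect lives in the test
suite as the independent oracle.

## 4. Metrics

Edge densities BgEdge, EggEdge, ContEdge are the fraction of edge pixels
in background, internal and contour-band regions. Ratios: CompRat =
EggEdge/BgEdge, DisRat = ContEdge/EggEdge, VisRat = ContEdge/BgEdge;
zero denominators yield NaN rather than infinities. VisRat ≡
DisRat × CompRat is asserted to 1e-12 as a pipeline invariant.

For survival modeling, complexity matching enters as **CompRat²** =
(log CompRat)² — zero at perfect matching and symmetric in over- vs
under-complexity.

Maculation is segmented by Otsu's threshold on internal luminance,
computed *exactly*: the between-class variance is maximized over every
split between consecutive distinct values (no histogram binning).
Histogram-based Otsu (including scikit-image's) returns a bin center
that can misclassify the whole threshold bin on near-discrete luminance
distributions — on synthetic two-tone eggs this produced maculation
fractions wrong by a factor of 6, which motivated the exact version.
Degenerate (near-constant) clutches are flagged `low_confidence`.

PropBgToEggColorMatch is the fraction of background pixels whose L\*,
a\*, b\* each lie within one clutch standard deviation of the clutch
mean — a box criterion, per the original method, not a Mahalanobis
ellipsoid.

## 5. Species comparison

Welch's unequal-variance t-test per metric with fractional
Welch-Satterthwaite degrees of freedom; ratio-scaled and chroma metrics
(DisRat, CompRat, ΔE, a\*-channels) are log-transformed first, dropping
non-positive values with a note. Assumption checks (Levene on medians,
Shapiro-Wilk per group) are reported, not enforced. Multiplicity control
is Benjamini-Hochberg step-up by default (Holm step-down available)
across the metric family; variables with undefined tests (insufficient
or degenerate data) are flagged and excluded from the adjustment.

## 6. Survival analysis

Visit logs (`nest_id, species, day, state`) are coded per nest:
`empty` → predation event at the detection day; `hatched` → censored at
hatching; other terminal states (e.g. abandonment) → censored at the
last day attended. Eggs reappearing after a loss is a coding error and
raises.

Cox proportional-hazards fits use lifelines (`CoxPHFitter`, Efron tie
handling) on an explicit design matrix: species is an indicator with
plover as reference, interactions are products of centered-as-given
columns. Collinearity screening computes VIF = 1/(1−R²) by explicit
least-squares regression and iteratively drops the predictor with the
largest VIF > 5, breaking ties toward the *smallest* univariate Cox
Wald |z| (the weakest marginal predictor goes first).

The candidate suite follows the original design: {Species} ∪ per-metric
{m, Species+m, Species×m} ∪ {Species + significant pair} ∪ {all metrics}
∪ {Species + all metrics} — 19 models over five metrics when a
two-metric significant set exists, 18 without one. Ranking uses
small-sample AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and Akaike weights;
models with Δ ≤ 2 are averaged conditionally per term, with unconditional
variance Σw(SE² + (β−β̄)²) and Wald 95% hazard-ratio intervals.
Kaplan-Meier curves per species come from lifelines.

In *synthetic* runs the enumeration uses the fixed five-metric study
suite rather than the data-driven VIF survivors: the VisRat =
DisRat × CompRat identity makes the ratio metrics mutually collinear in
simulated data (VIF 7–9), so pruning would shrink the suite and change
the model count. Pruning over the full eight-candidate pool still runs
and is logged; `suite_metrics: null` in the config switches to the
pruned set.

## 7. Synthetic generators

`SceneTruth` renders scenes directly in Lab: a substrate base color with
Gaussian texture and darker/cooler disks (density 1.8 /cm², radius
11 px, contrast 20 L\* by default), egg ellipses (1.1 × 1.5 cm
semi-axes, 2–3 per clutch) offset from the substrate by
(−16, −5, −12) Lab units, and maculation speckles (density 4.5 /cm²,
radius 4 px, contrast 28). Overlapping marks do not compound (a covered
mask ensures each pixel is stamped once), keeping planted contrasts
exact. Defaults were calibrated once, by forward parameter scans, so the
measured metrics land in realistic ranges (BgEdge ≈ 0.06, CompRat ≈ 1.4,
ΔE ≈ 16, PropBgToEggColorMatch ≈ 0.4) — they are study conditions, fixed
before and never tuned against test thresholds. The generator does *not*
emulate lighting gradients, shadows, focus falloff, JPEG artifacts or
calibration-card error; conclusions about detector behavior on real
field photographs are outside what these scenes can establish.

`SurvivalTruth` draws predation times from an exponential hazard
λ·exp(β_species·I[tern] + Σβ_m·x_m) (λ = 0.0075/day by default),
observed through nest checks every 3–4 days: events are detected at the
next check, censoring occurs at 25 days of incubation. The snapping
induces the interval-censoring coarseness of real monitoring;
`make_visit_table` additionally produces raw visit logs with exact
per-species predation counts for fate-coding tests.
`make_null_metric_table` samples metric vectors directly from realistic
per-metric laws (preserving the ratio identity) for statistics-stage
simulations that do not need rendered images.

## 8. Validation strategy and limitations

The original study's per-image metrics and model log-likelihoods depend
on unreleased photographs and are not reproducible. Validation therefore
splits into:

- **Exact arithmetic** against the published 19-row ranking recorded in
  `nestcam.reference` (AICc, Δ, Akaike weights, enumeration, fate
  tallies). One published row prints a log-likelihood inconsistent with
  its own AICc/Δ/weight (a transcription slip); both the printed and the
  row-consistent values are recorded, and the acceptance test asserts
  the 18/19 agreement pattern explicitly. Recomputed AICc values are
  compared at 0.06 tolerance: half an ulp of the printed 1-d.p. AICc
  plus the propagated 2-d.p. log-likelihood rounding.
- **Independent oracles** for every computational primitive: a loop
  reference Canny, brute-force Minkowski morphology, per-pixel metric
  recounts, exhaustive Otsu search, hand Welch/BH arithmetic, explicit
  regression VIFs, a written-out partial-likelihood search for the Cox
  coefficient, and hand product-limit Kaplan-Meier values.
- **Statistical properties**: planted-parameter recovery (species
  log-HR log 2.9 at n = 2000; 92–98 % CI coverage over 500 replicates at
  n = 150), null calibration of the comparison stage (family-wise
  adjusted rejection ≤ 0.05 + binomial error over 500 null datasets),
  and log-rank p-value uniformity under the null.

What this does not establish: performance on real photographs (lighting,
geometry and calibration error are unmodeled), behavior of the Cox
models under non-proportional hazards, or the biological validity of the
one-SD color-match box as a perceptual model — these are inherited
assumptions of the method, not artifacts of this implementation.
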