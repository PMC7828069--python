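# Methods

## Problem and scope

`marbliq` implements an image- and color-based workflow for estimating
pork-loin intramuscular fat (IMF%): marbling flecks are segmented from a
photograph of the Longissimus thoracis et lumborum (LTL) cutlet, muscle
and backfat morphometry are measured on the same calibrated image,
CIELAB color readings are aggregated with replicate quality control, and
the resulting 13-predictor table (carcass weight CW, five color
variables, seven image-analysis variables) is related to chemically
determined IMF% by discriminant (LDA, MDA) and regression (MLR,
polynomial SVR) models under repeated 7-fold cross-validation.

Because the matched raw data behind such studies (cutlet photographs
plus Soxhlet fat determinations on 20 animals) are not publicly
available, the package ships a synthetic-data generator whose ground
truth is exact by construction. Everything downstream is validated
against that ground truth or against closed-form worked examples.

## Image model and segmentation

A synthetic cutlet is a dark background (gray 8), a smooth
perturbed-ellipse muscle region (gray 120), bright elliptical fat flecks
(gray 220) placed inside the muscle, and a subcutaneous fat band (gray
235) riding the upper muscle boundary with a 3-px gap. Flecks are
rejection-sampled to be mutually 8-disconnected (their one-pixel-dilated
footprints may not touch), so connected-component labelling recovers
each planted particle individually and the recorded per-particle pixel
areas are exact. Fleck areas are lognormal (default mean 25 px, log-SD
0.35) truncated at 10 px — the particle-size filter's cutoff — so every
planted fleck survives filtering; an `inject_artifacts` option plants
1–9 px specks, recorded separately, to exercise the filter. Requesting a
fleck load above 50% of the muscle area is rejected as unphysical (real
marbling fractions are a few percent).

Segmentation follows the standard particle-analysis recipe: convert to
8-bit gray (ITU-R BT.601 luma), threshold *within the muscle ROI only*,
label components with 8-connectivity (the ImageJ particle-analyzer
convention; 4-connectivity available), discard components under 10 px
(inclusive at 10), and report NOParticles, Marb_area
(pixels × mm²/px²) and Marb_area% (fleck pixels / ROI pixels × 100).
Fat is taken as brighter than muscle, so binarization keeps pixels
≥ threshold. Two thresholds are provided because the manual protocol
(read the histogram after identifying a few unequivocal marbling pixels)
does not pin down one rule: `anchored_threshold` returns the minimum
anchor gray minus a margin, and `otsu_threshold` maximizes between-class
variance over the ROI histogram. On noise-free synthetic images both
recover the planted ground truth exactly.

Morphometry is deliberately simple and deterministic: width/height are
the axis-aligned extents of the ROI as imaged (no orientation
normalization), REA is the ROI pixel count in cm², and backfat thickness
(BFT) is the longest vertical run of the fat-band mask — the measurement
site is otherwise unspecified, and the maximum run is reproducible.

The default image scale is 0.03 mm/px. That is the only scale at which
the published descriptive ranges are mutually consistent: 16 particles
of the minimum 10 px at 0.03 mm/px give 16 × 10 × 0.0009 ≈ 0.144 mm²,
matching the published Marb_area minimum of 0.14 mm², and it matches a
16-megapixel frame of a ~12 cm cutlet. The end-to-end pipeline uses a
coarser 0.4 mm/px on smaller rasters so a full simulated study runs in
seconds; Marb_area% is scale-free, so this changes only the absolute
areas.

## Color metrics

Chroma C* = √(a*² + b*²) and hue H* = atan2(b*, a*) in degrees
(four-quadrant, so a* ≤ 0 is handled; for fresh pork both coincide with
tan⁻¹(b*/a*)). Replicates (three per sample by default) are summarized
per parameter by the arithmetic mean and CV% = 100 × sample SD/|mean|,
with C* and H* computed per reading before aggregation. CV% above 5 is
flagged but never rejected — replicate disagreement is treated as
intrinsic variability of the muscle surface.

## Grouping and scaling

Semi-quantitative groups: G1 = [0.6, 1.1]% IMF (central value 0.85),
G2 = [1.25, 1.5]% (central value 1.38 — the midpoint 1.375 rounded
half-up), G3 strictly above 1.5% (its published central value is a data
mean, not a midpoint, so the package refuses to compute it). All bounds
are inclusive except G3's lower bound; 1.5 → G2. Values in the gaps are
left unassigned in strict mode (default) or snapped to the nearest
interval in lenient mode — the boundary handling is explicit because
the gap (1.1, 1.25) is real.

Predictors are centred and scaled to unit sample SD. By default the
parameters are estimated on each training fold and applied to its
validation fold (no leakage); a `global_scaling` flag reproduces the
laxer whole-table reading some toolchains use.

## Models

* **LDA** — per-class means, pooled within-class covariance
  (n − k denominator), priors from class frequencies; decisions by the
  pooled-covariance Mahalanobis rule with priors; discriminant axes from
  the generalized eigenproblem of between- vs within-class scatter
  (tests cross-check decisions against scikit-learn's implementation).
  A singular pooled covariance raises, with a ridge flag
  (`ridge × trace/d` on the diagonal) as the escape hatch.
* **MDA** — each class a Gaussian mixture of subclasses (default 3, the
  customary default of the reference R implementation) with one
  covariance shared across all subclasses of all classes; per-class
  k-means initialization (seeded), EM to a log-likelihood gain below
  1e-8 or 500 iterations, and a degeneracy ridge of 1e-6 × trace/d when
  a subclass collapses. With one subclass per class MDA reduces exactly
  to LDA, which the tests assert on random datasets. A per-class
  covariance variant is available behind a flag.
* **MLR** — ordinary least squares with an intercept; rank-deficient
  designs raise with the collinear columns named (QR pivoting).
* **SVR** — ε-insensitive support vector regression with the polynomial
  kernel (scale·⟨u, v⟩ + offset)^degree, solved by scikit-learn's SVR to
  KKT tolerance 1e-6; the fitted model is stored as its kernel expansion
  (support vectors, dual coefficients, bias) and predictions are
  computed from those arrays, so JSON-serialized models reload exactly.
  Working defaults: degree 3, kernel scale 0.1, cost 1 (the optimized
  values for this prediction task); ε = 0.1 and offset = 1 are the
  conventional polynomial-kernel parameterization, and both are recorded
  in every serialized model. Note that at kernel scale 0.1 with cost 1
  the dual box constraint prevents exact interpolation of a unit-scale
  cubic; the exact-representation property (R² ≥ 0.999 on noiseless
  y = x³) holds at kernel scale 1, which is what the corresponding test
  uses.

## Validation protocol and metrics

One `CVScheme` (default 7 folds × 5 repetitions = 35 fitted models;
fold sizes differ by at most one; optional stratification by group) is
built once and reused for every model, so model comparisons share
identical splits. Classification splits whose training folds lose an
entire class, or where a class falls below the MDA subclass count, are
recorded as degenerate and excluded from the averages with a count.

Per-split classification metric: accuracy. Per-split regression
metrics: RMSE of raw errors and R² as the squared Pearson correlation
between observed and predicted — the convention of the R caret
toolchain this protocol mirrors. Report-level classification metrics are
one-vs-rest sensitivity and specificity per group, balanced accuracy
(their mean), overall accuracy with a Clopper–Pearson exact 95% CI
(normal approximation behind a flag) and an exact one-sided binomial
test against the no-information rate. Report-level regression
diagnostics come from the predicted-vs-observed simple linear fit:
slope and intercept with t-based 95% CIs, the fit's residual standard
error (RSE, n − 2 degrees of freedom), R² and adjusted R² (discounted
for the 13 predictors the underlying model consumed), RMSE on raw
errors, and — when the intercept is not significant at 5% — a
through-origin refit (n − 1 degrees of freedom), mirroring the practice
of dropping a non-significant intercept.

Variable importance is permutation importance: the mean drop in
accuracy (classifiers) or R² (regressors) over 20 permutations per
predictor, ties broken alphabetically. This stands in for the
unspecified importance method of the original toolchain; exact
reproduction of printed orderings is not claimed, but on synthetic
tables the generator's dominant link variable (BFT) ranks first.

## Feature-table generator

Predictors are drawn uniformly within the published population ranges
(CW 14.9–89.3 kg, L* 44.8–61.9, a* 0.99–13.6, b* 6.84–14.6, Width
5.3–12.0 cm, Height 2.74–8.75 cm, REA 11.7–55.0 cm² and below 85% of
the Width × Height box, BFT 0.39–6.05 cm, NOParticles 16–59, Marb_area
0.14–2.03 mm², Marb_area% 1.03–3.92); a* and b* are rejection-sampled so
the derived C* (9.0–17.0) and H* (34.1–83.8°) also stay in range. The
response is IMF% = 0.45 + 0.12·BFT + 0.10·Marb_area% + 0.10·BFT·CW/100
plus N(0, 0.05) noise: a smooth monotone link with a
backfat-by-maturity interaction, its coefficients fixed once so the link
spans ≈[0.61, 2.11] over the predictor ranges — matching the published
IMF% span of 0.62–2.08 — with BFT dominant, consistent with published
importance orderings. The noise SD of 0.05% IMF is a realistic
replicate-level uncertainty for gravimetric fat determination relative
to the ~1.5% IMF range.

What the generator does **not** emulate: realistic meat texture and
lighting, correlated predictors (real morphometric and color variables
co-vary with carcass weight; here they are independent draws), the
duplicate-measurement structure of the original 20-animal/39-measurement
design, or an RGB→CIELAB relationship between the synthetic images and
the color table (color is tabular, as measured by spectrophotometer).
Passing tests therefore demonstrate algorithmic correctness and
recoverability under known conditions, not field performance on real
cutlets.

## Numerical choices and limitations

* Thresholding convention: fat pixels satisfy gray ≥ threshold; the
  Otsu search is over the 256 integer partitions of the ROI histogram.
* Coordinates are row-major, 0-based, origin top-left; pixel→mm scale
  comes from configuration or ground truth (no ruler detection).
* Group central values use round-half-up, not banker's rounding.
* EM determinism: k-means initialization and all sampling use
  `numpy.random.default_rng` seeded explicitly; rerunning any pipeline
  with the same config yields byte-identical report bundles.
* Small-class folds: with 7 folds on ~39 samples and a minority group of
  ~5, MDA's default 3 subclasses can exceed a fold's class count; such
  splits are counted as degenerate rather than silently imputed.
* Headline cross-validated figures from the original 20-animal study
  (e.g. MDA CV accuracy ≈ 0.9, SVR CV R² ≈ 0.9) are not reproducible
  without that dataset and are not asserted anywhere; the test suite
  asserts the properties and worked examples that are derivable in
  closed form or by construction.
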