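# Methods

## Problem

Breslow thickness — the histological depth of melanoma invasion in mm — is
only available after excision, yet it determines staging and the surgical
margin.  This package implements and compares two preoperative estimators
on synthetic data: a multispectral-imaging (MSI) decision tree that bins
lesions into the three clinical categories < 1 mm, 1–2 mm (boundaries
inclusive) and > 2 mm, and a simulated high-frequency-ultrasound (HFUS)
depth measurement binned into the same categories.

## Synthetic cohort generator

The generator (`msibreslow.synthetic`) stands in for clinical data that is
not publicly deposited.  Its defaults are the study conditions and are
frozen; every stochastic element flows from one integer seed through named
sub-streams (cohort, hfus, shape, channel), so identical parameters and
seed give bit-identical output.

**Thickness law.** True Breslow depth is log-normal, moment-matched to an
arithmetic mean of 1.61 mm and SD of 1.69 mm, then clipped to
[0.135, 8.12] mm.  A log-normal was chosen because thickness is strictly
positive and right-skewed with SD comparable to the mean; no specific
distribution is prescribed by the cohort summary it matches.  Clipping
pulls the realized mean to ≈ 1.58 mm and the SD to ≈ 1.46 mm, still inside
the tolerance used by the calibration tests.  Subtype and anatomical site
are drawn independently from the published cohort proportions (e.g. SSM
68.32%, trunk 60/101).

**Ultrasound error.** A measurement is max(0, t + ε) with
ε ~ N(0, (σ₀ + γ·t)²), σ₀ = 0.08 mm, γ = 0.21: deeper tumors are measured
less precisely, consistent with the published per-category MSE pattern
(0.03 mm² for thin vs ≈ 1 mm² for thick lesions).  (σ₀, γ) were calibrated
once by grid search so that Pearson r(measured, true) ≈ 0.943 at
n = 10,000, then frozen.  The floor at 0 keeps measurements physical.

**Lesion rendering.** The mask is a star-convex polygon: a disk of radius
U(20, 32) px whose boundary is perturbed by radial Fourier harmonics
k = 2…6 with random weights and phases, total relative amplitude equal to
an *irregularity* level.  Irregularity is category-linked — thin melanomas
are rendered more irregular (levels 0.70 / 0.65 / 0.10 for the three
categories) — plus per-lesion Gaussian jitter (SD 0.18, truncated to
[0, 0.9]).  With jitter off, the realized circularity of thin-category
lesions stays below 0.75 and compact (> 2 mm) lesions stay above it with
wide margins (measured max 0.74 / min 0.95 over thousands of draws), which
is what makes the noiseless pipeline exactly recoverable.

Channel means inside the lesion: G is category-linked (14 A.U. for < 1 mm,
5 A.U. otherwise, on either side of the 8.0 A.U. threshold); IR falls
linearly, 159.2 − 23·t A.U., so the noiseless IR mean crosses the
113.7 A.U. threshold exactly at the 2 mm category boundary (the intercept
leaves a ≈ 0.5 A.U. quantization margin); R has a weak thickness trend
(95 − 4·t) and is deliberately ignored by the classifier; AF is rendered
(48 A.U.) but unused downstream.  Intensities get per-lesion scatter
(SD 4/6/8/35.8 A.U. for AF/G/R/IR) and per-pixel texture noise (SD 6),
then are quantized to 8 bits in [0, 255].  The IR scatter of 35.8 A.U. was
calibrated once so that r(mean IR, t) ≈ −0.659 at large n, including the
effect of 8-bit clipping; it is the dominant source of MSI
misclassification and gives the simulated MSI a realistic mid-range κ.

**"Noiseless" configuration.** `SimulationParams.noiseless()` zeroes the
ultrasound error, the per-pixel noise, the per-lesion intensity scatter
and the irregularity jitter.  Shape phases and lesion sizes remain random:
they are anatomy, not noise.  Under this configuration both classifiers
reach κ = 1 by construction, which the tests assert end-to-end.

**What the generator does not emulate.** Optics and acoustics (LED spectra,
speckle, attenuation), spatial texture structure, hair/bleeding artifacts,
inter-observer ROI variability, and any subtype- or site-dependence of
intensity or shape.  Passing tests therefore validate the *pipeline
machinery and its statistics*, not clinical performance on real lesions; in
particular the simulated MSI/HFUS κ gap mirrors the direction, not the
magnitude, of the clinical comparison.

## Feature extraction

Masks are single 8-connected components, ≥ 5 px (the moment-ellipse fit
needs 5); multi-component masks are rejected loudly rather than merged.
Conventions, frozen by tests:

* **Perimeter**: length of the sub-pixel marching-squares contour at the
  0.5 iso-level, simplified with Douglas–Peucker (tolerance 0.8 px).  The
  simplification removes digitization staircase on smooth boundaries while
  preserving straight runs; measured accuracy is +0.3% on a digital disk of
  radius 50 (circularity 0.990) and −4.9% on a 10×10 square.  Stock
  weighted-count estimators were measurably worse on one or the other
  (boundary-pixel weighting: −10% on the square; raw crack length: +26% on
  the disk).  The estimator is orientation-dependent at the ~10⁻³ level
  (Douglas–Peucker picks different sub-pixel vertices after rotation),
  which bounds the rotation-invariance tests.
* **Convex area**: shoelace area of the convex hull of foreground pixel
  centers (deterministic and oracle-checkable).  Because the hull of pixel
  centers is slightly smaller than the pixelated region, solidity of convex
  digital shapes overshoots 1 and is capped, as are circularity and
  roundness (ImageJ behaviour for digitization overshoot).
* **Major axis**: major-axis length of the ellipse with the region's second
  central moments (ImageJ "Fit Ellipse" semantics), via
  `skimage.measure.regionprops`.
* Coordinates are row-major with origin top-left; mask files are 0/255 PNG
  binarized at 128 on read.

## Classifier

The decision tree is total: circularity < 0.75 → (mean G ≥ 8.0 → < 1 mm,
else 1–2 mm); circularity ≥ 0.75 → (mean IR < 113.7 → > 2 mm, else
1–2 mm).  Tie handling is frozen: "over/higher" branches are closed (≥),
"under/lower" open (<).  Solidity, roundness and mean R are computed and
stored but unused by the tree; they belong to an earlier algorithm stage
that is out of scope here.  The intensity thresholds assume the 8-bit
(0–255 A.U.) scale of the generated images; because the original device's
arbitrary-unit scale is undefined, all three thresholds are configurable
(`ThresholdConfig`).  Thickness binning assigns exactly 1 mm and 2 mm to
the middle bin, keeping the three clinical groups exhaustive.

## Regression

`fit_multivariate` is plain OLS of thickness on (mean G, mean R, mean IR,
circularity) with an always-included intercept — no selection, no
regularization.  Its summary correlation is Pearson r between fitted and
observed values, identically √R²; significance is the overall regression
F-test.  Rank-deficient designs raise an error naming the collinear
predictors (read off the null-space singular vector).  The univariate IR
correlation uses the ROI mean intensity; other summaries (median, total)
would need the original data to distinguish.

## Evaluation

Cohen's κ uses (p_o − p_e)/(1 − p_e); its CI is κ ± z·SE with the
Fleiss–Cohen–Everitt large-sample SE, clipped to [−1, 1].  The CI method of
the published tables is not stated, so the tests cross-check the asymptotic
SE against a 10,000-draw multinomial bootstrap (they agree within 15%) and
require only approximate agreement (±25% on the half-width) with the
published interval.  Micro-averaging pools the one-vs-rest TP/FN/FP/TN
before applying the binary formulas; the identities micro sens = micro PPV
and micro spec = micro NPV hold algebraically for single-label problems and
are asserted.

**Table reconstruction.** From per-class (n, sensitivity, specificity) the
diagonal is round(sens·n) and the false positives of class k are
(N − n_k) − round(spec·(N − n_k)); Σ FP = Σ FN is enforced and a violation
is reported, never silently adjusted.  The published rows of both methods
turn out to be exactly self-consistent (Σ = 8 for the ultrasound table,
37 for the MSI table) and reproduce every printed Total-row value.  The six
off-diagonal cells are underdetermined by one degree of freedom; where a
full matrix is needed (the κ CI), the completion minimizing the squared
ordinal jump Σ c_ij (i−j)² is used — adjacent-category confusions are
clinically the most plausible — with ties broken deterministically.  κ
itself depends only on the diagonal and marginals, so it is unaffected by
the completion choice.

**MSE.** The continuous estimate scored for the ultrasound is the
measurement itself; for MSI it is the fitted value of the multivariate
model, since the decision tree outputs only a category.  This choice for
the MSI column is a modelling decision — the published analysis does not
say which continuous MSI estimate its MSE column scores.

## Problem sizes and numerical choices

Calibration statistics are computed at n = 10,000 (cohort mean, ultrasound
r), n = 5,000 (rendered IR correlation) and n = 300–400 for end-to-end
pipeline runs; coefficient-recovery uses 200 replicates of n = 200.  These
sizes keep Monte-Carlo error an order of magnitude below the assertion
tolerances (e.g. SE(r) ≈ 0.001 at n = 10,000).  All tests and the
acceptance script use fixed or CLI-provided seeds; derived sub-seeds stay
below 2³¹.

## Known limitations

* The generator's category-linked G channel and irregularity are a
  caricature: real lesions do not switch intensity regimes at category
  boundaries.
* The published per-class rows determine marginals only up to rounding to
  the printed precision; the reconstruction is exact for these tables but
  could fail (and would report) for rows printed at coarser precision.
* The perimeter convention is one defensible choice among several; shape
  thresholds (circularity 0.75) are only meaningful relative to the frozen
  estimator.
* No weighted κ, macro-averaging or ROC analysis; no automatic
  segmentation (ROIs are given); the AF channel is generated but never
  quantified.
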