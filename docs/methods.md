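# Methods

## The BCP score and its image-stage estimator

A strain elastogram is an RGB raster in which the scanner maps relative
tissue stiffness onto a color scale running red → yellow → green → blue
(soft → hard). The blue color proportion of a lymph node is

BCP = (blue pixels inside the node ROI) / (all node ROI pixels),

reported as a percent rounded to one decimal. The denominator counts every
ROI pixel, including any uncolored B-mode show-through inside the node
boundary; the published procedure is ambiguous on this point and counting
the whole selection is the interpretation that matches "the pixel value of
the whole LN".

**ROI.** Either an external binary mask (PNG, nonzero = inside) or seeded
region growing: the 8-connected component containing the seed of all pixels
whose Euclidean RGB distance to the *seed pixel's* color is ≤
`wand_tolerance` (default 32, the common magic-wand default). Distance to
the fixed seed color rather than to a running region mean keeps the result
order-independent and deterministic. On dual-panel frames (B-mode left,
elastography right) both segmentation and classification are restricted to
a user-supplied `panel_box`; panel layout is vendor-specific, so no
automatic panel detection is attempted. A ROI touching the panel border is
legal.

**Blue band.** Scanners publish only the ordinal color semantics, not
palette coordinates, so the stiff band is a configurable HSV box: hue ∈
[190°, 270°], saturation ≥ 0.15, value ≥ 0.15 by default. The hue window
covers the blue arm of clinical elastography palettes while excluding
cyan-green ambiguity at the band edge; the saturation/value floors reject
gray background and near-black pixels. HSV comes from the standard hexcone
conversion of 8-bit RGB. An all-soft node yields BCP = 0, not an error.

**Multiple images.** A node imaged more than once gets the unweighted mean
of its per-image BCPs.

## Synthetic elastograms

The renderer fills an analytic ellipse with a Gaussian-smoothed random
field standing in for relative stiffness (smoothing σ = min(H, W)/8, so the
field is spatially coherent and effectively tie-free), ranks the ellipse
pixels, and labels exactly `round(f · area)` of the stiffest pixels as the
stiff band for a requested blue fraction `f`. Soft pixels are mapped to
hues 0°–175° and stiff pixels to 205°–240° (saturation/value 0.9); the 30°
hue gap guarantees the default classifier band recovers the stiff set
pixel-for-pixel when noise is off, which is the closure property the image
tests assert. Outside the ellipse is gray speckle (zero saturation, so
never classified blue). Optional per-channel Gaussian noise (`noise_sd`, in
8-bit channel units) degrades this correspondence deliberately. The
renderer returns the image, the analytic ROI, the realized blue fraction
(`k/area`, within half a pixel of the request) and the exact blue mask —
the oracle for every downstream test.

The renderer emulates the color geometry of an elastogram, not ultrasound
physics: no speckle correlation, probe-pressure variability, depth
attenuation or frame-to-frame strain noise. Tests passing on rendered
images therefore validate the color-quantification pipeline, not robustness
to clinical image quality.

## Synthetic cohorts

Each record carries a station code, pathology subtype, label, BCP, short
axis, four binary B-mode features and a tri-state PET flag.

**BCP distributions.** Group BCPs are normal draws truncated to [0, 100] by
resampling. The defaults are the published group moments — malignant mean
57.1, SD 14.4; benign mean 31.1, SD 17.3 (percent) — and those moments
describe the *observed, in-range* data, so the parent normal is
moment-matched: its (μ, σ) are solved (via the truncated-normal moment
equations) so that the truncated distribution has exactly the requested
mean and SD. Without this correction the benign group's lower-tail
truncation would inflate its realized mean by ≈ 1.4 points. The correction
is negligible for the malignant group.

**Subtypes.** Subtype labels are always assigned (sampling weights = the
published cohort composition, 17/2/9/9/2 malignant and 22/14/2/2 benign).
Published per-subtype mean BCPs (e.g. squamous 71.6%, small-cell 45.8%,
normal lymphatic tissue 27.0%) ship as an optional preset rather than the
default because per-subtype SDs are unpublished; when enabled, each subtype
uses its own mean with the common group SD — a deliberate simplification.

**Features.** Each binary feature is drawn conditionally on the label from
a (sensitivity, specificity) pair; the defaults are the published pairs
(short axis > 1 cm 100%/5%, round shape 28.2%/100%, distinct margin
30.8%/90%, heterogeneous echo 64.1%/32.5%, vascular pattern 48.7%/50%,
SUV > 2.5 100%/15.4%). PET is measured with probability 28/79, NA
otherwise. Short-axis length is a continuous dressing over its own binary
flag (10 mm + Gamma(2, 2.4) when positive, uniform 5–10 mm when negative,
matching the published ≈ 14.7 mm mean); features are conditionally
independent given the label, which real B-mode features are not — the
feature benchmark is exercised end-to-end, but feature correlations are not
modeled.

**Closed-form oracle.** `binormal_auc` = Φ((μ₊ − μ₋)/√(σ₊² + σ₋²)) gives
the untruncated-binormal AUC; at the default parameters it is 0.876, and
simulated-cohort mean AUC agrees with it to well under the 0.02 the
truncation could shift it.

## Diagnostics

Higher BCP indicates malignancy throughout. Candidate thresholds are the
midpoints between consecutive distinct scores plus one sentinel below and
one above all observations; prediction is *malignant iff score strictly
above the threshold* (a node exactly at a cutoff is called benign, matching
the published "< cutoff benign / > cutoff malignant" convention with
equality resolved conservatively).

* **AUC** — trapezoidal area under the empirical curve with ROC points
  ordered by (FPR, then TPR) so tied-score diagonal segments are traced
  fully; this equals Mann–Whitney concordance with ties counted ½, and the
  test suite verifies the identity against exhaustive pair counting and
  `sklearn.metrics.roc_auc_score` on random small cohorts.
* **CI** — stratified (label-preserving) bootstrap percentile interval,
  2000 replicates by default, seeded; distribution-free and reproducible.
  No analytic (e.g. binormal or DeLong) interval is attempted. The reported
  interval is clipped to contain the point estimate.
* **Youden cutoff** — maximizes J = sensitivity + specificity − 1; ties
  break toward the lowest threshold (preserving sensitivity, the clinically
  dominant property for a rule-out test). The argmax uses a 1e-9 tolerance
  so floating-point noise cannot break mathematically exact ties.
* **Confusion metrics** — sensitivity, specificity, accuracy, PPV, NPV as
  one-decimal percents; a metric with a zero denominator is reported as
  undefined (None), never as 0.
* **Feature benchmark** — a binary feature is treated as
  predicted-malignant-when-positive; SUV metrics use the measured subset
  only. No multiple-testing correction is applied (none is in the reference
  analysis).
* **Group comparison** — per-label mean/SD (n − 1)/min/max and a two-sided
  Welch t-test; the unequal-variance form is chosen because the group SDs
  differ (14.4 vs 17.3).

## Numerical and design notes

* Coordinates are 0-based row-major; rectangles half-open. Files and
  reports use percent; internal computation uses fractions.
* Cohort CSVs are UTF-8, comma-separated, header required, `NA` for
  unmeasured SUV; readers validate per row and report offending line
  numbers. Station codes outside the standard thoracic set are rejected.
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  CLI runs log config, seed and version, and identical inputs give
  bit-identical outputs.
* Problem sizes in the test suite and acceptance script — 200 replicate
  cohorts for the AUC average, 500 for group-mean recovery, 160×200
  rendered frames — were chosen so that Monte-Carlo error is several times
  smaller than the tolerance being checked while the whole suite stays
  interactive.

## Known limitations

* The blue band is a documented approximation; a vendor's exact palette may
  need a recalibrated hue window.
* Region growing keys on the seed color, so a node spanning a wide hue
  range needs a generous tolerance or an external mask.
* The simulator reproduces group moments and feature margins, not joint
  feature correlations, within-node spatial structure, or inter-observer
  ROI variability; patient-level published results (the empirical 36.7%
  cutoff, the 27.9% all-benign floor) are dataset-specific observations and
  are not reproduced, only the procedure that derives them.
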