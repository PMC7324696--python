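# Methods

## Problem and endpoints

Hydrogel spacers reduce rectal dose in prostate EBRT by separating rectum
and prostate, but the benefit is patient-specific. The package predicts, from
pre-implant CT geometry alone, two endpoints of a 60 Gy / 20-fraction plan:

* **Pre-RV55** — percent of rectal volume receiving ≥ 55 Gy on the
  pre-implant plan. 55 Gy is used as the hypofractionated analogue of the
  conventional V70Gy (78 Gy / 2 Gy-per-fraction) toxicity threshold via the
  linear-quadratic model with α/β = 3.
* **ΔRV55** — the reduction of RV55 from the pre- to the post-implant plan.

Both are DVH points: cumulative curves are computed on fractional voxel
occupancy (2×2 in-plane supersampling of voxel centers against the slice
polygons, which reduces raster bias for thin walls), are left-closed
("volume receiving ≥ dose"), default to 0.05 Gy bins, and normalize to the
structure's own voxelized volume so curves start at 100 % and end at 0 %.
Binning is an implementation choice (the endpoints change by < 0.1
percentage points below 0.1 Gy bins).

## Structure recipes and geometric predictors

Structures are per-slice closed polygons on a uniform z-grid in patient LPS
millimetre coordinates (x left, y posterior, z superior; the posterior
margin acts along +y — axis conventions are ours, chosen to match DICOM).
Nested contours follow the even-odd rule, so annular wall slices stored as
two rings behave as a ring.

* **PTV**: anisotropic margin expansion of the CTV (defaults 7 mm, 5 mm
  posterior), implemented as 3D morphological dilation of a rasterized mask
  with a per-direction-scaled ellipsoidal structuring element (the standard
  TPS margin-tool behaviour), then re-contoured per slice with subpixel
  contours. The in-plane structuring radii are inflated by half the raster
  resolution so the discrete dilation is unbiased; at the default 1 mm
  raster an isotropically expanded sphere matches the closed form within
  2 %, and the error shrinks as the raster is refined.
* **RW** (rectal wall): organ minus its erosion by the wall thickness
  (default 3 mm). Erosion is computed on the vector contours as a sampled
  3D ball erosion: on each slice, the intersection of negative buffers of
  that slice and of its neighbours within the thickness, each by
  √(t² − Δz²). We deliberately do *not* erode purely in-plane: in-plane
  shelling misses organ end caps entirely (a spherical shell comes out 17 %
  light), whereas the sampled ball erosion is exact for cylinder interiors
  and matches the spherical-shell closed form within 3 % at 1 mm slices.
  Slices too thin to erode keep the whole slice as wall (logged).
* **RW17.5**: the wall truncated to the PTV z-extent plus 17.5 mm on each
  side; retained contours are unchanged, so the operation is idempotent.

Predictors (the feature vector): rectum, RW and CTV volumes (vector shoelace
areas × slice spacing, in cc); RinPTV = overlap volume of PTV and rectum
(per-slice polygon intersection); normalized RinPTV and CTV volumes as
percent of the **whole rectum** volume (the normalization denominator is the
whole organ, not the wall — sources disagree on the unit label and percent
is used throughout); and RWtoCTV, the unweighted mean over shared slices of
the symmetric 2D Hausdorff distance between the RW17.5 and CTV contour
curves, in cm, with its cube and inverse cube. Hausdorff distances are
measured between contour *curves* (not filled regions), symmetric by
default with a directed variant behind a flag, by dense boundary sampling
(0.05–0.1 mm) with exact point-to-segment distances; slices present in only
one structure are excluded from the mean (the height-limited wall exists to
match the structures' superior/inferior extents). Multi-polygon slices are
merged and the union boundary used.

## Model pipeline

All candidate predictors enter an OLS model of the endpoint and are removed
by **backward stepwise AIC** (drop the single term whose removal lowers AIC
the most; stop when no removal lowers it), then by **VIF pruning** (drop the
highest-VIF term while any VIF ≥ 5), then a cap of **three predictors**
(appropriate to n = 21) by further AIC-ordered removal. The AIC is the
Gaussian-profile form n·ln(RSS/n) + 2(k + 2); any monotone-equivalent
variant yields identical selections, which is the testable contract.
Equal-AIC removals (within 1e-9) drop the term with the larger p-value.
Exactly collinear candidates are resolved before the first fit by dropping
the infinite-VIF duplicate least correlated with the endpoint. Mutually
dependent predictors (rectum vs rectal-wall volume) are declared in
exclusive groups of which at most one — the member best correlated with the
endpoint — may enter. Two candidate sets mirror the published pair of
models: the full geometric set ("Model 1" candidates) and the TPS-derivable
volumes only, without the Hausdorff metrics ("Model 2" candidates).

Reported per model: squared structure coefficients r²s = r²_pears / R²
(apportioning explained variance among retained predictors), and LOOCV
statistics with the term set *frozen* across folds: predicted
R² = 1 − PRESS/SST (PRESS from explicit per-fold refits; the hat-matrix
shortcut is used as an independent test oracle), MAE, and %MAE = 100 ·
MAE / range(endpoint). α = 0.01 flags significance in reports only; it is
not a selection criterion.

## Published models and decision flowchart

Four frozen models ship as a versioned JSON registry (coefficients, SEs,
structure coefficients, fit and LOOCV statistics, the Pearson screening
table, and the cohort summary statistics used for nomogram ranges and
extrapolation warnings). Where the source tables disagree internally
(Pre-RV55 Model 2 R² 0.80 vs 0.87; ΔRV55 Model 1 MAE 1.27 vs 1.29), the
summary-table values (0.87, 1.29 — internally consistent with %MAE) are
adopted. The ΔRV55 Model 1 coefficients as printed do **not** satisfy the
OLS centroid identity at the cohort means (they predict ≈ −0.1 % where the
cohort mean is 4.5 %, consistent with a per-mm rather than per-cm RWtoCTV
coefficient); they are shipped verbatim, no unit guess applied, and using
them raises a warning. Model 2 is the default everywhere (better predicted
R² and %MAE, TPS-only inputs).

The flowchart screens predicted Pre-RV55 against ω₁ = 3.0 % first (patients
already below it gain little and are unlikely to develop bowel toxicity),
then predicted ΔRV55 against ω₂ = 3.5 %; both stages must pass for an
implant recommendation, and boundary values pass ("lower limit" read as
retain ≥, configurable). Predictions default to the models' output since
the use case is pre-implant, but the flowchart accepts measured values too.
Predictions from features outside the published training ranges, or ΔRV55
predictions above the largest observed reduction (~10 %), raise
extrapolation warnings.

Nomograms follow the standard convention: each predictor maps affinely to
points over its published range, scaled so the largest single-term
contribution span covers 0–100 points; the total-points axis maps back to
the prediction exactly (round-trip error < 0.1 %, tested). Zero-coefficient
predictors are excluded with a warning.

## Synthetic data

The generator exists so every stage is testable without clinical data; its
defaults are the published 21-patient cohort conditions.

* **Cohorts ("model" mode)**: volumes and the normalized overlap are drawn
  log-normal (right-skewed, matching the published max/mean ratios),
  distances normal, all truncated at the published min/max; the published
  summary statistics are the calibration targets. Endpoints follow the
  published Model 2 equations plus Gaussian noise with
  σ² = Var(ŷ)(1 − R²)/R², so large-n refits recover both the coefficients
  and the printed R². Only marginals are published; a Gaussian copula
  couples the rectum–CTV distance negatively to the normalized overlap
  (default −0.4), an explicit assumption. Endpoints are not truncated at
  zero, keeping the generating model exactly linear for recovery tests.
* **Phantoms ("geometric" mode)**: ellipsoidal CTV, tubular gently-bowed
  rectum placed at a controlled minimum gap (two-pass placement measures and
  corrects the realized gap), spherical bladder; spacer implant displaces
  the rectum posteriorly with a raised-cosine taper maximal at mid-gland
  (volume conserved exactly) and fills the vacated space with a spacer
  structure.
* **Surrogate dose**: prescription inside the PTV, sigmoidal falloff in
  distance to the PTV surface (80 % → 20 % over 8 mm by default, anchored at
  95 % on the surface). It is *not* a VMAT emulator: it exists to give
  geometry-dependent rectal V55 with the correct monotone structure — V55
  falls strictly as the rectum moves away from the PTV and saturates at
  zero once the rectum clears the 55 Gy isodose (~1.6 mm outside the PTV at
  the default penumbra). Consequently geometric-mode endpoints are smaller
  and steeper in the gap than clinical ones, and phantom RWtoCTV values run
  larger than the published mean (the phantom rectum is a full tube whose
  far wall dominates the Hausdorff distance). Passing geometric-mode tests
  therefore demonstrates pipeline correctness and monotone structure, not
  clinical dose realism; quantitative calibration checks use "model" mode.

All generators are deterministic under a fixed seed.

## Test problem sizes and numerical choices

Closed-form geometry oracles use spheres/cylinders/boxes at 1–2 mm slices
and the default 1 mm raster (tolerances 2–3 %); Hausdorff is verified
against brute-force max–min over 0.1 mm boundary samples within 0.2 mm; DVH
against per-voxel point-in-polygon counting on small grids; LOOCV against
the hat-matrix PRESS identity to 1e-8; parameter recovery uses 500
replicates of n = 21 cohorts; retention simulations use 200 cohorts of 21.
Degenerate inputs are defined behaviour: empty stacks error in derived-
structure operations, a constant response reports R² = 0 with a warning,
RSS = 0 gives an AIC of −inf with a warning, exact collinearity gives an
infinite VIF sentinel, and disjoint z-ranges in height limiting return an
empty structure with a warning.

## Known limitations

* The published per-patient features are not available, so the cohort-level
  retention (12/21) is checked as a simulation bracket, not reproduced.
* The surrogate dose model ignores beam geometry, bladder sparing and plan
  optimization trade-offs.
* DICOM support is read-only (axial CLOSED_PLANAR contours, uniform-offset
  dose grids); writing is limited to the internal JSON/CSV formats.
* The joint distribution of the geometric predictors is an assumption; only
  the marginals are calibrated.
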