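# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a methods appendix.  Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Radiobiological and PET conversions

* **BED.**  For a voxel receiving total dose `D` over `n` equal fractions,
  `BED = D · (1 + (D/n)/(α/β))`.  The default `α/β = 1.5 Gy` is the
  conventional prostate value; the 35 Gy / 7-fraction prescription maps to
  151.7 Gy.  The conversion is applied voxel-wise to the dose grid, so
  heterogeneous dose becomes heterogeneous BED non-linearly.
* **SUV.**  Body-weight SUV with decay correction to scan time:
  `SUV = c · w / (A₀ · 2^(−Δt/T½))` with activity concentration `c`
  (Bq/mL), body weight `w` (g), injected activity `A₀` (Bq), delay `Δt`
  and isotope half-life `T½` (s).  This is the most common convention;
  all four parameters are explicit arguments.

## Image processing chain

Fixed order: unit conversion → rasterization on the native CT grid →
trilinear resampling of volumes and fractional mask to 1 × 1 × 1 mm³ →
mask binarization at 0.5 → CT rounding to integer HU (ties away from
zero) → ROI isolation (NaN outside) → 64-level fixed-bin-number
discretization.  No re-segmentation (intensity range exclusion) is applied.

Numerical details worth knowing:

* The crossing-number test casts a +x ray and treats edges half-open in y,
  so points in line with vertices resolve deterministically.  Multiple
  polygons on one slice combine by the even-odd rule (nested contours
  carve holes).  Degenerate zero-area polygons contain nothing and warn.
* Resampling places the first output voxel centre half an output voxel
  inside the input's leading edge; resampling a grid already at the target
  spacing is exactly the identity, and trilinear outputs never overshoot
  the input range.  Dose/PET grids that differ from the CT frame are first
  resampled onto it (trilinear throughout); the phantom writes co-registered
  grids, so this path only activates for external data.
* Fixed-bin-number discretization maps the ROI minimum to level 1 and the
  maximum to level N (=64), making texture features invariant to affine
  intensity rescaling; a constant ROI maps wholly to level 1.
* The semi-automated PET segmentation (40% of the regional SUV maximum,
  restricted to the 26-connected component of the peak) is provided for
  completeness; feature extraction uses the stored GTV contours, which is
  how the delineation workflow it mimics stores its result.

## Feature catalogue

380 = 17 shape + 3 × 121 per-modality features; the catalogue is data
(`features/catalogue.py`), not constants scattered in code.  Families
follow IBSI definitions: population variance, Fisher (excess) kurtosis,
histogram entropy in bits, mode ties to the lowest level,
skewness/kurtosis of a constant ROI defined as 0.  Texture matrices use
64 levels, distance-1 Chebyshev neighbourhoods, 13 unique 3D directions
with per-direction features averaged (an IBSI-sanctioned aggregation),
26-connectivity zones/dependence, NGLDM coarseness parameter α = 0.  Only
voxel pairs/neighbourhoods fully inside the ROI contribute.  Local
intensity peak features are deliberately excluded to close the catalogue
at 380.

Shape features are mesh-based (marching cubes at 0.5 on the zero-padded
mask).  The binary mask is smoothed with a σ = 0.8 voxel Gaussian before
meshing: raw binary marching cubes overestimates a sphere's surface by
≈ 9% (staircase artefact), which would bias sphericity to ≈ 0.91; with
smoothing a digital r = 10 mm ball measures ≈ 0.99.  Axis lengths come
from a PCA of voxel centres (4√λ), the maximum 3D diameter from the convex
hull of voxel centres.

## Learning stack

* **ADASYN** (k = 5, full balancing β = 1 by default): synthesizes
  `G = (n_maj − n_min)·β` minority points, allocated per minority seed by
  the fraction of majority samples among its k nearest neighbours
  (largest-remainder rounding so the total is exact), each point a uniform
  convex combination with a random minority neighbour.  Originals are
  never modified.
* **NCA feature weighting** maximizes `Σᵢ pᵢ − λ Σ w²` with
  `p_ij ∝ exp(−Σ_r w_r² |x_ir − x_jr|)` and λ = 0.02, solved by
  per-sample stochastic gradient ascent (8 passes, learning rate
  0.3/(1 + 0.2·epoch)) with a proximal shrinkage step for the L2 term
  (stable for any λ).  Weights start at 1/√p so initial distances are
  O(1) and the softmax is not frozen onto single nearest neighbours; the
  returned weights are |w|.  A handful of SGD passes matches the
  full-batch optimum to within 2% on small problems (tested), which is why
  the default epoch count is small.  NCA runs on the ADASYN-augmented
  training fold (switchable).
* **Weak learners** are CART trees grown best-first on weighted Gini with
  at most 4 internal splits (`max_leaf_nodes = 5`), guaranteeing the tree
  is at least as good as the best single threshold.
* **RobustBoost** is the continuous-time boost-by-majority variant with
  Gaussian potential; self-time runs 0 → 1, examples are weighted by
  `exp(−(m − μ(t))²/2σ(t)²)` with
  `σ(t)² = (σ_f²+1)e^{2(1−t)} − 1`, `μ(t) = (θ−2ρ)e^{1−t} + 2ρ`,
  σ_f = 0.1, θ = 0, and ρ calibrated so the initial potential of a
  zero-margin example equals the 5% error goal.  Each cycle solves for the
  largest feasible time step (geometric halving) whose edge-balancing
  coefficient α (Brent root of the reweighted edge) does not increase the
  mean potential.  Failure to find a step three times in a row, a stalled
  clock, or t ≥ 1 terminates training; margins accumulate as
  `m += α·y·h(x)` and the final score is the weighted vote.  A plain
  AdaBoost with identical weak learners is provided as a comparator
  behind the same interface — under 10% label noise RobustBoost's held-out
  error is at least as good in the majority of seeded repetitions
  (tested).
* **Decision rule**: positive iff the vote score exceeds 0; the ROC uses
  the continuous score.

## Cross-validation protocol

Repeated stratified 10-fold CV (100 repetitions in the full protocol).
Standardization, ADASYN, NCA and tree fitting receive only training
indices (a runtime assertion checks fold disjointness); the feature sweep
refits the ensemble for every m = 1..8 on the same fold's NCA ranking.
Per repetition the ten test folds' scores are pooled into one metric set
(pooling chosen over per-fold averaging for stability at n ≈ 43); means
and population-σ are reported over repetitions, and the best m maximizes
mean accuracy (ties to the smaller m).  Degenerate splits (a training
side losing a class) trigger a logged fold re-draw.  Accuracy equals the
prevalence-weighted mean of sensitivity and specificity; this identity is
asserted per repetition.

## Phantom cohort

The generator emulates the study conditions: 43 patients at 30.2%
prevalence by default, a GTV of a few cm³ (per-axis semi-axes ~N(8, 1²) mm)
emitted as 24-vertex per-slice polygons with a ±2–3% smooth radial wobble,
CT soft-tissue background (40 ± 8 HU correlated noise), a PET focus ≥ 4×
background, ¹¹C radiopharmaceutical metadata, and a dose plateau exactly at
the 35 Gy prescription inside the GTV (plus a 0.5 mm margin absorbing the
polygon wobble) with a 5 mm-scale sigmoid penumbra.  Within-GTV dose
texture is a smoothed Gaussian field whose amplitude is
`dose_heterogeneity × U(0.4, 1.6)` per patient (default 1.5 Gy) — this
per-patient spread is what carries the outcome signal.

The outcome follows `logit P(event) = a + effect_size · z`, where z is the
cohort-standardized within-GTV BED variance and the intercept a is
calibrated by bisection to the target prevalence.  Driving the outcome
with BED variance is a modelling choice of this package (motivated by
dose-texture features being the plausible predictors in this setting),
not a clinical claim.  Event times are uniform on (6, 35) months, event-free
follow-up on (12, 102) months, so a 36-month binarization horizon labels
all simulated events positive.

What the phantom does *not* emulate: realistic anatomy and organs at risk,
PET reconstruction artefacts and partial-volume effects, registration
error between modalities, deliverability constraints of VMAT plans, or
censoring before the horizon that hides true late events.  Passing tests
therefore demonstrate the *pipeline's* correctness and anti-leakage
behaviour, not clinical performance on real patients; the clinical
numbers from a private 43-patient cohort are not reproducible here.

## Problem sizes used in the automated checks

The end-to-end checks run the full pipeline at reduced scale, chosen as
the smallest sizes at which the statistical properties are stable: the
leakage null uses 100 phantom patients with permuted labels and 10
repetitions of 10-fold CV (mean AUC must stay in [0.40, 0.60]); signal
recovery uses 200 patients, effect size 2, 10 repetitions (mean AUC at the
best feature count above 0.70 with BED-prefixed features dominating the
selection histogram).  `scripts/acceptance.py` uses 100 patients and 5
repetitions.  The full 100-repetition protocol is a `CVConfig` away.

## Serialization

Patients travel either as a portable container (raw little-endian float32
volumes + JSON sidecars; lossless to float32 precision) or as minimal
DICOM CT/PT/RTDOSE/RTSTRUCT (PT quantized through a 16-bit rescale slope,
so round trips are exact only to ~10⁻⁴ relative; the outcome label lives
in an `outcome.json` sidecar because no standard IOD carries it).  Models
serialize to JSON with trees as nested split records.

## Known limitations

* The exact 380-feature set of the original in-house benchmark is not
  recoverable; the catalogue is fixed here by family counts and IBSI
  definitions, and includes the four named headline predictors (BED
  variance, energy, integrated intensity, LZHGE).
* RobustBoost follows the published algorithm, not any particular
  toolbox's internals bit-for-bit.
* Oblique DICOM orientations are rejected rather than resliced.
* The NGTDM/NGLDM "busyness"/"strength" conventions use the guarded forms
  (0 when their denominators vanish).
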