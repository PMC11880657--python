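# Methods

## Problem setting

Whole-breast radiotherapy is planned with one of two techniques:
tangential-field 3D conformal radiotherapy (3D-CRT), the simpler default,
or intensity-modulated radiotherapy (IMRT), which trades more planning and
delivery effort for better target conformity and lower high-dose exposure
of the heart and ipsilateral lung — at the price of a larger low-dose bath
in the rest of the body. The package implements a decision-support
pipeline: predict the dose distribution each technique would deliver
directly from the CT and structure masks (no manual planning), derive
dose–volume-histogram (DVH) metrics from the predictions, and recommend
3D-CRT whenever its predicted plan satisfies the organ-at-risk (OAR)
constraints

* ipsilateral lung V20Gy < 30 %,
* heart V25Gy < 10 %,
* mean heart dose < 3 Gy (all comparisons strict),

falling back to IMRT otherwise. Recommendations are validated against
ground-truth technique labels with a 2×2 confusion matrix whose positive
class is 3D-CRT, reported as accuracy / recall / precision / F1 in percent
to one decimal.

Because no clinical imaging or dose data are distributed, the entire
pipeline is exercised on a synthetic phantom cohort whose construction is
itself part of the package (`phantom_sim`).

## Synthetic cohorts

Each phantom is a pseudo-3D stack of 12 axial slices on a 96×96 grid
(3 mm in-plane spacing). Slice thickness follows the emulated institution:
3.75 mm for `inst1`, 3 mm for `inst2`. Anatomy per slice: an elliptical
body contour, two posterior elliptical lungs, an elliptical heart, a
breast planning target volume (PTV) drawn as a crescent hugging the
anterior-lateral surface on the treated side, and (for node-positive
cases) a small nodal PTV on the cranial slices. Structure sizes vary
slowly along the stack so DVHs are genuinely volumetric while the
prediction network stays 2D. CT-like intensities are −1000 HU background,
≈20 HU soft tissue, −700 HU lung, with mild Gaussian noise inside the
body; the masks, not the intensities, carry most of the geometric signal,
as in clinical dose-prediction practice.

Case difficulty is controlled by recorded covariates:

* `heart_proximity` ∈ [0, 1] — interpolates the heart centre from a deep
  mediastinal position to the anterior chest wall beneath the tangents;
* `curvature` ∈ [0, 1] — how far the PTV wraps around the chest, which
  deepens the tangential field edge;
* `ptv_size` ∈ [0, 1] — angular extent and thickness of the PTV;
* node positivity (adds the nodal PTV).

Cohort mixes are sampled distributions (`CohortSpec`): laterality is
50/50, node positivity 0.75 (`inst1`) / 0.36 (`inst2`) following the two
institutions' reported nodal fractions, and `heart_proximity` follows a
Beta distribution per institution. The `inst2` defaults were chosen once,
during generator design, so that the constraint rule below accepts 3D-CRT
for roughly 23 of 30 cases of a validation-sized cohort — the acceptance
fraction of the clinical external-validation cohort the framework is
modelled on. The paper-side anatomical mix is otherwise unreported, so
these distributions are package defaults, stated in config and not
inferred from data.

## Analytic dose engines

Dose is produced by deterministic geometric surrogates, not transport
physics; they are designed to create a learnable CT→dose mapping and the
correct qualitative 3D-CRT/IMRT contrast, with every map obeying
0 ≤ dose ≤ 1.3 × prescription (prescription fixed at 50 Gy = 2 Gy × 25).

**Tangential 3D-CRT engine.** The opposed tangents are modelled in the
axial plane as a slab ("corridor") whose axis runs perpendicular to the
radial direction from the body centre to the PTV centroid — i.e. tangent
to the chest wall at the breast. The slab spans the PTV's extent along
that radial direction plus a 6 mm margin on both edges, so the deep edge
clips the chest wall exactly as clinical tangents do. Inside the corridor
the relative dose is 1 + 0.03·sin(πu) (u the normalized depth across the
slab: a wedge-compensated ripple, continuous at the field edges); outside
it falls off as a Gaussian penumbra, exp(−d²/2σ²) with σ = 6 mm on the
distance d beyond the nearer edge. Dose is zero outside the body and the
corridor is fixed per case from the axial PTV projection (beams do not
re-aim per slice). Heart dose is therefore monotone in `heart_proximity`:
moving the heart toward the chest wall strictly reduces its distance to
the slab.

**IMRT engine.** Two components, combined voxelwise by maximum:

* a conformal high-dose term P·exp(−d_PTV²/2σ²) on the Euclidean distance
  to the PTV surface (flat P inside the PTV). Because the PTV lies inside
  the corridor slab and distance-to-slab ≤ distance-to-PTV everywhere,
  this term never exceeds the 3D-CRT dose outside the PTV — which makes
  the high-dose OAR sparing (heart V25, lung V20 never worse than 3D-CRT)
  a provable property of the engine pair, not a statistical accident;
* a stylised low-dose bath of 5.3 Gy over soft tissue, attenuated to 35 %
  inside lung and 4 % inside the heart, standing in for the multi-beam
  low-dose spread of IMRT with an optimiser that steers fluence off the
  OARs. The bath amplitude is deliberately above 5 Gy so the
  "IMRT irradiates more body volume at low dose" contrast (body V5Gy)
  holds for every case; its flat spatial profile is an acknowledged
  simplification.

**Ground-truth labels.** A case is labelled `3DCRT` when the *simulated*
3D-CRT plan passes all three OAR constraints, else `IMRT` — the same rule
an independent observer applies to the two manually produced candidate
plans. Feeding the framework the reference (oracle) metrics must
therefore reproduce the labels exactly; this is used as an end-to-end
plumbing check.

## Data preparation

Per axial slice with a nonempty body mask: crop to the body bounding box
plus a 2-voxel margin; nearest-neighbour resample to a fixed square
(128×128 default; the reduced experiments use 64×64); scale CT to [0, 1]
with a 400/40 HU window/level; stack channels in the fixed order
(CT, body, ipsilateral lung, heart, breast PTV, nodal PTV), the nodal
channel being all-zero for node-negative cases so the channel count is
constant. The nearest-neighbour index rule is bit-exact: output pixel *i*
of *n_out* copies input pixel `floor((i+0.5)·n_in/n_out)` (ties toward
the larger index); mask channels therefore remain binary. Aspect ratio is
*not* preserved — each crop box is stretched to the square — so the crop
box and original shape are stored per slice and predictions are mapped
back through the inverse transform before any volumetric DVH is computed.
DVH metrics are evaluated on the original grid after back-mapping.
Renormalization scales any plan to the common 50 Gy prescription
(values × 50/original prescription).

Cross-validation splits are at patient level with a seeded permutation:
all slices of a case share a fold, folds differ in size by at most one,
and each fold serves once as the test set so every case receives exactly
one out-of-fold prediction. A structural (not statistical) leakage check
rejects any fold whose train and test case sets intersect.

## Dose regression network

A 2D U-Net with depthwise-separable (Xception-style) 3×3 convolutions,
implemented in NumPy with hand-derived backpropagation and a numba kernel
for the depthwise pass (`breastplan.nn`). Architecture: two conv+ReLU
pairs per resolution level, 2×2 max pooling, nearest-neighbour ×2
upsampling, skip concatenation, and a linear 1×1 dose head. Default
configuration is depth 4 with 32 base filters; the desk-scale experiments
use depth 3 with 16 base filters at 64×64. The exact block recipe of the
cited architecture family is not fully specified anywhere, so this layout
is a documented package default and fully configurable.

Training follows the fixed published hyperparameters: voxel-wise MSE,
Adam with learning rate 0.001, β₁ = 0.9, β₂ = 0.999, 20 epochs, no
validation split or early stopping. Batch size (unspecified in the source
protocol) defaults to 16. Internally the network regresses
dose/prescription (≈[0, 1.05]); predictions are rescaled to Gy, clamped
at zero, restored through the stored crop boxes and zeroed outside the
body. The head is linear rather than ReLU because a hard-rectified output
unit can silently die under MSE in the first epochs (observed during
development); non-negativity is enforced at prediction time instead.
Initialisation and batch shuffling are fully seeded; determinism is
best-effort (identical on one machine, not guaranteed bit-identical
across BLAS builds), so quality gates use tolerances, never exact values.

Training regimes mirror the two-institution transfer design: ModelA from
scratch on the `inst1` 3D-CRT cohort (k-fold CV); ModelB/ModelC fine-tune
ModelA's weights on `inst2` 3D-CRT / IMRT plans with *all* layers
trainable; ModelD trains from scratch on the `inst2` IMRT plans as the
fine-tuning control.

## Evaluation

DVH metrics are exact voxel statistics (no binning): Dmean; D95 as the
5th percentile of voxel doses with linear interpolation between order
statistics (the estimator is a documented choice — the source protocol
never defines one — and tests allow one interpolation step of slack);
V95 (% of structure volume ≥ 95 % of prescription); V20Gy; V25Gy. Both
V95 and D95 are reported for PTVs since clinical summaries quote both.
Empty structures raise a structure-absent signal and are excluded from
cohort tables, never reported as zero. Clinical-minus-predicted deltas
normalise dose metrics by the prescription (×100 %) and difference volume
metrics directly in percentage points; cohort tables report mean ± sample
SD per regime × structure × metric.

Spatial agreement uses isodose volumes (superlevel sets at a percentage
of prescription, computed volumetrically per case) compared with the Dice
similarity coefficient; the default threshold grid is 5 %…100 % in 5 %
steps (the exact grid of the source figures is unstated) and the headline
number is the mean DSC over the clinically emphasised 30–70 % band. Two
empty volumes are defined to agree perfectly (DSC 1.0), which occurs at
thresholds above both plans' maxima.

## Desk-scale study conditions

`breastplan.experiments` fixes the problem sizes used by the test suite
and the reproduction script: a 40-case `inst1` 3D-CRT source cohort with
k = 4 cross-validation of the reduced network (depth 3, 16 filters,
64×64, 20 epochs); a 15-case `inst2` IMRT-style target cohort for the
transfer comparison (10 training / 5 held-out cases, three repeat splits,
fine-tune initialised from the first source fold model); and fresh
30-case `inst2` cohorts for the decision-framework runs (matching the
30-patient external validation design). These sizes keep the full
pipeline at minutes on a single CPU while leaving each training run
enough data to reach high out-of-fold agreement (mean 30–70 % DSC ≈ 0.95
at the defaults).

## What passing the synthetic suite does and does not show

The generator provides exactly the structure the method needs — doses
that are deterministic functions of visible geometry, a difficulty
covariate that moves cases across the constraint boundaries, and a
paired-technique contrast with the right sign everywhere. It does *not*
emulate scatter and beam-hardening physics, wedge/MLC mechanics,
breathing motion, contouring variability, or inter-scanner intensity
differences. Passing therefore demonstrates that the pipeline — data
preparation, network, metrics, decision rule, and their couplings — is
implemented correctly and that transfer learning helps on small target
cohorts *under these conditions*; it does not certify clinical
performance numbers, which require real planning data.

## Known limitations

* Dose engines are 2.5-D (per-slice fields from one axial projection);
  no divergence, no build-up region, no field-in-field segments.
* The IMRT bath is spatially flat and slightly exaggerated to make the
  low-dose-bath contrast hold case-by-case.
* The NumPy/numba network is single-CPU; wall-clock, not capability,
  bounds the cohort sizes.
* The tie-break when both techniques fail the constraints recommends
  IMRT and flags the case for review (`needs_review`); the clinical rule
  is silent on this branch.
* PTV-coverage metrics are reported in the audit output but never gate
  the recommendation, which follows the OAR-only published rule.
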