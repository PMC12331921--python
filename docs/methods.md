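# Methods

## Problem setting

After surgical resection, glioblastoma radiotherapy must choose a clinical
target volume (CTV) on the pre-radiotherapy (pre-RT) MRI, weeks before the
pattern of regrowth is observable.  `ctvkit` treats CTV definition as a
voxel-wise prediction problem: from co-registered, skull-stripped pre-RT
maps — normalized post-contrast T1 (nT1c), T2-FLAIR (nFLAIR), apparent
diffusion coefficient (nADC), fractional anisotropy (nFA), and the
spectroscopic choline-to-NAA and choline-to-creatine indices (CNI, CCrI) —
predict the *composite lesion*: the union of contrast-enhancing (CEL) and
non-enhancing (NEL) lesion at both the pre-RT and the progression
timepoint.  A CTV that covers this composite covers where the tumour will
progress.

All volumes of a case share one 3 mm isotropic grid; margins, surface
distances and expansions are computed in physical millimetres via
Euclidean distance transforms, never in voxel units.

## ROI algebra and voxel transitions

Per timepoint: NEL = T2L \ CEL and NAV (normal-appearing voxels) =
brain \ (cavity ∪ ventricles ∪ T2L ∪ CEL).  Between timepoints each brain
voxel receives exactly one label: STABLE_NAV, NAV→NEL, NAV→CEL, NEL→CEL,
OTHER (e.g. voxels already enhancing at pre-RT), or OUTSIDE_BAND.  The
analysis band is the pre-RT lesion expanded by 40 mm — progression is not
observed beyond it, and restricting the negatives to the band controls the
otherwise overwhelming class imbalance.  Voxels in pre-RT T2L that become
CEL without having been NEL are OTHER, not a transition: only the three
progressed classes plus stable NAV are defined.

Per-patient statistics take the median of each channel over each
transition class with at least 5 voxels (metabolic channels additionally
require 5 *covered* voxels inside the PRESS box, so baseline fill never
contaminates a median).  Cohort inference is a paired Wilcoxon signed-rank
across patients on these medians; p-values are reported with conventional
banding (<0.05/<0.01/<0.001/<0.0001).  The unpaired Mann–Whitney rank-sum
is available as an option because the clinical description of the test is
ambiguous between the two; paired is the default since both class medians
come from the same patient.  The reported statistic is the signed rank sum
W⁺ − W⁻ so that swapping the compared classes flips its sign.

## Voxel-wise random forests

Two binary tasks against stable NAV: CEL progression (NAV→CEL ∪ NEL→CEL)
and NEL progression (NAV→NEL).  Features are the 13 channel values plus an
`mrsi_covered` flag; metabolic features outside the PRESS box keep their
baseline fill and the flag carries the coverage information explicitly.
Cross-validation is 5-fold, grouped by patient (no patient on both sides
of a fold) and stratified by treatment cohort; "five-fold" is taken as
primary and the 70/30 train/test ratio as descriptive.  Defaults: 200
trees, balanced class weights, impurity importances; the stable-NAV
majority can be down-sampled per case (seeded, recorded in provenance).
AUC is the ROC integral and is cross-checked in tests against the
brute-force pairwise-ordering count (ties ½).

## The size-adaptive Tversky loss (PCC)

For confusion sums TP, FP, FN restricted to the brain,

    T(α, β) = (TP + s) / (TP + α·FP + β·FN + s),        s = 1e-6

with α = β = ½ the Dice coefficient.  The Progression Coverage Coefficient
sets per-case weights from the lesion-to-brain voxel fraction
f = n_lesion/n_brain:

    β = 1/(f + 1),   α = 1 − β,

algebraically identical to β = n_brain/(n_brain + n_lesion).  β decreases
strictly in f: the smaller the lesion, the harder misses (undertreatment)
are punished.  At the cohort-average f ≈ 0.02, (α, β) ≈ (0.02, 0.98);
this fixed setting is the model-selection and reporting metric
`tversky_002_098`.

The lesion reference that sets f is the ground-truth composite target
during training and evaluation; at pure inference the pre-RT lesion is the
documented fallback.  Training uses soft (probability-weighted) counts for
differentiability; all reported metrics use hard binarized masks.  The
compound loss is (1 − soft PCC) + λ·BCE with probabilities clipped at
1e-7 before the logarithm; λ = 0 recovers pure PCC loss and λ defaults to
0.5 when the compound loss is selected.

## Segmentation network and training

A 4-stage 3D U-Net: two 3×3×3 convolution + ReLU units per stage, feature
width doubling from `base_features`, 2× average-pool downsampling,
nearest-neighbour upsampling, concatenation skips, and a 1×1×1 projection
to one logistic output channel.  Average pooling was chosen over max
pooling for its trivial adjoint; the downsampling operator is not fixed by
the clinical description and either is admissible.  Inputs are min-max
normalized per case within the brain; when metabolic channels are used the
PRESS-box coverage mask is concatenated as an extra input channel
(predictions outside the box are otherwise unstable).  Inputs whose
extents are not divisible by 2^(stages−1) are symmetrically zero-padded
and cropped back after the forward pass.

No autodiff framework is available in the target environment, so the
network is pure NumPy: convolutions are k³ shifted GEMMs with analytic
backward passes, verified in tests by finite differences and adjointness
checks.  The optimizer is Adam (the contract is "adaptive first-order
optimizer"; the rectified/lookahead variant reported clinically is an
implementation detail).  Batch size is 1.  Augmentation (axis flips, 90°
rotations co-applied to channels, target and brain mask; Gaussian noise,
channel shuffle and channel drop on channels only) is available but off by
default at desk scale.  Model selection maximizes validation
Tversky(0.02, 0.98) per epoch; the best epoch's weights are restored.

Patient splits are 67/16/17 train/validation/test, stratified by
treatment cohort, deterministic under seed, with a leakage guard asserted
at training start.  The hyperparameter search is two-phase (exhaustive
small grid, then random draws within the top-half range), ranked by
validation Tversky(0.02, 0.98); the clinically reported optimum (learning
rate 5×10⁻⁵, 48 base features, batch 1) ships as `paper_profile()`, while
desk-scale defaults are base 8, learning rate 10⁻³, ≤120 epochs.

## CTV construction and evaluation

* **DL** — binarize the probability field at 0.5 (not tuned; tuning
  exists behind a flag with validation-only optimization), keep
  26-connected components intersecting the pre-RT lesion ∪ cavity (else
  the largest), fill internal holes, clip to brain.
* **RTOG** — (CEL ∪ T2L) + 20 mm uniform expansion.
* **EORTC** — (CEL ∪ cavity) + 15 mm expansion, minus vasogenic edema.
  Edema is operationalized as the pre-RT NEL — the only T2-hyperintense
  non-enhancing compartment the data model defines — and the exclusion is
  a toggle because clinical edema and NEL are not strictly identical.
  Exclusion is applied after the expansion; the other order is reachable
  by expanding a reduced seed.
* **PRERT_ONLY** — the pre-RT lesion with no margin, a deliberately
  pathological baseline.

All expansions use the anisotropy-aware Euclidean distance transform with
inclusion at ≤ margin and are clipped to the brain (dose targets outside
the skull-stripped brain are meaningless).  Expansion is assumed fully 3D;
whether the clinical margins were drawn per-slice is not recorded.
Critical-structure removal takes an explicit organ-at-risk mask (no atlas
registration).

Evaluation reports six metrics per case: sensitivity, specificity, Dice,
HD95, Tversky(0.02, 0.98), PCC.  Specificity (and TN) is brain-restricted —
air voxels would inflate it meaninglessly.  HD95 extracts 6-connectivity
boundary voxels, computes both directed surface-distance sets in mm
(KD-tree nearest neighbours) and returns the 95th percentile of the pooled
set; the max-of-directed-percentiles convention is available behind a
flag.  Definition comparisons are paired Wilcoxon signed-rank per metric.

## Synthetic cohort generator

The generator emits the *statistical structure* the method relies on, not
tumour biophysics:

* Brain: an ellipsoid (≈1000 cm³ at the default 48³/3 mm grid) with two
  ventricle ellipsoids and a spherical resection cavity at the lesion
  centre.
* Lesions: a radially decaying field plus correlated noise, thresholded
  at the top-k voxels; CEL uses a smaller k of the same field, making
  CEL ⊆ T2L hold by construction.  Progression re-thresholds the same
  field with a per-case directional drift (new growth is anisotropic) and
  a larger k, restricted to the 40 mm band (hard constraint).
  Anti-angiogenic cohorts (ATT, ENZA) get a reduced enhancing fraction:
  progression biased toward non-enhancing growth.
* Channels: compartment baseline + transition-class shift + spatially
  correlated Gaussian noise (correlation length 2 voxels, SD 0.8) + white
  noise (SD 0.3).  Default transition shifts are ordered
  CNI (0.8) > CCrI ≈ nFLAIR (0.7) > nADC (0.3) > |nFA| (0.2), matching the
  reported significance ordering; magnitudes are free parameters — the
  clinical source reports significance levels, not effect sizes — chosen
  so the cross-validated voxel AUC lands near 0.9 rather than saturating.
* Cohort laws: log-normal lesion volumes (median 26.4 cm³, σ = 0.8,
  redrawn while exceeding 12% of the brain), treatment mix 44/27/30
  (SOC/ATT/ENZA) by largest remainder, log-normal progression times with
  per-cohort medians (4.7/12.0/7.1 months) giving an overall median near
  the 7-month early/late threshold.  Cases progressing at ≥7 months have
  their transition shifts attenuated ×0.4, which reproduces the reported
  early-better-than-late prediction ordering.
* MRSI coverage: an axis-aligned PRESS box centred on the lesion covering
  60% of the brain bounding-box volume; metabolic maps are baseline-filled
  outside it and the coverage mask is exported.

All randomness derives from one integer seed with per-case sub-seeds, so
case *i* is bit-reproducible in isolation.

**What a green test establishes** — that the pipeline recovers planted
effects with correct geometry, grouping and statistics at realistic class
imbalance.  **What it does not** — clinical performance: the generator has
no infiltration biophysics, no registration error, no scanner or site
effects, no pseudoprogression, and its lesion textures are far simpler
than real multiparametric MRI.  Desk-scale tests use 32³ grids with the
lesion-volume median scaled to 8 cm³ to preserve the lesion-to-brain
fraction (f ≈ 0.027) and hence the class-imbalance regime.

## Numerical choices

* Smoothing constant 1e-6 in all ratio scores; identities (e.g.
  Tversky(½,½) = Dice) are asserted at smooth = 0.
* Masks binarize at > 0.5 on read; probability fields are validated to
  [0, 1].
* Mask resampling is nearest-neighbour with `grid_mode=True` (pixel-area
  convention — preserves sphere volume within 15% at 1→3 mm); continuous
  channels are trilinear.
* Early/late split boundary: `early < 7 months <= late`.
* Network arithmetic is float32; losses and metrics accumulate in float64.

## Known limitations

* The NumPy trainer is single-threaded and desk-scale; the full-size
  configuration (48 base features) is expressible but slow on CPU.
* `resample_to_grid` aligns grids by the affine's direction/spacing only;
  sub-voxel origin shifts after resampling are ignored (documented
  tolerance: physical extent within one voxel).
* Deformable inter-exam registration, skull stripping, spectral
  reconstruction, dose computation and survival analysis are out of scope;
  inputs are assumed co-registered and skull-stripped.
* The DL-CTV threshold (0.5) is a convention, not an optimum; tuning it on
  validation data is available but off by default.
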