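# Methods notes

## The problem and the pipeline

The package implements a complete radiomics study design for a binary
lesion-classification task on paired ¹⁸F-FDG PET/CT: two breast nodule
classes (DLBCL-like lymphoma vs IDC-like carcinoma) that are hard to
separate on routine reading but differ in metabolic intensity and in
*intratumoral texture heterogeneity*.  The analysis unit is the lesion
(nodule), not the patient.  Stages: harmonization → three feature classes
(clinic, handcrafted, deep) → four-selector biomarker discovery → a
classifier grid with internal cross-validation and external testing →
attribution of the final model.

## Preprocessing

All volumes are resampled to 1×1×1 mm (trilinear for intensities, nearest
neighbour for masks so they stay binary).  CT is clamped to [−200, 300] HU;
this is read as a plain intensity window, with no histogram equalization.
PET activity concentration (kBq/mL) is converted to body-weight SUV,
SUV(v) = C(v)[Bq/mL]·W[g]/D[Bq]; the conversion refuses already-converted
input, and no additional decay correction is applied (the synthetic
generator emits decay-corrected concentrations).  2.5D patches take, per
orthogonal plane, the slice with the largest in-plane mask area (ties →
lowest index), crop the mask bounding box padded to a square with a 10 %
margin, resize bilinearly (CT 64×64, PET 128×128) and min-max scale each
patch to [0, 1].  Per-patch min-max rather than standardization was chosen
for CNN input stability with nonnegative SUV inputs.

## Handcrafted features

Discretization uses fixed bin widths of 0.25 SUV (PET) and 25 HU (CT) on
original images, width 1 on integer LBP codes, and a fixed 32-bin count on
wavelet/LoG outputs whose scale is lesion-dependent.  Texture matrices are
3D with the full 26-neighbourhood geometry: GLCM symmetric at distance 1
summed over the 13 unique directions; GLRLM runs summed over the same 13
directions (run percentage is normalized by voxels × directions,
consistent with the summed matrix); GLSZM zones are 26-connected; GLDM
uses dependence tolerance α = 0; NGTDM follows the IBSI definition.
Entropies use log₂ with ε = 1e−16 inside the logarithm.  Every matrix
family is verified feature-by-feature against independent brute-force
voxel-loop oracles in the test suite.

Shape features use face-counted surface area, which reproduces the
closed-form single-voxel (6 mm²) and cube (600 mm²) values exactly but
overestimates smooth surfaces by the staircase factor (a digitized
sphere's sphericity converges to 2/3, not 1).  This convention is kept for
its exact small-case algebra; mesh-based areas would trade that for
smooth-limit accuracy.

The default filter bank is {original, LBP-2D} — the two filters behind the
pipeline's headline biomarkers (`PET_original_gldm_DependenceEntropy`,
`PET_LBP-2D_gldm_DependenceEntropy`); `FeatureConfig.full()` adds the
8-band stationary wavelet decomposition and Laplacian-of-Gaussian.  The
feature-table column count is config-driven (`n_tif_columns`), 388 under
the default configuration, and is asserted rather than forced to any
particular total.

## The 2.5D CNN pair

CNN_CT and CNN_PET share one architecture and differ only in input size.
The three structural counts are construction-validated: 23 weighted layers
(11 convolutions + 11 switchable-norm affine transforms + 1 dense head),
5 max-pooling layers, and a 512-channel final pooling layer
(`block4_pool_2`) whose global average is the per-slice feature vector.
Channel widths (8→…→32, then a 1×1 lift to 512; ≈62k trainable parameters)
are the package's own choice at desk scale; pooling is placed early so the
large-input layers stay cheap on CPU.  Activations are mish
(x·tanh(softplus x)); normalization is switchable normalization — a
softmax-weighted blend of instance, layer and batch statistics with
separate mixing weights for means and variances, using running batch
statistics at inference.  Training is Adam with decoupled L2 weight decay
(λ = 1e−4), cosine-decayed learning rate from 1e−3, batch 16, binary
cross-entropy on the lesion class; everything is deterministic in the
seed.  The engine is a small reverse-mode autograd over numpy arrays
(float32, im2col convolutions through BLAS); inference runs with the tape
disabled.

Deep features are extracted per slice (not by channel-stacking the three
planes), which is what makes 512 × 3 planes × 2 modalities = 3072 features.
The feature extractors are trained once on the internal-site patches; the
modeling stage's fold-wise honesty applies to normalization and selection,
not to CNN training (retraining the CNNs inside every fold would multiply
their cost by the fold count for little change in the downstream
comparisons this package is used for).

## Selection and modeling

k = ⌊n/10⌋ (the one-in-ten rule; 38 at n = 386).  The four rankers are
ANOVA F; chi-square on min-max-scaled features binned into 10 equal-width
bins; ReliefF with 10 neighbours over all samples on range-normalized
Manhattan distances; and greedy mRMR in the MID (difference) scheme with
mutual information on 4-bin quantile-discretized features, run to a full
permutation with incrementally maintained redundancy sums.  Ties break by
score then feature name, making every ranking deterministic.

The intersection policy is *within-block across the four methods, union
across blocks*: a global 16-way intersection across modalities would
typically be empty, while per-block intersections retain features that are
top-k by every selector within their own modality/class.

The grid standardizes inside each training fold (leakage-free default; a
"paper" mode normalizes once on the full internal cohort for comparison),
evaluates ten classifier families, refits on all internal lesions and
tests on the untouched external site.  AUC uses the Mann–Whitney rank
formulation with midrank ties; confusion metrics are taken at probability
0.5; CIs are stratified percentile bootstrap with B = 2000.  The best cell
is chosen by internal CV AUC (choosing on external performance would
leak), ties broken by accuracy and then by simpler family.

## Attribution

Kernel SHAP solves the Shapley-kernel weighted least squares with the
efficiency constraint imposed by coefficient elimination, so local
accuracy (φ₀ + Σφᵢ = f(x)) holds to numerical precision.  With all 2^M − 2
coalitions enumerated — always done for M ≤ 12, the candidate-set scale —
the solution equals exact Shapley values, verified against a permutation
formula oracle.  The background is a ≤100-row sample of the training
data; attributions refer to the model's probability output.  LIME uses
binary masking perturbations with background draws, an exponential kernel
of width 0.75√M on cosine-style mask distance, and a ridge surrogate.

## The synthetic cohort: what is planted, and what it does not emulate

Lesions are ellipsoids (semi-axes 5–11 mm) in 40³ voxel volumes at 1 mm,
with soft-tissue CT background, SUV-equivalent PET background ≈ 1, body
weight ~N(59, 8.7) kg and a 3.7 MBq/kg dose protocol so the SUV conversion
is exercised at realistic magnitudes.  The DLBCL-like class has hotter
peaks (8.6 vs 7.9 SUV) and markedly more heterogeneous texture: a
higher-amplitude uptake field (sd 0.53 vs 0.28 of peak) mixing a rough
(1.3 mm) and a smooth (4.7 mm) spatial scale in coarse patches — diffuse
infiltration with metabolic niches — while the IDC-like class has milder
single-scale texture.  Both classes share a focal hot-spot nuisance
(Poisson(3) Gaussian spots) so simple order statistics (SUVmax, range)
stay noisy, and the external site applies a 0.92 intensity scale plus
0.23 SUV additive noise, which specifically degrades fragile fine-scale
texture readers across the pooled ranking cohort.

This construction makes the *GLDM dependence entropy* the best single
discriminator: it reads both the gray-level diversity (amplitude channel)
and the dependence-structure diversity (multi-scale patchiness channel),
and its log-compression makes it robust to the shared nuisances.  The
class/site parameters were fixed once by a randomized calibration against
two targets stated up front: single-feature AUC in the 0.90–0.95 band, and
the dependence-entropy feature ranking first among all extracted features
across independent seed sets.  Note that a *shorter correlation length
alone does not raise dependence entropy* at the fixed 0.25-SUV binning —
fine textures make the dependence axis degenerate (every voxel has
dependence 1), which lowers the joint entropy; heterogeneity is therefore
planted as amplitude + scale mixing, and the recoverability property
(heterogeneous class ⇒ stochastically larger DE) is the tested invariant.

The phantom does **not** emulate anatomy, scanner physics (PSF,
reconstruction), respiratory motion, segmentation error (masks are ground
truth), or patient-level correlation between multiple nodules.  Passing
tests therefore demonstrate that the pipeline recovers a planted effect of
the assumed form under controlled conditions — not clinical performance.

## Problem sizes and numerical choices

Default study size is 200 lesions (50/class/site), chosen so the full
pipeline — including CNN training (4–5 epochs) and the 20-seed
planted-biomarker recovery suite — completes on a single CPU in minutes.
Degenerate cases are defined rather than left to chance: constant ROIs
discretize to a single level; constant features score 0 for ANOVA, chi-square
and ReliefF and are excluded from mRMR's MI with a warning; SUVmax ≤ 0
yields MTV = TLG = 0 with a warning; empty per-block intersections are
valid (warned) empty contributions; grid-cell failures are recorded
without aborting the run.  Lesions whose drawn ellipsoid would be thinner
than 2 voxels on any semi-axis are redrawn, never emitted empty.

## Known limitations

* The CNN parameter total is not pinned to any particular value; only the
  layer/pool/channel counts are structural invariants.
* Whole-cohort feature ranking (used for biomarker discovery) sees both
  sites by design, mirroring the study it models; the modeling grid is the
  leakage-free component.
* ReliefF is O(n²) per block and mRMR O(F²) MI pairs; both are fine at
  desk scale but would need approximation for 10⁴-feature banks.
* Patient-level grouping is carried in the manifest but fold splitting is
  lesion-level by default (a grouped mode would prevent same-patient
  leakage when lesions per patient > 1; the phantom draws one lesion per
  synthetic patient, so the distinction is moot here).
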