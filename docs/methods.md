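# Methods

## The problem

Quantification of amyloid-β (Aβ) PET requires warping each subject's scan
into a standard template space so a fixed volume-of-interest (VOI) atlas can
be applied, then computing the standardized uptake value ratio (SUVR): mean
tracer uptake in a cortical target region divided by mean uptake in a
reference region (cerebellar gray, whole cerebellum, whole cerebellum plus
brain stem, pons, or a high-uptake pons subset, "ThPons"). PET-only spatial
normalization is hard for amyloid tracers because negative and positive
scans look fundamentally different: nonspecific white-matter binding is
present in everyone, while cortical gray-matter binding scales with amyloid
burden. A single fixed PET template therefore biases the registration of
whichever class it resembles less.

## The adaptive principal-component template

Given n training scans, spatially normalized and intensity-normalized by the
pons, with p voxels each, form X (p × n), the mean image μ, and the centred
matrix D = X − μ1′. The sample covariance is taken in its n × n Gram form,

    C = D′D / (n − 1) = V Λ V′,

and eigenimages are obtained by projecting the centred stack onto the
eigenvectors, I_PCi = D q_i. The p × p voxel covariance is never formed; the
Gram path gives the identical nonzero spectrum (verified against a dense
eigendecomposition at tiny p in the tests). Eigenimages keep the
intensity-like scale this projection gives them, ‖I_PCi‖ = √((n−1)λ_i).

The registration target is the two-component synthetic template

    I_synthetic = I_PC1 + w · I_PC2,    w ∈ [−1, 1].

With a training cohort spanning the negative-to-positive continuum, the
first component captures the shared, mean-like nonspecific pattern and the
second the amyloid-specific cortical pattern, so w sweeps the template's
appearance from Aβ− (w = −1) to Aβ+ (w = +1). The formula is used exactly
as written — the mean image is not added. Because eigenvector signs are
arbitrary, `fix_component_signs` orients I_PC1 to have positive mean over
the brain mask and I_PC2 positive mean over the cortical mask, making
w = +1 the amyloid-positive end by convention.

Only voxels inside a template-space brain mask enter the decomposition;
air voxels would contribute nothing but noise to the spectrum.

## Registration cascade

w is one extra coordinate of the optimization vector, so the spatial
transform and the template appearance are estimated jointly; at every
objective evaluation the template is re-synthesized for the current w.
All stages use Powell's direction-set method (no gradients — the metric is
histogram-based).

1. **Global affine.** A multiresolution (2-level, factor 2) 12-parameter
   affine — translations (mm), rotations (rad), scales, shears, composed
   T·R·Sh·Sc about the template centre — plus w, maximizing normalized
   mutual information, NMI = (H(A)+H(B))/H(A,B), over the whole volume with
   a 64-bin joint histogram.
2. **Masked refinement.** Continues the affine and adds a second-order
   polynomial deformation (3 × 10 coefficients on [−1,1]-normalized
   template coordinates, acting as an additive displacement on the
   affine-mapped coordinates, initialized to zero so the stage starts where
   stage 1 ended), still with w free, with NMI restricted to a cerebral
   mask without ventricles. The cerebellum and brain stem are excluded from
   this mask: the stage's purpose is the cortical fit, and the reference
   region receives its own refinement next — letting the polynomial chase
   the reference region would defeat that step. Ventricles are excluded
   because their size varies strongly across subjects.
3. **Reference-region rigid refinement.** A 6-parameter rigid transform for
   the cerebellum + brain stem, driven only by the high-uptake voxels of
   the synthetic template (w frozen at the accepted value): the threshold
   is the 85th percentile (linear-interpolation quantile, ≥ comparison) of
   the within-mask template intensities. The metric is normalized cross
   correlation over those voxels, and the search is box-bounded
   (±8 mm, ±5°) because the step is a local correction. The increment is
   blended into the global transform through a Gaussian-smoothed copy
   (σ = 3 mm) of the binary mask:

       y(x) = (1 − s(x)) · G(x) + s(x) · G(R(x)),

   linear interpolation between mapped coordinates, which keeps the
   composite displacement field continuous (the tests assert the exact
   Lipschitz bound |Δy| ≤ |ΔG| + |Δs||e| + s|Δe| with e = G∘R − G).

Resampling is pull-back throughout: iterate over the fixed/template grid,
map through the chain, sample the moving image trilinearly (nearest for
labels), out-of-field voxels set to 0.

### Numerical choices

* **Parameter scaling.** One Powell step is made commensurate across
  parameter types: rotations move in units of 0.01 rad, translations in mm,
  scales/shears in units of 0.01, polynomial coefficients in units of 0.1
  voxel, w in units of 0.1.
* **Initialization.** Intensity-centroid alignment for the translation,
  then a 3×3×3 rotation-candidate (±8° per axis) × 5-point w-candidate scan
  at the coarse level picks the starting basin. Before each level's Powell
  pass, w is re-scanned over 9 candidates at the current transform — w and
  the transform are coupled, and the joint line searches can leave w in a
  shallow side valley.
* **Optimizer settings.** xtol 5e-3 (scaled units), ftol 1e-4, at most 20
  Powell iterations per level with up to 3 direction-set restarts (a
  restart re-initializes the direction set, escaping the degenerate
  direction sets Powell accumulates on coupled objectives). Looser xtol
  measurably under-converges the rotation parameters.
* **Pyramid depth.** Two levels. A third (quarter-resolution) level leaves
  a 64-bin joint histogram with ~3.5k samples for 4096 bins; such sparse
  histograms created false NMI basins on the phantom.
* **Metric sampling.** At the finest level the metric uses a stride-2 voxel
  subgrid (the standard sampling-fraction trick), keeping one registration
  to roughly ten seconds on one CPU at the default phantom scale.
* **Matched pre-smoothing.** Both metric arms — the template components and
  the subject — are pre-smoothed by a common 0.5-voxel Gaussian for the NMI
  stages and the reference NCC. Trilinear interpolation low-pass filters
  the moving image at every evaluation; with only one arm smoothed the
  joint histogram marginals are asymmetric, which biased w by ~0.1 and the
  recovered local shift by ~0.5 voxel on known-truth phantoms.
* **Degenerate guards.** Constant images inside a metric mask give NMI 1
  with a warning; a worsened masked-refinement stage falls back to the
  affine result with a warning; w pinned at a bound is recorded in the
  chain metadata.

## Quantification

The subject is resampled to template space through the full chain,
intensity-normalized by the voxel mean of the pons VOI (the output pons
mean is exactly 1), and SUVR is reported for the cortical composite target
CTX against each reference region. ThPons is built once per template by
thresholding the training mean image within the pons VOI at the 0.85
quantile — a per-subject ThPons would change the region across patients.
The region statistic is the unweighted voxel mean throughout. SUVR is
invariant to any global rescaling of the input image.

## The phantom

No real scans ship with the package; every experiment runs on a geometric
digital phantom (64 × 64 × 54 voxels, 2 mm isotropic) with full ground
truth: an ellipsoidal cortical ribbon (~45% of cerebrum volume) over white
matter with two ventricles, an inferior cerebellum with a gray shell over a
white core, and a brain-stem cylinder containing a pons segment. Tissue
intensities are fixture conventions: WM 2.0, cortical GM 0.8 + 1.6·burden,
cerebellar GM 0.8, brain stem/pons 2.2, ventricles 0.1, background 0.

Cohort variability has two latent modes:

* **burden** a ∈ [0, 1] — cortical GM uptake rises linearly with amyloid
  burden (stratified uniformly over the cohort);
* **amplitude** — a per-subject global uptake multiplier (Normal,
  σ = 0.25, clipped to [0.4, 1.8]) on all brain tissue *except the pons*,
  emulating inter-subject and inter-scanner variability in tracer delivery
  and nonspecific retention relative to the pons. The empirical stability
  of the pons is the field's reason for using it as the reference region,
  and the mode survives pons normalization by construction.

This two-mode design makes the first principal component the global,
mean-like appearance pattern and the second the amyloid-specific cortical
pattern — the structure the adaptive template relies on. A fixed
multiplicative texture field (product of sinusoids, ±15%, 20 mm
wavelength, identical for every subject) stands in for within-tissue
structure (folia, tracts, perfusion gradients); without it the
correlation-driven rigid step has no spatial detail to lock onto.
Rendering applies a 4 mm FWHM Gaussian point-spread function — chosen to
match the *relative* resolution (PSF over structure size) of clinical
amyloid imaging on this roughly half-scale head. Warped subject scans apply
a known affine (rotations to ±10°, translations to ±8 mm, scales
0.95–1.05, small shears), and additive white Gaussian noise at 5% of the
brain-mean intensity. All draws flow from one named generator per seed;
identical truth records give bit-identical images.

What the phantom does **not** emulate: PET physics (attenuation, scatter,
reconstruction artifacts, spatially varying resolution), real anatomic
variability beyond one affine (no sulcal/gyral variation, no atrophy),
multi-frame dynamics, and scanner-specific noise textures. Passing tests
therefore show that the algorithmic chain is correct and self-consistent
under the stated appearance model — not that clinical accuracy figures
transfer to real data.

## What the shipped experiments measure

With the default settings on one CPU (problem sizes chosen for a desk-scale
run: n = 20 training, n = 20 warped subjects for the SUVR comparison,
n = 10 for the robustness rerun):

* the Gram-path PCA agrees with a dense covariance eigendecomposition to
  ~1e-12 relative at tiny p, and training images are reconstructed from the
  full model to <1e-6 relative error;
* two components explain ≥ 90% of the cohort variance (about 95% at the
  default noise level);
* the template weight is recovered with mean absolute error well under 0.1,
  and ≥ 95% of brain voxels map within 2 mm (one voxel) of ground truth;
* a +2-voxel local brain-stem shift is recovered within half a voxel per
  axis and the pons mean is restored to within 2% of the unshifted truth
  (without the rigid step the error is several percent);
* cortical SUVR computed through recovered chains agrees with SUVR through
  the generating chains at R² ≥ 0.95 for every reference region;
* the whole pipeline is deterministic: re-running a cohort reproduces the
  report bit for bit.

`scripts/acceptance.py` recomputes all of these from scratch for any seed.

## Known limitations

* The literal template formula (no mean image) means the template is a
  contrast image; it works because the training cohort's leading mode is
  mean-like. For a cohort with negligible nonspecific variability the
  template would lose its anatomic background and registration would
  degrade. Adding μ to the synthesis is a plausible variant reading and a
  one-line change.
* w for *rendered* (non-template-synthesized) subjects is only weakly
  identified by NMI, which is invariant to intensity remapping; w is a
  faithful positivity estimate when the subject's appearance lies in the
  template manifold.
* The polynomial stage extrapolates outside its mask; the reference-region
  rigid step exists precisely to correct the reference region afterwards,
  but other extra-mask structures (e.g., skull base) have no such guard.
* The rigid refinement uses one mask for cerebellum + brain stem jointly;
  independent refinements per structure are out of scope.
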