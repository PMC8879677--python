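# Methods

This note documents the models, numerical choices and evaluation protocols
implemented in `spineforge`, and what its synthetic studies do and do not
demonstrate.

## Problem and model

Given one sagittal and one coronal radiograph-like projection of a spine plus
per-vertebra 3D centroid annotations, the package reconstructs each vertebra's
full 3D shape and stacks the shapes at their centroids into a standing spine
model. Shape synthesis is posed as template registration: for vertebra *v*
with canonical template `y_t`, the network predicts a displacement field

    G = G_a + G_d,        y = G ∘ y_t,

where `G_a` is the field of a global affine pose (rotations θx, θy, θz about
the patch center and an isotropic scale S — no translation, because patches
are extracted with the vertebral centroid at the fixed pixel (size/2, size/2))
and `G_d` is a free-form per-voxel field for local surface detail. The warp
`∘` is a pull-back: the output reads the template at `x + u(x)`, sampled
trilinearly with zero padding; binary masks are produced by thresholding at
0.5 (ties counted as foreground) and multiplying by the vertebral label.

Because the warp is a pull-back, realizing a *pose* M = R(θx)R(θy)R(θz)T(S)
on the shape requires the field of M⁻¹ = Rz(−θz)Ry(−θy)Rx(−θx)T(1/S); the
affine decoder's four outputs are therefore interpreted as the vertebra's
pose, and τ is applied to the inverse matrix. This makes the decoder's
outputs directly comparable to generating poses in recovery experiments.

### Network

Each view has its own encoder: a convolutional stem for the image patch and
one for the VOI-annotation disc, fused by a squeeze-and-excitation block
(global-average squeeze, bottleneck with reduction 4, sigmoid gate); strided
3×3 convolutions reduce the patch to the latent grid; a learned per-pixel
projection expands the missing dimension (left–right for the sagittal view,
anterior–posterior for the coronal view), followed by an anisotropic 3D
convolution whose 5-tap axis runs along the expanded dimension. The two
views' latents are co-registered in one (x, y, z) frame and concatenated.

The affine decoder is an MLP over the *whole spine batch*: for each vertebra
the encoders' 2D feature maps (taken at half the patch resolution, where
in-plane positions — the only sign-carrying cue for axial rotation — are
still spatially resolved) are channel-reduced per view and flattened, then
concatenated with a downscaled template, the centroid relative to the
spine's mean (divided by 100 mm), the normalized label (label−8)/16 and a
presence bit, across all batch slots (shorter spines are zero-padded).
Rotations are bounded to ±π/4 by a scaled tanh; the scale is exp(ln2·tanh(·))
∈ [1/2, 2], guaranteeing S > 0. The deformable decoder is fully
convolutional: 3³ convolutions with ×2 nearest-neighbour upsampling from the
latent grid to the output grid, channels shrinking toward full resolution
(the field is smooth there), and a 1³ output head scaled by a fixed gain of
3 mm. Both output heads are zero-initialized, so an untrained model
reproduces the template atlas exactly — training starts from the identity
registration.

### Loss and optimization

    L = α_p · mean |y − label·(G ∘ y_t)| + α_s · mean(|u_x|+|u_y|+|u_z|),

with α_p = 10, α_s = 0.1, Adam at learning rate 1e-4. Both reductions are
voxel means, so the weights keep their balance across grid sizes. The
magnitude penalty is applied to the deformable field only: the affine field
encodes the pose and should not be shrunk toward zero. Targets are
{0, label}-valued crops of the ground-truth label volume around each
centroid. One spine forms one optimization step (the affine decoder fuses the
whole batch). "Until convergence" is operationalized as early stopping on
validation loss with patience 10 (restoring the best parameters); the
train/validation split is 5:1, assigned by hashing (sample id, seed), so it
is disjoint, exhaustive and reproducible. Ablations: `affine_only` drops
G_d, `deformable_only` drops G_a, `combined` uses both.

### Training core

The package ships a compact reverse-mode automatic-differentiation engine
(`autodiff.py`): float32 numpy arrays on a tape, with batched im2col
convolutions (built from one contiguous crop per kernel offset), nearest
upsampling, SE gating, and an analytically differentiated trilinear warp.
The warp sampler and the fused Adam update are JIT-compiled with numba when
available, with identical pure-python fallbacks. Gradients of every
operation are verified against central finite differences in the test
suite.

## Synthetic data

`phantoms` generates the study population. A vertebra is an ellipsoidal body
(semi-axes r, 0.85r, 0.6r) with a posterior spinous-process rod and lateral
transverse-process rods, as in real vertebrae; the transverse processes also
give the projections a first-order, sign-carrying cue for axial rotation,
without which θz is poorly identifiable from two orthogonal views of a
near-ellipsoid. Body size interpolates linearly from T1 (label 8) to L5
(label 24); the body surface is modulated by a smooth random quadratic field
shared across labels per seed, so voxel count is monotone in label by set
inclusion. Spines place vertebrae along a sinusoidal kyphosis/lordosis curve
with per-vertebra pose jitter (the sagittal tilt follows the curve tangent),
inside a soft-tissue cylinder (bone 1000, soft tissue 200, Gaussian noise
σ = 20). The template atlas is a ≥50%-occupancy majority vote (ties
included) of centroid-aligned canonical shapes, five per label.

What the phantom does **not** emulate: real vertebral morphology (endplates,
pedicles, facet joints), ribs and shoulder-girdle overlay, scatter/beam
hardening, detector noise, non-perpendicular view pairs, and inter-subject
anatomical correlation beyond the size-vs-label trend. Passing studies on
this population demonstrate that the estimator and its training loop work —
not clinical-grade accuracy on radiographs.

## Projections

DRRs integrate intensity along rays. Parallel mode sums voxel columns times
the spacing — exact, linear, and the analytic surface used in tests.
Perspective mode casts rays from a focal point 1500 mm from the volume center
to a detector at 1800 mm (magnification 1.2), sampling trilinearly at 0.5 mm
steps between the ray's bounding-box entry and exit; negative intensities are
clamped before integration. Label silhouettes use any-hit compositing.
Patches are 64×64 (configurable) with the projected centroid at pixel
(size/2, size/2), zero-padded at image borders, and z-score normalized
per patch after extraction; the VOI annotation is a 1 mm-radius disc at the
same fixed pixel.

## Evaluation metrics

* **Dice** 2|A∩B|/(|A|+|B|); **Hausdorff** symmetric max-max distance on
  6-connected surface voxels (the mesh-vertex definition mapped to voxel
  surfaces, as no meshing step exists); **Chamfer map**: squared distance
  from each of 2048 surface points (uniform with replacement, seeded) to the
  nearest reference point, directed prediction→reference.
* **Spectral distance.** The Laplace spectrum of a voxel shape is computed
  from the 6-neighbour finite-difference negative Laplacian on foreground
  voxels with Dirichlet (zero) exterior, scaled by 1/h²; the N = 50 smallest
  eigenvalues are extracted by a shift-invert sparse solver with a
  deterministic start vector. Axis-aligned rotations permute voxels, so the
  spectrum is exactly invariant under them. For an n³ voxel box the discrete
  eigenvalues are 4/h²·Σᵢ sin²(πkᵢ/(2(n+1))) — the continuum Dirichlet box of
  side (n+1)h: the zero boundary sits one spacing outside the mask, which
  matters when comparing λ₁ against 3π²/a².
* **WESD / nWESD.** ρ_N = [Σ_{n≤N} (|λₙ−ξₙ|/(λₙξₙ))^p]^{1/p} with p = 2 >
  d/2. The normalizer W bounds the full series: the first N terms by
  max(1/λₙ, 1/ξₙ)^p (strict, since |1/ξ−1/λ| < max(1/λ, 1/ξ)), the tail by
  the Li–Yau/Weyl lower bound λₙ ≥ (4dπ²/(d+2))·(n/(ω_d V))^{2/d} with
  V = max of the two volumes and ω_d the unit-ball volume, whose p-th powers
  sum to a Hurwitz zeta value ζ(2p/d, N+1). This guarantees nWESD = ρ_N/W ∈
  [0, 1). Raw Dirichlet eigenvalues are differenced (no volume
  pre-normalization).

## Study protocols (`benchmarks`)

Problem sizes were chosen so each study runs in minutes on one CPU core:
30 spines × 5 upper-thoracic vertebrae (labels 8–12) on 32³ patches.

* **Reconstruction study**: combined variant, 15 epochs; reports held-out
  vertebra-mean Dice at threshold 0.5 against the identity-template
  baseline. At these conditions the trained model reaches Dice ≈ 0.84–0.85
  vs ≈ 0.79–0.81 for the unwarped templates.
* **Pose-recovery study**: affine-only variant on widely excited poses
  (rotations ≤ 25°, scale ±15%, longer processes), a fixed budget of 120
  epochs keeping the final parameters; reports Pearson correlation between
  predicted and generating (θz, S) across all vertebrae. Wide excitation is
  an identifiability requirement of the experiment, not a claim about
  clinical pose ranges. The validation loss plateaus long before the
  pose correlations converge (most of the residual is deformable shape
  detail the affine family cannot express), so best-validation early
  stopping would systematically truncate pose learning; the fixed budget
  avoids that.

## Numerical choices and degenerate inputs

Euler order is R(θx)·R(θy)·R(θz)·T(S), literal matrix product; the
rotation/scaling center is the fixed centroid pixel. Trilinear interpolation
with zero padding everywhere; mask threshold 0.5 with ties in. Constant
images are rejected by z-normalization (σ = 0); empty masks make Dice /
Hausdorff / spectra undefined and raise; N may not exceed the foreground
voxel count; p ≤ d/2 is rejected. Angles are radians internally, degrees at
CLI and file boundaries. Centroid CSVs are mm from the corner of voxel 0
(voxel centers at (i+0.5)·spacing).

## Known limitations

* The deformable decoder's finest stage is channel-lean by design (CPU
  budget); very fine surface detail saturates before Dice ≈ 0.9 at 32³.
* θx recovery is confounded with the spinal-curve tangent (the generator
  ties sagittal tilt to the curve), so recovery is assessed on θz and S.
* The pipeline trains on perspective DRRs of phantoms and infers on DRRs of
  a held-out phantom; no claim is made about transfer to clinical
  radiographs beyond the normalization argument.
* nWESD's normalizer is a derived bound; different (tighter) constants in
  the literature would rescale nWESD values but not its ordering or its
  rigid invariance.
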