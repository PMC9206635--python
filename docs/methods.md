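# Methods

This note records the models, the synthetic data they are evaluated on,
the numerical choices, and the limits of what the desk-scale experiments
can show. It is the package's own account of its science; every number it
mentions is computed by the test suite or `scripts/acceptance.py`.

## The synthetic population generator

The generator stands in for real segmented cohorts (chest radiographs with
five labeled structures; cropped brain MRIs with nested subcortical
labels). It produces, for one seeded run:

* a **template**: a multi-structure labeled image plus its defining
  landmarks. The 2D "thorax-like" template has five structures — two large
  lung-like fields, a heart-like ellipse, and two thin clavicle-like bars
  whose area is below 5% of the largest structure, because the fate of
  small structures under generative modeling is one of the questions the
  metric suite must expose. The 3D "brain-like" template has three nested
  star-convex structures. Landmarks are placed by equal arc length along
  each 2D boundary (a fixed spherical grid in 3D), which gives exact
  point-by-point correspondence across the population by construction.
* a **deformation basis**: k Gaussian-smoothed random vector fields,
  de-meaned per component, Gram–Schmidt-orthogonalized and normalized to
  unit RMS displacement. Smoothness defaults to one eighth of the smallest
  grid extent; per-mode standard deviations decay geometrically from 5% of
  the smallest grid extent (3.2 px on a 64×64 grid) — displacements of a
  few pixels, the magnitude of anatomical variability at this resolution.
* **instances**: coefficients c_j ~ N(0, σ_j²) give a displacement field
  φ = Σ c_j·mode_j. Landmarks move by φ evaluated at their positions; the
  label image is the rasterization of the moved landmarks; the appearance
  is the template intensity plus a smooth per-instance offset (the
  template-plus-offset-then-warp generative assumption of the appearance
  deformable autoencoder), transported with the fixed-point inverse of φ
  so image content follows the landmarks. Instances whose landmarks leave
  the grid are redrawn, at most 100 times.

Because the true modes and coefficients are recorded, PCA identifiability
is testable: on 200 shapes from 3 modes, PCA retains exactly 3 modes with
≥ 99% of the variance and principal angles to the true span below 5°.

What the generator does **not** emulate: non-Gaussian coefficient
distributions, correspondence error, segmentation noise, topology changes,
and intensity structure beyond a smooth offset. Passing tests therefore
show that the pipeline is correct and that the qualitative orderings hold
under clean Gaussian conditions — not that any model will behave the same
on real clinical data. One consequence is discussed under "Limitations".

## Rasterization and distances

Coordinates are voxel-center based, 0-indexed, axis order (x, y[, z]).
2D structures are filled by a vectorized even-odd (crossing-number) rule
over pixel centers, checked in the tests against an independent geometric
oracle (shapely point-in-polygon); 3D structures are filled star-convexly
via spherical-Gaussian-weighted landmark radii. Surfaces are voxel centers
with a face-adjacent neighbor of another label (4-/6-connectivity); no
sub-voxel contouring is attempted, so no test asserts sub-voxel agreement.

ASSD between two label images is the symmetric mean nearest-neighbor
distance between surface point sets, averaged over structures. A structure
absent from **both** images is skipped with a warning. A structure absent
from exactly **one** image has no finite surface distance; by default it
is excluded from the average and flagged, and the omission is reported
separately as the missing-structure fraction — keeping the distance and
the "did the model generate the structure at all" question orthogonal,
which is how the evaluation plots treat them (distance curves plus
missing-structure bars). A `absent_policy="diagonal"` option instead
charges the grid diagonal as a finite worst-case penalty for workflows
that want a single scalar.

Label images are warped by one-hot encoding, linear interpolation of the
channels and a per-voxel argmax (ties toward the lower index), which keeps
boundaries smoother than nearest-neighbor resampling and matches how the
networks emit label probabilities. Displacement-field inversion uses the
standard fixed-point iteration (20 iterations, 0.01-voxel tolerance).

## Statistical models

The PCA shape model uses the economy SVD of the centered data matrix —
algebraically the N×N Gram-trick eigendecomposition, appropriate since
dm ≫ N throughout — with a 1e-12 eigenvalue floor for rank decisions. The
latent dimension is the smallest mode count reaching the variability
threshold (default 0.95). Sampling follows the fairness protocol used for
every family: z drawn per-dimension from a normal with the mean and
standard deviation of the training latents.

The locality model attenuates the sample covariance elementwise by a
Wendland C2 kernel of inter-landmark distance over a schedule of radii,
default (∞, D/2, D/4) with D the mean-shape bounding-box diagonal. The
radii, the kernel and the accumulation rule (coarse-to-fine, per-level 95%
variance cut, Gram–Schmidt against modes already kept, 1e-8 drop
tolerance) are this package's own concrete construction of the
"manipulate covariances by distance, multi-resolution" idea; the first
(global) level guarantees the plain PCA subspace is contained, so the
locality model's latent dimension and training-space reconstruction are
never worse. With a single infinite radius it reproduces plain PCA
exactly, which is asserted in the tests.

The appearance model warps each training image to the mean shape with a
thin-plate-spline interpolation of landmark displacements, takes a second
PCA there, and generates by sampling shape and appearance latents
independently (the correlation structure between the two is not modeled)
before warping back. Warp round trips cost ~0.01–0.03 mean absolute
intensity error on the smooth synthetic appearances, and the tests bound
reconstruction error in the mean-shape frame by 0.05.

## Neural models

All five families share one fixed architecture so that differences
reflect the modeling principle rather than architecture search: encoder =
three stride-2 convolutions with channels [in, 20, 40, 80] plus a fully
connected layer to the latent vector; decoder mirrors it with linear
(bi-/trilinear) upsampling and channels [80, 40, 20, out]; the grid must
be divisible by 8 per axis. The discriminator of the adversarial variant
repeats the encoder's convolutional shape ending in a real/fake
probability and shares no weights with the encoder. Label inputs are
one-hot encoded and trained with the weighted generalized Dice loss
(inverse squared class volume weights; absent classes weight 0); intensity
inputs use 1 − SSIM (box window 7, constants 0.01²/0.03² for range-1
data). The VAE, DAE and ADAE use a reparameterized latent with the
closed-form KL against N(0, 1), weight 1. The deformation decoders emit a
displacement field applied to a fixed template by differentiable backward
warping; the field pays a diffusion (squared forward differences) plus L1
penalty, both weighted by 10. Displacement fields are used directly — no
velocity-field exponentiation — matching the displacement formulation the
regularizer comes from.

The template is the voxelwise majority label (mean image for
intensities) of the training set, fixed before training. When shape
variation denies a small structure every majority vote, the majority
template would lack it and no deformation could recover it; in that case
the medoid training image (closest to the voxelwise mean) serves as
template, which by construction contains every structure it shows. The
tests assert the resulting guarantee: sampled DAE shapes never miss a
structure the template carries.

Training uses Adam (lr 1e-3, weight decay 1e-5, batch 8 by default,
epochs configurable; desk default 150). Weight decay is kept deliberately:
it nudges even KL-free latents toward normality, and the latent-normality
comparison between AE and VAE is asserted at trend level over three seeds.
A NaN loss aborts with a diagnostic rather than training on. Everything is
seeded: weight init, batch order, reparameterization draws and sampling,
so runs are bit-reproducible on fixed BLAS settings.

The layers run on a small reverse-mode autodiff engine written on numpy
(`shapearena.nn`): strided N-d convolution via an im2col view and one
tensordot, linear upsampling as cached per-axis interpolation matrices, a
self-adjoint box filter for SSIM, and a warp primitive differentiable in
both the image and the field. Every primitive's gradient is checked
against central finite differences in the test suite. 3D networks build
and train through the same code paths (the engine is dimension-generic);
full-scale settings (512/1024-dimensional latents, 64×96×64 volumes) are
expressible in `NetworkSpec` but are configuration, not something the
desk-scale suite trains.

## Metrics

Generalization ability, specificity, likeness/DSI, Shapiro–Wilk normality
(alpha 0.05, reported alongside the fraction; constant dimensions count as
rejected), compactness and the latent ambiguity score are implemented
model-agnostically over the shared contract, and the KS statistic, ASSD,
Dice and regularizer implementations are pinned to brute-force oracles in
the acceptance suite. Two protocol choices the evaluation fixes:
specificity and likeness compare generated samples against the fold's
**training** images (specificity asks whether samples resemble the data
the model saw), with the sample count equal to the reference count for
balanced KS comparisons, while generalization ability, LAS and normality
use held-out test images. Intra-class distance sets use unordered distinct
pairs; above 200 items pairs are subsampled with a fixed seed to bound the
quadratic cost.

## The experiment harness

The sweep trains every (model, training size, fold) cell — four folds for
N < 100, two otherwise, each fold a seeded without-replacement subsample
of the training split — evaluates the metric suite, averages over folds,
and writes rows incrementally so an interrupted sweep resumes without
recomputing. A failing cell is marked failed and the sweep continues.
Interpolation experiments decode the linear latent path between two
images (default: the first two test items) in 20 steps and record the
distance profile to both endpoints; for PCA models the decoded path is
exactly the linear blend of the endpoint reconstructions, which the tests
assert.

### Desk-scale sweep conditions

The qualitative-orderings test runs the sweep on a thorax-like population
of 120 instances with k = 8 ground-truth modes on a 64×64 grid, models
{SSM, LSSM, AE, VAE, DAE}, training sizes {5, 10, 20}, latent dimension
16, encoder channels [10, 20, 40], 80 epochs, batch 4, 10 evaluation
images. These sizes keep the full suite within a desktop-CPU run; the
channel widths and epoch count are below the fixed reference architecture,
and k = 8 exceeds the smallest training sizes so that generalization
differences are visible. The 64×64 grid is the smallest at which the
clavicle-like structures (~20 px) survive rasterization of every sampled
shape; on coarser grids even ground-truth instances can lose them.

## Limitations

* The generator draws mode coefficients from exact Gaussians, so the PCA
  models' latents are normal **by construction**. On real cohorts,
  non-normal latent distributions are a main cause of poor PCA-model
  specificity; that mechanism cannot appear here, and the specificity
  comparison between model families at desk scale favors PCA models more
  than real data would. The template-deformation autoencoder still reaches
  the best (lowest) specificity by collapsing toward its template — which
  also illustrates specificity's known blind spot: it does not reward
  diversity (that is what the likeness score is for).
* At desk-scale training budgets the plain and variational autoencoders
  remain partially under-fit on the thin clavicle-like structures (visible
  as nonzero missing-structure fractions), so their absolute GA and
  specificity values are upper bounds on what converged training yields.
* Voxel-center surfaces mean all distances carry rasterization noise of
  order half a pixel; assertions use margins accordingly. The same
  discretization can delete a structure outright: an extreme PCA sample
  that squeezes a clavicle-like bar below one pixel width rasterizes it to
  zero voxels even though the sampled contour still contains it, so the
  missing-structure fraction of landmark-based models is bounded away from
  zero by the grid, not by the model.
* The locality construction (kernel, radii, accumulation) and the SAM
  warping scheme are this package's own interpretations of ideas whose
  original formulations leave those details open; both are documented
  above and configurable.
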