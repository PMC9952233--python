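# Methods

`femurssm` builds a statistical shape model (SSM) of the healthy femur
from a population of triangle meshes and uses it to statistically
reconstruct the missing portion of a damaged femur. This note documents
the models, the numerical choices, and what the synthetic test substrate
does and does not establish.

## Pipeline overview

1. **Segmentation support.** Bone is thresholded from a CT intensity
   histogram by minimum-error (Kittler–Illingworth) threshold selection;
   metal prostheses are isolated with a separate narrow high-intensity
   band whose lower edge defaults to a cumulative-mass quantile.
   Isosurface extraction itself is ordinary marching cubes and is not
   re-implemented here.
2. **Mesh standardisation.** Largest face-connected component, then
   quadric edge-collapse decimation to 10,000 triangles.
3. **Rigid alignment.** Each specimen is aligned to a reference specimen
   by ICP over 50 farthest-point pseudo-landmarks, up to 150 iterations,
   with exact point-to-triangle closest-point matching.
4. **Dense correspondence.** A Gaussian-process deformation model over
   the reference is non-rigidly registered onto each specimen (1000
   sample points, up to 100 iterations, annealed observation noise).
5. **PCA model.** Generalized Procrustes cleanup, then Gram-matrix PCA
   gives the point-distribution model (PDM); Gaussian-kernel
   augmentation adds smooth extra variance.
6. **Reconstruction.** The model is fitted to the intact surface of a
   damaged specimen by GP posterior regression (pose and shape solved
   jointly); the posterior mean and ±1/2/3 SD variants along the leading
   posterior mode complete the bone, optionally stitched to the measured
   intact geometry.
7. **Morphometrics.** Five measurements per shape: maximum femoral
   length, Hausdorff distance to a reference, femoral neck anteversion,
   rotational-centre divergence, and the neck-shaft (inclination) angle.

All coordinates are millimetres. The canonical anatomical frame
(proximal +z, anterior +y, medial +x; left femur) is fixed at model
build and stored with the model.

## Models

### Deformation prior and augmentation kernel

Deformations of the reference surface are modelled as a zero-mean GP
with the isotropic matrix-valued squared-exponential kernel
k(p, q) = s² exp(−‖p−q‖²/2ℓ²) I₃ — the same scalar kernel on each
coordinate, symmetric in its arguments. A low-rank basis comes from a
Nyström approximation on 500 farthest-point inducing vertices; because
the full kernel matrix is G ⊗ I₃, each scalar eigenfunction yields three
vector-field modes of equal variance, which are re-orthonormalised
exactly after the Nyström extension.

Defaults: registration kernel s = 10 mm, ℓ = 0.25 × reference
bounding-box diagonal (long enough that leading modes are near-global,
short enough to move neck and shaft independently), rank 150.
Augmentation kernel s = 2 mm, ℓ = 30 mm, 50 extra modes: a deliberately
*short* lengthscale, adding local noise-robustness without offering the
fitter a cheap smooth-global explanation that would dilute the
population covariance (see "Fitting" below).

### Registration

Iterated closest-point regression in coefficient space: sample the
deformed reference (farthest-point, fixed after the first iteration),
match to exact closest points on the target, update coefficients by GP
posterior mean, anneal the noise 1.0 → 0.1 mm² (factor 0.95/iteration).
Matching is **symmetric**: an equal number of target samples is matched
back to the deformed reference each iteration. Without the reverse
direction, target features the reference never reaches (the greater
trochanter, a condyle lobe) exert no pull and registration can converge
with them unexplained — we observed 20–40 mm coverage gaps in about one
specimen in eight before adding it. After convergence each vertex is
reprojected onto the exact target surface, removing sub-millimetre
normal-direction residuals that would otherwise enter the PCA as noise
modes.

### PDM construction

Corresponded meshes are first re-aligned by exact generalized Procrustes
(rigid, no scaling — the model is deliberately not similarity-invariant,
so size is a genuine shape mode). Surface-based ICP leaves
millimetre-level pose scatter that PCA would otherwise absorb as a
spurious "pose mode" of large variance (λ ≈ 5×10⁴ mm² in our
populations); with dense correspondence the Procrustes step is exact and
cheap and removes it entirely. PCA uses the n×n Gram matrix (divisor
n−1); modes below 1e−10 of the leading eigenvalue are dropped;
eigenvector signs are fixed deterministically (largest-magnitude entry
positive), making the model invariant to input ordering.

Shape coefficients are expressed in per-mode standard-deviation units:
x(α) = μ + Φ diag(√λ) α, so "+2 SD of mode 1" is literally α = (2, 0, …).

### Reconstruction fitting

Partial observations pair model vertices with their exact closest points
on the damaged specimen's intact surface, subject to three gates:
distance ≤ 5 mm, the matched triangle not touching the open damage rim,
and normal consistency (dot > 0.5) — the last two prevent stubs of
missing anatomy from "observing" the wrong surface. The posterior over
coefficients is Gaussian with Σ = (I + QᵀQ/σ²)⁻¹ and mean
Σ Qᵀ(y − μ_obs)/σ², where Q stacks the scaled basis rows at observed
vertices; the posterior shape basis comes from the eigendecomposition of
√λ Σ √λ pushed through Φ.

Two choices matter greatly for partial data and were adopted after
quantitative failure analysis on the synthetic substrate:

* **Point-to-plane observations.** A closest-point match measures only
  the normal-direction discrepancy; its tangential component is an
  artefact of the perpendicular foot. Treating matches as isotropic 3-D
  constraints penalises the axial-stretch component of the size mode and
  stalls the fitted size coefficient at roughly half its true value.
  During iterative fitting each match therefore constrains only the
  component along the observed-surface normal. (The `posterior` function
  default remains point-to-point; the pipeline opts in.)
* **Joint pose + shape updates.** Rigid pose is degenerate with the
  size mode along the nearly cylindrical shaft. Alternating rigid-ICP
  and shape updates converges to a frame offset by about half the
  specimen's length deviation; instead, six small-angle pose columns
  enter the same regression as free (unpenalised) unknowns and the
  increment is solved jointly, with the pose part folded back into the
  specimen-to-model transform.

Fitting anneals σ² from 1.0 to 0.1 mm² (factor 0.9, up to 40
iterations). The final posterior, computed in the converged frame,
supplies the variant family: level ±k moves k posterior standard
deviations along the first posterior mode, whose sign is canonicalised
so +k inflates the shape (making the −3…+3 SD axis read
small-to-large when the leading mode is a size mode). A joint-mode
variant axis is available behind a flag. Stitching snaps intact-labelled
vertices to the measured surface with a 5 mm linear geodesic blend band.

### Morphometrics

* Head centre of rotation: algebraic least-squares sphere, seeded from a
  cap below the proximal apex and refined on consistent shell points.
* Neck axis: anchored at the head centre; cross-section slabs along the
  current direction are projected to the perpendicular plane and a
  circle is fitted to each (a circle centre is unbiased even for partial
  arcs, unlike a slab centroid — centroid- and cylinder-based estimators
  showed 2–7° junction-occlusion bias and were rejected); points near
  the shaft surface are excluded using the already-derived shaft axis.
  Iterated to convergence.
* Shaft axis: dominant principal direction of the mid-diaphysis band
  (25–75% of the height; face centroids included so coarse tessellation
  cannot empty the band).
* Table plane: through the two most posterior condyle points and the
  most posterior greater-trochanter point; anteversion is the literal
  axis-to-plane angle (90° minus the angle to the normal); the
  projected-axes convention common in radiology (projections into the
  transverse plane) is available via ``projected=True``. Inclination (neck-shaft angle) uses
  head-ward neck and distal-ward shaft directions, giving the obtuse
  clinical convention (~120–145°).
* Hausdorff distance: exact vertex-to-surface (point-to-triangle), with
  the symmetric max by default. Exactness comes from a KD-tree upper
  bound (nearest surface vertex) plus a centroid-ball lower-bound prune,
  so the reported value equals the exhaustive double loop.
* Maximum femoral length: largest distance between head-region vertices
  and distal-condylar vertices, regions defined through the axes so the
  measurement is rigid-equivariant.

All window fractions are configurable and explicit landmark hints
override detection.

## Synthetic data substrate

Cadaveric CT meshes cannot be redistributed, so all studies run on a
procedural femur emulator: a smooth union (exponential soft-min, k =
2 mm) of a shaft capsule, neck capsule, head sphere, two condyle
spheres, and a greater-trochanter sphere, meshed by marching cubes at a
2 mm voxel pitch (≈ clinical CT spacing) and decimated to 10,000 faces.
Ground truth (head centre/radius, neck and shaft axes, neck-shaft angle,
anteversion, maximum length) follows analytically from the parameters;
the posterior tangents of condyles and trochanter share one plane so the
anteversion table plane is exact by construction.

Population priors (independent draws): shaft length N(420, 20²) mm,
neck-shaft angle N(135, 3²)°, anteversion N(5, 1.5²)°, head radius
N(23, 1.5²) mm. Parameters not drawn from priors scale isometrically
with the drawn shaft length (shaft/condyle/trochanter radii, neck
length, offsets). This allometry is deliberate and load-bearing: real
femoral cross-sections scale strongly with bone length (forensic stature
estimation from fragments relies on exactly this), and it is the
population-level correlation that makes the proximal anatomy of a
distally-truncated specimen statistically predictable at all. With the
allometry switched off (`allometry=False`), the intact distal portion of
two femurs differing only in length is exactly congruent and *no* method
can infer the missing extent — a useful negative control.

What the generator does **not** emulate: anterior shaft bow, condylar
asymmetry, the lesser trochanter, cortical thickness, segmentation
noise beyond optional vertex-normal jitter, and any non-Gaussian
population structure. Passing studies therefore demonstrate the
correctness and statistical behaviour of the pipeline machinery, not
clinical-grade accuracy on real bones.

## Study sizes and numerical choices

The validation studies (driven by `femurssm/validation.py`, the test
suite, and `scripts/acceptance.py`) use: 100 random small-mesh pairs for
the Hausdorff oracle; a 50-vertex model for the dense-GP oracle; 20
rigid-recovery trials; a 512-bin mixture histogram; ten independent
n = 30 rebuilds for spectral recovery (a single n = 30 eigenvalue
estimate carries ~26% sampling noise, so medians over rebuilds
summarise central accuracy); an n = 30 population with ten hold-out
repetitions for the completion study; and 20 femurs for the
measurement closed loop. The completion population is registered once —
registrations involve only the reference and one target, so hold-out
models are assembled from subsets without re-registration, and the
reference specimen is never held out.

Degenerate inputs: decimation refuses targets < 4 faces and returns the
input (with a warning) when the target exceeds the face count; sphere
fits raise on coplanar points; rigid estimation raises on collinear
point sets and repairs reflections by sign correction; the posterior
solver adds 1e−10 jitter on a failed Cholesky factorisation and logs it.
Ties in farthest-point sampling and eigenvector signs resolve
deterministically, and every stochastic routine takes an explicit seed,
so all pipeline outputs are reproducible bit-for-bit on one platform.

## Known limitations

* Correspondence is registration-based; no groupwise (e.g.
  minimum-description-length) refinement is attempted, and tangential
  sliding between specimens survives into low-variance PCA modes.
* The ±k SD variant axis follows the first posterior mode only (the
  joint-axis alternative is behind a flag); which axis the original
  workflow varied is not determined by its description.
* Automatic landmarking assumes the canonical frame and a roughly
  femur-like topology; strongly pathological anatomy needs explicit
  hints.
* The damaged-specimen workflow assumes the prosthesis has already been
  removed upstream (by the metal threshold); missing-region detection is
  purely distance-based.
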