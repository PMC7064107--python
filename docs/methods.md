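# Methods

## Imaging model and units

The sample is described by an attenuation map f(x, y, z) in µm⁻¹ on a
cubic voxel grid (default 512³, 21.9 nm pitch).  The scan is parallel-beam
with the rotation axis along z, so each horizontal slice is an independent
2D problem.  For rotation angle θ the detector coordinate is
u = x cos θ + y sin θ and rays run along (−sin θ, cos θ); the angle grid is
the inclusive arithmetic sequence −50°, −49°, …, 50° (101 views).

Line integrals are accumulated **in detector-pixel length units**: the
projection of a map with values around 10⁻² µm⁻¹ across a few hundred
pixels is of order one, so the transmission e^(−p) spans roughly 1–80%.
This is the regime in which the stated incident photon counts
(10⁴–10⁵ per ray) produce the noise levels the pipeline is designed for,
and it makes reconstructed values come out directly in µm⁻¹ on any
reconstruction grid.  Treating the physical path length in µm instead
would put p at ~10⁻², where photon noise at those counts overwhelms the
signal entirely; the pixel-unit convention is therefore part of the model,
not a discretization detail.

## Phantoms

A phantom is an analytic object — a list of quadrics plus a constant slab —
never a voxel array; slices and projections are evaluated in closed form,
so references carry no rasterization bias.

* Two **outer** ellipsoids (semi-axes 0.18–0.30 of the grid, centres
  jittered by up to 4%) form the cell boundary.
* Two **chloroplast** ellipsoids (0.08–0.16) approximate the cup-shaped
  chloroplast; their centres are constrained to the outer union.  No
  boolean subtraction is attempted: two overlapping mid-sized ellipsoids
  give the right scale of internal structure at far lower complexity.
* Twenty **lipid** ellipsoids (0.015–0.040) and fifty **gold** fiducials
  (0.004–0.010) are placed by rejection sampling (cap 1000 attempts,
  32-point surface containment test) fully inside the outer union.
* Additive intensities, µm⁻¹: outer 0.002–0.005, chloroplast 0.004–0.008,
  lipid 0.006–0.012, gold 0.015–0.020.  The ranges are chosen so interior
  values fill a [0, 0.02] µm⁻¹ display window and gold is strictly the
  brightest category (enforced as an invariant).  All ranges are
  configurable.
* The **ice background** is a constant 0.002 µm⁻¹ square slab of half-width
  1.5× the detector half-width.  Because the slab is wider than the
  detector, every simulated sinogram is laterally truncated and the
  reconstructions show the bright boundary ring and cupping of truncated
  real scans.  The ring is deliberately *not* masked in reconstructions
  (it marks the field of view); metrics mask it.

Per phantom, 20 slices are taken uniformly over the central 80% of the
grid (the outermost 10% at each end usually misses the cell entirely).

The **surrogate multi-category generator** replaces external image
collections (optical micrographs, medical CT) with procedurally generated
images: a smoothed Gaussian random field, a random linear ramp, 6–15
overlapping random ellipses, and fine-grained texture, rescaled to
[0, 0.02] µm⁻¹.  A loader for user-supplied TIFF/PNG images can fill the
same role with real data.

What the generator does *not* emulate: zone-plate optics and detector
blur, phase contrast, scatter, rotation-axis drift and jitter motion, and
the true texture statistics of cellular material.  Green tests therefore
demonstrate that the algorithmic chain is correct and that the network
removes the artifacts *of this simulation*; they are evidence, not proof,
of performance on real micrographs.

## Noise

Transmission Poisson noise: counts I ~ Poisson(N₀ e^(−p)) per detector
pixel, with the measured log projection p̂ = ln(N₀ / max(I, 1)).  Zero
counts are clamped to one photon before the log.  By the delta method
Var(p̂) ≈ e^p / N₀; the test suite verifies mean and variance by Monte
Carlo.  During corpus generation the photon level of each sample is drawn
uniformly from {10⁴, 5×10⁴, 10⁵} so the network sees all three dose
levels.

## PWLS denoising

Objective (per projection image, i.e. per angle):

    Φ(p) = Σᵢ (p̂ᵢ − pᵢ)² / vᵢ + β Σᵢ Σ_{j∈Nᵢ} w_ij (pᵢ − pⱼ)²

* **Variance model** vᵢ = aᵢ exp(p̂ᵢ/η), aᵢ = 0.5, η = 1.  This is
  proportional to the delta-method variance of the log transform, so it
  reproduces the correct *relative* weighting; the absolute scale is
  absorbed by β.  The form is config-pluggable.
* **Edge weights** w_ij = exp(−(pᵢ−pⱼ)²/σ²), σ = 2, over the
  four-connectivity neighborhood, recomputed from the current estimate at
  the start of each sweep.
* **Solver**: per-pixel Gauss–Seidel in raster order,
  pᵢ ← (p̂ᵢ/vᵢ + 2β Σⱼ w_ij pⱼ) / (1/vᵢ + 2β Σⱼ w_ij), which is exact
  coordinate descent, so Φ with frozen weights is non-increasing within a
  sweep (a tested invariant).  One "iteration" = one full sweep; the
  default is two.  The sweep is compiled with numba.
* **β = 1.0 by default, with the variance map normalized to its median**,
  which makes the data and penalty terms commensurate at all three photon
  levels.  β is exposed in the config.
* The unit of processing is one projection image at fixed θ: a (v, u)
  detector image for a 3D stack, degenerating to a 1D detector row for a
  single-slice sinogram.

## Filtered back-projection

* **Kernel**: spatial-domain Ram–Lak taps, centre 1/(4d²), odd offsets
  −1/(π²n²d²), even offsets zero, at native detector sampling (d = 1
  pixel).  DC leakage of the truncated kernel is O(1/length) — about 0.1%
  of the signal at 512 detectors — and is covered by a regression test at
  that level rather than an idealized zero.
* **Filtering**: each row is zero-padded to the next power of two ≥ 2× the
  detector size; the kernel is laid out circularly on the padded length so
  the circular convolution equals exact linear convolution over the
  detector support (no wrap-around).
* **Back-projection**: pixel value = Δθ(rad) · Σ_θ q_θ(x cos θ + y sin θ)
  with linear interpolation in u.  With Δθ in radians a full 180° scan
  converges to f; a 100° window keeps the measured frequency wedge at the
  right amplitude and loses the rest, producing the tested missing-wedge
  signature (edges with normals in the measured fan recovered at full
  height, perpendicular edges essentially absent).
* **512 → 256 mapping**: filtering stays at native detector resolution;
  the filtered rows are linearly interpolated onto the coarser 256² grid
  (43.8 nm pitch).  No pre-binning.
* Volumes are reconstructed row-by-row (z decouples) and can be resliced
  sagittally by a pure axis permutation (an involution, tested).

## Artifact network

Depth-4, base-64-channel U-Net by default (fully configurable).  Each
stage: zero-padded 3×3 convolution → ReLU → batch normalization →
squeeze-and-excitation block (reduction 16, two-layer bottleneck with
sigmoid gate).  Down: 2×2 max pool.  Up: bilinear ×2 followed by a 2×2
convolution; a transposed-convolution decoder exists solely as the
checkerboard-artifact comparison baseline (a regression test asserts the
bilinear decoder leaves a weaker 2-pixel-period spectral peak).  Output:
1×1 convolution, one channel, no activation.  Spatial size is preserved at
every layer, so input and output sizes match for any input divisible by
2^depth.

Training: mean-squared error on artifact images (input − reference), Adam
(β₁ = 0.9, β₂ = 0.999), ℓ₂ regularization 10⁻⁴ applied as gradient-side
weight decay on convolution/dense weights only (not biases or BN
parameters).  Learning rate: 10⁻³ for a plateau of epochs, then geometric
decay per epoch to 10⁻⁵ at the final epoch.  All images are scaled by one
shared constant — the maximum |intensity| over the *training inputs* —
into [−1, 1]; the constant is stored in the checkpoint and re-used at
inference.  A 5% validation split feeds the training log and can be
disabled.  Batch normalization uses running statistics at inference, so
the trained network is a pure function of its input (tested).

The full-scale schedule (500 epochs, 2400 pairs at 256², batch 4) matches
the corpus recipe; it is a multi-day CPU run and is exercised end-to-end
at desk scale instead (below).

Because no deep-learning framework is assumed, the layer zoo
(convolutions, BN, SE, pooling, bilinear and transposed upsampling, Adam)
is implemented directly on numpy arrays with hand-written backpropagation.
Correctness rests on finite-difference gradient checks of every parameter
tensor and of the input gradient, run as part of the ordinary test suite.

## Corpus

Default recipe: 10 phantoms × 20 slices + 400 surrogate images = 600 base
images; quarter-turn augmentation (90/180/270°) gives 2400 pairs.
Phantom-slice sinograms are analytic — rotations are applied to the
ellipse geometry itself, exactly matching the pixel permutation of
np.rot90 — while surrogate images go through the discrete projector.
Originals and 90° rotations are reconstructed directly from noisy
projections; 180° and 270° rotations after two PWLS iterations
(1200/1200).  Every pair stores the corrupted reconstruction, the artifact
target, the rotation, the photon level and the PWLS flag; the manifest
records all counts and seeds, and rebuilding with the same seed is
bitwise-identical.

## Scaled-down study sizes

The package's own evaluation runs, chosen to exercise every stage on one
CPU in minutes:

* **Plain-FBP quality figure**: full scale — a fresh 512³ phantom, all 512
  slices, 10⁴ photons, 256² reconstruction (~1 minute).
* **Four-method study** (`desk_experiment`): 64³ phantoms and a 64-pixel
  detector; corpus of 2 phantoms × 10 slices + 30 surrogates ×4 rotations
  = 200 pairs at 64²; depth-2, base-8-channel network (SE reduction 4)
  trained 50 epochs, batch 4, learning-rate plateau 40 then decay;
  evaluation on a held-out phantom at 10⁴ photons.  Slices whose reference
  misses the cell entirely (constant image) are skipped, as SSIM is
  undefined on a zero-range reference.

## Numerical choices and degenerate inputs

* Tangent rays of an ellipse have a square-root singularity in the
  sinogram; discrete-vs-analytic projector agreement is therefore
  quantified as per-angle relative L2 error (< 1% at 256²/512-detector
  scale), not a pointwise maximum at the singularity.
* The ellipse-slice reduction completes the square of the 3D quadric;
  planes missing an ellipsoid (discriminant ≤ 0) are dropped exactly.
* Max-pool ties resolve to the first element (argmax); inputs are
  continuous so ties are measure-zero.
* SSIM uses the standard Gaussian 11-tap window (σ = 1.5), K₁ = 0.01,
  K₂ = 0.03, data range = reference max − min; a constant reference
  raises.  The FOV mask for RMSE is the disk of radius out_size/2 about
  the grid centre.
* Seeds: every stochastic step (phantom draw, placement, noise, shuffling,
  initialization) flows from an explicit integer seed through
  numpy Generators; derived seeds stay below 2³¹.

## Known limitations

* PWLS with β ≈ 1 on near-noiseless data slightly blurs projections; at
  low noise the FBP-vs-FBP+PWLS RMSE comparison is a near-tie (the
  four-method study asserts it with 5% slack).
* The discrete projector (rotate-and-sum, linear interpolation) conserves
  projected mass only to ~1–2% across angles at 64² scale.
* The U-Net at desk scale is a miniature: it demonstrates the ordering of
  methods and the mechanics of residual artifact learning, not the
  absolute quality achievable with the full 500-epoch, 256² training run.
* Real-acquisition effects (axis drift, jitter, blur, scatter) are out of
  scope; applying the pipeline to real stacks assumes those are corrected
  upstream.
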