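# Methods

`xlct` models a focused-beam x-ray luminescence computed tomography (FXLT)
scanner end to end: a first-generation-CT scan geometry in which a focused
x-ray pencil beam excites rare-earth nanophosphors inside a turbid cylinder,
the emitted optical photons diffuse to fiber-bundle detectors on the surface,
and the nanophosphor concentration map ρ(r) is reconstructed from the
resulting sinogram. On top of the physics sits a residual convolutional
network that doubles the number of sinogram projection views (15 → 30) so
that a short scan can be reconstructed with full-view quality.

## Forward model

**Excitation.** The beam is a zero-divergence 50 µm cylinder; at view angle θ
and lateral offset t the x-ray intensity at depth d past the cylinder entry
point follows Beer–Lambert, X = X₀·exp(−μₓ·d), with μₓ = 0.27 cm⁻¹ by
default (soft-tissue-like at ~40 keV; configurable). Because the beam is far
narrower than a voxel, its footprint is rasterized with a Gaussian
anti-aliasing kernel on the perpendicular distance to the beam line
(σ = 0.6 voxel, truncated at 3σ). This choice is load-bearing: a binary
half-voxel band — and even a one-voxel tent kernel — deposits ~10% more
total excitation when the beam runs along the lattice diagonal (the lattice
projection onto the beam-normal degenerates at 45° and the kernel has
appreciable Fourier content at the projected lattice frequency), which
permanently breaks rotational consistency of the simulated sinograms. The
Gaussian suppresses that resonant mode to ~10⁻⁶.

**Source formation.** S = η·X·ρ per voxel, with the luminescence yield η = 1
in relative units (no absolute radiometric calibration is attempted).

**Propagation.** Photon fluence at a boundary point r from an interior point
source r′ uses the diffusion-approximation kernel for a homogeneous medium,

    G∞(d) = exp(−μeff·d) / (4π·D·d),
    D = 1/[3(μa + μs′)],  μeff = √(3·μa·(μa + μs′)),

with an extrapolated-boundary image source: the cylinder boundary is
approximated locally at the detector by its tangent plane, and the mirror
source sits a distance 2(h + z_b) behind it, z_b = 2AD with A the
internal-reflection parameter from the Groenhuis formula (n = 1.37 default).
G = G∞(d_true) − G∞(d_image) is strictly positive and strictly decreasing in
source–detector distance. Default optics μa = 0.5 cm⁻¹, μs′ = 15 cm⁻¹ are
well inside the diffusion regime (μs′/μa = 30); a warning fires below
μs′ < 10·μa.

**Detectors.** Three point-aperture fiber bundles, 120° apart on the lateral
surface at the scan-plane height, first bundle at +90° from the beam
direction. They are mounted on the rotating gantry, so their angular
positions co-rotate with the view; this is what makes the sinogram
rotation-equivariant (rotating the phantom by one angular step shifts the
view index by one) and it matches the physical instrument, where the fibers
ride on the gantry. Aperture area is a scale factor (1 mm²).

**Scan.** 15 views over 180° (12° steps) for the few-view protocol, 30 views
(6° steps) for full-view; 50 translations of 0.5 mm per view; shape
(views, translations, 3). The discretized system matrix A has one row per
(view, translation, detector) with A[m, v] = η·X_m(v)·G(r_det(m), r_v)·ΔV·
aperture, so A·ρ reproduces the noiseless simulator to machine precision
(the two are different codings of the same physics, and are pinned together
by tests).

**Noise.** Optional shot-like Gaussian noise, σ = level·√(peak·signal) +
floor, so σ at the sinogram peak is level·peak; default level 1%. Unit and
oracle tests run noiseless; the experiment pipeline applies the default
level to every simulated measurement because the reference data-generation
procedure it emulates (Monte-Carlo photon transport) is intrinsically noisy.

## Phantoms

Digital cylinders (radius 12.5 mm, height 20 mm) with homogeneous background
optics and 1–4 non-overlapping spherical targets (radius 0.5–2.5 mm,
concentration 0.5–2.0 relative units) placed uniformly in the admissible
disc, rejection-sampled until containment and non-overlap hold. Optical
parameters are drawn uniformly within ±20% of (0.5, 15) cm⁻¹. Targets are
centered on the scan plane by default so the 2D slice carries the signal.
Rasterization is binary center-in-sphere at the slice grid; everything is
reproducible from a single integer seed.

The cylinder radius is chosen so the 50 × 0.5 mm translation span covers the
full diameter. The voxel default is 0.25 mm; the desk-scale experiment
profile uses a 64×64 slice grid (0.39 mm voxels) throughout — simulation,
system matrix and ground truth share one grid.

## Reconstruction

The inverse problem minimizes ‖A·ρ − Φ‖₂² + λ·TV(ρ≥0) in spirit; two
numerical choices matter:

- **Sensitivity equalization.** Column norms of A span several decades
  (voxels near a detector are exponentially more visible than central
  ones), which stalls plain proximal-gradient iterations: central targets
  are reconstructed several voxels off even after 1000 iterations. The
  solver therefore works on the column-normalized system A′ = A·S⁻¹ and
  minimizes F(u) = ‖A′u − Φ‖² + λ·TV(u) with u = S·ρ — isotropic TV on the
  sensitivity-weighted image — then reports ρ = u/S. With this change 20/20
  seeded single-target phantoms localize within 0.4 voxels.
- **Monotone FISTA.** Proximal gradient with Beck–Teboulle momentum, a
  Chambolle dual-projection TV prox (own implementation, cross-checked
  against the scikit-image reference), nonnegativity and cylinder-support
  projection, and a monotone acceptance rule so the recorded objective is
  nonincreasing. Step = 1/L with L from 60 power iterations; cap 500
  iterations (300 in the desk profile), relative-change tolerance 1e-6.

λ defaults to 1e-3 × max|A′ᵀΦ|, the standard "fraction of the maximal
back-projected datum" scale, so it tracks the data magnitude.

Metrics: PSNR = 10·log₁₀(range²/MSE) with range = ground-truth maximum
(+∞ sentinel for identical images); SSIM is the mean local structural
similarity with a uniform 7×7 window via scikit-image, with the same data
range. Target localization uses the intensity-weighted centroid of the
largest connected component above half maximum.

## View synthesis

A few-view sinogram is first upsampled to the 30-view angle grid by linear
interpolation along the view axis (original views preserved exactly;
inserted views are neighbour means; at the 180° wrap the neighbour is view 0
flipped along the translation axis). The residual network then predicts a
correction on that interpolation. Architecture (fixed): one 3×3/64
convolution, four residual blocks of three 3×3/64 convolutions with an
identity shortcut spanning the three layers, two 3×3/64 convolutions, one
3×3/32 convolution, and a single-filter 3×3 output convolution; ReLU after
every layer except the output. 17 convolutions, ≈450k parameters.

The network runs on a small in-repo reverse-mode autodiff engine
(`xlct.autodiff`: im2col convolution, ReLU, reductions) because no deep
learning framework is assumed in the runtime environment. Two training
details proved load-bearing:

- **Working domain.** Inputs and targets are normalized by the few-view
  sinogram maximum and square-root compressed. Raw readings span decades
  (diffusive decay), so in the raw domain the composite loss is dominated
  by a handful of bright pixels and training never leaves the interpolation
  baseline; in the sqrt domain the same architecture learns the
  trace-deghosting correction reliably. The scheme is recorded in the
  checkpoint so inference is self-contained.
- **Initialization.** The output convolution starts at std 0.01 rather than
  exactly zero: exact zero gates the gradient to every earlier layer and
  training plateaus at the interpolation baseline. Forcing the output layer
  to zero by hand still reproduces the interpolation exactly (residual
  identity).

Loss: α·(1 − SSIM) + (1 − α)·L1 with α = 0.8, SSIM computed with a uniform
7×7 window over the valid region (data range 1 in the normalized domain).
The sign convention (1 − SSIM) makes the loss vanish exactly at equality and
decrease as similarity rises. Optimizer: Adam, lr 1e-3, batch 4 in the
pipeline (batch 4 doubles the optimization steps per unit compute relative
to batch 8, which matters at desk scale), 80/10/10 split by phantom; the
three detector channels are independent single-channel samples sharing
weights. Training is deterministic given the seed.

## Experiment profiles and what a green test establishes

- `desk`: 100 phantoms, 64×64 grid, 12 epochs, ≈10 minutes on one CPU.
- `paper`: 400 phantoms, 0.25 mm voxels, 200 epochs (hours; not exercised
  by the test suite).

The synthetic world is deliberately idealized: homogeneous optics, analytic
diffusion kernel (no Monte-Carlo transport), point detectors, spherical
in-plane targets, and — critically — measurements simulated by the same
discretized physics used to build the reconstruction matrix (the
oracle-equivalence requirement pins them together). Green tests therefore
establish internal consistency and algorithmic correctness, not agreement
with a physical instrument.

One documented consequence: with data this faithful to the model, the raw
15-view TV reconstruction is already excellent (≈27–28 dB on held-out
four-target phantoms at 1% noise), so the trained synthesis network —
whose reconstructions reach ≈24–26 dB / SSIM ≈ 0.89–0.91, squarely in the
range the method is expected to deliver — does not *surpass* the few-view
baseline here, while the true 30-view reconstruction does (more data always
helps). Probing an intentionally mismatched configuration (measurements
simulated on the native 0.25 mm grid, reconstruction on the 64×64 grid)
drops the few-view baseline to ≈19–20 dB but floors every condition at the
grid-mismatch error, squeezing the spread to ~0.2 dB. Reproducing the
published ordering appears to require data whose model error is large and
structured (full Monte-Carlo transport) — explicitly out of scope here.
The improvement test is kept as stated and is expected to fail in this
synthetic world; the accompanying analysis lives with the test rather than
in a weakened assertion.

## Known limitations

- 2D single-slice reconstruction only; targets off the scan plane
  contribute only their slice cross-section.
- The planar-boundary image-source approximation degrades for sources close
  to the curved boundary and near the cylinder ends.
- The autodiff engine is single-threaded float32 and supports exactly the
  operations the network needs; it is not a general framework.
- Per-detector channels are kept separate throughout; summing bundles (an
  alternative reading of the instrument) is not implemented.
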