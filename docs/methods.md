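# Methods

This note documents the models implemented in `speckleseg`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
benchmark does and does not demonstrate.

## Speckle model and phantom generator

Fully developed speckle is modelled at the envelope level: per pixel the
echo quadratures are independent zero-mean Gaussians with standard
deviation σ, so the envelope M = √(Mr²+Mi²) is Rayleigh with scale σ
(mean σ√(π/2), variance (2−π/2)σ²). The noisy image is the elementwise
product of the clean reflectivity and the envelope. By default the
envelope is divided by its theoretical mean so that clean and noisy frames
share one brightness scale (`normalize=True`); note that a mean-normalised
Rayleigh envelope has a fixed coefficient of variation (≈ 0.52) regardless
of σ, so with normalization on, different σ values change the realisation
but not the severity of the multiplicative noise. No point-spread-function
convolution, spatial speckle correlation, attenuation or shadowing is
simulated — the model is exactly the envelope statistics above.

The phantom is a "bean": an ellipse (default semi-axes 30 × 20 px in a
128 × 128 frame) whose radius is reduced by `depth·max(0, cos(φ−φ₀))²`
(default depth 0.25) to imitate the renal hilum indentation. The interior
is darker (0.3) than the background (0.7), as for hypoechoic parenchyma;
the clean image is blurred with a Gaussian of 1 px to create soft edges
while the *unblurred* region is kept as ground truth. Intensities live in
[0, 1] internally; image I/O converts to/from 8- or 16-bit PNG. Pixel
(r, c) has its centre at coordinates (r, c) — the scikit-image convention
— consistently across boundary tracing, bilinear sampling and
rasterisation.

Because ln(P·N) = ln P + ln N, an offset logarithm (`ε = 10⁻⁶` on the
[0, 1] scale, since ln 0 is undefined) converts the multiplicative noise
to additive noise for the denoiser.

## Anisotropic diffusion

Explicit 4-neighbour Perona–Malik stepping with replicated borders. The
scheme preserves constants exactly, conserves the global mean to machine
precision (zero-flux borders), and obeys the discrete maximum principle
for λ ≤ 1/4. Defaults: rational conductivity (slightly better edge
retention than the exponential one at high contrast), λ = 0.2,
30 iterations, and an edge threshold k chosen per image as the 90th
percentile of the absolute neighbour differences (the filter then treats
the strongest decile of gradients as edges). Log-domain filtering is the
default in the estimator because the package's inputs are speckle images;
the functional API defaults to the plain intensity domain for generic use.

## PCNN initial contour

The standard pulse-coupled neuron lattice: feeding F and linking L decay
exponentially per iteration and are re-excited by the stimulus and by the
previous firing map through small convolution kernels; the internal
activity U = F(1+βL) fires where it exceeds a decaying dynamic threshold
θ, which then recharges by V_θ. Defaults (β = 0.2, retention factors 0.7 /
0.3 / 0.8 for F / L / θ, V_F = 0.01, V_L = 1, V_θ = 20, θ₀ = 1, 3 × 3
inverse-square-distance kernels with zero centre, 60 iterations) are for
stimuli scaled to [0, 1]; the stimulus is the denoised image, gray value
only.

The first firing wave sweeps the image in order of decreasing intensity,
so the cumulative first-fire map "fired by iteration a" is a monotone
family of thresholded images; the member with maximal binary entropy
(fired fraction closest to ½) separates the two intensity classes. Later
refire cycles desynchronise under noise and are ignored by construction.
Since the two classes of a two-level image give complementary — hence
equal-entropy — maps, the selected mask is polarity-normalised: if its
foreground occupies most of the image border it is inverted (the organ
never touches the frame in a B-mode scan). The mask is cleaned (largest
4-connected component, hole filling, one 3 × 3 opening), its boundary
traced at sub-pixel accuracy by marching squares, and resampled to 100
points equally spaced in arc length, clockwise in image coordinates.

## Snake

Discrete energy with constant elasticity α = 0.1 and rigidity β = 0.05;
external potential E = −|∇(G_σ∗I)|² with σ = 2 px, divided by its maximum
magnitude so it spans [−1, 0] whatever the image's dynamic range — without
this normalisation the edge force on a [0, 1] image is O(10⁻³) and the
defaults for κ (2.0), γ (1.0) and the convergence tolerance (0.05 px mean
displacement) would be meaningless. Evolution is the standard semi-implicit
scheme: the cyclic pentadiagonal internal-force matrix
(β, −(α+4β), 2α+6β, −(α+4β), β) is assembled densely and (A+γI)⁻¹ cached —
at n = 100 points the dense inverse is negligible and the contract is the
solution, not the factorisation. The row and column systems share the
matrix and are solved independently. The contour is resampled to equal arc
length every 25 iterations, points are clamped to the frame, and the loop
stops when the mean displacement falls below the tolerance (possibly
before the first resampling pass) or at 500 iterations. At a converged
contour the discrete Euler–Lagrange residual |A·x − κF| is bounded by
(‖A‖+γ)·tol, an order of magnitude under the 10·tol acceptance bound. No
balloon force and no gradient-vector-flow field: the PCNN initialisation
is assumed near the target.

## Cloud-model differential evolution

Candidate contours are encoded as per-point radial displacements along the
initial contour's outward normals (dimension 100, clamped to ±10 px), which
keeps them closed and ordered by construction. The optimizer is
DE/rand/1 with greedy (elitist) selection on the shared Snake energy;
pop 30, 150 generations, F = 0.5.

Three design choices matter and were driven by the geometry of the search
space:

- **Crossover.** Binomial crossover at CR < 1 mixes two smooth radial
  genomes coordinate-wise and every crossover boundary injects a kink that
  the elasticity term rejects wholesale (measured acceptance collapsed to
  ~2 % of trials). The default is therefore CR = 1 (the full mutant), which
  keeps trials inside the smooth span of the population; the operator still
  supports any CR for unstructured problems.
- **Cloud perturbation.** Every trial coordinate receives an additive drop
  from a normal cloud with Ex = 0 and He = He_frac·En (He_frac = 0.1). The
  entropy is two-dimensional: it anneals linearly over generations
  (En: 3 px → 0.3 px) *and* scales with the individual's fitness rank,
  En_i = En(stage)·(¼ + ¾·rank/(pop−1)), so good individuals are perturbed
  gently and poor ones broadly. For contour genomes the drop vector is
  circularly smoothed along the contour (Gaussian, n/20 points) and
  rescaled to En_i — pointwise-independent jitter of a smooth contour is
  otherwise never accepted. With He = 0 the generator reduces exactly to
  Gaussian sampling, and as En → 0 the whole operator degenerates to
  classical DE (verified trial-for-trial under shared seeds).
- **Hybrid pipeline.** The default segmenter runs a 50-iteration Snake
  descent from the PCNN contour, then the DE refinement seeded with the
  zero-displacement individual (so the final energy can never exceed the
  starting contour's), then a short Snake polish of the DE result (50
  iterations, kept only if it lowers the energy). The polish exists because
  the DE locates basins but does not descend them to the floor; without it
  a deeper basin found by the DE would not be exploited. A pure-DE mode is
  available via `pre_evolve_iters=0`.

For the abstract 10-D sphere benchmark the entropy schedule is set to the
problem's own scale (En: 0.05 → 10⁻⁶ on a [−5, 5] domain, CR = 0.9): the
contour defaults are in pixels and have no meaning there.

## Metrics and benchmark

PSNR uses the peak value of the stored representation (1.0 for float
images, 255 for 8-bit) and returns +∞ at zero MSE. MCC returns 0 when any
marginal is empty. The pixel error rate is frame-normalised,
(FP+FN)/all pixels, by default; a foreground-normalised variant
((FP+FN)/truth area) is available because published error rates often use
the region convention without saying so.

The benchmark is paired: per (σ, seed) cell one phantom is generated,
denoised once, one PCNN contour extracted, and both contour methods run
from that identical initialisation, so per-cell differences isolate the
optimizer. With 3 σ values × 10 seeds the suite runs in well under a
minute on one CPU; all stochastic stages are seeded, and a rerun with the
same configuration is byte-identical.

## What the synthetic tests do and do not show

The phantom validates the pipeline's mechanics — that diffusion denoises
without destroying the organ edge, that the PCNN wave isolates the organ,
that both contour methods converge, and that the cloud-DE refinement
reaches a lower value of the shared energy (and a slightly lower pixel
error) than the purely local descent from the same initialisation. On this
phantom the landscape is close to unimodal and the local Snake is already
near-optimal, so the margin between the two methods is small; on clinical
images — with attenuation, shadowing, heterogeneous parenchyma and edge
dropout, none of which the generator simulates — local descent fails more
often, and published comparisons report much larger separations (error
rates of order 10–20 %). Results on these phantoms therefore support
directional, not quantitative, conclusions about clinical performance.

## Known limitations

- The speckle generator has no spatial correlation; real speckle grains
  span several pixels.
- The PCNN "texture feature" sometimes mentioned alongside the gray value
  in the literature is not defined anywhere usable and is not implemented.
- The radial displacement encoding cannot represent contours that fold
  back on themselves relative to the initialisation.
- `extract_initial_contour` assumes the target is the largest bright or
  dark region not dominating the frame border; free-floating multi-organ
  scenes are out of scope.
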