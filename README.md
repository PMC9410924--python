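# speckleseg

Speckle-aware active-contour segmentation of B-mode ultrasound images, with
a synthetic phantom generator so the whole pipeline is testable without
clinical data.

Segmenting organs (e.g. the kidney in pediatric renal imaging) in B-mode
ultrasound is hard because the coherent imaging process corrupts every frame
with multiplicative speckle. This package implements a complete classical
pipeline for that problem, aimed at researchers in medical image analysis:

1. **Speckle model** (`speckleseg.phantom`). Under fully developed speckle
   the echo quadratures are i.i.d. Gaussians, Mr, Mi ~ N(0, σ²); the
   envelope M = √(Mr² + Mi²) is Rayleigh,
   p(M) = (M/σ²)·exp(−M²/2σ²), and corrupts the tissue reflectivity
   multiplicatively, P′ = P·N. Phantoms are a dark, kidney-shaped ("bean")
   region on a brighter background with the ground-truth mask retained.
2. **Denoising** (`speckleseg.denoise`). Perona–Malik anisotropic diffusion,
   Î(x) = I(x) + λ Σ_p c(|∇I_{x,p}|)·∇I_{x,p} over the 4-neighbourhood,
   with rational c(g) = 1/(1+(g/k)²) or exponential c(g) = exp(−(g/k)²)
   conductivity. Taking logarithms first (ln P′ = ln P + ln N) turns the
   multiplicative noise additive; log-domain filtering is the default.
3. **Initial contour** (`speckleseg.pcnn`). A pulse-coupled neural network —
   one neuron per pixel with feeding/linking inputs, multiplicative
   coupling U = F·(1+βL), and a decaying dynamic threshold θ — makes
   pixels of similar intensity fire synchronously. The maximal-entropy
   firing wave yields the segment whose traced boundary seeds the active
   contour.
4. **Active contour** (`speckleseg.snake`). The classical parametric Snake:
   E = Σᵢ [½(α|vᵢ₊₁−vᵢ|² + β|vᵢ₊₁−2vᵢ+vᵢ₋₁|²) + κ·E_ext(vᵢ)] with the
   Kass edge potential E_ext = −|∇(G_σ∗I)|², evolved by the semi-implicit
   scheme x⁺ = (A+γI)⁻¹(γx + κF_ext) until the Euler–Lagrange force
   balance F_int + F_ext = 0 holds.
5. **Cloud-model refinement** (`speckleseg.cloud`). A differential-evolution
   optimizer over per-point radial displacements of the contour, whose
   mutation noise comes from a normal cloud generator (Ex, En, He):
   En′ ~ N(En, He²), x ~ N(Ex, En′²). The entropy En anneals over
   generations and couples to each individual's fitness rank, so the search
   is fuzzy-explorative early and nearly deterministic late. Fitness is the
   same discrete Snake energy, so the refinement and the local descent
   optimize one objective and can be compared fairly.
6. **Metrics** (`speckleseg.metrics`). PSNR/MSE for denoising and
   DSC, MCC and pixel error rate for segmentation, plus a paired phantom
   benchmark of the two contour methods.

All stages are also exposed as scikit-learn-style estimators
(`PeronaMalikDenoiser`, `PCNNSegmenter`, `SnakeSegmenter`,
`CloudACMSegmenter`) with `get_params`/`set_params`/`clone` support and
fitted attributes (`mask_`, `contour_`, `energy_`, ...).

## Worked example

```python
from speckleseg import (generate_phantom, PeronaMalikDenoiser, PCNNSegmenter,
                        SnakeSegmenter, CloudACMSegmenter, psnr, dice,
                        pixel_error_rate)

phantom = generate_phantom(shape=(128, 128), sigma=0.8, seed=7)
den = PeronaMalikDenoiser().fit_transform(phantom.noisy)
print(f"PSNR noisy   : {psnr(phantom.clean, phantom.noisy):.2f} dB")
print(f"PSNR denoised: {psnr(phantom.clean, den):.2f} dB")

pcnn = PCNNSegmenter().fit(den)
snake = SnakeSegmenter().fit(den, init_contour=pcnn.contour_)
acm = CloudACMSegmenter(seed=7).fit(den, init_contour=pcnn.contour_)
for name, seg in [("snake", snake), ("cloud-acm", acm)]:
    print(f"{name:9s}: error rate = "
          f"{100 * pixel_error_rate(seg.mask_, phantom.truth_mask):.3f} %, "
          f"DSC = {dice(seg.mask_, phantom.truth_mask):.3f}, "
          f"energy = {seg.energy_:.2f}")
```

prints

```
PSNR noisy   : 9.13 dB
PSNR denoised: 18.74 dB
snake    : error rate = 0.452 %, DSC = 0.978, energy = -124.82
cloud-acm: error rate = 0.427 %, DSC = 0.979, energy = -125.08
```

Diffusion roughly doubles the PSNR of the speckled frame; both active
contours segment the phantom to within a fraction of a percent of frame
pixels, and the cloud-model refinement reaches a slightly lower energy of
the shared objective — and a slightly lower error — than the purely local
Snake descent started from the identical PCNN contour.

The same pipeline is scriptable from the shell:

```bash
speckleseg simulate --shape 128x128 --sigma 0.8 --seed 7 --out ph/
speckleseg denoise  --in ph/noisy.png --out den.png
speckleseg pcnn     --in den.png --out init.png --contour init.csv
speckleseg segment  --in ph/noisy.png --method cloud-acm --seed 7 --out mask.png
speckleseg evaluate --pred mask.png --truth ph/mask.png --report report.json
speckleseg benchmark --out results.csv
```

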