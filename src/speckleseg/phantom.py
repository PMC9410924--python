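"""Synthetic B-mode ultrasound phantoms with fully developed speckle.

Under fully developed speckle the echo's real and imaginary quadratures are
independent zero-mean Gaussians with common variance ``sigma**2``; their
envelope ``M = sqrt(Mr**2 + Mi**2)`` is Rayleigh distributed,

    p(M) = (M / sigma**2) * exp(-M**2 / (2 sigma**2)),   M >= 0,

and corrupts the tissue reflectivity multiplicatively, ``P' = P * N``.
Taking logarithms turns the multiplicative corruption into an additive one,
which is the domain in which the diffusion denoiser operates by default.

The phantom is a smooth dark organ-like region (a "bean": an ellipse with a
cosine indentation, mimicking a kidney outline in a coronal section) on a
brighter background, blurred to create soft edges, with the un-blurred
region kept as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import DimensionError, GeometryError

__all__ = [
    "RAYLEIGH_MEAN_FACTOR",
    "SpeckleField",
    "SpecklePhantom",
    "rayleigh_pdf",
    "rayleigh_cdf",
    "sample_speckle_field",
    "apply_multiplicative_noise",
    "log_transform",
    "inverse_log_transform",
    "bean_mask",
    "generate_phantom",
]

#: E[M] = sigma * sqrt(pi/2) for a Rayleigh envelope of scale sigma.
RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be finite and > 0, got {sigma!r}")
    return sigma


def _check_image(image) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise DimensionError(f"expected a 2D image of at least 3x3, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


@dataclass
class SpeckleField:
    """In-phase/quadrature speckle realisation and its Rayleigh envelope."""

    real_part: np.ndarray
    imag_part: np.ndarray
    sigma: float
    envelope: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.real_part = np.asarray(self.real_part, dtype=float)
        self.imag_part = np.asarray(self.imag_part, dtype=float)
        if self.real_part.shape != self.imag_part.shape:
            raise DimensionError("real and imaginary parts must share a shape")
        _check_sigma(self.sigma)
        self.envelope = np.hypot(self.real_part, self.imag_part)

    @property
    def shape(self):
        return self.envelope.shape


@dataclass
class SpecklePhantom:
    """Clean image, truth mask and speckled image sharing one frame."""

    clean: np.ndarray
    truth_mask: np.ndarray
    noisy: np.ndarray
    sigma: float
    seed: int
    object_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.clean.shape == self.truth_mask.shape == self.noisy.shape):
            raise DimensionError("clean, truth_mask and noisy must share one shape")

    @property
    def shape(self):
        return self.clean.shape


def rayleigh_pdf(m, sigma: float):
    """Rayleigh density of the speckle envelope: (m/s^2) exp(-m^2/(2 s^2)), 0 for m < 0."""
    sigma = _check_sigma(sigma)
    m = np.asarray(m, dtype=float)
    out = np.where(m < 0, 0.0, m / sigma**2 * np.exp(-np.square(m) / (2.0 * sigma**2)))
    return out if out.ndim else float(out)


def rayleigh_cdf(m, sigma: float):
    """Closed-form CDF 1 - exp(-m^2/(2 s^2)) of the envelope distribution."""
    sigma = _check_sigma(sigma)
    m = np.asarray(m, dtype=float)
    out = np.where(m < 0, 0.0, 1.0 - np.exp(-np.square(m) / (2.0 * sigma**2)))
    return out if out.ndim else float(out)


def sample_speckle_field(shape, sigma: float, seed) -> SpeckleField:
    """Draw a speckle field: i.i.d. N(0, sigma^2) quadratures per pixel.

    ``seed`` may be an int or a ``numpy.random.Generator``; results are
    bit-reproducible for a given integer seed.
    """
    sigma = _check_sigma(sigma)
    h, l = int(shape[0]), int(shape[1])
    if h < 3 or l < 3:
        raise DimensionError(f"shape must be at least 3x3, got {(h, l)}")
    rng = np.random.default_rng(seed)
    mr = rng.normal(0.0, sigma, size=(h, l))
    mi = rng.normal(0.0, sigma, size=(h, l))
    return SpeckleField(mr, mi, sigma)


def apply_multiplicative_noise(clean, field: SpeckleField, normalize: bool = True) -> np.ndarray:
    """Multiply a clean image by the speckle envelope, P' = P * N.

    With ``normalize`` the envelope is divided by its theoretical mean
    sigma*sqrt(pi/2), so the expected brightness of the output matches the
    clean image. Output is clipped to be non-negative.
    """
    clean = _check_image(clean)
    if clean.shape != field.shape:
        raise DimensionError(f"image shape {clean.shape} != field shape {field.shape}")
    envelope = field.envelope
    if normalize:
        envelope = envelope / (field.sigma * RAYLEIGH_MEAN_FACTOR)
    return np.clip(clean * envelope, 0.0, None)


def log_transform(image, offset: float = 1e-6) -> np.ndarray:
    """ln(image + offset): turns multiplicative speckle into additive noise."""
    image = np.asarray(image, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if np.any(image < 0):
        raise ValueError("log_transform expects a non-negative image")
    return np.log(image + offset)


def inverse_log_transform(image, offset: float = 1e-6) -> np.ndarray:
    """exp(image) - offset, the inverse of :func:`log_transform`."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    return np.exp(np.asarray(image, dtype=float)) - offset


def bean_mask(shape, center, semi_axes, indent_depth: float = 0.25,
              indent_angle: float = 0.0) -> np.ndarray:
    """Binary mask of an ellipse with a cosine indentation (kidney outline).

    A pixel at offset (dr, dc) from the centre, with elliptic radius
    e = hypot(dc/a, dr/b) and polar angle phi, is inside iff
    e <= 1 - depth * max(0, cos(phi - indent_angle))**2. depth = 0 gives a
    plain axis-aligned ellipse with semi-axes (a, b) = (cols, rows).
    """
    h, l = int(shape[0]), int(shape[1])
    cr, cc = float(center[0]), float(center[1])
    a, b = float(semi_axes[0]), float(semi_axes[1])  # a along columns, b along rows
    if a <= 0 or b <= 0:
        raise GeometryError("semi-axes must be positive")
    if not (cc - a >= 2 and cc + a <= l - 3 and cr - b >= 2 and cr + b <= h - 3):
        raise GeometryError("object must fit inside the frame with a 2-pixel margin")
    rows, cols = np.mgrid[0:h, 0:l]
    u = (cols - cc) / a
    v = (rows - cr) / b
    e = np.hypot(u, v)
    phi = np.arctan2(v, u)
    boundary = 1.0 - float(indent_depth) * np.maximum(0.0, np.cos(phi - indent_angle)) ** 2
    return (e <= boundary).astype(np.uint8)


def generate_phantom(shape=(128, 128), *, center=None, semi_axes=(30, 20),
                     indent_depth: float = 0.25, indent_angle: float = 0.0,
                     interior: float = 0.3, background: float = 0.7,
                     sigma: float = 0.8, blur_sd: float = 1.0, seed: int = 0,
                     normalize: bool = True) -> SpecklePhantom:
    """Build a speckled organ phantom with known ground truth.

    The clean image is the background level with the bean region set to the
    interior level, Gaussian-blurred by ``blur_sd`` pixels to create the soft
    edges typical of B-mode boundaries. The truth mask is the *unblurred*
    region. ``sigma = 0`` is the no-noise limit (noisy == clean). Interior
    darker than background emulates the hypoechoic renal parenchyma.
    """
    h, l = int(shape[0]), int(shape[1])
    if center is None:
        center = ((h - 1) / 2.0, (l - 1) / 2.0)
    mask = bean_mask((h, l), center, semi_axes, indent_depth, indent_angle)
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise GeometryError(f"truth mask must be a single component, got {n_comp}")

    clean = np.full((h, l), float(background))
    clean[mask.astype(bool)] = float(interior)
    if blur_sd > 0:
        clean = ndimage.gaussian_filter(clean, blur_sd, mode="nearest")

    if sigma == 0:
        noisy = clean.copy()
    else:
        field_ = sample_speckle_field((h, l), sigma, seed)
        noisy = apply_multiplicative_noise(clean, field_, normalize=normalize)

    spec = {
        "center": [float(center[0]), float(center[1])],
        "semi_axes": [float(semi_axes[0]), float(semi_axes[1])],
        "indent_depth": float(indent_depth),
        "indent_angle": float(indent_angle),
        "interior": float(interior),
        "background": float(background),
        "blur_sd": float(blur_sd),
        "normalize": bool(normalize),
    }
    return SpecklePhantom(clean=clean, truth_mask=mask, noisy=noisy,
                          sigma=float(sigma), seed=int(seed), object_spec=spec)
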