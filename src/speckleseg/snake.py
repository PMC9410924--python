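"""Classical parametric active contour (Snake).

The discrete energy over the closed contour v_1..v_n is

    G_snake = sum_i [ G_int(v_i) + kappa * G_ext(v_i) ]
    G_int   = 1/2 * ( alpha |v_{i+1} - v_i|^2 + beta |v_{i+1} - 2 v_i + v_{i-1}|^2 )

with the external potential the classical edge functional
G_ext = -|grad(G_sigma (*) I)|^2, whose minima lie on intensity edges.

Stationarity (the Euler-Lagrange force balance F_int + F_ext = 0) is reached
by the semi-implicit update applied independently to the row and column
coordinate vectors,

    x[t+1] = (A + gamma I)^(-1) (gamma x[t] + kappa F_ext,x(v[t]))

where A is the cyclic pentadiagonal internal-force matrix with stencil
(beta, -(alpha + 4 beta), 2 alpha + 6 beta, -(alpha + 4 beta), beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path
from scipy import ndimage
from sklearn.base import BaseEstimator

from .contours import as_contour, resample_closed
from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "SnakeParams",
    "EnergyTrace",
    "SegmentationResult",
    "internal_energy",
    "edge_potential",
    "sample_bilinear",
    "snake_energy",
    "internal_matrix",
    "evolve_snake",
    "contour_to_mask",
    "SnakeSegmenter",
]


@dataclass
class SnakeParams:
    """Active-contour weights and evolution controls.

    alpha: elasticity (first-derivative) weight.
    beta: rigidity (second-derivative) weight.
    gamma: evolution step size of the semi-implicit scheme.
    kappa: external (edge) force weight.
    edge_sigma: Gaussian pre-smoothing scale of the edge map, in pixels.
    tol: convergence threshold on the mean point displacement, in pixels.
    resample_every: iterations between equal-arc-length resampling passes.
    """

    alpha: float = 0.1
    beta: float = 0.05
    gamma: float = 1.0
    kappa: float = 2.0
    edge_sigma: float = 2.0
    max_iter: int = 500
    tol: float = 0.05
    resample_every: int = 25

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.tol <= 0:
            raise ConfigurationError("gamma and tol must be > 0")
        if min(self.alpha, self.beta, self.kappa) < 0 or self.alpha + self.beta + self.kappa == 0:
            raise ConfigurationError("alpha, beta, kappa must be >= 0 with a positive sum")
        if self.max_iter < 0 or self.resample_every < 1:
            raise ConfigurationError("max_iter >= 0 and resample_every >= 1 required")


@dataclass
class EnergyTrace:
    total: list = field(default_factory=list)
    internal: list = field(default_factory=list)
    external: list = field(default_factory=list)
    mean_disp: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.total)


@dataclass
class SegmentationResult:
    contour: np.ndarray
    mask: np.ndarray
    trace: object
    converged: bool
    energy: float


def internal_energy(contour, alpha: float, beta: float) -> float:
    """1/2 sum_i [alpha |v_{i+1}-v_i|^2 + beta |v_{i+1}-2v_i+v_{i-1}|^2], cyclic."""
    pts = as_contour(contour)
    d1 = np.roll(pts, -1, axis=0) - pts
    d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
    return 0.5 * float(alpha * np.sum(d1 ** 2) + beta * np.sum(d2 ** 2))


def edge_potential(image, edge_sigma: float = 2.0, normalize: bool = True):
    """Edge potential E = -|grad(G_sigma (*) I)|^2 and its attracting force.

    With ``normalize`` (default) the potential is divided by its maximum
    magnitude so it spans [-1, 0] regardless of the image's dynamic range;
    this keeps the kappa/gamma/tol defaults meaningful across inputs. The
    minima stay on the edges either way.

    Returns ``(potential, force)`` where ``force`` is a (2, h, w) array
    holding the (row, col) components of -grad E, i.e. the field that pulls
    contour points toward edges.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DimensionError("expected a 2D image")
    smoothed = ndimage.gaussian_filter(image, edge_sigma, mode="nearest") if edge_sigma > 0 \
        else image
    gr, gc = np.gradient(smoothed)
    potential = -(gr ** 2 + gc ** 2)
    if normalize:
        peak = -potential.min()
        if peak > 0:
            potential = potential / peak
    er, ec = np.gradient(potential)
    force = np.stack([-er, -ec])
    return potential, force


def sample_bilinear(field_: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinearly sample a 2D field at (row, col) sub-pixel points."""
    pts = np.asarray(points, dtype=float)
    return ndimage.map_coordinates(field_, [pts[:, 0], pts[:, 1]],
                                   order=1, mode="nearest")


def snake_energy(contour, image, params: SnakeParams | None = None, *,
                 potential: np.ndarray | None = None) -> float:
    """Total discrete Snake energy: internal + kappa * sampled edge potential.

    ``potential`` may be supplied to avoid recomputing the edge map (this is
    the objective shared with the cloud-model optimizer).
    """
    if params is None:
        params = SnakeParams()
    pts = as_contour(contour)
    if potential is None:
        potential, _ = edge_potential(image, params.edge_sigma)
    external = float(np.sum(sample_bilinear(potential, pts)))
    return internal_energy(pts, params.alpha, params.beta) + params.kappa * external


def internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Cyclic pentadiagonal matrix A of the discrete internal forces."""
    row = np.zeros(n)
    row[0] = 2 * alpha + 6 * beta
    row[1] = row[-1] = -(alpha + 4 * beta)
    if n > 4:
        row[2] = row[-2] = beta
    else:  # wrap-around contributions coincide
        row[2] += 2 * beta
    A = np.empty((n, n))
    for i in range(n):
        A[i] = np.roll(row, i)
    return A


def _clamp(points: np.ndarray, shape) -> np.ndarray:
    points[:, 0] = np.clip(points[:, 0], 0.0, shape[0] - 1.0)
    points[:, 1] = np.clip(points[:, 1], 0.0, shape[1] - 1.0)
    return points


def evolve_snake(contour, image, params: SnakeParams | None = None) -> SegmentationResult:
    """Semi-implicit Snake evolution from an initial contour.

    The row and column coordinates are updated through the identical system
    matrix (A + gamma I) independently; the contour is resampled to equal
    arc length every ``resample_every`` iterations and stops when the mean
    point displacement drops below ``tol``.
    """
    if params is None:
        params = SnakeParams()
    image = np.asarray(image, dtype=float)
    pts = _clamp(as_contour(contour).copy(), image.shape)
    n = len(pts)
    A = internal_matrix(n, params.alpha, params.beta)
    solver = np.linalg.inv(A + params.gamma * np.eye(n))
    potential, force = edge_potential(image, params.edge_sigma)

    trace = EnergyTrace()
    converged = False
    for it in range(params.max_iter):
        fr = sample_bilinear(force[0], pts)
        fc = sample_bilinear(force[1], pts)
        new_r = solver @ (params.gamma * pts[:, 0] + params.kappa * fr)
        new_c = solver @ (params.gamma * pts[:, 1] + params.kappa * fc)
        new_pts = _clamp(np.column_stack([new_r, new_c]), image.shape)
        disp = float(np.mean(np.linalg.norm(new_pts - pts, axis=1)))
        pts = new_pts
        if (it + 1) % params.resample_every == 0:
            pts = resample_closed(pts, n)
        e_int = internal_energy(pts, params.alpha, params.beta)
        e_ext = float(np.sum(sample_bilinear(potential, pts)))
        trace.internal.append(e_int)
        trace.external.append(e_ext)
        trace.total.append(e_int + params.kappa * e_ext)
        trace.mean_disp.append(disp)
        if disp < params.tol:
            converged = True
            break

    energy = snake_energy(pts, image, params, potential=potential)
    return SegmentationResult(contour=pts, mask=contour_to_mask(pts, image.shape),
                              trace=trace, converged=converged, energy=energy)


def contour_to_mask(contour, shape) -> np.ndarray:
    """Rasterize the closed polygon: pixel centres inside by the even-odd rule."""
    pts = np.asarray(contour, dtype=float)
    h, l = int(shape[0]), int(shape[1])
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        return np.zeros((h, l), dtype=np.uint8)
    path = Path(pts[:, ::-1])  # Path expects (x, y) = (col, row)
    cols, rows = np.meshgrid(np.arange(l), np.arange(h))
    centres = np.column_stack([cols.ravel(), rows.ravel()])
    inside = path.contains_points(centres)
    return inside.reshape(h, l).astype(np.uint8)


class SnakeSegmenter(BaseEstimator):
    """sklearn-style wrapper: ``fit(image, init_contour=...)`` evolves a Snake.

    Fitted attributes: ``contour_``, ``mask_``, ``trace_``, ``converged_``,
    ``energy_``.
    """

    def __init__(self, alpha=0.1, beta=0.05, gamma=1.0, kappa=2.0, edge_sigma=2.0,
                 max_iter=500, tol=0.05, resample_every=25):
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.kappa = kappa
        self.edge_sigma = edge_sigma
        self.max_iter = max_iter
        self.tol = tol
        self.resample_every = resample_every

    def _params(self) -> SnakeParams:
        return SnakeParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                           kappa=self.kappa, edge_sigma=self.edge_sigma,
                           max_iter=self.max_iter, tol=self.tol,
                           resample_every=self.resample_every)

    def fit(self, X, y=None, init_contour=None):
        if init_contour is None:
            raise ConfigurationError("SnakeSegmenter requires init_contour")
        result = evolve_snake(init_contour, X, self._params())
        self.contour_ = result.contour
        self.mask_ = result.mask
        self.trace_ = result.trace
        self.converged_ = result.converged
        self.energy_ = result.energy
        return self

    def fit_predict(self, X, y=None, init_contour=None):
        return self.fit(X, init_contour=init_contour).mask_
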