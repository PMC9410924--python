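"""Pulse-coupled neural network (PCNN) region extraction.

One neuron per pixel, driven by the stimulus S (the denoised image scaled to
[0, 1]) and laterally coupled to its neighbours through the firing map Y of
the previous iteration:

    F[a] = exp(-a_F) * F[a-1] + S + V_F * (M (*) Y[a-1])
    L[a] = exp(-b_L) * L[a-1] + V_L * (W (*) Y[a-1])
    U[a] = F[a] * (1 + beta * L[a])
    Y[a] = 1 where U[a] > theta[a-1], else 0
    theta[a] = exp(-b_theta) * theta[a-1] + V_theta * Y[a]

with (*) a 2D correlation with replicated borders.  Pixels of similar
intensity cross the decaying dynamic threshold at the same iteration and
fire synchronously, so each firing map delineates an intensity class; the
map of maximal binary entropy (fired fraction closest to 1/2) is taken as
the segment, and its traced outer boundary seeds the active contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from .contours import ensure_clockwise, resample_closed
from .exceptions import ConfigurationError, DimensionError, NoSegmentationError

__all__ = [
    "DEFAULT_KERNEL",
    "PCNNParams",
    "PCNNState",
    "PCNNRun",
    "pcnn_step",
    "run_pcnn",
    "binary_entropy",
    "select_segment_iteration",
    "normalize_mask_polarity",
    "extract_initial_contour",
    "PCNNSegmenter",
]

#: 3x3 inverse-square-distance coupling weights, zero centre.
DEFAULT_KERNEL = np.array([[0.5, 1.0, 0.5],
                           [1.0, 0.0, 1.0],
                           [0.5, 1.0, 0.5]])


@dataclass
class PCNNParams:
    """PCNN coefficients. Decay constants are per-iteration exponents: the
    retained fraction per step is exp(-decay). Defaults correspond to
    retention factors 0.7 (feed), 0.3 (link), 0.8 (threshold) on [0, 1]
    stimuli."""

    beta: float = 0.2
    decay_f: float = math.log(1 / 0.7)
    decay_l: float = math.log(1 / 0.3)
    decay_theta: float = math.log(1 / 0.8)
    vf: float = 0.01
    vl: float = 1.0
    vtheta: float = 20.0
    kernel_m: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    kernel_w: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    theta0: float = 1.0
    max_iter: int = 60

    def __post_init__(self) -> None:
        if min(self.decay_f, self.decay_l, self.decay_theta) <= 0:
            raise ConfigurationError("decay constants must be > 0")
        if self.vtheta <= 0:
            raise ConfigurationError("vtheta must be > 0 (threshold must recharge)")
        if min(self.vf, self.vl) < 0:
            raise ConfigurationError("amplification coefficients must be >= 0")
        for name in ("kernel_m", "kernel_w"):
            kern = np.asarray(getattr(self, name), dtype=float)
            if kern.ndim != 2 or kern.shape[0] % 2 == 0 or kern.shape[1] % 2 == 0:
                raise ConfigurationError(f"{name} must be 2D with odd dimensions")
            if np.any(kern < 0) or kern[kern.shape[0] // 2, kern.shape[1] // 2] != 0:
                raise ConfigurationError(f"{name} must be non-negative with zero centre")
            setattr(self, name, kern)
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


@dataclass
class PCNNState:
    """All coupled fields of the network at one iteration."""

    feed: np.ndarray
    link: np.ndarray
    internal: np.ndarray
    theta: np.ndarray
    fired: np.ndarray
    iteration: int = 0

    @classmethod
    def initial(cls, shape, theta0: float) -> "PCNNState":
        zeros = np.zeros(shape)
        return cls(feed=zeros.copy(), link=zeros.copy(), internal=zeros.copy(),
                   theta=np.full(shape, float(theta0)), fired=np.zeros(shape, dtype=np.uint8),
                   iteration=0)


@dataclass
class PCNNRun:
    """Per-iteration firing maps plus the first-fire index map (-1 = never)."""

    fired_maps: np.ndarray          # (T, h, w) uint8
    first_fire: np.ndarray          # (h, w) int, -1 where a pixel never fired
    all_fired: bool


def _correlate(field_: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.correlate(field_, kernel, mode="nearest")


def pcnn_step(state: PCNNState, stimulus: np.ndarray, params: PCNNParams) -> PCNNState:
    """Advance the network by one iteration of the coupled recursion."""
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.shape != state.feed.shape:
        raise DimensionError(f"stimulus shape {stimulus.shape} != state shape {state.feed.shape}")
    y_prev = state.fired.astype(float)
    feed = (math.exp(-params.decay_f) * state.feed + stimulus
            + params.vf * _correlate(y_prev, params.kernel_m))
    link = (math.exp(-params.decay_l) * state.link
            + params.vl * _correlate(y_prev, params.kernel_w))
    internal = feed * (1.0 + params.beta * link)
    fired = (internal > state.theta).astype(np.uint8)
    theta = math.exp(-params.decay_theta) * state.theta + params.vtheta * fired
    return PCNNState(feed=feed, link=link, internal=internal, theta=theta,
                     fired=fired, iteration=state.iteration + 1)


def run_pcnn(image, params: PCNNParams | None = None) -> PCNNRun:
    """Iterate the network from rest (F = L = U = 0, theta = theta0).

    Records every firing map and the iteration at which each pixel first
    fired. With a decaying threshold and positive stimuli, every pixel is
    guaranteed to fire within ceil((ln theta0 - ln S_min)/b_theta) + 1
    iterations; ``all_fired`` flags whether that happened within the budget.
    """
    if params is None:
        params = PCNNParams()
    stimulus = np.asarray(image, dtype=float)
    state = PCNNState.initial(stimulus.shape, params.theta0)
    maps = np.empty((params.max_iter,) + stimulus.shape, dtype=np.uint8)
    first_fire = np.full(stimulus.shape, -1, dtype=int)
    for a in range(params.max_iter):
        state = pcnn_step(state, stimulus, params)
        maps[a] = state.fired
        newly = (first_fire < 0) & (state.fired == 1)
        first_fire[newly] = a + 1
    return PCNNRun(fired_maps=maps, first_fire=first_fire,
                   all_fired=bool(np.all(first_fire > 0)))


def binary_entropy(p: float) -> float:
    """Shannon entropy of a Bernoulli(p) map, in nats; 0 at p in {0, 1}."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * math.log(p) - (1 - p) * math.log(1 - p))


def select_segment_iteration(run, criterion: str = "entropy"):
    """Pick the firing map that best separates the image into two classes.

    Accepts a :class:`PCNNRun` or a sequence of binary maps. The default
    criterion is the binary Shannon entropy of the fired fraction (maximal
    when half the pixels fire); ties are broken by the earliest iteration.
    Trivial all-0 / all-1 maps are excluded.

    Given a :class:`PCNNRun` the candidates are the cumulative first-fire
    maps ("fired by iteration a"): the first firing wave sweeps the image in
    order of decreasing intensity, so the maximal-entropy cut lands on the
    boundary between the two intensity classes. Later refire cycles
    desynchronise under noise and are thereby ignored. A raw sequence of
    maps is scored as given.

    Returns ``(mask, iteration_index)`` with a 0-based index into the maps.
    """
    if isinstance(run, PCNNRun):
        a = np.arange(1, len(run.fired_maps) + 1)
        fired = run.first_fire > 0
        maps = ((run.first_fire[None] <= a[:, None, None]) & fired[None]).astype(np.uint8)
    else:
        maps = np.asarray(run)
    if criterion != "entropy":
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    best_idx, best_score = -1, -1.0
    for idx, m in enumerate(maps):
        p = float(np.mean(m))
        score = binary_entropy(p)
        if score > best_score and 0.0 < p < 1.0:
            best_idx, best_score = idx, score
    if best_idx < 0:
        raise NoSegmentationError("all firing maps are trivial (all-0 or all-1)")
    return np.asarray(maps[best_idx], dtype=np.uint8), best_idx


def normalize_mask_polarity(mask) -> np.ndarray:
    """Orient a two-class map so foreground = the interior object.

    On a two-level image the PCNN firing maps of the two intensity classes
    have complementary fired fractions and hence equal entropy, so entropy
    alone cannot say which class is the organ. In B-mode scans the organ
    never touches the frame: if the foreground occupies the majority of the
    image border the mask is inverted.
    """
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    border = np.concatenate([mask[0], mask[-1], mask[1:-1, 0], mask[1:-1, -1]])
    if border.mean() > 0.5:
        mask = (1 - mask).astype(np.uint8)
    return mask


def extract_initial_contour(mask, min_area: int = 50, n_points: int = 100) -> np.ndarray:
    """Trace the initial closed contour from a binary segment map.

    Keeps the largest 4-connected component with area >= ``min_area``, fills
    holes, applies one 3x3 binary opening, traces the outer boundary at
    sub-pixel accuracy, and resamples it to ``n_points`` equally spaced
    points, oriented clockwise in image coordinates.
    """
    mask = (np.asarray(mask) > 0)
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n == 0:
        raise NoSegmentationError("empty mask")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area:
        raise NoSegmentationError(f"largest component ({int(areas[best - 1])} px) "
                                  f"below min_area={min_area}")
    comp = ndimage.binary_fill_holes(labels == best)
    opened = ndimage.binary_opening(comp, structure=np.ones((3, 3)))
    if opened.any():
        labels2, n2 = ndimage.label(opened)
        sizes = ndimage.sum_labels(np.ones_like(labels2), labels2,
                                   index=np.arange(1, n2 + 1))
        comp = labels2 == (int(np.argmax(sizes)) + 1)
    boundaries = measure.find_contours(comp.astype(float), 0.5)
    if not boundaries:
        raise NoSegmentationError("component has no traceable boundary")
    boundary = max(boundaries, key=len)
    if np.allclose(boundary[0], boundary[-1]):
        boundary = boundary[:-1]
    if len(boundary) < 4:
        raise NoSegmentationError("degenerate boundary")
    return ensure_clockwise(resample_closed(boundary, n_points))


class PCNNSegmenter(BaseEstimator):
    """Clustering-style estimator: fit(image) -> ``mask_`` and ``contour_``.

    The stimulus is min-max rescaled to [0, 1]; the network is run for
    ``max_iter`` iterations, the maximal-entropy firing map is selected,
    polarity-normalised (organ assumed interior), and its boundary traced
    and resampled to ``n_points``. Intended input is the denoised image.
    """

    def __init__(self, beta=0.2, decay_f=math.log(1 / 0.7), decay_l=math.log(1 / 0.3),
                 decay_theta=math.log(1 / 0.8), vf=0.01, vl=1.0, vtheta=20.0,
                 theta0=1.0, max_iter=60, min_area=50, n_points=100):
        self.beta = beta
        self.decay_f = decay_f
        self.decay_l = decay_l
        self.decay_theta = decay_theta
        self.vf = vf
        self.vl = vl
        self.vtheta = vtheta
        self.theta0 = theta0
        self.max_iter = max_iter
        self.min_area = min_area
        self.n_points = n_points

    def _params(self) -> PCNNParams:
        return PCNNParams(beta=self.beta, decay_f=self.decay_f, decay_l=self.decay_l,
                          decay_theta=self.decay_theta, vf=self.vf, vl=self.vl,
                          vtheta=self.vtheta, theta0=self.theta0, max_iter=self.max_iter)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DimensionError("PCNNSegmenter expects a single 2D image")
        lo, hi = float(X.min()), float(X.max())
        stimulus = (X - lo) / (hi - lo) if hi > lo else np.zeros_like(X)
        run = run_pcnn(stimulus, self._params())
        selected, idx = select_segment_iteration(run)
        mask = normalize_mask_polarity(selected)
        self.run_ = run
        self.selected_iteration_ = idx + 1
        self.mask_ = mask
        self.contour_ = extract_initial_contour(mask, self.min_area, self.n_points)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).mask_
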