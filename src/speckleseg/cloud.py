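"""Cloud-model differential evolution refinement of the active contour.

The normal cloud model represents a fuzzy-stochastic concept by three
digital characteristics: the expectation Ex (centre), the entropy En > 0
(dispersion of the drops) and the hyper-entropy He >= 0 (dispersion of the
dispersion). The forward normal cloud generator draws, per drop,

    En' ~ N(En, He^2)  (resampled until > 0),
    x   ~ N(Ex, En'^2),
    mu  = exp(-(x - Ex)^2 / (2 En'^2)).

The optimizer is DE/rand/1/bin over per-point radial displacements of the
contour along its outward normals, with an additive cloud perturbation of
every trial coordinate whose entropy anneals linearly from ``en_init`` to
``en_final`` over the generations (broad fuzzy exploration early, nearly
deterministic exploitation late). Fitness is the discrete Snake energy, so
the refinement and the classical Snake minimize the same objective; greedy
selection makes the best-so-far energy non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .contours import as_contour, outward_normals
from .exceptions import ConfigurationError
from .snake import (SegmentationResult, SnakeParams, contour_to_mask,
                    edge_potential, internal_energy, sample_bilinear)

__all__ = [
    "CloudParams",
    "CloudDrops",
    "DEConfig",
    "normal_cloud_generator",
    "entropy_schedule",
    "cloud_de_generation",
    "cloud_de_minimize",
    "optimize_contour",
    "CloudACMSegmenter",
]


@dataclass
class CloudParams:
    """Digital characteristics (Ex, En, He) of a normal cloud."""

    ex: float = 0.0
    en: float = 1.0
    he: float = 0.0

    def __post_init__(self) -> None:
        if self.en <= 0:
            raise ConfigurationError("entropy En must be > 0")
        if self.he < 0:
            raise ConfigurationError("hyper-entropy He must be >= 0")


@dataclass
class CloudDrops:
    """Cloud-drop samples and their membership degrees."""

    x: np.ndarray
    mu: np.ndarray


@dataclass
class DEConfig:
    """Differential-evolution controls for the contour refinement.

    en_init / en_final: entropy schedule of the cloud perturbation, in
    pixels of radial displacement; he_frac sets He = he_frac * En.
    """

    pop_size: int = 30
    generations: int = 150
    f_scale: float = 0.5
    # cr = 1 keeps trials inside the smooth span of the population: on
    # closed-contour genomes coordinate-wise mixing creates kinks that the
    # elasticity energy rejects wholesale
    cr: float = 1.0
    en_init: float = 3.0
    en_final: float = 0.3
    he_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigurationError("DE needs pop_size >= 4 (3 donors + target)")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if not 0.0 < self.f_scale <= 2.0:
            raise ConfigurationError("f_scale must lie in (0, 2]")
        if not 0.0 <= self.cr <= 1.0:
            raise ConfigurationError("cr must lie in [0, 1]")
        if not self.en_init >= self.en_final > 0:
            raise ConfigurationError("require en_init >= en_final > 0")
        if self.he_frac < 0:
            raise ConfigurationError("he_frac must be >= 0")


def normal_cloud_generator(params: CloudParams, n: int, seed) -> CloudDrops:
    """Forward normal cloud generator: n drops with membership degrees.

    ``seed`` may be an int or a ``numpy.random.Generator``. He = 0 reduces
    to plain Gaussian sampling around Ex with scale En (all mu from the
    fixed-width membership function).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if params.he == 0:
        en_prime = np.full(n, params.en)
    else:
        en_prime = rng.normal(params.en, params.he, size=n)
        while np.any(en_prime <= 0):
            bad = en_prime <= 0
            en_prime[bad] = rng.normal(params.en, params.he, size=int(bad.sum()))
    x = rng.normal(params.ex, en_prime)
    dev2 = np.square(x - params.ex)
    en2 = np.square(en_prime)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(en2 > 0, np.exp(-dev2 / (2.0 * en2)),
                      (dev2 == 0).astype(float))  # en'^2 underflow: point mass at Ex
    return CloudDrops(x=x, mu=mu)


def entropy_schedule(config: DEConfig, stage: int) -> float:
    """Linear anneal of En from en_init (stage 0) to en_final (last stage)."""
    if config.generations == 1:
        return config.en_final
    t = min(max(stage, 0), config.generations - 1) / (config.generations - 1)
    return config.en_init + (config.en_final - config.en_init) * t


def cloud_de_generation(population, fitness, objective, config: DEConfig, stage: int,
                        rng_de: np.random.Generator, rng_cloud: np.random.Generator,
                        bounds=None, perturb_smooth: float | None = None):
    """One DE/rand/1/bin generation with cloud perturbation and greedy selection.

    For each target i a trial t = a + F (b - c) is built from three distinct
    donors, crossed over binomially at rate ``cr`` with one forced
    coordinate, then every trial coordinate receives an additive drop from
    a normal cloud (Ex = 0, He = he_frac * En) whose entropy couples the
    generation to the individual's fitness rank:
    En_i = En(stage) * (1/4 + 3/4 * rank_i / (pop - 1)), so the entropy
    anneals over generations while, within a generation, fit individuals
    are perturbed gently (exploitation) and poor ones broadly
    (exploration). The trial replaces the target iff its fitness is no
    worse, so the best individual always survives. Mutation/crossover draws
    come from ``rng_de`` and cloud draws from ``rng_cloud``, so the operator
    degenerates to classical DE as En -> 0 under a shared ``rng_de``.

    ``perturb_smooth`` (in coordinates) circularly smooths the drop vector
    and rescales it back to the scheduled entropy. For genomes that encode
    closed contours this turns the perturbation into a shape deformation
    instead of point-wise jitter, which the internal smoothness energy would
    otherwise always reject; leave ``None`` for unstructured problems.

    Returns ``(new_population, new_fitness)``.
    """
    pop = np.asarray(population, dtype=float)
    fit = np.asarray(fitness, dtype=float).copy()
    s, d = pop.shape
    if len(fit) != s:
        raise ConfigurationError("population and fitness sizes differ")
    if s < 4:
        raise ConfigurationError("DE needs pop_size >= 4")
    en = entropy_schedule(config, stage)
    # two-dimensional cloud coupling: the entropy seen by an individual
    # depends on the generation (annealed en) and on its fitness rank --
    # fit individuals receive small, exploitative drops, poor ones large,
    # explorative ones
    ranks = np.empty(s, dtype=float)
    ranks[np.argsort(fit)] = np.arange(s)
    rank_factor = 0.25 + 0.75 * ranks / max(s - 1, 1)
    new_pop = pop.copy()
    for i in range(s):
        candidates = np.delete(np.arange(s), i)
        a, b, c = pop[rng_de.choice(candidates, size=3, replace=False)]
        mutant = a + config.f_scale * (b - c)
        cross = rng_de.random(d) < config.cr
        cross[rng_de.integers(d)] = True
        trial = np.where(cross, mutant, pop[i])
        en_i = en * rank_factor[i]
        cloud = CloudParams(ex=0.0, en=en_i, he=config.he_frac * en_i)
        drops = normal_cloud_generator(cloud, d, rng_cloud).x
        if perturb_smooth is not None:
            drops = ndimage.gaussian_filter1d(drops, perturb_smooth, mode="wrap")
            scale = float(np.std(drops))
            if scale > 0:
                drops *= en_i / scale
        trial = trial + drops
        if bounds is not None:
            trial = np.clip(trial, bounds[0], bounds[1])
        trial_fit = float(objective(trial))
        if trial_fit <= fit[i]:
            new_pop[i] = trial
            fit[i] = trial_fit
    return new_pop, fit


def cloud_de_minimize(objective, init_population, config: DEConfig, bounds=None,
                      perturb_smooth: float | None = None):
    """Run the full cloud-DE loop from an initial population.

    Returns ``(best_x, best_f, trace)`` where ``trace`` is a dict of
    per-generation ``best_energy`` and ``mean_energy`` arrays.
    """
    pop = np.asarray(init_population, dtype=float)
    seq = np.random.SeedSequence(config.seed).spawn(2)
    rng_de = np.random.default_rng(seq[0])
    rng_cloud = np.random.default_rng(seq[1])
    fit = np.array([float(objective(x)) for x in pop])
    best_trace, mean_trace = [], []
    for stage in range(config.generations):
        pop, fit = cloud_de_generation(pop, fit, objective, config, stage,
                                       rng_de, rng_cloud, bounds=bounds,
                                       perturb_smooth=perturb_smooth)
        best_trace.append(float(fit.min()))
        mean_trace.append(float(fit.mean()))
    best = int(np.argmin(fit))
    trace = {"generation": np.arange(1, config.generations + 1),
             "best_energy": np.asarray(best_trace),
             "mean_energy": np.asarray(mean_trace)}
    return pop[best], float(fit[best]), trace


def optimize_contour(init, image, snake_params: SnakeParams | None = None,
                     config: DEConfig | None = None,
                     max_displacement: float = 10.0) -> SegmentationResult:
    """Global refinement of a contour by cloud-DE over radial displacements.

    Each individual is a vector of per-point displacements along the initial
    contour's outward normals (clamped to +/- ``max_displacement`` px), which
    keeps candidate contours closed and ordered by construction. Fitness is
    the discrete Snake energy on ``image``. The zero-displacement individual
    is always included, so with greedy selection the final energy never
    exceeds the initial contour's energy.
    """
    if snake_params is None:
        snake_params = SnakeParams()
    if config is None:
        config = DEConfig()
    image = np.asarray(image, dtype=float)
    pts0 = as_contour(init)
    normals = outward_normals(pts0)
    potential, _ = edge_potential(image, snake_params.edge_sigma)

    def decode(disp: np.ndarray) -> np.ndarray:
        pts = pts0 + disp[:, None] * normals
        pts[:, 0] = np.clip(pts[:, 0], 0.0, image.shape[0] - 1.0)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, image.shape[1] - 1.0)
        return pts

    def objective(disp: np.ndarray) -> float:
        pts = decode(disp)
        ext = float(np.sum(sample_bilinear(potential, pts)))
        return internal_energy(pts, snake_params.alpha, snake_params.beta) \
            + snake_params.kappa * ext

    n = len(pts0)
    seq = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng_init = np.random.default_rng(seq)
    cloud0 = CloudParams(ex=0.0, en=config.en_init, he=config.he_frac * config.en_init)

    def smooth_individual() -> np.ndarray:
        # circularly smoothed cloud drops: candidate contours start smooth,
        # and DE recombination keeps the population in that smooth span
        drops = normal_cloud_generator(cloud0, n, rng_init).x
        disp = ndimage.gaussian_filter1d(drops, sigma=max(n / 20.0, 1.0), mode="wrap")
        scale = np.std(disp)
        if scale > 0:
            disp *= config.en_init / (3.0 * scale) * rng_init.uniform(0.5, 3.0)
        return np.clip(disp, -max_displacement, max_displacement)

    pop = np.stack([np.zeros(n)] + [smooth_individual()
                                    for _ in range(config.pop_size - 1)])
    best_disp, best_fit, trace = cloud_de_minimize(
        objective, pop, config, bounds=(-max_displacement, max_displacement),
        perturb_smooth=max(n / 20.0, 1.0))
    contour = decode(best_disp)
    return SegmentationResult(contour=contour, mask=contour_to_mask(contour, image.shape),
                              trace=trace, converged=True, energy=best_fit)


class CloudACMSegmenter(BaseEstimator):
    """Cloud-model ACM: short Snake descent, then cloud-DE refinement.

    ``fit(image, init_contour=...)`` runs ``pre_evolve_iters`` iterations of
    the semi-implicit Snake from the initial contour (a cheap local descent
    toward the edges), then the global cloud-DE refinement of the result,
    then ``polish_iters`` further Snake iterations so that a basin located
    by the DE is descended to its floor. Set ``pre_evolve_iters=0`` for the
    pure-DE ablation. Fitted attributes: ``contour_``, ``mask_``,
    ``trace_``, ``energy_``.
    """

    def __init__(self, alpha=0.1, beta=0.05, gamma=1.0, kappa=2.0, edge_sigma=2.0,
                 pre_evolve_iters=50, polish_iters=50, pop_size=30, generations=150,
                 f_scale=0.5, cr=1.0, en_init=3.0, en_final=0.3, he_frac=0.1,
                 max_displacement=10.0, seed=0):
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.kappa = kappa
        self.edge_sigma = edge_sigma
        self.pre_evolve_iters = pre_evolve_iters
        self.polish_iters = polish_iters
        self.pop_size = pop_size
        self.generations = generations
        self.f_scale = f_scale
        self.cr = cr
        self.en_init = en_init
        self.en_final = en_final
        self.he_frac = he_frac
        self.max_displacement = max_displacement
        self.seed = seed

    def _snake_params(self) -> SnakeParams:
        return SnakeParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                           kappa=self.kappa, edge_sigma=self.edge_sigma,
                           max_iter=self.pre_evolve_iters)

    def _config(self) -> DEConfig:
        return DEConfig(pop_size=self.pop_size, generations=self.generations,
                        f_scale=self.f_scale, cr=self.cr, en_init=self.en_init,
                        en_final=self.en_final, he_frac=self.he_frac, seed=self.seed)

    def fit(self, X, y=None, init_contour=None):
        from .snake import contour_to_mask, evolve_snake, snake_energy

        if init_contour is None:
            raise ConfigurationError("CloudACMSegmenter requires init_contour")
        contour = as_contour(init_contour)
        if self.pre_evolve_iters > 0:
            contour = evolve_snake(contour, X, self._snake_params()).contour
        result = optimize_contour(contour, X, self._snake_params(), self._config(),
                                  max_displacement=self.max_displacement)
        contour, energy = result.contour, result.energy
        if self.polish_iters > 0:
            params = self._snake_params()
            params.max_iter = self.polish_iters
            polished = evolve_snake(contour, X, params)
            # keep the polish only if it does not degrade the shared objective
            if polished.energy <= energy:
                contour, energy = polished.contour, polished.energy
        self.contour_ = contour
        self.mask_ = contour_to_mask(contour, np.asarray(X).shape)
        self.trace_ = result.trace
        self.energy_ = energy
        return self

    def fit_predict(self, X, y=None, init_contour=None):
        return self.fit(X, init_contour=init_contour).mask_
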