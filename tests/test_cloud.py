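"""Normal cloud generator and cloud-model differential evolution."""

import numpy as np
import pytest
from scipy import stats

from speckleseg.cloud import (CloudACMSegmenter, CloudParams, DEConfig,
                              cloud_de_generation, cloud_de_minimize,
                              entropy_schedule, normal_cloud_generator,
                              optimize_contour)
from speckleseg.contours import contour_centroid
from speckleseg.exceptions import ConfigurationError
from speckleseg.pcnn import extract_initial_contour
from speckleseg.snake import SnakeParams, snake_energy


def sphere(x):
    return float(np.sum(np.square(x)))


def classical_de_generation(pop, fit, objective, f_scale, cr, rng_de):
    """Plain DE/rand/1/bin oracle mirroring the implementation's rng_de
    draw protocol (no cloud perturbation)."""
    s, d = pop.shape
    new_pop, fit = pop.copy(), fit.copy()
    for i in range(s):
        candidates = np.delete(np.arange(s), i)
        a, b, c = pop[rng_de.choice(candidates, size=3, replace=False)]
        mutant = a + f_scale * (b - c)
        cross = rng_de.random(d) < cr
        cross[rng_de.integers(d)] = True
        trial = np.where(cross, mutant, pop[i])
        trial_fit = float(objective(trial))
        if trial_fit <= fit[i]:
            new_pop[i] = trial
            fit[i] = trial_fit
    return new_pop, fit


class TestNormalCloudGenerator:
    def test_membership_formula_and_peak(self):
        drops = normal_cloud_generator(CloudParams(ex=2.0, en=1.0, he=0.0), 50, seed=0)
        exact = np.exp(-((drops.x - 2.0) ** 2) / 2.0)
        np.testing.assert_allclose(drops.mu, exact, rtol=1e-12)
        assert np.all((drops.mu >= 0) & (drops.mu <= 1))
        # a drop landing exactly at Ex has membership 1
        assert np.exp(-((2.0 - 2.0) ** 2) / 2.0) == 1.0

    def test_he_zero_moments(self):
        drops = normal_cloud_generator(CloudParams(ex=0.0, en=1.0, he=0.0),
                                       100_000, seed=3)
        assert np.std(drops.x) == pytest.approx(1.0, rel=0.02)

    def test_he_zero_is_gaussian_ks(self):
        drops = normal_cloud_generator(CloudParams(ex=0.5, en=2.0, he=0.0),
                                       20_000, seed=4)
        res = stats.kstest(drops.x, stats.norm(loc=0.5, scale=2.0).cdf)
        assert res.pvalue > 0.01

    def test_reference_settings_statistics(self):
        # Ex = 0, En = 1, He = 0.04: drops concentrate within three widened
        # standard deviations and centre on the expectation
        drops = normal_cloud_generator(CloudParams(ex=0.0, en=1.0, he=0.04),
                                       100_000, seed=5)
        assert abs(np.mean(drops.x)) < 0.02
        within = np.mean(np.abs(drops.x) <= 3 * (1.0 + 4 * 0.04))
        assert within >= 0.995

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            CloudParams(en=0.0)
        with pytest.raises(ConfigurationError):
            CloudParams(en=1.0, he=-0.1)


class TestEntropySchedule:
    def test_linear_endpoints(self):
        cfg = DEConfig(en_init=3.0, en_final=0.3, generations=10)
        assert entropy_schedule(cfg, 0) == pytest.approx(3.0)
        assert entropy_schedule(cfg, 9) == pytest.approx(0.3)
        assert entropy_schedule(cfg, 4) == pytest.approx(3.0 + (0.3 - 3.0) * 4 / 9)


class TestCloudDE:
    def test_pop_size_validation(self):
        with pytest.raises(ConfigurationError):
            DEConfig(pop_size=3)

    def test_best_so_far_nonincreasing(self, rng):
        cfg = DEConfig(pop_size=12, generations=40, en_init=0.5, en_final=0.01,
                       seed=0)
        pop = rng.uniform(-3, 3, (12, 6))
        _, _, trace = cloud_de_minimize(sphere, pop, cfg)
        best = trace["best_energy"]
        assert all(b <= a + 1e-15 for a, b in zip(best, best[1:]))

    def test_greedy_selection_never_worsens_slots(self, rng):
        cfg = DEConfig(pop_size=8, generations=1, en_init=0.5, en_final=0.1,
                       seed=1)
        seq = np.random.SeedSequence(1).spawn(2)
        rng_de = np.random.default_rng(seq[0])
        rng_cloud = np.random.default_rng(seq[1])
        pop = rng.uniform(-2, 2, (8, 5))
        fit = np.array([sphere(x) for x in pop])
        _, new_fit = cloud_de_generation(pop, fit, sphere, cfg, 0, rng_de, rng_cloud)
        assert np.all(new_fit <= fit + 1e-15)

    def test_degenerates_to_classical_de(self, rng):
        # En -> 0 with shared rng_de protocol: trials identical to plain DE
        cfg = DEConfig(pop_size=10, generations=6, f_scale=0.5, cr=0.9,
                       en_init=1e-300, en_final=1e-301, he_frac=0.0, seed=7)
        seq = np.random.SeedSequence(7).spawn(2)
        rng_de = np.random.default_rng(seq[0])
        rng_cloud = np.random.default_rng(seq[1])
        rng_oracle = np.random.default_rng(seq[0])
        pop = rng.normal(0, 1, (10, 6))
        fit = np.array([sphere(x) for x in pop])
        p1, f1 = pop.copy(), fit.copy()
        p2, f2 = pop.copy(), fit.copy()
        for stage in range(cfg.generations):
            p1, f1 = cloud_de_generation(p1, f1, sphere, cfg, stage, rng_de, rng_cloud)
            p2, f2 = classical_de_generation(p2, f2, sphere, 0.5, 0.9, rng_oracle)
        assert np.max(np.abs(p1 - p2)) < 1e-12

    def test_sphere_benchmark_small(self):
        # quick version of the known-optimum benchmark
        hits = 0
        for seed in range(10):
            cfg = DEConfig(pop_size=30, generations=200, f_scale=0.5, cr=0.9,
                           en_init=0.05, en_final=1e-6, he_frac=0.1, seed=seed)
            pop = np.random.default_rng(seed + 1000).uniform(-5, 5, (30, 10))
            _, best, _ = cloud_de_minimize(sphere, pop, cfg)
            hits += best < 1e-3
        assert hits >= 9


class TestOptimizeContour:
    def test_final_energy_never_exceeds_init(self, clean_phantom):
        init = extract_initial_contour(clean_phantom.truth_mask, 50, 100)
        params = SnakeParams()
        cfg = DEConfig(pop_size=8, generations=20, seed=0)
        res = optimize_contour(init, clean_phantom.clean, params, cfg)
        assert res.energy <= snake_energy(init, clean_phantom.clean, params) + 1e-9

    def test_dilated_disc_recovers_boundary(self, disc_phantom):
        truth_c = extract_initial_contour(disc_phantom.truth_mask, 50, 100)
        cen = contour_centroid(truth_c)
        r_truth = np.linalg.norm(truth_c - cen, axis=1).mean()
        init = cen + (truth_c - cen) * (1 + 5.0 / 20.0)  # dilate 5 px
        res = optimize_contour(init, disc_phantom.clean, SnakeParams(),
                               DEConfig(seed=0))
        radii = np.linalg.norm(res.contour - cen, axis=1)
        assert np.mean(np.abs(radii - r_truth)) < 1.0

    def test_deterministic_under_seed(self, disc_phantom):
        init = extract_initial_contour(disc_phantom.truth_mask, 50, 100)
        cfg = DEConfig(pop_size=8, generations=15, seed=42)
        a = optimize_contour(init, disc_phantom.clean, SnakeParams(), cfg)
        b = optimize_contour(init, disc_phantom.clean, SnakeParams(), cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.contour, b.contour)


class TestCloudACMSegmenterEstimator:
    def test_requires_init_contour(self, clean_phantom):
        with pytest.raises(ConfigurationError):
            CloudACMSegmenter().fit(clean_phantom.clean)

    def test_fit_sets_attributes(self, clean_phantom):
        from speckleseg.metrics import dice
        init = extract_initial_contour(clean_phantom.truth_mask, 50, 100)
        seg = CloudACMSegmenter(pop_size=8, generations=10, seed=0)
        seg.fit(clean_phantom.clean, init_contour=init)
        assert seg.mask_.shape == clean_phantom.clean.shape
        assert dice(seg.mask_, clean_phantom.truth_mask) >= 0.9
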