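"""Snake energetics and semi-implicit evolution."""

import math

import numpy as np
import pytest

from speckleseg.contours import resample_closed
from speckleseg.exceptions import ConfigurationError
from speckleseg.metrics import dice
from speckleseg.pcnn import PCNNSegmenter, extract_initial_contour
from speckleseg.snake import (SnakeParams, SnakeSegmenter, contour_to_mask,
                              edge_potential, evolve_snake, internal_energy,
                              internal_matrix, sample_bilinear, snake_energy)


def circle_contour(radius, center=(32.0, 32.0), n=100):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(t),
                            center[1] + radius * np.cos(t)])


class TestInternalEnergy:
    def test_square_elastic_energy(self):
        # regular 4-gon on the unit circle: chords sqrt(2), 1/2*1*4*2 = 4
        square = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        assert internal_energy(square, alpha=1.0, beta=0.0) == pytest.approx(4.0)

    def test_collinear_points_have_zero_rigidity(self):
        # closed contour with a long straight run: interior second
        # differences vanish there
        pts = np.column_stack([np.zeros(8), np.arange(8, dtype=float)])
        pts = np.vstack([pts, [[1.0, 3.5]]])
        e_straight = internal_energy(pts, alpha=0.0, beta=1.0)
        d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
        interior = 0.5 * np.sum(d2[2:6] ** 2)
        assert interior == pytest.approx(0.0, abs=1e-12)
        assert e_straight > 0  # the closing corner still bends

    def test_translation_invariance(self, rng):
        pts = circle_contour(10) + rng.normal(0, 0.1, (100, 2))
        shifted = pts + np.array([5.0, 7.0])
        assert internal_energy(pts, 0.3, 0.7) == \
            pytest.approx(internal_energy(shifted, 0.3, 0.7), rel=1e-12)


class TestEdgePotential:
    def test_constant_image_gives_zero_field(self):
        pot, force = edge_potential(np.full((32, 32), 0.5))
        np.testing.assert_array_equal(pot, 0.0)
        np.testing.assert_array_equal(force, 0.0)

    def test_step_edge_minimum_on_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        pot, _ = edge_potential(img, edge_sigma=2.0)
        col = int(np.argmin(pot[16]))
        assert abs(col - 15.5) <= 1.5

    def test_force_points_toward_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        _, force = edge_potential(img, edge_sigma=2.0)
        fc = sample_bilinear(force[1], np.array([[16.0, 11.0]]))
        assert fc[0] > 0  # pull in +col direction, toward the edge


class TestSnakeEnergy:
    def test_reduces_to_internal_on_constant_image(self):
        img = np.full((64, 64), 0.3)
        pts = circle_contour(15)
        params = SnakeParams(beta=0.0)
        assert snake_energy(pts, img, params) == \
            pytest.approx(internal_energy(pts, params.alpha, 0.0))

    def test_shrinking_circle_decreases_energy(self):
        img = np.full((64, 64), 0.3)
        assert snake_energy(circle_contour(10), img) < \
            snake_energy(circle_contour(20), img)

    def test_kappa_zero_image_independent(self, rng):
        pts = circle_contour(12)
        params = SnakeParams(kappa=0.0)
        e1 = snake_energy(pts, rng.uniform(0, 1, (64, 64)), params)
        e2 = snake_energy(pts, rng.uniform(0, 1, (64, 64)), params)
        assert e1 == pytest.approx(e2)


class TestInternalMatrix:
    def test_stencil_and_structure(self):
        A = internal_matrix(8, alpha=0.2, beta=0.1)
        np.testing.assert_allclose(A, A.T, atol=1e-14)
        np.testing.assert_allclose(A.sum(axis=1), 0.0, atol=1e-12)
        assert A[0, 0] == pytest.approx(2 * 0.2 + 6 * 0.1)
        assert A[0, 1] == pytest.approx(-(0.2 + 4 * 0.1))
        assert A[0, 2] == pytest.approx(0.1)

    def test_stacked_and_separate_solves_agree(self, rng):
        # x and y share one matrix and are solved independently
        A = internal_matrix(50, 0.1, 0.05) + np.eye(50)
        rhs = rng.normal(0, 1, (50, 2))
        stacked = np.linalg.solve(A, rhs)
        separate = np.column_stack([np.linalg.solve(A, rhs[:, 0]),
                                    np.linalg.solve(A, rhs[:, 1])])
        np.testing.assert_allclose(stacked, separate, atol=1e-12)


class TestEvolveSnake:
    def test_circle_shrinks_monotonically_without_edges(self):
        img = np.full((64, 64), 0.5)
        params = SnakeParams(alpha=0.1, beta=0.0, kappa=0.0, tol=1e-12,
                             max_iter=1, resample_every=1000)
        pts = circle_contour(20)
        radii = [20.0]
        for _ in range(30):
            pts = evolve_snake(pts, img, params).contour
            radii.append(float(np.linalg.norm(pts - (32, 32), axis=1).mean()))
        assert all(b < a for a, b in zip(radii, radii[1:]))

    def test_internal_energy_nonincreasing_without_edges(self):
        img = np.full((64, 64), 0.5)
        params = SnakeParams(kappa=0.0, tol=1e-12, max_iter=60,
                             resample_every=1000)
        res = evolve_snake(circle_contour(20), img, params)
        energies = res.trace.internal
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_semi_implicit_matches_explicit_euler_small_step(self, rng):
        # explicit-integrator oracle in the small-coefficient limit
        img = np.full((64, 64), 0.5)
        alpha, beta = 1e-5, 1e-5
        pts = circle_contour(15) + rng.normal(0, 0.3, (100, 2))
        params = SnakeParams(alpha=alpha, beta=beta, gamma=1.0, kappa=0.0,
                             tol=1e-15, max_iter=1, resample_every=1000)
        semi = evolve_snake(pts, img, params).contour
        A = internal_matrix(100, alpha, beta)
        explicit = pts - (A @ pts)
        assert np.max(np.abs(semi - explicit)) < 1e-6

    def test_converged_contour_satisfies_euler_lagrange(self, clean_phantom):
        img = clean_phantom.clean
        init = extract_initial_contour(clean_phantom.truth_mask, 50, 100)
        params = SnakeParams()
        res = evolve_snake(init, img, params)
        assert res.converged
        A = internal_matrix(len(res.contour), params.alpha, params.beta)
        _, force = edge_potential(img, params.edge_sigma)
        fr = sample_bilinear(force[0], res.contour)
        fc = sample_bilinear(force[1], res.contour)
        res_r = np.abs(A @ res.contour[:, 0] - params.kappa * fr)
        res_c = np.abs(A @ res.contour[:, 1] - params.kappa * fc)
        assert res_r.mean() < 10 * params.tol
        assert res_c.mean() < 10 * params.tol

    def test_trace_lengths_match_iterations(self, clean_phantom):
        init = extract_initial_contour(clean_phantom.truth_mask, 50, 100)
        res = evolve_snake(init, clean_phantom.clean, SnakeParams(max_iter=7,
                                                                  tol=1e-12))
        assert len(res.trace) == len(res.trace.mean_disp) == 7

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            SnakeParams(alpha=0.0, beta=0.0, kappa=0.0)

    def test_noise_free_phantom_end_to_end(self, clean_phantom):
        seg = PCNNSegmenter().fit(clean_phantom.clean)
        res = evolve_snake(seg.contour_, clean_phantom.clean, SnakeParams())
        assert dice(res.mask, clean_phantom.truth_mask) >= 0.93


class TestContourToMask:
    def test_square_area(self):
        square = np.array([[10.0, 10.0], [10.0, 40.0], [40.0, 40.0], [40.0, 10.0]])
        mask = contour_to_mask(square, (64, 64))
        assert abs(int(mask.sum()) - 900) <= 2 * (4 * 30)  # within a 1-px ring

    def test_degenerate_contour_empty(self):
        line = np.array([[5.0, 5.0], [5.0, 10.0], [5.0, 5.0], [5.0, 10.0]])
        assert contour_to_mask(line, (16, 16)).sum() == 0

    def test_disc_round_trip(self):
        rr, cc = np.mgrid[0:64, 0:64]
        mask = (np.hypot(rr - 31.5, cc - 31.5) <= 20).astype(np.uint8)
        contour = extract_initial_contour(mask, min_area=50)
        back = contour_to_mask(contour, (64, 64))
        assert dice(back, mask) >= 0.98


class TestSnakeSegmenterEstimator:
    def test_requires_init_contour(self, clean_phantom):
        with pytest.raises(ConfigurationError):
            SnakeSegmenter().fit(clean_phantom.clean)

    def test_fitted_attributes(self, clean_phantom):
        init = extract_initial_contour(clean_phantom.truth_mask, 50, 100)
        seg = SnakeSegmenter(max_iter=10).fit(clean_phantom.clean,
                                              init_contour=init)
        assert seg.mask_.shape == clean_phantom.clean.shape
        assert seg.contour_.shape == (100, 2)
        assert isinstance(seg.energy_, float)


def test_resample_closed_preserves_shape():
    pts = circle_contour(10, n=37)
    out = resample_closed(pts, 64)
    radii = np.linalg.norm(out - (32, 32), axis=1)
    np.testing.assert_allclose(radii, 10.0, atol=0.1)
    seg_lengths = np.linalg.norm(np.diff(np.vstack([out, out[:1]]), axis=0), axis=1)
    np.testing.assert_allclose(seg_lengths, seg_lengths.mean(), rtol=0.05)
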