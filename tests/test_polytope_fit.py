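"""Geometry oracles (Monte-Carlo hull volume, LP membership), elbow hand
computations, simplex recovery of planted truth, and shuffle-test contracts."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment, linprog

from paretocell import (
    bootstrap_vertices,
    explained_variance_curve,
    find_elbow,
    fit_simplex,
    generate_simplex_cloud,
    hull_volume,
    percent_inside,
    shuffle_test,
    simplex_volume,
    sweep_dimensions,
    t_ratio,
)
from paretocell.polytope_fit import line_statistic

TRIANGLE = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])


class TestFitSimplex:
    def test_vertex_only_data_recovered_exactly(self):
        pts = np.repeat(TRIANGLE, 20, axis=0)
        fit = fit_simplex(pts, 3, seed=0, expand=False)
        cost = np.linalg.norm(TRIANGLE[:, None] - fit.vertices[None], axis=2)
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].max() < 1e-6
        assert fit.sse < 1e-8

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            fit_simplex(TRIANGLE, 1)

    def test_degenerate_rank_reported(self):
        line = np.outer(np.linspace(0, 1, 30), [1.0, 2.0])
        with pytest.raises(ValueError, match="rank"):
            fit_simplex(line, 3)

    def test_planted_triangle_recovered_within_five_percent(self):
        from paretocell import estimate_archetypes

        diam = 4 * np.sqrt(2)
        pts, _ = generate_simplex_cloud(1000, TRIANGLE, noise_sigma=0.2, seed=3)
        verts = estimate_archetypes(pts, 3, seed=0)
        cost = np.linalg.norm(TRIANGLE[:, None] - verts[None], axis=2)
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].mean() < 0.05 * diam

    def test_loss_not_worse_than_initialization(self):
        pts, _ = generate_simplex_cloud(300, TRIANGLE, noise_sigma=0.3, seed=1)
        fit = fit_simplex(pts, 3, seed=0, expand=False)
        # EV from returned weights must reproduce 1 - SSE/SST
        resid = pts - fit.weights @ fit.vertices_raw
        sse = (resid**2).sum()
        assert sse == pytest.approx(fit.sse, rel=1e-8)
        assert fit.explained_variance == pytest.approx(1 - sse / fit.sst, rel=1e-8)


class TestExplainedVarianceCurve:
    def test_segment_data_explained_by_two_vertices(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(size=(200, 1))
        pts = t @ [[3.0, 1.0]] + rng.normal(0, 1e-3, size=(200, 2))
        ev = explained_variance_curve(pts, range(2, 4), seed=0)
        assert ev[2] > 0.999

    def test_curve_in_unit_interval_and_monotone(self):
        pts, _ = generate_simplex_cloud(300, TRIANGLE, noise_sigma=0.3, seed=2)
        ev = explained_variance_curve(pts, seed=0)
        vals = [ev[k] for k in sorted(ev)]
        assert all(0 <= v <= 1 for v in vals)
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_triangle_gain_concentrated_at_three(self):
        pts2, _ = generate_simplex_cloud(500, TRIANGLE, noise_sigma=0.1, seed=3)
        pts = np.hstack([pts2, np.random.default_rng(0).normal(0, 0.1, (500, 1))])
        ev = explained_variance_curve(pts, range(2, 5), seed=0)
        assert ev[3] - ev[2] > 5 * (ev[4] - ev[3])


class TestFindElbow:
    def test_hand_computed_example(self):
        ev = {2: 0.5, 3: 0.8, 4: 0.9, 5: 0.93, 6: 0.95}
        # chord (2,0.5)-(6,0.95): distances 0.186 (k=3), 0.174 (k=4), 0.092 (k=5)
        assert find_elbow(ev) == 3

    def test_linear_curve_returns_smallest_k(self):
        assert find_elbow({2: 0.2, 3: 0.4, 4: 0.6, 5: 0.8}) == 2

    def test_step_curve(self):
        assert find_elbow({2: 0.1, 3: 0.99, 4: 0.99, 5: 0.99}) == 3

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            find_elbow({2: 0.5, 3: 0.9})


class TestVolumes:
    def test_unit_square_area(self):
        square = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
        assert hull_volume(square) == pytest.approx(1.0)

    def test_unit_three_simplex(self):
        v = np.vstack([np.zeros(3), np.eye(3)])
        assert hull_volume(v) == pytest.approx(1 / 6)
        assert simplex_volume(v) == pytest.approx(1 / 6)

    def test_simplex_volume_triangle_and_degenerate(self):
        assert simplex_volume(np.array([[0, 0], [1, 0], [0, 1.0]])) == pytest.approx(0.5)
        assert simplex_volume(np.array([[0, 0], [1, 1], [2, 2.0]])) == 0.0

    def test_random_tetrahedron_cross_oracle(self):
        v = np.random.default_rng(4).normal(size=(4, 3))
        assert simplex_volume(v) == pytest.approx(hull_volume(v), rel=1e-9)

    @pytest.mark.parametrize("dim", [2, 3, 4])
    def test_hull_volume_matches_monte_carlo(self, dim):
        rng = np.random.default_rng(dim)
        pts = rng.normal(size=(40, dim))
        vol = hull_volume(pts)
        lo, hi = pts.min(0), pts.max(0)
        box = np.prod(hi - lo)
        m = 200_000
        samples = rng.uniform(lo, hi, size=(m, dim))
        # LP-free membership: point in hull iff it is a convex combination;
        # use Delaunay from scipy as an independent membership oracle
        from scipy.spatial import Delaunay

        inside = Delaunay(pts).find_simplex(samples) >= 0
        mc = box * inside.mean()
        assert vol == pytest.approx(mc, rel=0.02)


class TestTRatioAndInside:
    def test_points_at_vertices_give_unit_t_ratio(self):
        pts = np.repeat(TRIANGLE, 10, axis=0)
        assert t_ratio(pts, TRIANGLE) == pytest.approx(1.0)

    def test_half_filled_simplex_below_one(self):
        rng = np.random.default_rng(0)
        w = rng.dirichlet([1, 1, 1], size=500)
        w = w[w[:, 0] > 0.5]  # corner half only
        pts = w @ TRIANGLE
        assert t_ratio(pts, TRIANGLE) < 0.8

    def test_vertices_and_centroid_inside(self):
        assert percent_inside(TRIANGLE, TRIANGLE) == 1.0
        assert percent_inside(TRIANGLE.mean(0, keepdims=True), TRIANGLE) == 1.0

    def test_membership_matches_linear_program_oracle(self):
        rng = np.random.default_rng(1)
        verts = rng.normal(size=(4, 3)) * 3
        pts = rng.normal(size=(60, 3))
        ours = []
        for p in pts:
            ours.append(percent_inside(p[None], verts) == 1.0)
        for p, mine in zip(pts, ours):
            res = linprog(
                c=np.zeros(4),
                A_eq=np.vstack([verts.T, np.ones(4)]),
                b_eq=np.append(p, 1.0),
                bounds=[(0, None)] * 4,
                method="highs",
            )
            assert res.success == mine

    def test_degenerate_simplex_rejected(self):
        flat = np.array([[0, 0], [1, 1], [2, 2.0]])
        with pytest.raises(ValueError):
            percent_inside(np.zeros((1, 2)), flat)


class TestShuffleTest:
    def test_strong_triangle_reaches_minimum_p(self):
        pts, _ = generate_simplex_cloud(1000, TRIANGLE, noise_sigma=0.05, seed=0)
        res = shuffle_test(pts, 3, n_shuffles=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            shuffle_test(TRIANGLE, 3, n_shuffles=0)

    def test_line_statistic_direction(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(-1, 1, size=(300, 1))
        pts = np.hstack([3 * t, 3 * t]) + rng.normal(0, 0.05, size=(300, 2))
        v = np.array([[-3.0, -3.0], [3.0, 3.0]])
        assert line_statistic(pts, v) > 0.99
        res = shuffle_test(pts, 2, n_shuffles=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)


class TestSweepDimensions:
    def test_planted_tetrahedron_found_significant(self):
        v4 = np.vstack([np.zeros(3), 4 * np.eye(3)])
        pts, _ = generate_simplex_cloud(800, v4, noise_sigma=0.15, seed=5)
        scores = np.hstack([pts, np.random.default_rng(0).normal(0, 0.15, (800, 2))])
        fit = sweep_dimensions(scores, "s", dims=(5, 4, 3, 2), n_shuffles=99, seed=2)
        assert fit.significant
        assert fit.n_vertices == 4
        assert len(fit.all_p_values) >= 1

    def test_null_records_all_dimension_pvalues(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(300, 5)) * np.array([3, 2.5, 2, 1.5, 1.0])
        fit = sweep_dimensions(scores, "null", dims=(5, 4, 3, 2), n_shuffles=49, seed=3)
        if not fit.significant:
            assert len(fit.all_p_values) == 4
            # the returned fit is the first sweep record; its fitting space
            # is full-dimensional for the chosen vertex count
            assert fit.all_p_values[0][0] == 5
            if fit.n_vertices >= 3:
                assert fit.dimension == fit.n_vertices - 1
        assert all(0 < p <= 1 for _, _, p in fit.all_p_values)

    def test_dims_cap_vertex_count(self):
        pts, _ = generate_simplex_cloud(300, TRIANGLE, noise_sigma=0.2, seed=7)
        fit = sweep_dimensions(pts, "s", dims=(3, 2), n_shuffles=49, seed=4)
        assert fit.n_vertices <= 3  # d=2 allows at most 3 vertices


class TestBootstrap:
    def test_zero_noise_vertices_have_negligible_covariance(self):
        pts = np.repeat(TRIANGLE, 40, axis=0)
        boots, discarded = bootstrap_vertices(pts, 3, n_boot=30, seed=0)
        assert discarded == 0
        for mean, cov in boots:
            assert np.trace(cov) < 1e-10

    def test_covariance_grows_with_noise(self):
        traces = []
        for sigma in (0.01, 0.1, 0.5):
            pts, _ = generate_simplex_cloud(300, TRIANGLE, noise_sigma=sigma, seed=8)
            boots, _ = bootstrap_vertices(pts, 3, n_boot=30, seed=1)
            traces.append(sum(np.trace(cov) for _, cov in boots))
        assert traces[0] < traces[1] < traces[2]
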