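import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from gafcm import (
    DegenerateClusterError,
    DegeneratePixelError,
    FCMParams,
    compute_cost,
    fcm_run,
    spatial_function,
    spatial_membership,
    update_centers,
    update_memberships,
)
from gafcm.fcm import fitness_burst
from conftest import random_instance


class TestUpdateMemberships:
    def test_coincident_pixel_is_crisp(self):
        u = update_memberships([50.0], [50.0, 200.0], m=2.0)
        assert u[:, 0].tolist() == [1.0, 0.0]

    def test_coincident_tie_goes_to_lowest_cluster(self):
        u = update_memberships([50.0], [50.0, 50.0], m=2.0)
        assert u[:, 0].tolist() == [1.0, 0.0]

    def test_single_cluster_memberships_are_one(self, rng):
        x = rng.uniform(0, 255, 12)
        u = update_memberships(x, [99.0], m=2.0)
        assert np.all(u == 1.0)

    @pytest.mark.parametrize("m", [2.0, 1.5, 3.0])
    def test_matches_scalar_oracle(self, m):
        x = np.array([0.0, 50.0, 200.0, 250.0])
        centers = np.array([50.0, 200.0])
        u = update_memberships(x, centers, m)
        ref = np.array(oracles.memberships_naive(x.tolist(), centers.tolist(), m))
        np.testing.assert_allclose(u, ref, atol=1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            update_memberships([np.nan, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            update_memberships([1.0], [np.inf])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_columns_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        x, centers, m = random_instance(r)
        u = update_memberships(x, centers, m)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(u >= 0) and np.all(u <= 1)


class TestUpdateCenters:
    def test_crisp_memberships_give_arithmetic_mean(self):
        x = [10.0, 20.0, 100.0]
        u = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        c = update_centers(x, u, m=2.0)
        np.testing.assert_allclose(c, [15.0, 100.0])

    @pytest.mark.parametrize("n_clusters", [2, 3, 5])
    def test_uniform_memberships_give_global_mean(self, n_clusters):
        x = [0.0, 100.0]
        u = np.full((n_clusters, 2), 1.0 / n_clusters)
        np.testing.assert_allclose(update_centers(x, u, m=2.0), 50.0)

    def test_matches_scalar_oracle(self):
        x = np.array([0.0, 50.0, 200.0, 250.0])
        u = update_memberships(x, [50.0, 200.0], m=2.0)
        c = update_centers(x, u, m=2.0)
        ref = oracles.centers_naive(x.tolist(), u.tolist(), 2.0)
        np.testing.assert_allclose(c, ref, atol=1e-10)
        assert np.all(c >= x.min()) and np.all(c <= x.max())

    def test_zero_mass_cluster_raises(self):
        u = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateClusterError) as err:
            update_centers([5.0, 6.0], u, m=2.0)
        assert err.value.clusters == (1,)


class TestComputeCost:
    def test_zero_when_pixels_sit_on_their_centers(self):
        x = [0.0, 10.0]
        u = np.eye(2)
        assert compute_cost(x, [0.0, 10.0], u, m=2.0) == 0.0

    def test_matches_double_loop_oracle(self):
        x = np.array([0.0, 50.0, 200.0, 250.0])
        centers = np.array([50.0, 200.0])
        u = update_memberships(x, centers, m=2.0)
        ref = oracles.cost_naive(x.tolist(), centers.tolist(), u.tolist(), 2.0)
        assert compute_cost(x, centers, u, 2.0) == pytest.approx(ref, abs=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_cost([0.0, 1.0], [0.0], np.eye(2), 2.0)


class TestSpatial:
    def test_uniform_field_interior_and_corner(self):
        height, width, C = 5, 5, 2
        u = np.full((C, height * width), 1.0 / C)
        h = spatial_function(u, (height, width), window=3).reshape(C, height, width)
        assert h[0, 2, 2] == pytest.approx(9 / C)
        assert h[0, 0, 0] == pytest.approx(4 / C)
        assert h[0, 0, 2] == pytest.approx(6 / C)

    def test_matches_nested_loop_oracle(self, rng):
        u = rng.dirichlet(np.ones(2), size=9).T.copy()
        h = spatial_function(u, (3, 3), window=3)
        ref = np.array(oracles.spatial_naive(u.tolist(), 3, 3, 3))
        np.testing.assert_allclose(h, ref, atol=1e-10)

    def test_even_window_rejected(self):
        u = np.full((2, 9), 0.5)
        with pytest.raises(ValueError):
            spatial_function(u, (3, 3), window=4)

    def test_p1_q0_is_identity(self, rng):
        u = rng.dirichlet(np.ones(3), size=9).T.copy()
        h = spatial_function(u, (3, 3), window=3)
        np.testing.assert_allclose(spatial_membership(u, h, p=1, q=0), u, atol=1e-12)

    def test_p0_q1_is_normalised_spatial(self, rng):
        u = rng.dirichlet(np.ones(3), size=9).T.copy()
        h = spatial_function(u, (3, 3), window=3)
        np.testing.assert_allclose(
            spatial_membership(u, h, p=0, q=1), h / h.sum(axis=0), atol=1e-12
        )

    def test_p1_q1_matches_oracle(self, rng):
        u = rng.dirichlet(np.ones(2), size=9).T.copy()
        h = spatial_function(u, (3, 3), window=3)
        ref = np.array(oracles.spatial_membership_naive(u.tolist(), h.tolist(), 1.0, 1.0))
        np.testing.assert_allclose(spatial_membership(u, h, 1.0, 1.0), ref, atol=1e-10)

    def test_all_zero_pixel_raises(self):
        u = np.zeros((2, 4))
        h = np.zeros((2, 4))
        with pytest.raises(DegeneratePixelError):
            spatial_membership(u, h, 1.0, 1.0)


class TestFCMRun:
    def test_two_block_image_converges_to_block_levels(self, two_block_image):
        params = FCMParams(n_clusters=2, max_iter=200, tol=0.0)
        res = fcm_run(two_block_image, [80.0, 170.0], params)
        ref = oracles.fcm_fixed_point_naive(
            two_block_image.ravel().tolist(), [80.0, 170.0], 2.0, iterations=500
        )
        np.testing.assert_allclose(np.sort(res.centers), np.sort(ref), atol=1e-6)
        np.testing.assert_allclose(np.sort(res.centers), [20.0, 230.0], atol=1.0)

    def test_infinite_tolerance_stops_after_one_iteration(self, two_block_image):
        params = FCMParams(n_clusters=2, tol=np.inf)
        res = fcm_run(two_block_image, [80.0, 170.0], params)
        assert res.iterations_run == 1
        assert len(res.cost_trace) == 1

    def test_cost_trace_non_increasing(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 255, (6, 6))
            params = FCMParams(n_clusters=3, max_iter=25, tol=0.0)
            res = fcm_run(x, rng.uniform(0, 255, 3), params)
            diffs = np.diff(res.cost_trace)
            assert np.all(diffs <= 1e-9 * max(res.cost_trace[0], 1.0))

    def test_iteration_cap_respected(self, rng):
        x = rng.uniform(0, 255, (5, 5))
        params = FCMParams(n_clusters=2, max_iter=3, tol=0.0)
        assert fcm_run(x, [10.0, 200.0], params).iterations_run <= 3

    def test_permutation_equivariance(self, rng):
        x = rng.uniform(0, 255, 20)
        init = np.array([30.0, 120.0, 220.0])
        params = FCMParams(n_clusters=3, max_iter=10, tol=0.0)
        a = fcm_run(x, init, params)
        b = fcm_run(x, init[::-1].copy(), params)
        np.testing.assert_allclose(a.centers, b.centers[::-1], atol=1e-12)
        np.testing.assert_allclose(a.memberships, b.memberships[::-1], atol=1e-12)

    def test_near_crisp_memberships_as_m_approaches_one(self):
        x = np.array([10.0, 10.0, 240.0, 240.0])
        u = update_memberships(x, [10.0 + 1e-6, 240.0], m=1.01)
        hard = np.argmax(u, axis=0)
        np.testing.assert_array_equal(hard, [0, 0, 1, 1])
        assert np.all(u.max(axis=0) > 0.999)

    def test_spatial_variant_keeps_columns_stochastic(self, rng):
        x = rng.uniform(0, 255, (6, 6))
        params = FCMParams(n_clusters=3, max_iter=8, spatial_enabled=True, window=3)
        res = fcm_run(x, [30.0, 120.0, 230.0], params)
        np.testing.assert_allclose(res.memberships.sum(axis=0), 1.0, atol=1e-9)


class TestFitnessBurst:
    """The fused fitness kernel must agree exactly with the primitive chain."""

    @pytest.mark.parametrize("inner", [1, 2, 3])
    def test_matches_primitive_chain(self, inner):
        r = np.random.default_rng(7)
        for _ in range(30):
            x, centers, m = random_instance(r)
            cost, new_c = fitness_burst(x, centers, m, inner)
            try:
                c = centers.copy()
                u = None
                for _ in range(inner):
                    u = update_memberships(x, c, m)
                    c = update_centers(x, u, m)
                ref = compute_cost(x, c, u, m)
            except DegenerateClusterError:
                assert not np.isfinite(cost)
                continue
            assert cost == pytest.approx(ref, rel=1e-10, abs=1e-10)
            np.testing.assert_allclose(new_c, c, atol=1e-10)

    def test_degenerate_cluster_gives_infinite_cost(self):
        cost, _ = fitness_burst([5.0], [5.0, 200.0], 2.0, 1)
        assert cost == np.inf


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 1.0},
            {"n_clusters": 0},
            {"window": 4},
            {"tol": -1.0},
            {"p": -0.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FCMParams(**kwargs)
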