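"""Fuzzy c-means: update formulas, convergence, and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frpsurv.fcm import (
    FCMConfig,
    FuzzyPartition,
    fcm_fit,
    fcm_objective,
    update_centers,
    update_memberships,
)
from oracles import centers_loop, fcm_loop, memberships_loop


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"c": 0}, {"c": 2, "m": 1.0}, {"c": 2, "m": 0.5},
        {"c": 2, "delta": 0.0}, {"c": 2, "max_iter": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FCMConfig(**kwargs)


class TestFit:
    def test_two_well_separated_pairs(self):
        """Points {0,0,10,10} with c=2 split into centers ~{0,10}, near-one-hot."""
        part = fcm_fit([0.0, 0.0, 10.0, 10.0], FCMConfig(c=2, seed=0))
        assert part.converged
        np.testing.assert_allclose(np.sort(part.centers.ravel()), [0.0, 10.0],
                                   atol=1e-3)
        # centers sorted ascending, so points 0,1 belong to cluster 0
        assert part.memberships[:2, 0].min() > 0.99
        assert part.memberships[2:, 1].min() > 0.99

    def test_single_cluster_degenerate(self, rng):
        pts = rng.normal(size=(9, 3))
        part = fcm_fit(pts, FCMConfig(c=1, seed=0))
        assert np.all(part.memberships == 1.0)
        np.testing.assert_allclose(part.centers[0], pts.mean(axis=0))

    def test_agrees_with_loop_oracle_from_same_init(self):
        """Full fit on 6 scalars matches a literal loop iteration of the
        update formulas to 1e-6 (same initialization, same stopping rule)."""
        pts = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        c, m = 2, 2.0
        U0 = np.random.default_rng(42).dirichlet(np.ones(c), size=6)
        part = fcm_fit(pts, FCMConfig(c=c, m=m, delta=1e-9, max_iter=200), init=U0)
        U_o, V_o, _ = fcm_loop(pts[:, None], c, m, 1e-9, 200, U0)
        order = np.argsort(V_o[:, 0])
        np.testing.assert_allclose(part.centers, V_o[order], atol=1e-6)
        np.testing.assert_allclose(part.memberships, U_o[:, order], atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_loop_oracle_random_instances(self, seed):
        """Randomised <=10-point instances agree with the loop oracle."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 11)
        pts = rng.normal(size=(n, 2))
        c = int(rng.integers(2, 4))
        U0 = rng.dirichlet(np.ones(c), size=n)
        part = fcm_fit(pts, FCMConfig(c=c, delta=1e-8, max_iter=300), init=U0)
        U_o, V_o, _ = fcm_loop(pts, c, 2.0, 1e-8, 300, U0)
        # align oracle clusters to the package's deterministic order
        from frpsurv.fcm import _sort_key
        order = np.argsort(_sort_key(V_o), kind="stable")
        np.testing.assert_allclose(part.centers, V_o[order], atol=1e-6)
        np.testing.assert_allclose(part.memberships, U_o[:, order], atol=1e-6)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            fcm_fit([], FCMConfig(c=2))
        with pytest.raises(ValueError):
            fcm_fit([1.0, 1.0, 1.0], FCMConfig(c=2))  # c > distinct points
        with pytest.raises(ValueError):
            fcm_fit([1.0, np.nan, 2.0], FCMConfig(c=2))

    def test_permuting_points_permutes_membership_rows(self, rng):
        pts = rng.normal(size=(8, 2))
        c = 3
        U0 = rng.dirichlet(np.ones(c), size=8)
        perm = rng.permutation(8)
        cfg = FCMConfig(c=c, delta=1e-9, max_iter=200)
        a = fcm_fit(pts, cfg, init=U0)
        b = fcm_fit(pts[perm], cfg, init=U0[perm])
        np.testing.assert_allclose(b.memberships, a.memberships[perm], atol=1e-9)
        np.testing.assert_allclose(b.centers, a.centers, atol=1e-9)

    def test_c_equals_n_well_separated_gives_near_identity(self):
        pts = np.array([0.0, 10.0, 20.0, 30.0])
        part = fcm_fit(pts, FCMConfig(c=4, seed=1, delta=1e-9, max_iter=500))
        # centers sorted ascending -> membership matrix close to identity
        assert np.abs(part.memberships - np.eye(4)).max() < 0.05

    @pytest.mark.parametrize("seed", range(20))
    def test_row_sums_and_objective_monotone(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(20, 1))
        part = fcm_fit(pts, FCMConfig(c=3, seed=seed))
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)
        trace = part.objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)

    def test_partition_roundtrip(self, rng, tmp_path):
        part = fcm_fit(rng.normal(size=(12, 2)), FCMConfig(c=3, seed=0))
        part.save(tmp_path / "part")
        back = FuzzyPartition.load(tmp_path / "part")
        np.testing.assert_array_equal(back.memberships, part.memberships)
        np.testing.assert_array_equal(back.centers, part.centers)
        assert back.converged == part.converged


class TestUpdateCenters:
    def test_one_hot_gives_cluster_means(self):
        pts = np.array([[0.0], [1.0], [10.0], [12.0]])
        U = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        V = update_centers(pts, U, m=2.0)
        np.testing.assert_allclose(V.ravel(), [0.5, 11.0])

    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_uniform_memberships_give_grand_mean(self, rng, m):
        pts = rng.normal(size=(7, 3))
        U = np.full((7, 2), 0.5)
        V = update_centers(pts, U, m=m)
        np.testing.assert_allclose(V, np.tile(pts.mean(axis=0), (2, 1)))

    def test_matches_loop_formula(self, rng):
        pts = rng.normal(size=(5, 2))
        U = rng.dirichlet(np.ones(3), size=5)
        np.testing.assert_allclose(update_centers(pts, U, 2.0),
                                   centers_loop(pts, U, 2.0), atol=1e-12)

    def test_centers_in_convex_hull_1d(self, rng):
        pts = rng.normal(size=(10, 1))
        U = rng.dirichlet(np.ones(3), size=10)
        V = update_centers(pts, U, 2.0)
        assert (V >= pts.min() - 1e-12).all() and (V <= pts.max() + 1e-12).all()

    def test_zero_mass_cluster_errors(self):
        with pytest.raises(ValueError):
            update_centers([[0.0], [1.0]], np.array([[1.0, 0.0], [1.0, 0.0]]), 2.0)


class TestUpdateMemberships:
    def test_equidistant_point_splits_evenly(self):
        U = update_memberships([[0.0]], [[-1.0], [1.0]], m=2.0)
        np.testing.assert_allclose(U, [[0.5, 0.5]])

    def test_coincident_point_gets_full_membership(self):
        U = update_memberships([[1.0], [5.0]], [[1.0], [3.0]], m=2.0)
        np.testing.assert_allclose(U[0], [1.0, 0.0])
        np.testing.assert_allclose(U.sum(axis=1), 1.0)

    def test_distance_ratio_formula(self):
        """Point at distances (1, 3): mu_1 = 1/(1 + (1/3)^2) = 0.9."""
        U = update_memberships([[0.0]], [[1.0], [3.0]], m=2.0)
        np.testing.assert_allclose(U, [[0.9, 0.1]], atol=1e-12)
        np.testing.assert_allclose(U, memberships_loop([[0.0]], [[1.0], [3.0]], 2.0),
                                   atol=1e-12)

    def test_matches_loop_formula_random(self, rng):
        pts = rng.normal(size=(6, 2))
        V = rng.normal(size=(3, 2))
        np.testing.assert_allclose(update_memberships(pts, V, 2.5),
                                   memberships_loop(pts, V, 2.5), atol=1e-12)

    def test_nearest_center_gets_largest_membership(self, rng):
        pts = rng.normal(size=(10, 2))
        V = rng.normal(size=(4, 2))
        U = update_memberships(pts, V, 2.0)
        d = np.linalg.norm(pts[:, None] - V[None], axis=2)
        np.testing.assert_array_equal(U.argmax(axis=1), d.argmin(axis=1))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 4), st.floats(1.2, 4.0))
def test_membership_rows_always_sum_to_one(seed, c, m):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(rng.integers(c + 1, 15), 2))
    part = fcm_fit(pts, FCMConfig(c=c, m=m, seed=seed))
    np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)
    assert part.memberships.min() >= 0.0 and part.memberships.max() <= 1.0


def test_objective_decreases_under_alternating_updates(rng):
    """One center+membership update pair never increases the objective."""
    pts = rng.normal(size=(15, 2))
    U = rng.dirichlet(np.ones(3), size=15)
    for _ in range(5):
        V = update_centers(pts, U, 2.0)
        U_new = update_memberships(pts, V, 2.0)
        assert fcm_objective(pts, U_new, V, 2.0) <= fcm_objective(pts, U, V, 2.0) + 1e-12
        U = U_new
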