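"""Affine-invariant SPD geometry: closed forms, invariances, mean estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsalign import geometry as geo
from conftest import random_spd

pos = st.floats(min_value=0.05, max_value=20.0, allow_nan=False)


class TestValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            geo.validate_spd(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            geo.validate_spd(np.diag([1.0, -0.5]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            geo.validate_spd(np.diag([1.0, np.inf]))


class TestTrialCovariance:
    def test_orthogonal_unit_power_rows_give_identity(self):
        E = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        assert np.allclose(geo.trial_covariance(E, "plain"), np.eye(2))

    def test_trace_normalized_has_unit_trace(self, rng):
        E = rng.normal(size=(3, 50))
        E -= E.mean(axis=1, keepdims=True)
        C = geo.trial_covariance(E, "trace_normalized")
        assert np.isclose(np.trace(C), 1.0, atol=1e-10)

    def test_plain_matches_per_sample_summation(self, rng):
        E = rng.normal(size=(3, 300))
        E -= E.mean(axis=1, keepdims=True)
        brute = sum(np.outer(E[:, t], E[:, t]) for t in range(300)) / 300
        assert np.allclose(geo.trial_covariance(E, "plain"), brute, atol=1e-12)

    def test_rank_deficient_ridge_and_error(self):
        E = np.zeros((2, 10))
        E[0] = np.linspace(-1, 1, 10)  # rank 1
        C = geo.trial_covariance(E)  # ridge keeps it SPD
        assert np.linalg.eigvalsh(C)[0] > 0
        with pytest.raises(ValueError, match="rank-deficient"):
            geo.trial_covariance(E, ridge=False)


class TestMatrixPower:
    def test_identity_and_zero_power(self, rng):
        C = random_spd(rng)
        assert np.allclose(geo.matrix_power(C, 1.0), C)
        assert np.allclose(geo.matrix_power(C, 0.0), np.eye(3))

    def test_diagonal_square_root(self):
        assert np.allclose(geo.matrix_power(np.diag([4.0, 9.0]), 0.5), np.diag([2.0, 3.0]))

    def test_half_power_squares_back(self, rng):
        C = random_spd(rng)
        S = geo.matrix_power(C, 0.5)
        assert np.allclose(S @ S, C, atol=1e-10)


class TestDistance:
    def test_self_distance_zero(self, rng):
        C = random_spd(rng)
        assert geo.riemannian_distance(C, C) < 1e-12

    def test_log_eigenvalue_closed_form(self):
        assert np.isclose(geo.riemannian_distance(np.eye(3), np.diag([np.e**2, 1, 1])), 2.0)

    @given(a=pos, b=pos, c=pos, d=pos)
    @settings(max_examples=50, deadline=None)
    def test_diagonal_closed_form(self, a, b, c, d):
        expected = np.sqrt(np.log(c / a) ** 2 + np.log(d / b) ** 2)
        assert np.isclose(
            geo.riemannian_distance(np.diag([a, b]), np.diag([c, d])), expected, rtol=1e-9
        )

    def test_congruence_invariance(self, rng):
        for _ in range(100):
            C1, C2 = random_spd(rng), random_spd(rng)
            W = rng.normal(size=(3, 3))
            while abs(np.linalg.det(W)) < 1e-3:
                W = rng.normal(size=(3, 3))
            d1 = geo.riemannian_distance(C1, C2)
            d2 = geo.riemannian_distance(W @ C1 @ W.T, W @ C2 @ W.T)
            assert abs(d1 - d2) < 1e-9 * max(1.0, d1)

    def test_inversion_invariance(self, rng):
        C1, C2 = random_spd(rng), random_spd(rng)
        d = geo.riemannian_distance(C1, C2)
        di = geo.riemannian_distance(np.linalg.inv(C1), np.linalg.inv(C2))
        assert np.isclose(d, di, rtol=1e-9)

    def test_symmetry_in_arguments(self, rng):
        C1, C2 = random_spd(rng), random_spd(rng)
        assert np.isclose(
            geo.riemannian_distance(C1, C2), geo.riemannian_distance(C2, C1), rtol=1e-10
        )

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            geo.riemannian_distance(np.eye(2), np.eye(3))


class TestGeodesic:
    def test_endpoints(self, rng):
        M, C = random_spd(rng), random_spd(rng)
        assert np.allclose(geo.geodesic(M, C, 0.0), M, atol=1e-12)
        assert np.allclose(geo.geodesic(M, C, 1.0), C, atol=1e-10)

    def test_commuting_midpoint_is_geometric_mean(self):
        mid = geo.geodesic(np.diag([1.0, 4.0]), np.diag([4.0, 1.0]), 0.5)
        assert np.allclose(mid, np.diag([2.0, 2.0]), atol=1e-12)

    @pytest.mark.parametrize("t", [0.25, 0.5, 0.75])
    def test_distance_proportionality(self, rng, t):
        M, C = random_spd(rng), random_spd(rng)
        g = geo.geodesic(M, C, t)
        assert np.isclose(
            geo.riemannian_distance(M, g), t * geo.riemannian_distance(M, C), atol=1e-9
        )

    def test_reversal_symmetry(self, rng):
        M, C = random_spd(rng), random_spd(rng)
        for t in (0.2, 0.7):
            assert np.allclose(geo.geodesic(M, C, t), geo.geodesic(C, M, 1 - t), atol=1e-9)

    def test_t_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            geo.geodesic(np.eye(2), np.eye(2), 1.5)


class TestRiemannianMean:
    def test_singleton_and_copies(self, rng):
        C = random_spd(rng)
        assert np.allclose(geo.riemannian_mean([C]), C)
        assert np.allclose(geo.riemannian_mean([C] * 5), C, atol=1e-9)

    def test_two_point_mean_is_geodesic_midpoint(self, rng):
        A, B = np.diag([1.0, 4.0]), np.diag([4.0, 1.0])
        assert np.allclose(geo.riemannian_mean([A, B]), np.diag([2.0, 2.0]), atol=1e-10)
        A, B = random_spd(rng), random_spd(rng)
        assert np.allclose(geo.riemannian_mean([A, B]), geo.geodesic(A, B, 0.5), atol=1e-8)

    def test_commuting_family_geometric_mean(self, rng):
        diags = rng.uniform(0.2, 5.0, size=(7, 3))
        mean = geo.riemannian_mean([np.diag(d) for d in diags])
        expected = np.diag(np.exp(np.log(diags).mean(axis=0)))
        assert np.allclose(mean, expected, atol=1e-10)

    def test_permutation_invariance(self, rng):
        Cs = [random_spd(rng) for _ in range(6)]
        m1 = geo.riemannian_mean(Cs)
        m2 = geo.riemannian_mean(Cs[::-1])
        assert np.allclose(m1, m2, atol=1e-7)

    def test_gradient_norm_at_fixed_point(self, rng):
        Cs = [random_spd(rng) for _ in range(5)]
        M = geo.riemannian_mean(Cs, tol=1e-10)
        isqrt = geo.matrix_power(M, -0.5)
        T = np.mean([geo.logm(isqrt @ C @ isqrt) for C in Cs], axis=0)
        assert np.linalg.norm(T, "fro") <= 1e-10

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            geo.riemannian_mean([])

    def test_nonconvergence_reports_gradient(self, rng):
        Cs = [random_spd(rng) for _ in range(5)]
        with pytest.raises(geo.MeanConvergenceError) as exc:
            geo.riemannian_mean(Cs, tol=1e-16, max_iter=1)
        assert exc.value.gradient_norm > 0


class TestRecursiveMean:
    def test_first_update_is_midpoint(self):
        M2 = geo.recursive_mean_update(np.eye(2), np.diag([4.0, 4.0]), 1)
        assert np.allclose(M2, np.diag([2.0, 2.0]), atol=1e-12)

    def test_commuting_sequence_geometric_mean_by_induction(self, rng):
        diags = rng.uniform(0.2, 5.0, size=(9, 3))
        M = np.diag(diags[0])
        for i, d in enumerate(diags[1:], start=1):
            M = geo.recursive_mean_update(M, np.diag(d), i)
        expected = np.diag(np.exp(np.log(diags).mean(axis=0)))
        assert np.allclose(M, expected, atol=1e-10)

    def test_order_dependence(self, rng):
        Cs = [random_spd(rng) for _ in range(4)]
        def run(seq):
            M = seq[0]
            for i, C in enumerate(seq[1:], start=1):
                M = geo.recursive_mean_update(M, C, i)
            return M
        assert not np.allclose(run(Cs), run(Cs[::-1]), atol=1e-6)

    def test_converges_toward_batch_mean(self, rng):
        # inductive mean over i.i.d. draws approaches the batch Karcher mean
        Cs = [random_spd(rng) for _ in range(500)]
        M = Cs[0]
        snapshots = {}
        for i, C in enumerate(Cs[1:], start=1):
            M = geo.recursive_mean_update(M, C, i)
            if i + 1 in (50, 500):
                snapshots[i + 1] = M
        batch50 = geo.riemannian_mean(Cs[:50], max_iter=200)
        batch500 = geo.riemannian_mean(Cs, max_iter=200)
        d50 = geo.riemannian_distance(snapshots[50], batch50)
        d500 = geo.riemannian_distance(snapshots[500], batch500)
        assert d500 < d50

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError, match="i >= 1"):
            geo.recursive_mean_update(np.eye(2), np.eye(2), 0)
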