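"""Solver: objective pieces, constraints, monotone ascent, reductions."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gakcca import (
    FitConfig,
    GroupData,
    build_gram_set,
    constraint_value,
    empirical_cov,
    fit_gakcca,
    full_design,
    generate_case1,
    objective,
    relation_measure,
)
from gakcca.core import get_scheme, validate_design

from conftest import cca_first_correlation, pearson


def random_group_data(rng, n=25, dims=(2, 3, 2)):
    return GroupData([rng.standard_normal((n, p)) for p in dims])


class TestEmpiricalCov:
    def test_zero_coefficient(self):
        rng = np.random.default_rng(0)
        K = rng.standard_normal((4, 4))
        K = K @ K.T
        a = rng.standard_normal(4)
        assert empirical_cov(np.zeros(4), K, K, a) == 0.0

    def test_self_covariance_nonnegative(self):
        rng = np.random.default_rng(1)
        K = rng.standard_normal((5, 5))
        K = K @ K.T
        a = rng.standard_normal(5)
        v = empirical_cov(a, K, K, a)
        assert v >= 0
        np.testing.assert_allclose(v, np.linalg.norm(K @ a) ** 2 / 5)

    def test_two_step_score_oracle_and_symmetry(self):
        rng = np.random.default_rng(2)
        K1 = rng.standard_normal((4, 4))
        K1 = K1 + K1.T
        K2 = rng.standard_normal((4, 4))
        K2 = K2 + K2.T
        a1, a2 = rng.standard_normal(4), rng.standard_normal(4)
        y1, y2 = K1 @ a1, K2 @ a2
        assert empirical_cov(a1, K1, K2, a2) == pytest.approx(y1 @ y2 / 4)
        assert empirical_cov(a1, K1, K2, a2) == pytest.approx(
            empirical_cov(a2, K2, K1, a1)
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            empirical_cov(np.zeros(3), np.eye(4), np.eye(4), np.zeros(4))


class TestConstraintValue:
    def test_zero_coefficients(self):
        grams = [np.eye(3), np.eye(3)]
        assert constraint_value([np.zeros(3)] * 2, grams, 0.5) == 0.0

    def test_tau_one_reduces_to_norm_term(self):
        rng = np.random.default_rng(3)
        grams = []
        for _ in range(2):
            A = rng.standard_normal((5, 5))
            grams.append(A @ A.T)
        a = [rng.standard_normal(5) for _ in range(2)]
        expected = sum(ai @ K @ ai for ai, K in zip(a, grams))
        assert constraint_value(a, grams, 1.0) == pytest.approx(expected)

    def test_matches_naive_double_sum(self):
        rng = np.random.default_rng(4)
        n, p, tau = 6, 3, 0.3
        grams = []
        for _ in range(p):
            A = rng.standard_normal((n, n))
            grams.append(A @ A.T)
        a = [rng.standard_normal(n) for _ in range(p)]
        naive = 0.0
        for l in range(p):
            for lp in range(p):
                naive += (1 - tau) * (a[l] @ grams[l] @ grams[lp] @ a[lp]) / n
        for l in range(p):
            naive += tau * a[l] @ grams[l] @ a[l]
        assert constraint_value(a, grams, tau) == pytest.approx(naive)

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            constraint_value([np.zeros(3)], [np.eye(3)], 0.0)


class TestObjective:
    @pytest.mark.parametrize("scheme", ["horst", "centroid", "factorial"])
    def test_zero_coefficients(self, scheme):
        data = random_group_data(np.random.default_rng(5), n=10)
        gs = build_gram_set(data)
        coeffs = [[np.zeros(10) for _ in range(p)] for p in gs.dims]
        assert objective(coeffs, gs, full_design(3), scheme) == 0.0

    def test_two_groups_horst_double_counts(self):
        rng = np.random.default_rng(6)
        data = random_group_data(rng, n=12, dims=(2, 2))
        gs = build_gram_set(data)
        coeffs = [[rng.standard_normal(12) for _ in range(2)] for _ in range(2)]
        cov = sum(
            empirical_cov(coeffs[0][l], gs.centered[0][l], gs.centered[1][m], coeffs[1][m])
            for l in range(2)
            for m in range(2)
        )
        assert objective(coeffs, gs, full_design(2), "horst") == pytest.approx(2 * cov)

    def test_factorial_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        data = random_group_data(rng, n=9, dims=(2, 1, 3))
        gs = build_gram_set(data)
        coeffs = [[rng.standard_normal(9) for _ in range(p)] for p in gs.dims]
        C = full_design(3)
        naive = 0.0
        for j in range(3):
            for k in range(3):
                if j == k:
                    continue
                tot = 0.0
                for l in range(gs.dims[j]):
                    for m in range(gs.dims[k]):
                        tot += empirical_cov(
                            coeffs[j][l], gs.centered[j][l], gs.centered[k][m], coeffs[k][m]
                        )
                naive += C[j, k] * tot**2
        assert objective(coeffs, gs, C, "factorial") == pytest.approx(naive)


class TestFit:
    def test_identical_blocks_perfectly_related(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((30, 1))
        data = GroupData([x.copy(), x.copy()])
        for tau in (0.05, 0.5, 1.0):
            fit = fit_gakcca(data, config=FitConfig(tau=tau))
            assert relation_measure(fit, 0, 1) == pytest.approx(1.0, abs=1e-6)

    def test_one_dim_linear_kernel_recovers_pearson(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(40)
        y = 0.6 * x + 0.8 * rng.standard_normal(40)
        data = GroupData([x[:, None], y[:, None]])
        fit = fit_gakcca(data, kernel="linear", config=FitConfig(tau=1e-6))
        got = abs(pearson(fit.group_scores[0], fit.group_scores[1]))
        assert got == pytest.approx(abs(pearson(x, y)), abs=1e-3)

    @pytest.mark.parametrize("scheme", ["horst", "centroid", "factorial"])
    def test_monotone_trace_and_feasible_constraints(self, scheme):
        rng = np.random.default_rng(10)
        for rep in range(5):
            data = random_group_data(rng, n=20)
            gs = build_gram_set(data)
            fit = fit_gakcca(data, scheme=scheme, gram_set=gs, config=FitConfig(tau=0.2))
            assert np.all(np.diff(fit.objective_trace) >= -1e-10)
            for j in range(3):
                cv = constraint_value(fit.coefficients[j], gs.centered[j], 0.2)
                assert cv == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance_of_gaussian_scores(self):
        rng = np.random.default_rng(11)
        data = random_group_data(rng, n=25)
        scaled_blocks = [b.copy() for b in data.blocks]
        scaled_blocks[1][:, 0] *= 37.5
        scaled = GroupData(scaled_blocks)
        f1 = fit_gakcca(data, config=FitConfig(tau=0.3))
        f2 = fit_gakcca(scaled, config=FitConfig(tau=0.3))
        for a, b in zip(f1.group_scores, f2.group_scores):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_linear_kernel_matches_cca_eigen_oracle(self):
        rng = np.random.default_rng(12)
        for rep in range(4):
            n = int(rng.integers(15, 30))
            p1, p2 = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            X = rng.standard_normal((n, p1))
            Y = 0.5 * X[:, [0] * p2] + rng.standard_normal((n, p2))
            data = GroupData([X, Y])
            fit = fit_gakcca(data, kernel="linear", config=FitConfig(tau=1e-6))
            got = abs(pearson(fit.group_scores[0], fit.group_scores[1]))
            assert got == pytest.approx(cca_first_correlation(X, Y), abs=1e-4)

    def test_brute_force_optimizer_equivalence(self):
        # n=6, two univariate groups: direct SLSQP maximization over the
        # two constraint ellipsoids must find the same maximum.
        rng = np.random.default_rng(13)
        n, tau = 6, 0.5
        data = GroupData([rng.standard_normal((n, 1)) for _ in range(2)])
        gs = build_gram_set(data)
        fit = fit_gakcca(data, gram_set=gs, config=FitConfig(tau=tau))

        K1, K2 = gs.centered[0][0], gs.centered[1][0]

        def neg_obj(v):
            a1, a2 = v[:n], v[n:]
            return -2.0 * (K1 @ a1) @ (K2 @ a2) / n

        def con(v, idx, K):
            a = v[idx]
            y = K @ a
            return (1 - tau) * (y @ y) / n + tau * a @ K @ a - 1.0

        cons = [
            {"type": "eq", "fun": con, "args": (slice(0, n), K1)},
            {"type": "eq", "fun": con, "args": (slice(n, 2 * n), K2)},
        ]
        best = -np.inf
        for restart in range(10):
            v0 = rng.standard_normal(2 * n)
            res = minimize(
                neg_obj, v0, method="SLSQP", constraints=cons,
                options={"maxiter": 500, "ftol": 1e-14},
            )
            if res.success:
                best = max(best, -res.fun)
        assert best == pytest.approx(fit.objective, abs=1e-4)

    def test_nonconvergence_flagged_not_raised(self):
        data = random_group_data(np.random.default_rng(14), n=20)
        fit = fit_gakcca(data, config=FitConfig(tau=0.1, max_iter=1, tol=1e-16))
        assert not fit.converged

    def test_random_init_deterministic(self):
        data = random_group_data(np.random.default_rng(15), n=20)
        cfg = FitConfig(tau=0.2, init="random", seed=42)
        f1 = fit_gakcca(data, config=cfg)
        f2 = fit_gakcca(data, config=cfg)
        np.testing.assert_array_equal(f1.group_scores[0], f2.group_scores[0])

    def test_rho_is_per_pair_scale(self):
        data = random_group_data(np.random.default_rng(16), n=20)
        fit = fit_gakcca(data, config=FitConfig(tau=0.2))
        assert fit.rho == pytest.approx(fit.objective / 2)

    def test_invalid_tau_rejected(self):
        data = random_group_data(np.random.default_rng(17), n=10)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                fit_gakcca(data, config=FitConfig(tau=bad))


class TestDesignAndScheme:
    def test_design_validation(self):
        with pytest.raises(ValueError):
            validate_design(np.ones((3, 3)), 3)  # nonzero diagonal
        with pytest.raises(ValueError):
            validate_design(np.zeros((2, 2)), 2)  # no connection
        C = full_design(3)
        np.testing.assert_array_equal(validate_design(C, 3), C)

    def test_scheme_functions(self):
        assert get_scheme("horst").g(-2.0) == -2.0
        assert get_scheme("centroid").g(-2.0) == 2.0
        assert get_scheme("centroid").gprime(0.0) == 0.0
        assert get_scheme("factorial").g(-2.0) == 4.0
        with pytest.raises(ValueError):
            get_scheme("unknown")
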