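"""Unit tests for the GLS core: control covariance, coefficient estimation,
inverse-method standard errors, t/p statistics, BH adjustment and variance
moderation."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from ruvmeth.core import (
    ControlSet,
    DesignSpec,
    GlsContext,
    MethylationMatrix,
    bh_adjust,
    control_covariance,
    gls_fit,
    inverse_method_se,
    moderate_variances,
    rank_features,
    t_and_p,
)

from conftest import all_controls, make_matrix, simple_design


def dense_gls_oracle(M, sigma, Y):
    """Independent brute-force GLS formula: (M'S^-1 M)^-1 M'S^-1 Y."""
    Si = np.linalg.inv(sigma)
    return np.linalg.inv(M.T @ Si @ M) @ M.T @ Si @ Y


class TestControlCovariance:
    def test_white_noise_controls_give_identity(self, rng):
        # iid unit-variance controls: law of large numbers drives Sigma_c -> I
        n, n_c = 8, 10000
        Y = make_matrix(rng.standard_normal((n, n_c)))
        design = simple_design(n)
        ctx = control_covariance(Y, design, all_controls(Y), ridge_lambda=0.0)
        # residualizing iid N(0,1) columns against Z leaves covariance P I P' = P,
        # the projection off Z's span; with an intercept that is I - J/n
        Z = design.Z
        P = np.eye(n) - Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        assert np.allclose(ctx.effective, P, atol=0.05)

    def test_hand_computed_three_sample_case(self):
        # residualized control columns (1,0,0) and (0,2,0): Sigma = (1/2) R R'
        R = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        sigma = (R @ R.T) / 2
        assert np.allclose(sigma, np.diag([0.5, 2.0, 0.0]))
        # same through the API: pick Z the control columns are orthogonal to,
        # so residualization leaves them untouched
        Y = MethylationMatrix(R, ("a", "b", "c"), ("c1", "c2"))
        design = DesignSpec(X=np.array([[1.0], [0.0], [0.0]]),
                            Z=np.array([[0.0], [0.0], [1.0]]))
        ctx = control_covariance(Y, design, all_controls(Y))
        # controls residualized against Z=(0,0,1) zero their third entry (already 0)
        expected = np.diag([0.5, 2.0, 0.0])
        assert np.allclose(ctx.sigma_c, expected, atol=1e-12)
        # Sigma_c is singular, so an automatic ridge must have been applied
        assert ctx.ridge_lambda > 0
        assert np.all(np.linalg.eigvalsh(ctx.effective) > 0)

    def test_duplicating_controls_leaves_covariance_unchanged(self, rng):
        n = 6
        Y = make_matrix(rng.standard_normal((n, 4)))
        design = simple_design(n)
        ctx1 = control_covariance(Y, design, all_controls(Y), ridge_lambda=0.0)
        Ydup = MethylationMatrix(
            np.hstack([Y.values, Y.values]),
            Y.sample_ids,
            Y.feature_ids + tuple(f + "_dup" for f in Y.feature_ids),
        )
        ctx2 = control_covariance(Ydup, design, all_controls(Ydup), ridge_lambda=0.0)
        assert np.allclose(ctx1.sigma_c, ctx2.sigma_c, atol=1e-12)

    def test_unknown_control_ids_named_in_error(self, rng):
        Y = make_matrix(rng.standard_normal((5, 3)))
        design = simple_design(5)
        with pytest.raises(KeyError, match="nope"):
            control_covariance(Y, design, ControlSet(("f0", "nope")))

    def test_constant_controls_rejected(self):
        Y = make_matrix(np.ones((5, 3)))
        design = simple_design(5)
        with pytest.raises(ValueError, match="constant"):
            control_covariance(Y, design, all_controls(Y))


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self, rng):
        n, m = 10, 30
        Y = make_matrix(rng.standard_normal((n, m)))
        design = simple_design(n)
        ctx = GlsContext(np.eye(n), 0.0, n)
        beta = gls_fit(Y, design, ctx)
        M = design.full_matrix
        ols = (np.linalg.pinv(M) @ Y.values)[-1]
        assert np.allclose(beta, ols, atol=1e-10)

    def test_exact_model_recovered_under_any_covariance(self, rng):
        n = 8
        design = simple_design(n)
        b_true = 1.7
        y = design.Z[:, 0] * 0.3 + design.X[:, 0] * b_true
        Y = make_matrix(y[:, None])
        A = rng.standard_normal((n, n))
        ctx = GlsContext(A @ A.T + 0.5 * np.eye(n), 0.0, n)
        assert np.allclose(gls_fit(Y, design, ctx), [b_true], atol=1e-9)

    def test_hand_case_three_samples_diagonal_weights(self):
        # n=3, Z=intercept, X=(0,1,1), Sigma=diag(1,1,4), Y=(0,1,5)
        design = DesignSpec(X=np.array([[0.0], [1.0], [1.0]]), Z=np.ones((3, 1)))
        sigma = np.diag([1.0, 1.0, 4.0])
        Y = make_matrix(np.array([[0.0], [1.0], [5.0]]))
        expected = dense_gls_oracle(design.full_matrix, sigma, Y.values)[-1, 0]
        got = gls_fit(Y, design, GlsContext(sigma, 0.0, 3))
        assert np.allclose(got, [expected], atol=1e-10)

    def test_random_small_instances_match_dense_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 9))
            m = int(rng.integers(1, 6))
            design = DesignSpec(X=rng.standard_normal((n, 1)), Z=np.ones((n, 1)))
            A = rng.standard_normal((n, n))
            sigma = A @ A.T + n * np.eye(n)
            Y = make_matrix(rng.standard_normal((n, m)))
            expected = dense_gls_oracle(design.full_matrix, sigma, Y.values)[-1]
            got = gls_fit(Y, design, GlsContext(sigma, 0.0, n))
            assert np.allclose(got, expected, atol=1e-10)


class TestInverseMethodSe:
    def test_zero_residual_feature_gets_zero_se(self):
        n = 8
        design = simple_design(n)
        y = 0.5 + design.X[:, 0] * 2.0
        Y = make_matrix(y[:, None])
        ctx = GlsContext(np.eye(n), 0.0, n)
        se, reps = inverse_method_se(Y, design, ctx, B=10, seed=3)
        assert np.allclose(se, 0.0, atol=1e-10)
        for r in reps:
            assert np.allclose(r.gamma_hat, 0.0, atol=1e-10)

    def test_scaling_feature_scales_se_leaves_t_unchanged(self, rng):
        n = 20
        design = simple_design(n)
        y = rng.standard_normal(n)
        c = 3.7
        Y = make_matrix(np.column_stack([y, c * y]))
        ctx = GlsContext(np.eye(n), 0.0, n)
        beta = gls_fit(Y, design, ctx)
        se, _ = inverse_method_se(Y, design, ctx, B=25, seed=5)
        assert se[1] == pytest.approx(c * se[0], rel=1e-10)
        assert beta[1] == pytest.approx(c * beta[0], rel=1e-10)
        assert beta[1] / se[1] == pytest.approx(beta[0] / se[0], rel=1e-10)

    def test_homoscedastic_calibration_against_analytic_ols_variance(self, rng):
        # closed-form OLS variance sigma^2 [(M'M)^-1]_bb is the oracle
        n, m, B, sigma_noise = 50, 2000, 200, 0.7
        design = simple_design(n)
        Y = make_matrix(sigma_noise * rng.standard_normal((n, m)))
        ctx = GlsContext(np.eye(n), 0.0, n)
        se, reps = inverse_method_se(Y, design, ctx, B=B, seed=7)
        M = design.full_matrix
        analytic = sigma_noise**2 * np.linalg.inv(M.T @ M)[-1, -1]
        assert np.mean(se**2) == pytest.approx(analytic, rel=0.10)
        # random-column coefficients are mean-zero on null data (3 MC SEs)
        gam = np.array([r.gamma_hat for r in reps])
        mc_se = gam.std(ddof=1) / np.sqrt(gam.size)
        assert abs(gam.mean()) < 3 * mc_se

    def test_more_replicates_reduce_monte_carlo_spread(self, rng):
        n, m = 30, 400
        design = simple_design(n)
        sd = np.exp(0.4 * rng.standard_normal(m))
        Y = make_matrix(rng.standard_normal((n, m)) * sd)
        ctx = GlsContext(np.eye(n), 0.0, n)
        se50, _ = inverse_method_se(Y, design, ctx, B=50, seed=11)
        se500, _ = inverse_method_se(Y, design, ctx, B=500, seed=11)
        spread50 = np.var(se50 / sd)
        spread500 = np.var(se500 / sd)
        assert spread500 < spread50

    def test_deterministic_given_seed(self, rng):
        n, m = 12, 20
        design = simple_design(n)
        Y = make_matrix(rng.standard_normal((n, m)))
        ctx = GlsContext(np.eye(n), 0.0, n)
        se1, _ = inverse_method_se(Y, design, ctx, B=20, seed=42)
        se2, _ = inverse_method_se(Y, design, ctx, B=20, seed=42)
        assert np.array_equal(se1, se2)

    def test_rejects_tiny_B(self, rng):
        n = 8
        design = simple_design(n)
        Y = make_matrix(rng.standard_normal((n, 3)))
        ctx = GlsContext(np.eye(n), 0.0, n)
        with pytest.raises(ValueError, match="B"):
            inverse_method_se(Y, design, ctx, B=1)


class TestTAndP:
    def test_zero_t_gives_p_one_and_normal_limit(self):
        t, p = t_and_p(np.array([0.0]), np.array([1.0]), df=5)
        assert t[0] == 0.0 and p[0] == 1.0
        _, p = t_and_p(np.array([1.96]), np.array([1.0]), df=10000)
        assert p[0] == pytest.approx(2 * st.norm.sf(1.96), abs=1e-3)

    def test_p_strictly_decreasing_in_abs_t(self):
        ts = np.linspace(0.1, 5, 25)
        _, p = t_and_p(ts, np.ones_like(ts), df=7)
        assert np.all(np.diff(p) < 0)

    def test_zero_se_handling(self):
        t, p = t_and_p(np.array([0.0, 2.0]), np.array([0.0, 0.0]), df=4)
        assert p[0] == 1.0 and t[0] == 0.0
        assert p[1] == 0.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            t_and_p(np.array([1.0]), np.array([1.0]), df=0)


def bh_bruteforce(p):
    """Step-up reference: p_(j) m/j, suffix minima, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_all_equal_p_unchanged(self):
        p = np.full(7, 0.37)
        assert np.allclose(bh_adjust(p), p)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=30), hst.randoms())
    def test_permutation_equivariance(self, p, rnd):
        p = np.array(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        direct = bh_adjust(p)
        via_perm = np.empty_like(direct)
        via_perm[perm] = bh_adjust(p[perm])
        assert np.allclose(direct, via_perm, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestModerateVariances:
    def test_identical_variances_unchanged(self):
        se = np.full(10, 0.8)
        beta = np.linspace(-1, 1, 10)
        mod = moderate_variances(se, df=6, beta=beta)
        assert np.allclose(mod.se**2, 0.64, atol=1e-12)

    def test_shrinkage_is_convex_combination(self, rng):
        m = 200
        s2 = 2.0 * rng.chisquare(5, m) / 5
        mod = moderate_variances(np.sqrt(s2), df=5, beta=rng.standard_normal(m))
        lo = np.minimum(s2, mod.s0_sq)
        hi = np.maximum(s2, mod.s0_sq)
        assert np.all(mod.se**2 >= lo - 1e-12)
        assert np.all(mod.se**2 <= hi + 1e-12)

    def test_prior_scale_recovered_from_scaled_chisquare(self, rng):
        s0_sq, df, m = 2.0, 4, 5000
        s2 = s0_sq * rng.chisquare(df, m) / df
        mod = moderate_variances(np.sqrt(s2), df=df, beta=np.zeros(m))
        assert mod.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_needs_enough_positive_ses(self):
        with pytest.raises(ValueError):
            moderate_variances(np.array([1.0, 0.0, 0.0, 0.0]), df=4, beta=np.zeros(4))


class TestRanks:
    def test_ranks_are_permutation_with_deterministic_ties(self):
        p = np.array([0.5, 0.1, 0.5, 0.1])
        t = np.array([1.0, 2.0, 2.0, 2.0])
        ids = ("d", "c", "b", "a")
        r = rank_features(p, t, ids)
        assert sorted(r) == [1, 2, 3, 4]
        # p=0.1 group first; within it |t| equal so id lexicographic: a then c
        assert r[3] == 1 and r[1] == 2
        # p=0.5 group: higher |t| first
        assert r[2] == 3 and r[0] == 4
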