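"""Tests of the four-regression mediation system and its bootstrap."""

import itertools

import numpy as np
import pytest
from scipy import stats

import medvox as mv
from medvox._ols import SingularFitError
from medvox.bootstrap import bc_interval
from medvox.mediation import _paths_from_indices

from conftest import lstsq_oracle


class TestFitMediation:
    def test_normal_equations_oracle(self, eight_points):
        """Coefficients and SEs equal the independent least-squares solution."""
        A, B, C = eight_points
        fit = mv.fit_mediation(A, B, C)
        ones = np.ones_like(A)
        b1, s1 = lstsq_oracle(C, np.column_stack([ones, A]))
        b3, s3 = lstsq_oracle(B, np.column_stack([ones, A]))
        b2, s2 = lstsq_oracle(C, np.column_stack([ones, B, A]))
        Ac, Bc = A - A.mean(), B - B.mean()
        b4, s4 = lstsq_oracle(C, np.column_stack([ones, B, A, Ac * Bc]))
        assert fit.c == pytest.approx(b1[1], abs=1e-8)
        assert fit.a == pytest.approx(b3[1], abs=1e-8)
        assert fit.b == pytest.approx(b2[1], abs=1e-8)
        assert fit.c_prime == pytest.approx(b2[2], abs=1e-8)
        assert fit.d == pytest.approx(b4[3], abs=1e-8)
        assert fit.se_a == pytest.approx(s3[1], rel=1e-8)
        assert fit.se_b == pytest.approx(s2[1], rel=1e-8)
        assert fit.se_d == pytest.approx(s4[3], rel=1e-8)

    def test_matches_statsmodels(self, mediation_data):
        """Dual-route check against statsmodels OLS."""
        import statsmodels.api as sm

        A, B, C = mediation_data
        fit = mv.fit_mediation(A, B, C)
        sm2 = sm.OLS(C, sm.add_constant(np.column_stack([B, A]))).fit()
        assert fit.b == pytest.approx(sm2.params[1], rel=1e-10)
        assert fit.se_b == pytest.approx(sm2.bse[1], rel=1e-10)
        assert fit.p_b == pytest.approx(sm2.pvalues[1], rel=1e-8)

    def test_perfect_mediation_chain(self):
        """Near-noiseless chain C = B ~ A: full mediation, ab -> 1.

        (An exactly noiseless chain makes B and A collinear in the
        direct-effect regression, so an infinitesimal perturbation of B
        identifies the fit; the limit is a = b = c = 1, c' = 0.)
        """
        A = np.array([1.0, 2.0, 4.0, 7.0, 11.0, 13.0])
        rng = np.random.default_rng(0)
        B = A + rng.standard_normal(6) * 1e-4
        fit = mv.fit_mediation(A, B, B.copy())
        assert fit.a == pytest.approx(1.0, abs=1e-3)
        assert fit.b == pytest.approx(1.0, abs=1e-3)
        assert fit.c == pytest.approx(1.0, abs=1e-3)
        assert fit.c_prime == pytest.approx(0.0, abs=1e-3)
        assert fit.ab == pytest.approx(1.0, abs=1e-3)

    def test_null_mediator(self):
        rng = np.random.default_rng(0)
        n = 3000
        A = rng.uniform(20, 90, n)
        B = rng.standard_normal(n)
        C = 100 - 0.5 * A + rng.standard_normal(n) * 5
        fit = mv.fit_mediation(A, B, C)
        assert abs(fit.ab) < 0.02
        assert fit.c_prime == pytest.approx(fit.c, abs=0.02)

    def test_indirect_effect_identity(self, mediation_data):
        A, B, C = mediation_data
        fit = mv.fit_mediation(A, B, C)
        assert fit.ab == pytest.approx(fit.c - fit.c_prime, rel=1e-10)
        assert fit.p_joint == max(fit.p_a, fit.p_b_directional)

    @pytest.mark.parametrize("bad", ["constant_A", "constant_B", "short"])
    def test_degenerate_inputs(self, bad):
        A = np.arange(10.0)
        B = np.linspace(0, 1, 10)
        C = np.linspace(5, 1, 10)
        if bad == "constant_A":
            with pytest.raises(SingularFitError, match="A"):
                mv.fit_mediation(np.ones(10), B, C)
        elif bad == "constant_B":
            with pytest.raises(SingularFitError, match="B"):
                mv.fit_mediation(A, np.full(10, 2.0), C)
        else:
            with pytest.raises(mv.InsufficientDataError):
                mv.fit_mediation(A[:4], B[:4], C[:4])

    def test_scale_equivariance(self, mediation_data):
        A, B, C = mediation_data
        f1 = mv.fit_mediation(A, B, C)
        f2 = mv.fit_mediation(A, 3.0 * B, C)
        assert f2.a == pytest.approx(3.0 * f1.a, rel=1e-10)
        assert f2.b == pytest.approx(f1.b / 3.0, rel=1e-10)
        assert f2.ab == pytest.approx(f1.ab, rel=1e-10)
        assert f2.c == pytest.approx(f1.c, rel=1e-10)
        assert f2.c_prime == pytest.approx(f1.c_prime, rel=1e-10)


class TestDirectionalB:
    def test_halving_when_opposite_sign(self):
        """Two-tailed p of 0.04 becomes one-tailed 0.02 in the right tail."""
        df = 100
        t = stats.t.isf(0.02, df)  # two-tailed p = 0.04, b positive
        se = 1.0
        p, flag = mv.directional_b_pvalue(t * se, se, df, a_sign=-1.0)
        assert p == pytest.approx(0.02, rel=1e-10)
        assert not flag

    def test_wrong_direction_near_one(self):
        p, _ = mv.directional_b_pvalue(8.0, 1.0, 200, a_sign=1.0)
        assert p > 0.999

    def test_t_cdf_oracle(self, mediation_data):
        A, B, C = mediation_data
        fit = mv.fit_mediation(A, B, C)
        t = fit.b / fit.se_b
        df = fit.n - 3
        expect = stats.t.cdf(t, df) if fit.a > 0 else stats.t.sf(t, df)
        assert fit.p_b_directional == pytest.approx(expect, rel=1e-12)

    def test_zero_a_falls_back_to_two_tailed(self):
        p, flag = mv.directional_b_pvalue(2.0, 1.0, 50, a_sign=0.0)
        assert flag
        assert p == pytest.approx(2 * stats.t.sf(2.0, 50), rel=1e-12)


class TestModerationScreen:
    def test_zero_incremental_variance(self, mediation_data):
        A, B, C = mediation_data
        fit = mv.fit_mediation(A, B, C)
        fit.f2_interaction = 0.0
        passed, reasons = mv.moderation_screen(fit)
        assert passed == (fit.p_d > 0.05)

    def test_null_interaction_passes_mostly(self):
        """With d = 0 truly, the screen passes in >= 90% of replicates."""
        rng = np.random.default_rng(1)
        passes = 0
        reps = 200
        for _ in range(reps):
            n = 252
            A = rng.uniform(20, 90, n)
            B = 2 - 0.02 * A + rng.standard_normal(n) * 0.5
            C = 100 - 5 * B - 0.3 * A + rng.standard_normal(n) * 8
            fit = mv.fit_mediation(A, B, C)
            passed, _ = mv.moderation_screen(fit)
            passes += passed
        assert passes / reps >= 0.90

    def test_strong_interaction_fails(self):
        rng = np.random.default_rng(2)
        n = 252
        A = rng.uniform(20, 90, n)
        B = 2 - 0.02 * A + rng.standard_normal(n) * 0.5
        Ac, Bc = A - A.mean(), B - B.mean()
        C = 100 - 5 * B - 0.3 * A + 0.5 * Ac * Bc + rng.standard_normal(n) * 2
        passed, reasons = mv.moderation_screen(mv.fit_mediation(A, B, C))
        assert not passed
        assert reasons


class TestBootstrapAB:
    def test_symmetric_distribution_equals_percentile(self):
        """Median-unbiased bootstrap: BC interval = plain percentile."""
        boot = np.concatenate([-np.linspace(0.1, 2, 500), np.linspace(0.1, 2, 500)])
        lo, hi = bc_interval(boot, estimate=0.0, level=0.95)
        assert lo == pytest.approx(np.quantile(boot, 0.025), abs=1e-9)
        assert hi == pytest.approx(np.quantile(boot, 0.975), abs=1e-9)

    def test_default_resample_count(self):
        import inspect

        sig = inspect.signature(mv.bootstrap_ab)
        assert sig.parameters["n_boot"].default == 15_000

    def test_identity_holds_on_every_resample(self, mediation_data):
        A, B, C = mediation_data
        res = mv.bootstrap_ab(A, B, C, n_boot=1000, seed=3)
        comp = res.components
        assert np.allclose(comp["a"] * comp["b"], comp["c"] - comp["c_prime"],
                           rtol=1e-10, atol=1e-12)
        assert np.allclose(res.boot, comp["a"] * comp["b"])

    def test_exhaustive_enumeration_oracle(self):
        """n=5: BC bounds from sampling match full resample enumeration.

        All 5^5 ordered resamples are enumerated; degenerate ones
        (constant or collinear age/mediator, for which the system is
        unidentifiable) are excluded, matching the redraw policy, which
        conditions sampling on non-degeneracy.
        """
        A = np.array([25.0, 40.0, 55.0, 70.0, 85.0])
        B = np.array([1.8, 1.5, 1.0, 0.9, 0.4])
        C = np.array([120.0, 110.0, 100.0, 95.0, 80.0])
        abs_enum = []
        for idx in itertools.product(range(5), repeat=5):
            idx = np.array(idx)
            a_, b_, c_ = A[idx], B[idx], C[idx]
            if np.ptp(a_) == 0 or np.ptp(b_) == 0:
                continue
            if abs(np.corrcoef(a_, b_)[0, 1]) >= 1 - 1e-12:
                continue
            X3 = np.column_stack([np.ones(5), a_])
            a_hat = np.linalg.lstsq(X3, b_, rcond=None)[0][1]
            X2 = np.column_stack([np.ones(5), b_, a_])
            b_hat = np.linalg.lstsq(X2, c_, rcond=None)[0][1]
            abs_enum.append(a_hat * b_hat)
        abs_enum = np.array(abs_enum)
        est = mv.fit_mediation(A, B, C).ab
        # independent BC construction on the enumerated distribution
        from scipy.stats import norm

        z0 = norm.ppf(np.mean(abs_enum < est))
        zq = norm.ppf(0.975)
        lo_q = norm.cdf(2 * z0 - zq)
        hi_q = norm.cdf(2 * z0 + zq)
        res = mv.bootstrap_ab(A, B, C, n_boot=40_000, seed=4)
        # sampled bounds must fall inside the enumeration quantile bracket
        # implied by the Monte Carlo error of the quantile level
        p_hat = np.mean(abs_enum < est)
        se_p = np.sqrt(p_hat * (1 - p_hat) / res.n_boot)
        for bound, q, sgn in [(res.ci[0], lo_q, -1), (res.ci[1], hi_q, +1)]:
            # level uncertainty: quantile estimation + z0 estimation noise
            se_q = np.sqrt(q * (1 - q) / res.n_boot)
            se_z0 = 2 * norm.pdf(2 * z0 + sgn * zq) / norm.pdf(z0) * se_p
            tol = 4 * (se_q + se_z0)
            lo_bracket = np.quantile(abs_enum, max(q - tol, 0.0))
            hi_bracket = np.quantile(abs_enum, min(q + tol, 1.0))
            assert lo_bracket - 1e-9 <= bound <= hi_bracket + 1e-9

    def test_vectorized_paths_match_single_fits(self, mediation_data):
        A, B, C = mediation_data
        rng = np.random.default_rng(5)
        idx = rng.integers(0, len(A), size=(8, len(A)))
        a, b, c, cp = _paths_from_indices(A, B, C, idx)
        for r in range(8):
            f = mv.fit_mediation(A[idx[r]], B[idx[r]], C[idx[r]])
            assert a[r] == pytest.approx(f.a, rel=1e-9)
            assert b[r] == pytest.approx(f.b, rel=1e-9)
            assert c[r] == pytest.approx(f.c, rel=1e-9)
            assert cp[r] == pytest.approx(f.c_prime, rel=1e-9)

    def test_rejects_too_few_resamples(self, mediation_data):
        A, B, C = mediation_data
        with pytest.raises(ValueError):
            mv.bootstrap_ab(A, B, C, n_boot=500, seed=0)
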