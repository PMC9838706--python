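"""Tests of diagnostics: RESET, heteroscedasticity, latent scores, FD,
and global residualization."""

import numpy as np
import pandas as pd
import pytest

import medvox as mv
from medvox._ols import SingularFitError
from medvox.diagnostics import diagnostic_report
from medvox.simulate import VoxelStack


class TestReset:
    def test_numerator_df_is_three(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        y = 1 + x + rng.standard_normal(100)
        F, (df1, df2), p = mv.reset_test(y, x)
        assert df1 == 3
        assert df2 == 100 - 2 - 3

    def test_power_against_quadratic(self):
        """y = x^2 with symmetric x: rejection > 90% at alpha = 0.05."""
        rng = np.random.default_rng(1)
        rej = 0
        for _ in range(50):
            x = rng.standard_normal(200)
            y = x**2 + rng.standard_normal(200) * 0.5
            _, _, p = mv.reset_test(y, x)
            rej += p < 0.05
        assert rej / 50 > 0.9

    def test_null_rejection_near_nominal(self):
        rng = np.random.default_rng(2)
        rej = 0
        for _ in range(400):
            x = rng.standard_normal(150)
            y = 2 - x + rng.standard_normal(150)
            _, _, p = mv.reset_test(y, x)
            rej += p < 0.05
        assert 0.02 <= rej / 400 <= 0.08


class TestWhiteWooldridge:
    def test_df_and_null_mean(self):
        """Under homoscedasticity the statistic is chi^2(2): mean near 2."""
        rng = np.random.default_rng(3)
        stats_ = []
        for _ in range(500):
            x = rng.standard_normal(200)
            y = 1 + x + rng.standard_normal(200)
            beta = np.polyfit(x, y, 1)
            fitted = np.polyval(beta, x)
            chi2, df, p = mv.white_wooldridge_test(y - fitted, fitted)
            assert df == 2
            stats_.append(chi2)
        m = np.mean(stats_)
        assert m == pytest.approx(2.0, abs=3 * np.std(stats_) / np.sqrt(500))

    def test_power_against_proportional_sd(self):
        rng = np.random.default_rng(4)
        rej = 0
        for _ in range(50):
            x = rng.uniform(1, 5, 250)
            y = 2 * x * (1 + rng.standard_normal(250) * 0.3)
            beta = np.polyfit(x, y, 1)
            fitted = np.polyval(beta, x)
            _, _, p = mv.white_wooldridge_test(y - fitted, fitted)
            rej += p < 0.05
        assert rej / 50 > 0.8

    def test_constant_fitted_rejected(self):
        with pytest.raises(ValueError):
            mv.white_wooldridge_test(np.ones(10), np.ones(10))

    def test_report_covers_three_equations(self, mediation_data):
        A, B, C = mediation_data
        rep = diagnostic_report(mv.fit_mediation(A, B, C))
        assert set(rep) == {"eq1", "eq2", "eq3"}
        for eq in rep.values():
            assert eq["white_df"] == 2
            assert 0 <= eq["white_p"] <= 1


class TestLatentScore:
    def test_rank_one_case_is_affine_in_any_subtest(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(60)
        M = np.column_stack([2 * base + 1, -3 * base + 5, base])
        score = mv.latent_score(M, 100.0, 15.0)
        r = abs(np.corrcoef(score, base)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_loadings_match_eigendecomposition_oracle(self):
        M = np.array([
            [44.0, 21.0, 30.0, 12.0],
            [38.0, 18.0, 25.0, 10.0],
            [50.0, 24.0, 33.0, 14.0],
            [30.0, 12.0, 21.0, 6.0],
            [41.0, 20.0, 28.0, 11.0],
        ])
        score = mv.latent_score(M, 0.0, 1.0)
        Zs = (M - M.mean(0)) / M.std(0, ddof=1)
        corr = np.corrcoef(Zs.T)
        vals, vecs = np.linalg.eigh(corr)
        v1 = vecs[:, -1]
        oracle = Zs @ v1
        if np.corrcoef(oracle, Zs.sum(1))[0, 1] < 0:
            oracle = -oracle
        oracle = (oracle - oracle.mean()) / oracle.std(ddof=1)
        assert np.allclose(score, oracle, atol=1e-8)

    def test_target_moments_exact(self):
        rng = np.random.default_rng(6)
        M = rng.standard_normal((100, 4))
        score = mv.latent_score(M, 106.6, 19.5)
        assert score.mean() == pytest.approx(106.6, abs=1e-10)
        assert score.std(ddof=1) == pytest.approx(19.5, abs=1e-10)

    def test_constant_column_rejected(self):
        M = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            mv.latent_score(M, 0.0, 1.0)


class TestFdSummaries:
    def test_static_parameters_are_zero(self):
        mean_fd, prop = mv.fd_summaries(np.zeros((10, 6)))
        assert mean_fd == 0.0
        assert prop == 0.0

    def test_hand_computed_fixture(self):
        """One 1 mm x-step across 10 frames: mean FD 1/9, proportion 1/9."""
        P = np.zeros((10, 6))
        P[5:, 0] = 1.0
        mean_fd, prop = mv.fd_summaries(P)
        assert mean_fd == pytest.approx(1.0 / 9)
        assert prop == pytest.approx(1.0 / 9)

    def test_rotation_radius_applied(self):
        P = np.zeros((2, 6))
        P[1, 3] = 0.01  # radians
        mean_fd, _ = mv.fd_summaries(P, radius_mm=50.0)
        assert mean_fd == pytest.approx(0.5)

    def test_default_threshold_and_format_error(self):
        import inspect

        assert inspect.signature(mv.fd_summaries).parameters[
            "threshold_mm"].default == 0.9
        with pytest.raises(ValueError, match="6 columns"):
            mv.fd_summaries(np.zeros((5, 4)))


class TestResidualizeAll:
    def _study(self, seed=7):
        cfg = mv.SimulationConfig(n_subjects=120, grid_shape=(6, 6, 4),
                                  missing_floor=80, seed=seed)
        return mv.simulate_study(cfg)

    def test_uncorrelated_covariate_only_removes_means(self):
        cohort, stack, _ = self._study()
        rng = np.random.default_rng(8)
        cohort = cohort.copy()
        cohort["noise_cov"] = rng.standard_normal(len(cohort))
        out, stack2 = mv.residualize_all(cohort, stack, ["noise_cov"])
        r = np.corrcoef(out["A"], cohort["A"] - cohort["A"].mean())[0, 1]
        assert r > 0.99

    def test_covariate_equal_to_age_forces_downstream_error(self):
        cohort, stack, _ = self._study()
        cohort = cohort.copy()
        cohort["agecopy"] = cohort["A"]
        out, stack2 = mv.residualize_all(cohort, stack, ["agecopy"])
        assert np.allclose(out["A"], 0.0, atol=1e-9)
        with pytest.raises(SingularFitError, match="A"):
            mv.fit_mediation(out["A"], stack2.summary(), out["C"])

    def test_idempotence(self):
        cohort, stack, _ = self._study()
        cols = ["motion_mean_fd", "motion_prop_high"]
        out1, s1 = mv.residualize_all(cohort, stack, cols)
        out2, s2 = mv.residualize_all(out1, s1, cols)
        assert np.allclose(out1["A"], out2["A"], atol=1e-10)
        assert np.allclose(out1["C"], out2["C"], atol=1e-10)
        assert np.allclose(
            np.where(s1.mask, s1.values, 0), np.where(s2.mask, s2.values, 0),
            atol=1e-8,
        )

    def test_collinear_covariates_raise(self):
        cohort, stack, _ = self._study()
        cohort = cohort.copy()
        cohort["fd2"] = 2 * cohort["motion_mean_fd"]
        with pytest.raises(SingularFitError):
            mv.residualize_all(cohort, stack, ["motion_mean_fd", "fd2"])

    def test_planted_motion_confounder_attenuated(self):
        """A motion variable driving both mediator and outcome inflates
        the indirect effect; residualizing it restores the true value."""
        rng = np.random.default_rng(9)
        raw_ab, res_ab = [], []
        true_ab = (-0.02) * (-5.0)
        for _ in range(40):
            n = 300
            A = rng.uniform(20, 90, n)
            fd = 0.1 + 0.004 * (A - 20) + rng.standard_normal(n) * 0.1
            B = 2 - 0.02 * A - 2.0 * fd + rng.standard_normal(n) * 0.5
            C = 100 - 5.0 * B - 0.3 * A - 30.0 * fd + rng.standard_normal(n) * 8
            raw_ab.append(mv.fit_mediation(A, B, C).ab)
            cohort = pd.DataFrame({
                "subject_id": [str(i) for i in range(n)],
                "A": A, "C": C, "motion_mean_fd": fd,
            })
            vals = B[:, None]
            stack = VoxelStack(vals, np.ones_like(vals, bool),
                               np.zeros((1, 3)), np.zeros((1, 3), int),
                               (1, 1, 1), np.eye(4))
            out, s2 = mv.residualize_all(cohort, stack, ["motion_mean_fd"])
            res_ab.append(mv.fit_mediation(out["A"], s2.values[:, 0],
                                           out["C"]).ab)
        raw_ab, res_ab = np.array(raw_ab), np.array(res_ab)
        se = res_ab.std(ddof=1) / np.sqrt(len(res_ab))
        # residualized estimate is pulled toward the confounder-free truth
        assert abs(res_ab.mean() - true_ab) < abs(raw_ab.mean() - true_ab)
        assert abs(res_ab.mean() - true_ab) < 3 * se + 0.02
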