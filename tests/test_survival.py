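import numpy as np
import pandas as pd
import pytest
from scipy import stats

import clonalsig as cs
from clonalsig.survival import breslow_loglik_and_grad

from .conftest import make_survival


class TestCoxUnivariable:
    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(size=30)
        with pytest.raises(ValueError, match="degenerate"):
            cs.cox_univariable(pd.Series(np.ones(30)), t, np.ones(30, int))

    def test_no_events_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="events"):
            cs.cox_univariable(
                pd.Series(rng.normal(size=20)),
                rng.exponential(size=20),
                np.zeros(20, int),
            )

    def test_two_group_hr_recovery(self):
        # binary covariate, true HR = 2 (exponential groups)
        rng = np.random.default_rng(1)
        hrs = []
        for _ in range(50):
            x = (rng.random(400) < 0.5).astype(float)
            t = rng.exponential(np.exp(-np.log(2) * x))
            fit = cs.cox_univariable(pd.Series(x, name="grp"), t, np.ones(400, int))
            hrs.append(fit.summary["hr"].iloc[0])
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.2)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            x, t, e = make_survival(500, 0.0, rng)
            fit = cs.cox_univariable(pd.Series(x), t, e)
            ps.append(fit.summary["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_hr_is_exp_of_coef_and_ci_ordered(self):
        rng = np.random.default_rng(3)
        x, t, e = make_survival(100, 0.5, rng, censor_scale=2.0)
        s = cs.cox_univariable(pd.Series(x), t, e).summary.iloc[0]
        assert s.hr == pytest.approx(np.exp(s.coef))
        assert s.hr_lower < s.hr < s.hr_upper
        assert 0 < s.p <= 1


class TestCoxScoreTestAndScreen:
    def test_score_test_equals_logrank_on_binary_split(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(4)
        x = (rng.random(60) < 0.4).astype(float)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(60, int)
        chi2, p = cs.cox_score_test(x, t, e)
        ref = multivariate_logrank_test(t, x, e)
        assert chi2 == pytest.approx(float(ref.test_statistic), rel=1e-10)
        assert p == pytest.approx(float(ref.p_value), rel=1e-10)

    def test_vectorized_screen_agrees_with_lifelines(self):
        rng = np.random.default_rng(5)
        n, G = 150, 12
        X = pd.DataFrame(
            rng.standard_normal((n, G)), columns=[f"g{i}" for i in range(G)]
        )
        eta = 0.6 * X["g0"] - 0.4 * X["g1"]
        t = rng.exponential(np.exp(-eta))
        e = np.ones(n, int)
        screen = cs.cox_screen(X, t, e)
        for g in ["g0", "g1", "g5"]:
            ref = cs.cox_univariable(X[g], t, e).summary.iloc[0]
            assert screen.loc[g, "coef"] == pytest.approx(ref.coef, abs=1e-6)
            assert screen.loc[g, "p"] == pytest.approx(ref.p, rel=1e-4, abs=1e-12)

    def test_screen_flags_constant_columns_as_nan(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=40), "c": np.ones(40)})
        screen = cs.cox_screen(X, rng.exponential(size=40), np.ones(40, int))
        assert np.isnan(screen.loc["c", "p"])
        assert np.isfinite(screen.loc["a", "p"])


class TestCoxMultivariable:
    def test_duplicated_column_raises_collinearity_error(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        X = pd.DataFrame({"score": x, "copy": x})
        with pytest.raises(ValueError, match="collinear"):
            cs.cox_multivariable(X, rng.exponential(size=50), np.ones(50, int))

    def test_empty_covariate_set_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="empty"):
            cs.cox_multivariable(
                pd.DataFrame(index=range(20)), rng.exponential(size=20), np.ones(20, int)
            )

    def test_planted_effect_recovered_next_to_noise_covariates(self):
        rng = np.random.default_rng(9)
        n = 500
        score = rng.standard_normal(n)
        noise1 = rng.standard_normal(n)
        sex = rng.choice(["m", "f"], size=n)
        t = rng.exponential(np.exp(-0.8 * score))
        X = pd.DataFrame({"score": score, "noise": noise1, "sex": sex})
        fit = cs.cox_multivariable(X, t, np.ones(n, int))
        assert fit.summary.loc["score", "coef"] == pytest.approx(0.8, abs=0.15)
        assert fit.summary.loc["noise", "hr"] == pytest.approx(1.0, abs=0.15)
        assert fit.summary.loc["sex[m]", "hr"] == pytest.approx(1.0, abs=0.3)


class TestLassoCox:
    @staticmethod
    def _toy(seed=0, n=120, p=5, betas=(0.8, -0.5, 0.3, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"g{i}" for i in range(p)]
        )
        eta = X.to_numpy() @ np.asarray(betas)
        t = rng.exponential(np.exp(-eta))
        c = rng.exponential(2.0, n)
        return X, np.minimum(t, c), (t <= c).astype(int)

    def test_negative_penalty_rejected(self):
        X, t, e = self._toy()
        with pytest.raises(ValueError):
            cs.lasso_cox(X, t, e, lam=-0.1)

    def test_huge_penalty_selects_nothing(self):
        X, t, e = self._toy()
        path = cs.lasso_cox(X, t, e, lam=50.0)
        assert path.selected == []
        assert (path.coefficients == 0).all()

    def test_zero_penalty_matches_unpenalized_fit(self):
        X, t, e = self._toy()
        path = cs.lasso_cox(X, t, e, lam=0.0)
        ref = cs.cox_multivariable(X, t, e)
        assert np.abs(path.coefficients - ref.summary["coef"]).max() < 1e-4

    def test_kkt_conditions_hold_at_solution(self):
        X, t, e = self._toy(seed=3)
        lam = 0.08
        path = cs.lasso_cox(X, t, e, lam=lam)
        Z = (X - X.mean()) / X.std(ddof=0)
        beta = path.coefficients_std.to_numpy()
        _, grad = breslow_loglik_and_grad(beta, Z.to_numpy(), t, e)
        g = -grad / len(t)
        active = beta != 0
        assert np.abs(g[active] + lam * np.sign(beta[active])).max() < 1e-6
        assert (np.abs(g[~active]) <= lam + 1e-6).all()

    def test_agrees_with_independent_coordinate_descent(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        X, t, e = self._toy(seed=5)
        y = np.array(
            [(bool(ev), tt) for ev, tt in zip(e, t)], dtype=[("e", bool), ("t", float)]
        )
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        cn = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[0.06], tol=1e-9)
        cn.fit(Z, y)
        path = cs.lasso_cox(X, t, e, lam=0.06)
        np.testing.assert_allclose(
            path.coefficients_std.to_numpy(), cn.coef_.ravel(), atol=5e-4
        )

    def test_planted_genes_recovered_in_sweep(self):
        # 3 strong genes among 100 noise genes: some penalty recovers all 3
        # with few false selections
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 300, 100
            X = pd.DataFrame(
                rng.standard_normal((n, p)), columns=[f"g{i}" for i in range(p)]
            )
            eta = 0.8 * X["g0"] - 0.8 * X["g1"] + 0.6 * X["g2"]
            t = rng.exponential(np.exp(-eta.to_numpy()))
            e = np.ones(n, int)
            for lam in (0.02, 0.05, 0.08, 0.12, 0.2):
                sel = set(cs.lasso_cox(X, t, e, lam=lam).selected)
                if {"g0", "g1", "g2"} <= sel and len(sel - {"g0", "g1", "g2"}) <= 5:
                    ok += 1
                    break
        assert ok == 10


class TestKmLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        res = cs.km_logrank(g, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_three_groups_use_two_degrees_of_freedom(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(size=30)
        g = pd.Series(np.repeat(["a", "b", "c"], 10))
        res = cs.km_logrank(g, t, np.ones(30, int))
        assert res.df == 2

    def test_small_split_matches_permutation_reference(self):
        # 6 samples, no ties/censoring: compare the log-rank p against the
        # exhaustive permutation distribution of the statistic
        import itertools

        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, int)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        obs = cs.km_logrank(pd.Series(labels), t, e).statistic
        stats_perm = []
        for idx in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(idx)] = "a"
            stats_perm.append(cs.km_logrank(pd.Series(lab), t, e).statistic)
        p_perm = np.mean([s >= obs - 1e-12 for s in stats_perm])
        # asymptotic chi2 p and exact permutation p agree loosely at n=6
        p_asym = cs.km_logrank(pd.Series(labels), t, e).p
        assert abs(p_asym - p_perm) < 0.25

    def test_unused_category_level_is_an_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        g = pd.Series(pd.Categorical(["a", "a", "b", "b"], categories=["a", "b", "c"]))
        with pytest.raises(ValueError, match="empty"):
            cs.km_logrank(g, t, np.ones(4, int))

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(size=40)
        g = pd.Series(["x"] * 40)
        t2 = np.concatenate([t, t])
        g2 = pd.Series(["x"] * 40 + ["y"] * 40)
        res = cs.km_logrank(g2, t2, np.ones(80, int))
        curve = res.curves["x"]
        ts = np.sort(t)
        for i, tt in enumerate(ts):
            emp = 1 - (i + 1) / 40
            km_val = curve.loc[curve["time"] == tt, "survival"].iloc[0]
            assert km_val == pytest.approx(emp, abs=1e-12)
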