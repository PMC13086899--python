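import numpy as np
import pandas as pd
import pytest

from neuroallometry import (
    PhyloTree,
    grade_shift,
    leverage_screen,
    pgls_fit,
    simulate_bm,
    simulate_tree,
    slope_index,
    two_factor_pgls,
    wald_chi2,
)
from neuroallometry.allometry import ConfoundedFactorsError, PGLSFit
from neuroallometry.tree import PhyloCovariance

from conftest import star_tree


def _design(x):
    return pd.DataFrame({"intercept": 1.0, "log_x": x})


def _identity_cov(labels):
    return PhyloCovariance(list(labels), np.eye(len(labels)))


class TestPGLSFit:
    def test_reduces_to_ols_with_identity_covariance(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        labels = [f"s{i}" for i in range(20)]
        x = pd.Series(rng.normal(size=20), index=labels)
        y = pd.Series(2 + 0.5 * x + rng.normal(0, 0.3, 20), index=labels, name="y")
        fit = pgls_fit(y, _design(x), _identity_cov(labels))
        ols = sm.OLS(y.values, sm.add_constant(x.values)).fit()
        np.testing.assert_allclose(fit.params.values, ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.cov_params.values, ols.cov_params(), atol=1e-8)
        np.testing.assert_allclose(fit.r2, ols.rsquared, atol=1e-8)

    def test_matches_statsmodels_gls_on_tree_covariance(self, tree15):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        labels = tree15.tip_labels
        cov = tree15.vcv()
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=2), index=labels)
        y = pd.Series(1 + 1.3 * x.values + simulate_bm(tree15, 0.1, 0.0, rng=3),
                      index=labels, name="y")
        fit = pgls_fit(y, _design(x), cov)
        gls = sm.GLS(y.values, sm.add_constant(x.values), sigma=cov.matrix).fit()
        np.testing.assert_allclose(fit.params.values, gls.params, atol=1e-8)
        np.testing.assert_allclose(fit.se.values, gls.bse, atol=1e-8)

    def test_matches_independent_reference_fit(self, tree4):
        """Coefficients frozen from an independent GLS implementation
        (R nlme::gls with a Brownian correlation on the same tree)."""
        x = pd.Series(np.log([1, 2, 7, 9.0]), index=list("ABCD"))
        y = pd.Series([2.1, 2.4, 5.2, 6.0], index=list("ABCD"), name="y")
        fit = pgls_fit(y, _design(x), tree4.vcv())
        np.testing.assert_allclose(
            fit.params.values, [1.88632840980, 1.68614785443], atol=1e-8)

    def test_perfect_fit(self, tree15):
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=5), index=tree15.tip_labels)
        y = (3.0 + 2.0 * x).rename("y")
        fit = pgls_fit(y, _design(x), tree15.vcv())
        np.testing.assert_allclose(fit.params["log_x"], 2.0, atol=1e-10)
        assert fit.sigma2 < 1e-20
        np.testing.assert_allclose(fit.r2, 1.0, atol=1e-10)

    def test_unbiased_slope_recovery(self, tree15):
        slopes = []
        cov = tree15.vcv()
        labels = tree15.tip_labels
        for i in range(300):
            x = pd.Series(simulate_bm(tree15, 0.5, 15.0, rng=2 * i), index=labels)
            y = pd.Series(0.5 + 1.3 * x.values + simulate_bm(tree15, 0.03, 0.0, rng=2 * i + 1),
                          index=labels, name="y")
            slopes.append(pgls_fit(y, _design(x), cov).params["log_x"])
        assert abs(np.mean(slopes) - 1.3) < 0.02

    def test_too_few_species_rejected(self, tree4):
        y = pd.Series([1.0, 2.0], index=["A", "B"], name="y")
        x = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError, match="insufficient"):
            pgls_fit(y, _design(x), tree4.vcv())

    def test_pairwise_deletion_drops_missing_species(self, tree15):
        labels = tree15.tip_labels
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=6), index=labels)
        y = (1 + x).rename("y")
        y.iloc[0] = np.nan
        fit = pgls_fit(y, _design(x), tree15.vcv())
        assert fit.n == 14 and labels[0] not in fit.species


class TestWaldChi2:
    def test_zero_when_constraint_met(self, tree15):
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=7), index=tree15.tip_labels)
        y = (3.0 + 1.0 * x).rename("y")
        noisy = y + pd.Series(simulate_bm(tree15, 0.05, 0.0, rng=8), index=y.index)
        fit = pgls_fit(noisy, _design(x), tree15.vcv())
        b = float(fit.params["log_x"])
        chi2, df, p = wald_chi2(fit, "log_x", b)
        assert chi2 < 1e-18 and df == 1 and abs(p - 1.0) < 1e-12

    def test_single_constraint_is_squared_z(self, tree15):
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=9), index=tree15.tip_labels)
        y = (1 + 1.2 * x + pd.Series(simulate_bm(tree15, 0.05, 0.0, rng=10),
                                     index=x.index)).rename("y")
        fit = pgls_fit(y, _design(x), tree15.vcv())
        chi2, _, _ = wald_chi2(fit, "log_x", 1.0)
        z = (fit.params["log_x"] - 1.0) / fit.se["log_x"]
        assert abs(chi2 - z**2) < 1e-10

    def test_rank_deficient_constraints_rejected(self, tree15):
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=11), index=tree15.tip_labels)
        y = (1 + x + pd.Series(simulate_bm(tree15, 0.05, 0.0, rng=12),
                               index=x.index)).rename("y")
        fit = pgls_fit(y, _design(x), tree15.vcv())
        with pytest.raises(ValueError, match="rank"):
            wald_chi2(fit, np.array([[0.0, 1.0], [0.0, 2.0]]), 0.0)


class TestSlopeIndex:
    @pytest.mark.parametrize("b,expected", [(1.0, 0.0), (1.2, 0.2)])
    def test_arithmetic(self, tree15, b, expected):
        x = pd.Series(simulate_bm(tree15, 1.0, 0.0, rng=13), index=tree15.tip_labels)
        y = (b * x).rename("y")
        fit = pgls_fit(y, _design(x), tree15.vcv())
        si = slope_index(fit, b0=1.0)
        assert abs(si["si"] - expected) < 1e-9

    def test_shallow_scaling_detected(self):
        """Slopes planted well below isometry show up as significant si < 0."""
        hits = 0
        reps = 60
        for i in range(reps):
            t = simulate_tree(15, seed=500 + i)
            labels = t.tip_labels
            x = pd.Series(simulate_bm(t, 0.5, 15.0, rng=3 * i), index=labels)
            y = pd.Series(0.7 * x.values + simulate_bm(t, 0.03, 0.0, rng=3 * i + 1),
                          index=labels, name="y")
            si = slope_index(pgls_fit(y, _design(x), t.vcv()), b0=1.0)
            hits += (si["si"] < 0) and (si["p_b"] < 0.05)
        assert hits / reps >= 0.8


class TestGradeShift:
    @staticmethod
    def _sim(seed, ratio=2.0, b1=1.0, b2=1.0, n=15):
        t = simulate_tree(n, seed=seed)
        labels = t.tip_labels
        rng = np.random.default_rng(seed + 10_000)
        x = pd.Series(simulate_bm(t, 0.5, 15.0, rng=rng), index=labels)
        g = pd.Series(["g1"] * (n // 2) + ["g2"] * (n - n // 2), index=labels)
        la = np.where(g == "g1", np.log(ratio), 0.0)
        b = np.where(g == "g1", b1, b2)
        resid = simulate_bm(t, 0.03, 0.0, rng=rng)
        y = pd.Series(la + b * x.values + resid, index=labels, name="y")
        return t, x, y, g

    def test_identical_groups_give_zero_gsi(self):
        t = star_tree(8)
        labels = t.tip_labels
        x = pd.Series(np.tile([0.0, 1.0, 2.0, 3.0], 2), index=labels)
        y = (2 + x).rename("y")
        g = pd.Series(["g1"] * 4 + ["g2"] * 4, index=labels)
        res = grade_shift(y, x, g, t.vcv(), group1="g1")
        assert not res.slopes_differ
        assert abs(res.gsi) < 1e-10
        assert res.gsi_p > 0.999

    def test_small_group_rejected(self):
        t, x, y, g = self._sim(0)
        g.iloc[:] = "g2"
        g.iloc[:2] = "g1"
        with pytest.raises(ValueError, match=">= 3"):
            grade_shift(y, x, g, t.vcv(), group1="g1")

    def test_intercept_ratio_recovery(self):
        gsis = []
        for i in range(40):
            t, x, y, g = self._sim(i, ratio=2.0)
            res = grade_shift(y, x, g, t.vcv(), group1="g1")
            if res.gsi is not None:
                gsis.append(res.gsi)
        mean, se = np.mean(gsis), np.std(gsis, ddof=1) / np.sqrt(len(gsis))
        assert abs(mean - 1.0) < 2 * se + 0.05

    def test_planted_slope_difference_detected_and_gsi_invalidated(self):
        detected = 0
        reps = 40
        for i in range(reps):
            t, x, y, g = self._sim(i, ratio=1.0, b1=1.4, b2=0.8)
            res = grade_shift(y, x, g, t.vcv(), group1="g1")
            if res.slopes_differ:
                detected += 1
                assert res.gsi is None and not res.gsi_valid
        assert detected / reps >= 0.8

    def test_gsi_invariant_to_uniform_rescaling(self):
        t, x, y, g = self._sim(3)
        res = grade_shift(y, x, g, t.vcv(), group1="g1")
        # rescale raw x and y by positive constants for every species
        res2 = grade_shift(y + np.log(7.0), x + np.log(4.0), g, t.vcv(), group1="g1")
        assert abs(res.gsi - res2.gsi) < 1e-10


class TestLeverage:
    @staticmethod
    def _fit_with_residuals(resid):
        labels = [f"s{i}" for i in range(len(resid))]
        r = pd.Series(resid, index=labels, dtype=float)
        return PGLSFit(
            response="y", predictors=["intercept"],
            params=pd.Series([0.0], index=["intercept"]),
            cov_params=pd.DataFrame([[1.0]], index=["intercept"], columns=["intercept"]),
            sigma2=1.0, n=len(resid), df_resid=len(resid) - 1,
            resid_raw=r, resid_whitened=r, r2=0.0, r2_adj=0.0, species=labels,
        )

    def test_equal_residuals_flag_nothing(self):
        lev = leverage_screen(self._fit_with_residuals([0.5] * 10))
        assert not lev["flagged"].any()

    def test_single_outlier_flagged(self):
        lev = leverage_screen(self._fit_with_residuals([1.0] * 14 + [10.0]))
        assert lev["flagged"].sum() == 1
        assert lev["flagged"].iloc[-1]

    def test_zero_residuals_defined_as_zero(self):
        lev = leverage_screen(self._fit_with_residuals([0.0] * 8))
        assert (lev["leverage"] == 0).all()
        assert not lev["flagged"].any()


class TestTwoFactor:
    @staticmethod
    def _sim(seed, activity_ratio=1.0):
        t = simulate_tree(16, seed=seed)
        labels = t.tip_labels
        rng = np.random.default_rng(seed + 999)
        x = pd.Series(simulate_bm(t, 0.5, 15.0, rng=rng), index=labels)
        act = pd.Series(["diurnal"] * 8 + ["nocturnal"] * 8, index=labels)
        mig = pd.Series((["migratory"] * 4 + ["non-migratory"] * 4) * 2, index=labels)
        la = np.where(act == "diurnal", np.log(activity_ratio), 0.0)
        y = pd.Series(la + x.values + simulate_bm(t, 0.03, 0.0, rng=rng),
                      index=labels, name="y")
        return t, x, y, act, mig

    def test_confounded_factors_rejected(self):
        t, x, y, act, _ = self._sim(0)
        mig = act.map({"diurnal": "migratory", "nocturnal": "non-migratory"})
        with pytest.raises(ConfoundedFactorsError):
            two_factor_pgls(y, x, act, mig, t.vcv())

    def test_activity_only_effect_leaves_migration_nonsignificant(self):
        nonsig = 0
        reps = 30
        for i in range(reps):
            t, x, y, act, mig = self._sim(i, activity_ratio=2.0)
            _, tests = two_factor_pgls(y, x, act, mig, t.vcv())
            nonsig += not tests.loc[["migration", "migration_x"], "significant"].any()
        assert nonsig / reps >= 0.8

    def test_null_data_rarely_significant(self):
        sig = 0
        reps = 30
        for i in range(reps):
            t, x, y, act, mig = self._sim(100 + i, activity_ratio=1.0)
            _, tests = two_factor_pgls(y, x, act, mig, t.vcv())
            sig += tests["significant"].any()
        assert sig / reps <= 0.5  # four tests at alpha=0.05, small n
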