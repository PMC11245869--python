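"""Residual-outcome machinery, BH, matching, Cox and Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiage.inference import (
    bh_adjust,
    cox_association,
    fit_reference_model,
    iqr_outlier_mask,
    propensity_match,
    residual_outcome_battery,
    residual_outcome_test,
    spearman,
)


def _pheno(n_sur, n_dec, rng, seed_cols=True):
    n = n_sur + n_dec
    return pd.DataFrame(
        {
            "group": ["survived"] * n_sur + ["deceased"] * n_dec,
            "age": rng.uniform(55, 70, n),
            "sex": rng.choice(["M", "F"], n),
            "complications": rng.integers(0, 2, n),
        },
        index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
    )


class TestIQROutliers:
    def test_constant_vector_no_outliers(self):
        assert iqr_outlier_mask(np.full(10, 3.0)).all()

    def test_single_gross_outlier_dropped(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 1000], dtype=float)
        keep = iqr_outlier_mask(x)
        # fences from linear-interpolation quartiles of the full vector
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert not keep[-1]
        assert keep[:-1].all()
        assert q3 + 1.5 * (q3 - q1) < 1000

    def test_data_inside_fences_untouched(self, rng):
        x = rng.uniform(-1, 1, 30)
        assert iqr_outlier_mask(x).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_mask([1.0, 2.0, np.nan, np.nan])


class TestReferenceModel:
    def test_noiseless_recovery(self, rng):
        pheno = _pheno(20, 10, rng)
        est = pd.Series(2.0 * pheno["age"], index=pheno.index, name="e")
        model = fit_reference_model(est, pheno)
        assert model.params["age"] == pytest.approx(2.0, abs=1e-10)
        survivors = pheno.index[pheno.group == "survived"]
        resid = est[survivors] - model.predict(
            pd.DataFrame({"age": pheno.loc[survivors, "age"],
                          "sex": pheno.loc[survivors, "sex"].map({"M": 1, "F": 0}),
                          "complications": pheno.loc[survivors, "complications"]})
        )
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_survivor_residuals_sum_to_zero(self, rng):
        pheno = _pheno(27, 23, rng)
        est = pd.Series(pheno["age"] + rng.normal(0, 2, 50), index=pheno.index, name="e")
        r = residual_outcome_test(est, pheno)
        # survivor mean residual is 0 by construction: reproduce via model
        model = fit_reference_model(est, pheno)
        survivors = pheno.index[pheno.group == "survived"]
        sex = pheno["sex"].map({"M": 1, "F": 0})
        X = pd.DataFrame({"age": pheno["age"], "sex": sex, "complications": pheno["complications"]})
        resid = est[survivors] - model.predict(X.loc[survivors])
        assert abs(resid.sum()) < 1e-9

    def test_coefficient_recovery_within_three_se(self, rng):
        """beta_age=1.2, beta_sex=-0.5 at n=27 survivors, sigma=0.5: estimates
        within 3 SE in >= 95% of 200 replicates."""
        import statsmodels.api as sm

        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            pheno = _pheno(27, 0, rng)
            sex01 = pheno["sex"].map({"M": 1, "F": 0}).astype(float)
            est = pd.Series(
                1.2 * pheno["age"] - 0.5 * sex01 + rng.normal(0, 0.5, 27),
                index=pheno.index, name="e",
            )
            model = fit_reference_model(est, pheno)
            X = sm.add_constant(pd.DataFrame({
                "age": pheno["age"], "sex": sex01,
                "complications": pheno["complications"].astype(float)}))
            fit = sm.OLS(est, X).fit()
            ok = (abs(fit.params["age"] - 1.2) <= 3 * fit.bse["age"]
                  and abs(fit.params["sex"] - (-0.5)) <= 3 * fit.bse["sex"])
            hits += int(ok)
        assert hits / n_rep >= 0.95

    def test_collinear_design_rejected(self, rng):
        pheno = _pheno(10, 5, rng)
        pheno["complications"] = 1  # aliased with intercept
        est = pd.Series(rng.normal(size=15), index=pheno.index, name="e")
        with pytest.raises(ValueError, match="collinear"):
            fit_reference_model(est, pheno)


class TestResidualOutcomeTest:
    def test_identical_groups_give_t_zero_p_one(self, rng):
        pheno = _pheno(10, 10, rng)
        base = rng.normal(60, 3, 10)
        pheno["age"] = np.concatenate([np.arange(55, 65)] * 2).astype(float)
        pheno["sex"] = ["M", "F", "M", "M", "F", "F", "M", "F", "M", "F"] * 2
        pheno["complications"] = [0, 0, 1, 0, 1, 1, 0, 1, 1, 0] * 2
        est = pd.Series(np.concatenate([base, base]), index=pheno.index, name="e")
        r = residual_outcome_test(est, pheno)
        assert r.t_statistic == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == pytest.approx(1.0, abs=1e-10)

    def test_large_shift_always_detected(self, rng):
        for _ in range(20):
            pheno = _pheno(27, 23, rng)
            sigma = 1.0
            est = pd.Series(pheno["age"] + rng.normal(0, sigma, 50), index=pheno.index, name="e")
            est[pheno.group == "deceased"] += 5 * sigma
            r = residual_outcome_test(est, pheno)
            assert r.p_value < 1e-3
            assert r.t_statistic > 0  # deceased minus survived

    def test_outliers_removed_before_medians(self, rng):
        pheno = _pheno(10, 10, rng)
        pheno["sex"] = ["M", "F", "M", "M", "F", "F", "M", "F", "M", "F"] * 2
        pheno["complications"] = [0, 0, 1, 0, 1, 1, 0, 1, 1, 0] * 2
        est = pd.Series(rng.normal(0, 1, 20), index=pheno.index, name="e")
        est.iloc[0] = 1e6
        r = residual_outcome_test(est, pheno)
        assert r.n_outliers_removed >= 1
        assert abs(r.median_survived) < 10  # the 1e6 value cannot be the median source
        assert r.n_survived + r.n_deceased == 20 - r.n_outliers_removed

    def test_reduces_to_plain_t_test_when_covariates_uninformative(self, rng):
        """If the estimate is independent of age/sex/complications, the
        residual-outcome p-value distribution matches the plain two-sample
        t-test distribution (KS at 500 simulations)."""
        p_res, p_t = [], []
        for _ in range(500):
            pheno = _pheno(15, 15, rng)
            est = pd.Series(rng.normal(size=30), index=pheno.index, name="e")
            r = residual_outcome_test(est, pheno)
            p_res.append(r.p_value)
            g = pheno.group == "deceased"
            p_t.append(stats.ttest_ind(est[g], est[~g]).pvalue)
        d, p = stats.ks_2samp(p_res, p_t)
        assert p > 0.01

    def test_battery_applies_bh(self, rng):
        pheno = _pheno(20, 20, rng)
        table = pd.DataFrame(
            {f"e{k}": rng.normal(size=40) for k in range(5)}, index=pheno.index
        )
        out = residual_outcome_battery(table, pheno)
        assert (out["bh_p_value"] >= out["p_value"] - 1e-12).all()
        assert out.shape[0] == 5


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_adjusted_at_least_nominal_and_capped(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_matches_classic_decision_rule(self, rng):
        """The BH-significant set at level q equals the classic step-up set."""
        q = 0.05
        p = np.sort(rng.uniform(0, 0.5, 40))
        adj = bh_adjust(p)
        m = len(p)
        ranks = np.arange(1, m + 1)
        passing = np.where(p <= q * ranks / m)[0]
        classic = set(range(passing.max() + 1)) if passing.size else set()
        assert set(np.where(adj <= q)[0]) == classic

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([-0.1, 0.5])


class TestPropensityMatch:
    def _confounded(self, rng, n_t=40, n_c=200, shift=0.8):
        n = n_t + n_c
        x1 = np.concatenate([rng.normal(shift, 1, n_t), rng.normal(0, 1, n_c)])
        x2 = np.concatenate([rng.normal(0.5 * shift, 1, n_t), rng.normal(0, 1, n_c)])
        return pd.DataFrame(
            {
                "group": ["deceased"] * n_t + ["survived"] * n_c,
                "x1": x1,
                "x2": x2,
            },
            index=[f"s{j}" for j in range(n)],
        )

    def test_identical_covariates_yield_zero_smd(self):
        pheno = pd.DataFrame(
            {"group": ["deceased"] * 5 + ["survived"] * 8, "x": 1.0},
            index=[f"s{j}" for j in range(13)],
        )
        res = propensity_match(pheno, ["x"], penalized=True)
        assert res.pairs.shape[0] == 5
        assert res.smd_after.abs().max() == 0.0

    def test_confounding_reduced_below_0p2(self, rng):
        pheno = self._confounded(rng)
        res = propensity_match(pheno, ["x1", "x2"])
        assert res.smd_before.abs().max() > 0.5
        assert res.smd_after.abs().max() < 0.2

    def test_every_treated_matched_once_without_reuse(self, rng):
        pheno = self._confounded(rng, n_t=30, n_c=50)
        res = propensity_match(pheno, ["x1", "x2"])
        assert res.pairs.shape[0] == 30
        assert res.pairs["deceased"].is_unique
        assert res.pairs["survived"].is_unique

    def test_missing_covariates_rejected(self, rng):
        pheno = self._confounded(rng, n_t=5, n_c=8)
        pheno.loc[pheno.index[0], "x1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            propensity_match(pheno, ["x1"])


class TestCox:
    def _toy(self):
        # two groups, interleaved distinct event times (finite MLE, no ties)
        return pd.DataFrame(
            {
                "group": ["survived"] * 4 + ["deceased"] * 4,
                "followup_time": [2.0, 4.0, 6.0, 8.0, 1.0, 3.0, 5.0, 7.0],
                "event": [1, 1, 0, 1, 1, 1, 1, 1],
                "x": [0, 0, 0, 0, 1, 1, 1, 1],
            },
            index=[f"s{j}" for j in range(8)],
        )

    @staticmethod
    def _partial_loglik(beta, df):
        """Brute-force Cox partial log-likelihood (no ties)."""
        x = df["x"].to_numpy(dtype=float)
        t = df["followup_time"].to_numpy()
        e = df["event"].to_numpy()
        ll = 0.0
        for i in np.where(e == 1)[0]:
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll

    def test_log_hr_matches_grid_search_oracle(self):
        df = self._toy()
        est = pd.Series(df["x"].astype(float), index=df.index, name="x")
        res = cox_association(est, df, "x")
        grid = np.linspace(-5, 5, 20001)
        ll = np.array([self._partial_loglik(b, df) for b in grid])
        oracle = grid[np.argmax(ll)]
        assert res["log_hr"] == pytest.approx(oracle, abs=1e-3)

    def test_rescaling_invariance(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "followup_time": rng.exponential(5, n) + 0.01,
                "event": rng.integers(0, 2, n),
                "group": "survived",
            },
            index=[f"s{j}" for j in range(n)],
        )
        x = pd.Series(rng.normal(size=n), index=df.index, name="x")
        r1 = cox_association(x, df, "x")
        r2 = cox_association(10.0 * x, df, "x")
        assert r2["log_hr"] == pytest.approx(r1["log_hr"] / 10.0, rel=1e-6)
        assert r2["p_value"] == pytest.approx(r1["p_value"], rel=1e-6)

    def test_few_events_warns(self, rng):
        df = self._toy()
        df["event"] = [0, 1, 0, 0, 1, 0, 0, 0]
        df["age"] = rng.uniform(55, 70, 8)
        est = pd.Series(rng.normal(size=8), index=df.index, name="est")
        with pytest.warns(UserWarning):
            cox_association(est, df, "est", covariates=["age", "x"])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_ranks_match_exhaustive_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 8.0, 8.0])
        rho, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on midranks
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_zero_rank_variance_flagged(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_properties(pvals):
    """BH output is within [p, 1] elementwise and order-preserving in ranks."""
    adj = bh_adjust(pvals)
    p = np.asarray(pvals)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.integers(min_value=-10_000, max_value=10_000), min_size=4, max_size=50),
    st.integers(min_value=-3, max_value=3),
    st.integers(min_value=-1024, max_value=1024),
)
def test_iqr_mask_affine_invariance(values, log2_scale, shift):
    """The IQR outlier mask is invariant under positive affine transforms
    (power-of-two scales and integer data keep the arithmetic exact)."""
    x = np.asarray(values, dtype=float)
    m1 = iqr_outlier_mask(x)
    m2 = iqr_outlier_mask(2.0**log2_scale * x + shift)
    assert (m1 == m2).all()
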