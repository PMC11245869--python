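"""DMP/DVP calling, empirical-Bayes moderation, comb-p regions, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiage.diffmeth import (
    CombPParams,
    dmp_test,
    dmr_combp,
    dvp_test,
    ebayes_moderate,
    fisher_enrichment,
    stouffer_liptak,
    summarize_genic_distribution,
)
from epiage.io import FLAG_COLUMNS


def _pheno(n_sur, n_dec, rng=None):
    n = n_sur + n_dec
    idx = pd.Index([f"s{j}" for j in range(n)], name="sample_id")
    df = pd.DataFrame({"group": ["survived"] * n_sur + ["deceased"] * n_dec}, index=idx)
    if rng is not None:
        df["age"] = rng.uniform(55, 70, n)
        df["sex"] = rng.choice(["M", "F"], n)
        df["complications"] = rng.integers(0, 2, n)
    return df


def _beta(values, probes=None):
    values = np.atleast_2d(values)
    probes = probes or [f"cg{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestDMP:
    def test_identical_groups_not_called(self, rng):
        base = rng.uniform(0.3, 0.7, 20)
        beta = _beta(np.column_stack([base] * 12).T).T
        beta = _beta(np.tile(base[:, None], (1, 20)))
        res = dmp_test(beta, _pheno(10, 10))
        assert np.allclose(res["delta_beta"], 0.0)
        assert not res["is_dmp"].any()

    def test_significant_but_small_delta_not_called(self, rng):
        """BH-significant probe with |delta beta| below 0.05 fails the dual rule."""
        n = 200  # large n makes a 0.03 shift highly significant
        x = np.concatenate([rng.normal(0.50, 0.01, n), rng.normal(0.53, 0.01, n)])
        beta = _beta(x.reshape(1, -1))
        res = dmp_test(beta, _pheno(n, n))
        assert res["bh_p_value"].iloc[0] < 0.01
        assert abs(res["delta_beta"].iloc[0]) < 0.05
        assert not res["is_dmp"].iloc[0]

    def test_ols_path_matches_t_test_oracle(self, rng):
        """Group-only OLS fit equals the per-probe two-sample t-test exactly."""
        beta = _beta(rng.uniform(0.2, 0.8, (100, 30)))
        res = dmp_test(beta, _pheno(15, 15), robust=False, moderate=False)
        dec = np.array([False] * 15 + [True] * 15)
        t, p = stats.ttest_ind(beta.to_numpy()[:, dec], beta.to_numpy()[:, ~dec], axis=1)
        np.testing.assert_allclose(res["t"].to_numpy(), t, atol=1e-10)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p, atol=1e-10)

    def test_covariate_adjustment_changes_coefficient_not_delta(self, rng):
        pheno = _pheno(15, 15, rng)
        conf = pheno["age"].to_numpy() / 100
        beta = _beta((0.3 + 0.5 * conf + rng.normal(0, 0.01, 30)).reshape(1, -1))
        raw = dmp_test(beta, pheno)
        adj = dmp_test(beta, pheno, covariates=["age"])
        assert raw["delta_beta"].iloc[0] == pytest.approx(adj["delta_beta"].iloc[0])
        assert raw["coefficient"].iloc[0] != pytest.approx(adj["coefficient"].iloc[0], abs=1e-6)

    def test_rank_deficient_design_names_column(self, rng):
        pheno = _pheno(8, 8, rng)
        pheno["dup"] = (pheno["group"] == "deceased").astype(float)
        beta = _beta(rng.uniform(0.2, 0.8, (5, 16)))
        with pytest.raises(ValueError, match="aliased"):
            dmp_test(beta, pheno, covariates=["dup"])

    def test_robust_path_downweights_outliers(self, rng):
        base = np.concatenate([rng.normal(0.4, 0.01, 15), rng.normal(0.4, 0.01, 15)])
        spoiled = base.copy()
        spoiled[0] = 0.99  # single gross outlier in survived group
        res_r = dmp_test(_beta(spoiled.reshape(1, -1)), _pheno(15, 15), robust=True)
        res_o = dmp_test(_beta(spoiled.reshape(1, -1)), _pheno(15, 15), robust=False)
        # robust coefficient should sit closer to the uncontaminated value (~0)
        assert abs(res_r["coefficient"].iloc[0]) < abs(res_o["coefficient"].iloc[0])

    def test_hyper_hypo_partition_is_exhaustive(self, small_dataset):
        res = dmp_test(small_dataset.beta.iloc[:200], small_dataset.phenotype)
        assert set(res["direction"].unique()) <= {"hyper", "hypo"}
        assert ((res["delta_beta"] > 0) == (res["direction"] == "hyper")).all()


class TestEbayes:
    def test_equal_variances_unchanged(self):
        s2 = np.full(50, 0.04)
        mod, df, info = ebayes_moderate(s2, 10.0)
        np.testing.assert_allclose(mod, 0.04, rtol=1e-6)

    def test_shrinks_toward_prior(self, rng):
        d0, s0 = 4.0, 0.04
        d = 10
        s2 = s0 * d0 / rng.chisquare(d0, 5000) * rng.chisquare(d, 5000) / d
        mod, df_total, info = ebayes_moderate(s2, float(d))
        # moderated values lie between raw and prior, dispersion reduced
        assert np.var(np.log(mod)) < np.var(np.log(s2))
        assert df_total > d

    def test_prior_df_recovery_within_50_percent(self, rng):
        """Scaled-inverse-chi-square variances (d0=4, s0^2=0.04): recovered d0
        within +-50% at 10000 probes."""
        d0, s0_2 = 4.0, 0.04
        d = 20
        true_var = d0 * s0_2 / rng.chisquare(d0, 10000)
        s2 = true_var * rng.chisquare(d, 10000) / d
        _, _, info = ebayes_moderate(s2, float(d))
        assert 0.5 * d0 <= info["d0"] <= 1.5 * d0


class TestDVP:
    def test_equal_variance_not_called(self, rng):
        beta = _beta(rng.normal(0.5, 0.05, (30, 40)))
        res = dvp_test(beta, _pheno(20, 20))
        assert not res["is_dvp"].any()
        assert np.abs(res["log_variance_ratio"]).median() < 1.0

    def test_exact_threshold_ratio_not_called(self):
        """|log2 VR| exactly 2 fails the strict inequality."""
        base = np.array([0.4, 0.45, 0.5, 0.55, 0.6, 0.42, 0.48, 0.52, 0.58, 0.5])
        dec = 0.5 + (base - 0.5) * 2.0   # deviations doubled: variance ratio exactly 4
        beta = _beta(np.concatenate([base, dec]).reshape(1, -1))
        res = dvp_test(beta, _pheno(10, 10))
        assert res["log_variance_ratio"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert not res["is_dvp"].iloc[0]

    def test_planted_inflation_detected(self, rng):
        detected = 0
        n_rep = 10
        for _ in range(n_rep):
            sur = rng.normal(0.5, 0.02, (1, 25))
            dec = rng.normal(0.5, 0.08, (1, 25))   # 16-fold variance
            res = dvp_test(_beta(np.hstack([sur, dec])), _pheno(25, 25))
            detected += int(res["is_dvp"].iloc[0] and res["direction"].iloc[0] == "hypervariable")
        assert detected >= 9

    def test_zero_variance_flagged_and_excluded(self):
        row = np.concatenate([np.full(10, 0.5), np.linspace(0.4, 0.6, 10)])
        res = dvp_test(_beta(row.reshape(1, -1)), _pheno(10, 10))
        assert res["zero_variance"].iloc[0]
        assert not res["is_dvp"].iloc[0]

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            dvp_test(_beta(rng.random((3, 4))), _pheno(2, 2))


def _annotation(probes, chrom, pos):
    ann = pd.DataFrame(
        {"chrom": chrom, "position": pos, "gene": "G", "feature": "Body"},
        index=pd.Index(probes, name="probe_id"),
    )
    for f in FLAG_COLUMNS:
        ann[f] = False
    return ann


class TestDMR:
    def _flat_background(self, rng, n=400, spacing=1000):
        probes = [f"cg{i}" for i in range(n)]
        ann = _annotation(probes, "chr1", np.arange(1, n + 1) * spacing)
        p = pd.Series(rng.uniform(size=n), index=probes)
        return probes, ann, p

    def test_planted_cluster_found_and_matches_oracle(self, rng):
        """5 contiguous probes at p=1e-6 within 100 bp: one significant region
        whose p matches a direct Stouffer-Liptak computation to 1e-8."""
        probes, ann, p = self._flat_background(rng)
        cluster = probes[200:205]
        ann.loc[cluster, "position"] = 200_500 + np.array([0, 25, 50, 75, 100])
        ann = ann.sort_values("position")
        p.loc[cluster] = 1e-6
        res = dmr_combp(p, ann)
        hits = res[res["n_probes"] == 5]
        assert len(hits) == 1
        region = hits.iloc[0]
        assert region["is_significant"]
        # independent oracle: z-combination over the 5x5 correlation matrix
        params = CombPParams()
        from epiage.diffmeth import _estimate_acf, _acf_at

        order = np.argsort(ann["position"].to_numpy())
        z_all = stats.norm.isf(np.clip(p.loc[ann.index[order]].to_numpy(), 1e-300, 1 - 1e-16))
        acf = _estimate_acf(z_all, ann["chrom"].to_numpy()[order],
                            ann["position"].to_numpy()[order], params)
        pos5 = 200_500 + np.array([0, 25, 50, 75, 100])
        d = np.abs(pos5[:, None] - pos5[None, :])
        sigma = _acf_at(d, acf, params)
        np.fill_diagonal(sigma, 1.0)
        z = stats.norm.isf(np.full(5, 1e-6))
        oracle = stats.norm.sf(z.sum() / np.sqrt(sigma.sum()))
        assert region["region_p"] == pytest.approx(oracle, abs=1e-8)

    def test_independent_probes_uncorrelated_oracle(self):
        """With identity correlation, the combination reduces to plain Stouffer."""
        p = np.array([1e-4, 1e-3, 0.01])
        sigma = np.eye(3)
        got = stouffer_liptak(p, sigma)
        z = stats.norm.isf(p)
        expected = stats.norm.sf(z.sum() / np.sqrt(3))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_isolated_significant_probe_suppressed(self, rng):
        probes, ann, p = self._flat_background(rng)
        p.loc[probes[100]] = 1e-9
        res = dmr_combp(p, ann)
        if len(res):
            assert probes[100] not in ",".join(res["probes"]).split(",")

    def test_probe_order_invariance(self, rng):
        """Results do not depend on the input row order (sorted internally)."""
        probes, ann, p = self._flat_background(rng, n=100, spacing=300)
        p.iloc[40:43] = 1e-7
        res1 = dmr_combp(p, ann)
        perm = rng.permutation(len(p))
        res2 = dmr_combp(p.iloc[perm], ann.iloc[perm])
        pd.testing.assert_frame_equal(res1, res2)

    def test_uniform_null_rarely_calls_regions(self, rng):
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            probes, ann, p = self._flat_background(rng, n=300, spacing=200)
            res = dmr_combp(p, ann)
            hits += int(len(res) and res["is_significant"].any())
        assert hits <= max(1, int(0.1 * n_rep))


class TestEnrichment:
    def test_zero_overlap_near_one(self):
        res = fisher_enrichment(["g1"], {"S": [f"x{i}" for i in range(50)]},
                                ["g1"] + [f"x{i}" for i in range(99)])
        assert res.loc["S", "p_value"] > 0.5

    def test_three_of_three_in_ten(self):
        universe = [f"g{i}" for i in range(10)]
        res = fisher_enrichment(universe[:3], {"S": universe[:3]}, universe)
        assert res.loc["S", "p_value"] == pytest.approx(1 / math.comb(10, 3), abs=1e-12)

    def test_matches_hypergeometric_tail_oracle(self, rng):
        """50 random tables against an exact tail sum built from math.comb."""
        for _ in range(50):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            members = universe[:K]
            glist = list(rng.choice(universe, size=n, replace=False))
            res = fisher_enrichment(glist, {"S": members}, universe)
            k = len(set(glist) & set(members))
            tail = sum(
                math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                for j in range(k, min(K, n) + 1)
            )
            assert res.loc["S", "p_value"] == pytest.approx(tail, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["g"], {"S": ["g"]}, [])


class TestGenicSummary:
    def test_single_class_is_100_percent(self):
        ann = _annotation(["a", "b"], "chr1", [100, 200])
        out = summarize_genic_distribution(["a", "b"], ann)
        assert out.loc["Body", "percent"] == pytest.approx(100.0)

    def test_two_to_one_split(self):
        ann = _annotation(["a", "b", "c"], "chr1", [100, 200, 300])
        ann.loc["c", "feature"] = "TSS200"
        out = summarize_genic_distribution(["a", "b", "c"], ann)
        assert out.loc["Body", "percent"] == pytest.approx(66.67, abs=0.01)
        assert out.loc["TSS200", "percent"] == pytest.approx(33.33, abs=0.01)

    def test_percentages_sum_to_100(self, rng, small_dataset):
        probes = list(rng.choice(small_dataset.annotation.index, 50, replace=False))
        out = summarize_genic_distribution(probes, small_dataset.annotation)
        if len(out):
            assert out["percent"].sum() == pytest.approx(100.0, abs=0.05)
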