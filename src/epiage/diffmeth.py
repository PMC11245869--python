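"""Differential methylation, variability and region calling plus enrichment.

DMP: per-probe linear model of beta on group plus covariates (OLS or Huber
robust IRLS), optional empirical-Bayes variance moderation, BH adjustment,
and the dual call rule (BH p < 0.05 AND raw |delta beta| > 0.05).

DVP: absolute-deviation (Levene/Brown-Forsythe style) regression per probe,
called at |log2 variance ratio| > 2 AND nominal p < 0.001.

DMR: comb-p style spatial combination — autocorrelation of z-scores by
genomic-distance bin, Stouffer-Liptak smoothing within a window, seeded
region growth, correlation-adjusted Stouffer-Liptak region p, and a Sidak
correction for the number of region-sized windows the probes cover.

Enrichment: one-sided Fisher's exact (hypergeometric upper tail) over GMT
gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dmp_test",
    "ebayes_moderate",
    "dvp_test",
    "dmr_combp",
    "fisher_enrichment",
    "summarize_genic_distribution",
    "CombPParams",
]


# ---------------------------------------------------------------------------
# design helpers

def _dmp_design(phenotype: pd.DataFrame, covariates: list[str] | None) -> tuple[np.ndarray, list[str]]:
    cols = {"intercept": np.ones(len(phenotype))}
    cols["group"] = (phenotype["group"] == "deceased").astype(float).to_numpy()
    for c in covariates or []:
        col = phenotype[c]
        if col.dtype == object or str(col.dtype) == "category":
            if c == "sex":
                cols[c] = col.map({"M": 1.0, "F": 0.0}).to_numpy()
            else:  # categorical -> dummy levels (reference = first)
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                for dc in dummies.columns:
                    cols[dc] = dummies[dc].astype(float).to_numpy()
        else:
            cols[c] = col.astype(float).to_numpy()
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient DMP design; aliased columns: {aliased}")
    return X, names


def _huber_irls(
    X: np.ndarray, Y: np.ndarray, c: float = 1.345, max_iter: int = 50, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Huber M-estimation across probes (Y: samples x probes).

    Returns (coefficients: p x probes, robustness weights: samples x probes).
    MAD scale, tuning constant 1.345.
    """
    n, p = X.shape
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    for _ in range(max_iter):
        R = Y - X @ beta
        scale = np.median(np.abs(R - np.median(R, axis=0)), axis=0) * 1.4826
        scale = np.where(scale < 1e-10, 1e-10, scale)
        U = np.abs(R / scale)
        W = np.minimum(1.0, c / np.maximum(U, 1e-12))
        # per-probe weighted normal equations, batched
        Xw = X[:, :, None] * W[:, None, :]                # n x p x m
        XtWX = np.einsum("ni,njm->ijm", X, Xw)
        XtWy = np.einsum("ni,nm->im", X, W * Y)
        new = np.empty_like(beta)
        for j in range(Y.shape[1]):
            new[:, j] = np.linalg.solve(XtWX[:, :, j], XtWy[:, j])
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    R = Y - X @ beta
    scale = np.median(np.abs(R - np.median(R, axis=0)), axis=0) * 1.4826
    scale = np.where(scale < 1e-10, 1e-10, scale)
    W = np.minimum(1.0, c / np.maximum(np.abs(R / scale), 1e-12))
    return beta, W


def dmp_test(
    beta: pd.DataFrame,
    phenotype: pd.DataFrame,
    covariates: list[str] | None = None,
    robust: bool = False,
    moderate: bool = False,
    bh_alpha: float = 0.05,
    delta_beta_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-probe differential methylation between deceased and survived.

    Returns a frame with the fitted group coefficient, raw group-mean
    delta beta (deceased - survived), t, nominal and BH-adjusted p, and the
    dual-rule call flag.
    """
    pheno = phenotype.loc[beta.columns]
    X, names = _dmp_design(pheno, covariates)
    gi = names.index("group")
    Y = beta.to_numpy(dtype=float).T                      # samples x probes
    n, p = X.shape

    if robust:
        coef, W = _huber_irls(X, Y)
        resid = Y - X @ coef
        # weighted residual variance and weighted (X^T W X)^{-1}_gg per probe
        s2 = np.einsum("nm,nm->m", W * resid, resid) / (n - p)
        Xw = X[:, :, None] * W[:, None, :]
        XtWX = np.einsum("ni,njm->ijm", X, Xw)
        gg = np.empty(Y.shape[1])
        for j in range(Y.shape[1]):
            gg[j] = np.linalg.inv(XtWX[:, :, j])[gi, gi]
        var_coef = s2 * gg
    else:
        pinv = np.linalg.pinv(X)
        coef = pinv @ Y
        resid = Y - X @ coef
        s2 = np.sum(resid**2, axis=0) / (n - p)
        XtX_inv_gg = np.linalg.inv(X.T @ X)[gi, gi]
        var_coef = s2 * XtX_inv_gg
        gg = np.full(Y.shape[1], XtX_inv_gg)

    df_resid = float(n - p)
    if moderate:
        s2_mod, df_total, info = ebayes_moderate(s2, df_resid)
        var_coef = s2_mod * gg
        df_t = df_total
    else:
        df_t = df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[gi] / np.sqrt(var_coef)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_t)

    dec = (pheno["group"] == "deceased").to_numpy()
    mb = beta.to_numpy(dtype=float)
    delta = np.nanmean(mb[:, dec], axis=1) - np.nanmean(mb[:, ~dec], axis=1)

    from .inference import bh_adjust

    bh = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "coefficient": coef[gi],
            "delta_beta": delta,
            "t": t,
            "p_value": pvals,
            "bh_p_value": bh,
        },
        index=beta.index,
    )
    out["is_dmp"] = (out["bh_p_value"] < bh_alpha) & (out["delta_beta"].abs() > delta_beta_threshold)
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    return out


def ebayes_moderate(
    per_probe_variances: np.ndarray, residual_df: float
) -> tuple[np.ndarray, float, dict]:
    """Empirical-Bayes shrinkage of per-probe variances toward a pooled prior.

    Moment-matching on log variances: the prior is scaled-inverse-chi-square
    with df d0 and scale s0^2, estimated from the mean/variance of log s^2
    via di/trigamma identities. Posterior: (d0 s0^2 + d s^2) / (d0 + d).
    Returns (moderated variances, total df d0 + d, info dict).
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(per_probe_variances, dtype=float)
    if np.any(s2 <= 0):
        ok = s2 > 0
        if not ok.any():
            raise ValueError("all variances non-positive")
        s2 = np.where(ok, s2, np.min(s2[ok]))
    d = float(residual_df)
    e = np.log(s2)
    var_e = float(np.var(e, ddof=1)) if s2.size > 1 else 0.0
    if var_e < 1e-12:
        # degenerate: no dispersion at all, the common value is the prior
        return s2.copy(), float("inf"), {"d0": float("inf"), "s0_2": float(np.exp(np.mean(e))), "fallback": False}
    target = var_e - float(polygamma(1, d / 2))
    if target <= 1e-8 or not np.isfinite(target):
        # no excess dispersion: infinite prior df, all shrink to the common value
        log_s0 = float(np.mean(e)) - float(digamma(d / 2)) + np.log(d / 2)
        s0_2 = float(np.exp(log_s0))
        if not np.isfinite(s0_2):
            warnings.warn("prior estimate non-finite; falling back to unmoderated variances")
            return s2, d, {"d0": 0.0, "s0_2": float("nan"), "fallback": True}
        return np.full_like(s2, s0_2), float("inf"), {"d0": float("inf"), "s0_2": s0_2, "fallback": False}
    # invert trigamma by Newton iteration (limma-style)
    y = target
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        delta = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    log_s0 = float(np.mean(e)) - float(digamma(d / 2)) + np.log(d / 2) + float(digamma(d0 / 2)) - np.log(d0 / 2)
    s0_2 = float(np.exp(log_s0))
    if not (np.isfinite(d0) and np.isfinite(s0_2) and d0 > 0):
        warnings.warn("prior estimate non-finite; falling back to unmoderated variances")
        return s2, d, {"d0": float("nan"), "s0_2": float("nan"), "fallback": True}
    mod = (d0 * s0_2 + d * s2) / (d0 + d)
    return mod, d0 + d, {"d0": d0, "s0_2": s0_2, "fallback": False}


# ---------------------------------------------------------------------------
# DVP

def dvp_test(
    beta: pd.DataFrame,
    phenotype: pd.DataFrame,
    center: str = "mean",
    log_base: float = 2.0,
    ratio_threshold: float = 2.0,
    p_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Differential variability per probe via absolute-deviation regression.

    z = |beta - group center| regressed on group gives the nominal p
    (Brown-Forsythe when center="median", Levene-with-mean otherwise); the
    variance ratio (deceased over survived) is reported in the chosen log
    base. Call rule: |log VR| > ratio_threshold AND p < p_threshold, both
    strict.
    """
    pheno = phenotype.loc[beta.columns]
    dec = (pheno["group"] == "deceased").to_numpy()
    if dec.sum() < 3 or (~dec).sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    B = beta.to_numpy(dtype=float)
    centerfn = np.nanmean if center == "mean" else np.nanmedian
    cd = centerfn(B[:, dec], axis=1)
    cs = centerfn(B[:, ~dec], axis=1)
    Z = np.empty_like(B)
    Z[:, dec] = np.abs(B[:, dec] - cd[:, None])
    Z[:, ~dec] = np.abs(B[:, ~dec] - cs[:, None])

    # per-probe two-sample t on the absolute deviations (OLS of z on group)
    t, p = stats.ttest_ind(Z[:, dec], Z[:, ~dec], axis=1, equal_var=True)

    var_d = np.nanvar(B[:, dec], axis=1, ddof=1)
    var_s = np.nanvar(B[:, ~dec], axis=1, ddof=1)
    zero_var = (var_d <= 0) | (var_s <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_vr = np.log(var_d / var_s) / np.log(log_base)

    out = pd.DataFrame(
        {
            "log_variance_ratio": log_vr,
            "levene_t": t,
            "levene_p": p,
            "zero_variance": zero_var,
        },
        index=beta.index,
    )
    out["is_dvp"] = (
        ~zero_var
        & (np.abs(out["log_variance_ratio"]) > ratio_threshold)
        & (out["levene_p"] < p_threshold)
    )
    out["direction"] = np.where(out["log_variance_ratio"] > 0, "hypervariable", "hypovariable")
    return out


# ---------------------------------------------------------------------------
# comb-p style DMR calling

@dataclass(frozen=True)
class CombPParams:
    acf_bin_bp: int = 50
    acf_max_bp: int = 500
    smooth_window_bp: int = 500
    seed_p: float = 0.01
    merge_dist_bp: int = 500
    min_probes: int = 2
    sidak_alpha: float = 0.05


def _estimate_acf(z: np.ndarray, chrom: np.ndarray, pos: np.ndarray, params: CombPParams) -> np.ndarray:
    """Correlation of z-scores for probe pairs binned by genomic distance."""
    nbins = params.acf_max_bp // params.acf_bin_bp
    sums = np.zeros(nbins)
    sums2x = np.zeros(nbins)
    sums2y = np.zeros(nbins)
    sumx = np.zeros(nbins)
    sumy = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    n = z.size
    for i in range(n):
        j = i + 1
        while j < n and chrom[j] == chrom[i] and pos[j] - pos[i] <= params.acf_max_bp:
            b = min((pos[j] - pos[i]) // params.acf_bin_bp, nbins - 1)
            sums[b] += z[i] * z[j]
            sumx[b] += z[i]
            sumy[b] += z[j]
            sums2x[b] += z[i] ** 2
            sums2y[b] += z[j] ** 2
            counts[b] += 1
            j += 1
    acf = np.zeros(nbins)
    for b in range(nbins):
        if counts[b] >= 10:
            cov = sums[b] / counts[b] - (sumx[b] / counts[b]) * (sumy[b] / counts[b])
            sx = np.sqrt(max(sums2x[b] / counts[b] - (sumx[b] / counts[b]) ** 2, 1e-12))
            sy = np.sqrt(max(sums2y[b] / counts[b] - (sumy[b] / counts[b]) ** 2, 1e-12))
            acf[b] = cov / (sx * sy)
    return np.clip(acf, 0.0, 0.99)


def _acf_at(dist: np.ndarray, acf: np.ndarray, params: CombPParams) -> np.ndarray:
    """Pairwise correlation looked up from the binned ACF (0 beyond range)."""
    out = np.zeros(dist.shape)
    within = (dist > 0) & (dist <= params.acf_max_bp)
    bins = np.minimum(dist[within] // params.acf_bin_bp, len(acf) - 1).astype(int)
    out[within] = acf[bins]
    return out


def stouffer_liptak(pvals: np.ndarray, sigma: np.ndarray) -> float:
    """Correlation-adjusted Stouffer-Liptak combination of p-values."""
    p = np.clip(np.asarray(pvals, dtype=float), 1e-300, 1 - 1e-16)
    z = stats.norm.isf(p)
    denom = np.sqrt(float(np.sum(sigma)))
    return float(stats.norm.sf(np.sum(z) / denom))


def dmr_combp(
    p_values: pd.Series,
    annotation: pd.DataFrame,
    params: CombPParams = CombPParams(),
) -> pd.DataFrame:
    """comb-p style region calling from per-probe nominal p-values.

    Returns regions (chrom, 0-based half-open start/end, n_probes, min p,
    Stouffer-Liptak region p, Sidak-corrected p, significance flag).
    """
    ann = annotation.loc[p_values.index]
    order = np.lexsort((ann["position"].to_numpy(), ann["chrom"].to_numpy()))
    chrom = ann["chrom"].to_numpy()[order]
    pos = ann["position"].to_numpy()[order].astype(np.int64)
    pv = p_values.to_numpy(dtype=float)[order]
    probes = p_values.index.to_numpy()[order]
    same = chrom[1:] == chrom[:-1]
    if np.any(same & (np.diff(pos) < 0)):
        raise ValueError("annotation positions unsorted within chromosome")

    pv = np.clip(pv, 1e-300, 1 - 1e-16)
    z = stats.norm.isf(pv)
    acf = _estimate_acf(z, chrom, pos, params)

    # Stouffer-Liptak smoothing within +/- window/2
    half = params.smooth_window_bp // 2
    n = pv.size
    smooth = np.empty(n)
    lo = 0
    hi = 0
    for i in range(n):
        while lo < i and (chrom[lo] != chrom[i] or pos[i] - pos[lo] > half):
            lo += 1
        hi = max(hi, i)
        while hi + 1 < n and chrom[hi + 1] == chrom[i] and pos[hi + 1] - pos[i] <= half:
            hi += 1
        idx = np.arange(lo, hi + 1)
        if idx.size == 1:
            smooth[i] = pv[i]
        else:
            d = np.abs(pos[idx][:, None] - pos[idx][None, :])
            sigma = _acf_at(d, acf, params)
            np.fill_diagonal(sigma, 1.0)
            smooth[i] = stouffer_liptak(pv[idx], sigma)

    # seed + merge regions
    seeds = smooth < params.seed_p
    regions = []
    i = 0
    while i < n:
        if not seeds[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and chrom[j + 1] == chrom[i] and seeds[j + 1] and (
            pos[j + 1] - pos[j] <= params.merge_dist_bp
        ):
            j += 1
        regions.append((i, j))
        i = j + 1

    # genome span covered by the tested probes, for the Sidak correction
    covered = 0
    for c in np.unique(chrom):
        cp = pos[chrom == c]
        covered += int(cp.max() - cp.min()) + 1

    rows = []
    for i0, i1 in regions:
        idx = np.arange(i0, i1 + 1)
        if idx.size < params.min_probes:
            continue
        d = np.abs(pos[idx][:, None] - pos[idx][None, :])
        sigma = _acf_at(d, acf, params)
        np.fill_diagonal(sigma, 1.0)
        region_p = stouffer_liptak(pv[idx], sigma)
        start0 = int(pos[idx[0]]) - 1              # 0-based half-open
        end0 = int(pos[idx[-1]])
        width = max(end0 - start0, 1)
        m_eff = max(covered / width, 1.0)
        sidak_p = float(-np.expm1(m_eff * np.log1p(-region_p))) if region_p < 1 else 1.0
        rows.append(
            {
                "chrom": chrom[i0],
                "start": start0,
                "end": end0,
                "n_probes": int(idx.size),
                "min_p": float(pv[idx].min()),
                "region_p": region_p,
                "sidak_p": sidak_p,
                "is_significant": sidak_p < params.sidak_alpha,
                "probes": ",".join(probes[idx]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_probes", "min_p",
            "region_p", "sidak_p", "is_significant", "probes",
        ],
    )


# ---------------------------------------------------------------------------
# enrichment + genic summary

def fisher_enrichment(
    gene_list: list[str] | set[str],
    gene_sets: dict[str, list[str]],
    universe: list[str] | set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of the gene list in each set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    glist = set(gene_list) & universe
    rows = []
    N = len(universe)
    n = len(glist)
    for name, members in gene_sets.items():
        mset = set(members) & universe
        K = len(mset)
        k = len(mset & glist)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        table = np.array([[k, n - k], [K - k, N - K - (n - k)]])
        odds = (
            (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
            if table[0, 1] > 0 and table[1, 0] > 0
            else np.inf
        )
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "list_size": n,
                "universe_size": N,
                "p_value": p,
                "odds_ratio": float(odds),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def summarize_genic_distribution(
    dmp_probes: list[str] | pd.Index, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Counts and percentages of genic DMPs per genic feature class."""
    ann = annotation.loc[list(dmp_probes)]
    genic = ann[ann["feature"] != "intergenic"]
    counts = genic["feature"].value_counts()
    total = int(counts.sum())
    pct = counts / total * 100.0 if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "percent": pct.round(2)})
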