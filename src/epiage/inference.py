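"""Statistical machinery on the per-sample estimator table.

The core procedure is the two-stage residual-outcome regression: per
estimator, (1) remove pooled-cohort IQR outliers, (2) fit an ordinary
least-squares reference model estimator ~ age + sex + complications on the
survived group only, (3) residualize the whole cohort against that model and
compare group residuals with a Student t-test, (4) Benjamini-Hochberg adjust
across the estimator battery. Also here: propensity-score matching with
greedy nearest-neighbour pairing, Cox proportional-hazards association and
Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "iqr_outlier_mask",
    "fit_reference_model",
    "residual_outcome_test",
    "residual_outcome_battery",
    "bh_adjust",
    "propensity_match",
    "cox_association",
    "spearman",
    "ReferenceModel",
    "ResidualTestResult",
    "MatchResult",
]


# ---------------------------------------------------------------------------
# outliers

def iqr_outlier_mask(values: pd.Series | np.ndarray, k: float = 1.5) -> np.ndarray:
    """True where the value is kept: inside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation on the pooled (both-group) vector;
    missing values are dropped (flagged False).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values for IQR fences")
    q1, q3 = np.quantile(x[finite], [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return finite & (x >= lo) & (x <= hi)


# ---------------------------------------------------------------------------
# reference model + residual-outcome test

@dataclass
class ReferenceModel:
    """OLS fit of an estimator on age, sex, complications over survivors only."""

    estimator: str
    params: pd.Series            # const, age, sex, complications
    sigma2: float
    nobs: int
    coding: dict = field(default_factory=lambda: {"sex": {"M": 1, "F": 0}, "complications": "0/1"})

    def predict(self, design: pd.DataFrame) -> pd.Series:
        X = design[["age", "sex", "complications"]]
        Xc = sm.add_constant(X, has_constant="add")
        return pd.Series(Xc.to_numpy() @ self.params.to_numpy(), index=design.index)


def _design(phenotype: pd.DataFrame) -> pd.DataFrame:
    sex = phenotype["sex"]
    if sex.dtype == object:
        sex = sex.map({"M": 1, "F": 0, 1: 1, 0: 0})
    return pd.DataFrame(
        {
            "age": phenotype["age"].astype(float),
            "sex": sex.astype(float),
            "complications": phenotype["complications"].astype(float),
        },
        index=phenotype.index,
    )


def fit_reference_model(
    estimates: pd.Series, phenotype: pd.DataFrame, estimator: str | None = None
) -> ReferenceModel:
    """Fit the survivor-group reference regression."""
    name = estimator or estimates.name or "estimate"
    survivors = phenotype.index[phenotype["group"] == "survived"]
    survivors = survivors.intersection(estimates.dropna().index)
    if len(survivors) < 5:
        raise ValueError(f"{name}: only {len(survivors)} survivors with values (need >= 5)")
    X = _design(phenotype.loc[survivors])
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(f"{name}: collinear reference design, columns {list(Xc.columns)}")
    fit = sm.OLS(estimates.loc[survivors].astype(float), Xc).fit()
    return ReferenceModel(
        estimator=name, params=fit.params, sigma2=float(fit.scale), nobs=int(fit.nobs)
    )


@dataclass
class ResidualTestResult:
    estimator: str
    n_outliers_removed: int
    n_survived: int
    n_deceased: int
    median_survived: float
    q1_survived: float
    q3_survived: float
    median_deceased: float
    q1_deceased: float
    q3_deceased: float
    t_statistic: float
    p_value: float
    bh_p_value: float | None = None
    degenerate: bool = False

    def as_row(self) -> dict:
        return self.__dict__.copy()


def residual_outcome_test(
    estimates: pd.Series,
    phenotype: pd.DataFrame,
    estimator: str | None = None,
    equal_var: bool = True,
    iqr_k: float = 1.5,
) -> ResidualTestResult:
    """The two-stage residual-outcome comparison for one estimator."""
    name = estimator or estimates.name or "estimate"
    est = estimates.reindex(phenotype.index).astype(float)
    keep = iqr_outlier_mask(est, k=iqr_k)
    n_out = int((~keep & np.isfinite(est.to_numpy())).sum())
    kept = phenotype.index[keep]
    pheno = phenotype.loc[kept]
    est = est.loc[kept]
    groups = pheno["group"]
    if (groups == "survived").sum() == 0 or (groups == "deceased").sum() == 0:
        raise ValueError(f"{name}: a group is empty after outlier removal")

    model = fit_reference_model(est, pheno, name)
    resid = est - model.predict(_design(pheno))
    rs = resid[groups == "survived"].to_numpy()
    rd = resid[groups == "deceased"].to_numpy()

    degenerate = (np.var(rs) == 0 and np.var(rd) == 0)
    if degenerate and np.allclose(rs.mean(), rd.mean()):
        t, p = 0.0, 1.0
    elif degenerate:
        t, p = np.inf, 0.0
    else:
        t, p = stats.ttest_ind(rd, rs, equal_var=equal_var)

    raw_s = est[groups == "survived"]
    raw_d = est[groups == "deceased"]
    return ResidualTestResult(
        estimator=name,
        n_outliers_removed=n_out,
        n_survived=len(rs),
        n_deceased=len(rd),
        median_survived=float(raw_s.median()),
        q1_survived=float(raw_s.quantile(0.25)),
        q3_survived=float(raw_s.quantile(0.75)),
        median_deceased=float(raw_d.median()),
        q1_deceased=float(raw_d.quantile(0.25)),
        q3_deceased=float(raw_d.quantile(0.75)),
        t_statistic=float(t),
        p_value=float(p),
        degenerate=degenerate,
    )


def residual_outcome_battery(
    estimate_table: pd.DataFrame, phenotype: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Run the residual-outcome test per estimator column and BH-adjust."""
    rows = [
        residual_outcome_test(estimate_table[c], phenotype, c, equal_var=equal_var)
        for c in estimate_table.columns
    ]
    df = pd.DataFrame([r.as_row() for r in rows]).set_index("estimator")
    df["bh_p_value"] = bh_adjust(df["p_value"].to_numpy())
    return df


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0,1]")
    from statsmodels.stats.multitest import multipletests

    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# propensity matching

@dataclass
class MatchResult:
    pairs: pd.DataFrame                # columns: deceased, survived, score_deceased, score_survived
    scores: pd.Series
    smd_before: pd.Series
    smd_after: pd.Series


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    num = x_t.mean() - x_c.mean()
    den = np.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2.0)
    return float(num / den) if den > 0 else 0.0


def propensity_match(
    phenotype: pd.DataFrame,
    covariates: list[str],
    ratio: int = 1,
    caliper: float | None = None,
    penalized: bool = False,
) -> MatchResult:
    """1:ratio greedy nearest-neighbour matching on a logistic propensity score.

    Deceased (treated) units are matched in order of descending score,
    without replacement. Standardized mean differences are reported before
    and after matching.
    """
    treated = phenotype.index[phenotype["group"] == "deceased"]
    control = phenotype.index[phenotype["group"] == "survived"]
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both groups must be non-empty")
    X = phenotype[covariates].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {bad}")
    y = (phenotype["group"] == "deceased").astype(int)
    Xc = sm.add_constant((X - X.mean()) / X.std(ddof=1).replace(0, 1))
    if penalized:
        fit = sm.Logit(y, Xc).fit_regularized(alpha=1.0, disp=0)
        scores = pd.Series(1 / (1 + np.exp(-(Xc.to_numpy() @ np.asarray(fit.params)))), index=X.index)
    else:
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as e:  # perfect separation raises in statsmodels
            raise ValueError(
                f"propensity logistic fit failed ({e}); retry with penalized=True"
            ) from e
        if not res.mle_retvals.get("converged", True):
            raise ValueError("propensity logistic fit did not converge; retry with penalized=True")
        scores = pd.Series(res.predict(Xc), index=X.index)

    available = set(control)
    pairs = []
    for t in sorted(treated, key=lambda s: -scores[s]):
        for _ in range(ratio):
            if not available:
                break
            cands = sorted(available)
            dists = np.abs(scores[cands].to_numpy() - scores[t])
            j = int(np.argmin(dists))
            if caliper is not None and dists[j] > caliper:
                continue
            c = cands[j]
            available.discard(c)
            pairs.append(
                {"deceased": t, "survived": c, "score_deceased": scores[t], "score_survived": scores[c]}
            )
    pairs_df = pd.DataFrame(pairs)

    smd_before = pd.Series(
        {c: _smd(X.loc[treated, c].to_numpy(), X.loc[control, c].to_numpy()) for c in covariates}
    )
    if len(pairs_df):
        mt, mc = pairs_df["deceased"], pairs_df["survived"]
        smd_after = pd.Series(
            {c: _smd(X.loc[mt, c].to_numpy(), X.loc[mc, c].to_numpy()) for c in covariates}
        )
    else:
        smd_after = pd.Series(dtype=float)
    return MatchResult(pairs=pairs_df, scores=scores, smd_before=smd_before, smd_after=smd_after)


# ---------------------------------------------------------------------------
# survival + correlation

def cox_association(
    estimates: pd.Series,
    phenotype: pd.DataFrame,
    estimator: str | None = None,
    covariates: list[str] | None = None,
    penalizer: float = 0.0,
) -> dict:
    """Cox proportional-hazards association of an estimator with mortality.

    Partial-likelihood fit with Efron tie handling; returns the hazard ratio
    per unit of the estimator with a 95% Wald interval. A small ridge
    `penalizer` stabilizes heavily covariate-adjusted fits when events are
    scarce relative to coefficients.
    """
    import warnings

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    name = estimator or estimates.name or "estimate"
    covariates = covariates or []
    df = pd.DataFrame(
        {
            name: estimates.reindex(phenotype.index).astype(float),
            "followup_time": phenotype["followup_time"].astype(float),
            "event": phenotype["event"].astype(int),
        }
    )
    for c in covariates:
        col = phenotype[c]
        if col.dtype == object:
            col = col.map({"M": 1, "F": 0}).fillna(col)
        df[c] = pd.to_numeric(col)
    df = df.dropna()
    constant = [c for c in covariates if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"{name}: dropping constant covariates {constant}")
        df = df.drop(columns=constant)
        covariates = [c for c in covariates if c not in constant]
    n_coef = 1 + len(covariates)
    if df["event"].sum() < n_coef:
        warnings.warn(
            f"{name}: {int(df['event'].sum())} events for {n_coef} coefficients; estimates unstable"
        )
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="followup_time", event_col="event")
    except ConvergenceError as e:
        hint = "" if penalizer else " (consider a small ridge penalizer)"
        raise RuntimeError(f"{name}: Cox fit did not converge{hint}: {e}") from e
    s = cph.summary.loc[name]
    return {
        "estimator": name,
        "log_hr": float(s["coef"]),
        "hr": float(s["exp(coef)"]),
        "hr_ci_low": float(s["exp(coef) lower 95%"]),
        "hr_ci_high": float(s["exp(coef) upper 95%"]),
        "p_value": float(s["p"]),
        "n": int(df.shape[0]),
        "n_events": int(df["event"].sum()),
        "covariates": covariates,
    }


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; returns (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 paired finite values")
    xr = stats.rankdata(x[ok])
    yr = stats.rankdata(y[ok])
    if np.var(xr) == 0 or np.var(yr) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)
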