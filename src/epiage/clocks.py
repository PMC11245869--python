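"""Coefficient-driven DNAm estimator engine.

One generic linear engine serves every CpG-weighted estimator: age clocks
(with or without the adult/juvenile log-linear age transform), pace-of-aging
measures, DNAm telomere-length surrogates, plasma-protein EpiScores and CRP
methylation scores. They differ only in their coefficient file, output
transform and units. PC-clocks additionally carry a centering vector and a
probe x component rotation, and weight the projected components.

Coefficient file format (CSV)::

    # name: my_clock
    # intercept: 12.5
    # transform: identity          (or horvath_age:20)
    # standardize: false
    # missing_policy: impute_cohort_mean
    probe_id,weight[,reference_mean]
    cg0001,0.25,
    ...

PC models are a trio of CSVs: center (probe_id,center), rotation
(probe_id,PC1..PCk) and weights (component,weight with name/intercept
metadata in comment lines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClockModel",
    "PCClockModel",
    "load_clock_model",
    "save_clock_model",
    "load_pc_clock_model",
    "save_pc_clock_model",
    "compute_linear_estimate",
    "compute_pc_estimate",
    "horvath_age_transform",
    "age_acceleration",
]

TRANSFORMS = ("identity", "horvath_age")
MISSING_POLICIES = ("error", "impute_reference_mean", "impute_cohort_mean")


class ClockModelError(ValueError):
    pass


class MissingProbesError(ClockModelError):
    def __init__(self, name: str, probes: list[str]):
        self.probes = probes
        super().__init__(
            f"model {name!r}: {len(probes)} model probes absent from beta matrix "
            f"(first few: {probes[:5]})"
        )


@dataclass
class ClockModel:
    """A linear CpG-weighted estimator."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    transform: str = "identity"          # "identity" | "horvath_age"
    adult_age: float = 20.0              # only used by horvath_age
    missing_policy: str = "impute_cohort_mean"
    standardize: bool = False            # z-scale betas per probe before weighting
    reference_means: dict[str, float] | None = None

    def __post_init__(self):
        if not self.coefficients and self.intercept is None:
            raise ClockModelError(f"model {self.name!r}: empty coefficient map")
        if self.transform not in TRANSFORMS:
            raise ClockModelError(f"model {self.name!r}: unknown transform {self.transform!r}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ClockModelError(
                f"model {self.name!r}: unknown missing policy {self.missing_policy!r}"
            )
        if self.missing_policy == "impute_reference_mean" and not self.reference_means:
            raise ClockModelError(
                f"model {self.name!r}: impute_reference_mean requires reference means"
            )


@dataclass
class PCClockModel:
    """A principal-component clock: project centered betas, weight components."""

    name: str
    intercept: float
    center: pd.Series                 # probe -> centering value
    rotation: pd.DataFrame            # probes x components
    component_weights: pd.Series      # component -> weight

    def __post_init__(self):
        if not set(self.rotation.index) <= set(self.center.index):
            raise ClockModelError(f"model {self.name!r}: rotation probes not subset of center probes")
        if not set(self.component_weights.index) <= set(self.rotation.columns):
            raise ClockModelError(
                f"model {self.name!r}: weighted components missing from rotation"
            )


def horvath_age_transform(x, adult_age: float = 20.0):
    """Invert the log-linear juvenile/adult age warp back to years.

    Negative warped values map through (1+adult_age)*exp(x)-1 (juvenile,
    limit -1 as x -> -inf); non-negative values map linearly. Continuous at 0
    with value adult_age.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, (1.0 + adult_age) * np.exp(np.minimum(x, 0.0)) - 1.0,
                   (1.0 + adult_age) * x + adult_age)
    return out if out.ndim else float(out)


def _parse_metadata(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise ClockModelError(f"{path}:{lineno}: malformed metadata line {line!r}")
            key, value = body.split(":", 1)
            meta[key.strip()] = value.strip()
    return meta, n_comment


def load_clock_model(path: str | Path) -> ClockModel:
    path = Path(path)
    meta, skip = _parse_metadata(path)
    df = pd.read_csv(path, skiprows=skip)
    if "probe_id" not in df.columns or "weight" not in df.columns:
        raise ClockModelError(f"{path}: need probe_id and weight columns")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        first = df.index[df["probe_id"] == dup.iloc[0]][1] + skip + 2
        raise ClockModelError(f"{path}:{first}: duplicate probe {dup.iloc[0]!r}")
    transform = meta.get("transform", "identity")
    adult_age = 20.0
    if transform.startswith("horvath_age"):
        if ":" in transform:
            transform, aa = transform.split(":", 1)
            adult_age = float(aa)
        transform = "horvath_age"
    refs = None
    if "reference_mean" in df.columns and df["reference_mean"].notna().any():
        refs = dict(zip(df["probe_id"], df["reference_mean"].astype(float)))
    try:
        return ClockModel(
            name=meta.get("name", path.stem),
            intercept=float(meta.get("intercept", 0.0)),
            coefficients=dict(zip(df["probe_id"], df["weight"].astype(float))),
            transform=transform,
            adult_age=adult_age,
            missing_policy=meta.get("missing_policy", "impute_cohort_mean"),
            standardize=meta.get("standardize", "false").lower() in ("true", "1", "yes"),
            reference_means=refs,
        )
    except ClockModelError:
        raise
    except ValueError as e:
        raise ClockModelError(f"{path}: {e}") from e


def save_clock_model(model: ClockModel, path: str | Path) -> None:
    path = Path(path)
    transform = model.transform
    if transform == "horvath_age":
        transform = f"horvath_age:{model.adult_age:g}"
    with open(path, "w") as fh:
        fh.write(f"# name: {model.name}\n")
        fh.write(f"# intercept: {float(model.intercept)!r}\n")
        fh.write(f"# transform: {transform}\n")
        fh.write(f"# standardize: {str(model.standardize).lower()}\n")
        fh.write(f"# missing_policy: {model.missing_policy}\n")
        has_ref = model.reference_means is not None
        fh.write("probe_id,weight" + (",reference_mean" if has_ref else "") + "\n")
        for probe, w in model.coefficients.items():
            row = f"{probe},{float(w)!r}"
            if has_ref:
                row += f",{float(model.reference_means[probe])!r}" if probe in model.reference_means else ","
            fh.write(row + "\n")


def _model_betas(beta: pd.DataFrame, probes: list[str], model_name: str,
                 policy: str, reference_means: dict[str, float] | None) -> pd.DataFrame:
    """Betas restricted to model probes, missing rows handled per policy."""
    missing = [p for p in probes if p not in beta.index]
    if missing and policy == "error":
        raise MissingProbesError(model_name, missing)
    sub = beta.reindex(probes)
    if missing:
        if policy == "impute_reference_mean":
            fill = pd.Series({p: (reference_means or {}).get(p, np.nan) for p in missing})
            if fill.isna().any():
                raise MissingProbesError(model_name, fill.index[fill.isna()].tolist())
            for p in missing:
                sub.loc[p] = fill[p]
        else:  # impute_cohort_mean: no cohort values exist for an absent probe;
            # fall back to 0.5 (uninformative methylation fraction)
            sub.loc[missing] = 0.5
    # per-sample missing cells -> cohort (row) mean
    if sub.isna().any().any():
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    return sub


def compute_linear_estimate(beta: pd.DataFrame, model: ClockModel) -> pd.Series:
    """intercept + sum_i w_i * beta_i per sample, then the model's transform."""
    probes = list(model.coefficients)
    if probes:
        sub = _model_betas(beta, probes, model.name, model.missing_policy, model.reference_means)
        if model.standardize:
            mu = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
            sub = sub.sub(mu, axis=0).div(sd, axis=0)
        w = np.array([model.coefficients[p] for p in probes])
        raw = model.intercept + sub.to_numpy().T @ w
    else:
        raw = np.full(beta.shape[1], model.intercept, dtype=float)
    if model.transform == "horvath_age":
        raw = horvath_age_transform(raw, model.adult_age)
    return pd.Series(raw, index=beta.columns, name=model.name)


def compute_pc_estimate(beta: pd.DataFrame, model: PCClockModel) -> pd.Series:
    """intercept + sum_k w_k (rotation^T (beta - center))_k per sample."""
    probes = list(model.center.index)
    sub = _model_betas(beta, probes, model.name, "impute_cohort_mean", None)
    centered = sub.to_numpy() - model.center.to_numpy()[:, None]
    rot = model.rotation.reindex(index=probes).fillna(0.0)
    comps = rot.to_numpy().T @ centered                     # components x samples
    w = model.component_weights.reindex(rot.columns).fillna(0.0).to_numpy()
    vals = model.intercept + w @ comps
    return pd.Series(vals, index=beta.columns, name=model.name)


def save_pc_clock_model(model: PCClockModel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    model.center.rename("center").to_csv(prefix.with_suffix(".center.csv"), index_label="probe_id")
    model.rotation.to_csv(prefix.with_suffix(".rotation.csv"), index_label="probe_id")
    with open(prefix.with_suffix(".weights.csv"), "w") as fh:
        fh.write(f"# name: {model.name}\n# intercept: {float(model.intercept)!r}\n")
        fh.write("component,weight\n")
        for comp, w in model.component_weights.items():
            fh.write(f"{comp},{float(w)!r}\n")


def load_pc_clock_model(prefix: str | Path) -> PCClockModel:
    prefix = Path(prefix)
    center = pd.read_csv(prefix.with_suffix(".center.csv"), index_col="probe_id")["center"]
    rotation = pd.read_csv(prefix.with_suffix(".rotation.csv"), index_col="probe_id")
    wpath = prefix.with_suffix(".weights.csv")
    meta, skip = _parse_metadata(wpath)
    weights = pd.read_csv(wpath, skiprows=skip, index_col="component")["weight"]
    return PCClockModel(
        name=meta.get("name", prefix.stem),
        intercept=float(meta.get("intercept", 0.0)),
        center=center,
        rotation=rotation,
        component_weights=weights,
    )


def age_acceleration(
    estimates: pd.Series,
    chronological_age: pd.Series,
    cell_counts: pd.DataFrame | None = None,
) -> pd.Series:
    """Residuals of the estimate regressed on chronological age.

    With cell-count columns supplied the residual is the intrinsic variant
    (adjusted for estimated cell composition as well as age). Residuals sum
    to zero by the OLS normal equations.
    """
    import statsmodels.api as sm

    idx = estimates.index
    if chronological_age.reindex(idx).isna().any():
        raise ValueError("missing chronological ages")
    if len(idx) < 3:
        raise ValueError("need at least 3 samples for age acceleration")
    X = pd.DataFrame({"age": chronological_age.reindex(idx).astype(float)}, index=idx)
    if cell_counts is not None:
        X = X.join(cell_counts.reindex(idx).astype(float))
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(f"collinear design in age-acceleration regression: columns {list(Xc.columns)}")
    fit = sm.OLS(estimates.astype(float), Xc).fit()
    resid = fit.resid
    resid.name = f"{estimates.name}_accel" if estimates.name else "accel"
    return resid
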