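"""Sample QC and the probe-filter cascade for EPIC-like beta matrices.

The cascade applies independent predicates, so ordering does not change the
final probe set: detection-p failures (p > 0.01 in at least one sample), sex
chromosomes, SNP-mapping probes, blacklist flags (cross-reactive,
non-specific, variant-containing, masked), and finally a multimodality
screen that drops probes whose beta distribution is bi-/tri-modal in any sex
stratum of the survived group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dip import dip_pvalue, dip_statistic, null_dip_distribution
from .io import FLAG_COLUMNS

__all__ = [
    "FilterReport",
    "compute_beta",
    "sample_qc",
    "probe_filter",
    "multimodality_filter",
]


@dataclass
class FilterReport:
    """Ordered record of removals; counts must reconcile with dimensions."""

    n_input: int
    rules: list[tuple[str, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add(self, rule: str, n_removed: int) -> None:
        self.rules.append((rule, int(n_removed)))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.rules)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "rules": [{"rule": r, "n_removed": n} for r, n in self.rules],
            "params": self.params,
        }


def compute_beta(
    methylated: pd.DataFrame, unmethylated: pd.DataFrame, offset: float = 100.0
) -> pd.DataFrame:
    """beta = M / (M + U + offset); the offset stabilises low-intensity probes."""
    if not methylated.index.equals(unmethylated.index) or not methylated.columns.equals(
        unmethylated.columns
    ):
        raise ValueError("methylated/unmethylated matrices are not conformable")
    m = methylated.to_numpy(dtype=float)
    u = unmethylated.to_numpy(dtype=float)
    if np.nanmin(m) < 0 or np.nanmin(u) < 0:
        raise ValueError("negative intensities")
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / denom, np.nan)
    return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)


def sample_qc(detp: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], FilterReport]:
    """Keep samples whose mean probe detection p-value is below alpha."""
    if detp.size == 0:
        raise ValueError("empty detection p-value matrix")
    mean_p = detp.mean(axis=0)
    keep = mean_p.index[mean_p < alpha].tolist()
    report = FilterReport(n_input=detp.shape[1], params={"alpha": alpha, "axis": "samples"})
    report.add(f"mean_detection_p>={alpha}", detp.shape[1] - len(keep))
    return keep, report


def probe_filter(
    detp: pd.DataFrame,
    annotation: pd.DataFrame,
    detp_threshold: float = 0.01,
    blacklists: dict[str, set[str]] | None = None,
    on_missing_annotation: str = "error",
) -> tuple[list[str], FilterReport]:
    """Drop probes failing detection in any sample, on sex chromosomes, or flagged.

    `blacklists` maps a category name to a set of probe ids (plain-text lists);
    they are OR-ed with the corresponding annotation flag columns.
    """
    probes = detp.index
    missing = probes.difference(annotation.index)
    if len(missing):
        if on_missing_annotation == "error":
            raise ValueError(
                f"{len(missing)} probes absent from annotation (first: {missing[:3].tolist()})"
            )
        warnings.warn(f"{len(missing)} probes missing annotation treated as unflagged")
    ann = annotation.reindex(probes)

    fail_detp = (detp > detp_threshold).any(axis=1)
    flags = {c: ann[c].map(lambda v: bool(v) if pd.notna(v) else False) for c in FLAG_COLUMNS}
    if blacklists:
        for cat, ids in blacklists.items():
            hit = probes.isin(ids)
            flags[cat] = flags.get(cat, pd.Series(False, index=probes)) | hit

    report = FilterReport(
        n_input=len(probes),
        params={"detp_threshold": detp_threshold, "axis": "probes"},
    )
    drop = pd.Series(False, index=probes)
    for rule, mask in [(f"detection_p>{detp_threshold}_in_any_sample", fail_detp)] + [
        (name, m) for name, m in flags.items()
    ]:
        newly = mask & ~drop
        report.add(rule, int(newly.sum()))
        drop |= mask
    keep = probes[~drop].tolist()
    return keep, report


def multimodality_filter(
    beta: pd.DataFrame,
    phenotype: pd.DataFrame,
    method: str = "dip",
    alpha: float = 0.05,
    min_stratum: int = 5,
    n_null: int = 1000,
    max_components: int = 3,
    seed: int = 0,
) -> tuple[list[str], FilterReport]:
    """Drop probes multimodal in any sex stratum of the survived group.

    method="dip": Hartigan's dip with a Monte-Carlo uniform null at the
    stratum's sample size. method="gmm": Gaussian mixtures on M-values with
    BIC model selection (multimodal iff a 2- or 3-component fit wins).
    """
    if method not in ("dip", "gmm"):
        raise ValueError(f"unknown multimodality method {method!r}")
    survived = phenotype.index[phenotype["group"] == "survived"]
    strata = []
    for sex, members in phenotype.loc[survived].groupby("sex").groups.items():
        cols = [s for s in members if s in beta.columns]
        if len(cols) < min_stratum:
            warnings.warn(f"sex stratum {sex!r} has {len(cols)} survivors < {min_stratum}; skipped")
            continue
        strata.append((sex, cols))

    drop = pd.Series(False, index=beta.index)
    rng = np.random.default_rng(seed)
    for sex, cols in strata:
        vals = beta[cols].to_numpy()
        if method == "dip":
            null = null_dip_distribution(len(cols), n_null, rng)
            crit = np.quantile(null, 1 - alpha)
            for i in range(vals.shape[0]):
                x = vals[i][~np.isnan(vals[i])]
                if x.size >= 4 and dip_statistic(x) > crit:
                    drop.iloc[i] = True
        else:
            drop |= _gmm_multimodal(vals, max_components, rng)

    report = FilterReport(
        n_input=beta.shape[0],
        params={
            "method": method,
            "alpha": alpha,
            "min_stratum": min_stratum,
            "n_null": n_null,
            "strata": [sex for sex, _ in strata],
            "axis": "probes",
        },
    )
    report.add("multimodal_in_any_survived_sex_stratum", int(drop.sum()))
    return beta.index[~drop].tolist(), report


def _gmm_multimodal(vals: np.ndarray, max_components: int, rng) -> pd.Series | np.ndarray:
    from sklearn.mixture import GaussianMixture

    out = np.zeros(vals.shape[0], dtype=bool)
    for i in range(vals.shape[0]):
        x = vals[i][~np.isnan(vals[i])]
        if x.size < 6 or np.ptp(x) == 0:
            continue
        m = np.log2(np.clip(x, 1e-6, 1 - 1e-6) / (1 - np.clip(x, 1e-6, 1 - 1e-6)))
        X = m.reshape(-1, 1)
        bics = []
        for k in range(1, max_components + 1):
            gm = GaussianMixture(n_components=k, random_state=int(rng.integers(2**31)), n_init=1)
            gm.fit(X)
            bics.append(gm.bic(X))
        out[i] = int(np.argmin(bics)) > 0
    return out
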