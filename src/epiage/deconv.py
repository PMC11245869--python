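"""Reference-based blood cell-type deconvolution.

Per sample, the observed betas on the reference probes are modelled as a
mixture beta ~ R f of purified cell-type profiles. Fractions are estimated
by non-negative least squares; the sum-to-one constraint is imposed via a
heavily weighted augmentation row (Lawson-Hanson trick) followed by exact
renormalization, which is exact on noiseless mixtures and keeps the simplex
constraints to machine precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["estimate_cell_fractions"]

CONSTRAINTS = ("nonneg", "nonneg_sum_to_one")


def estimate_cell_fractions(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
    constraint: str = "nonneg_sum_to_one",
    min_overlap: int | None = None,
    sum_weight: float = 1e4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate per-sample cell-type fractions from a purified reference panel.

    Returns (fractions: samples x cell types, residual norm per sample on the
    shared probes).
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"constraint must be one of {CONSTRAINTS}")
    if reference.shape[1] < 2:
        raise ValueError("reference needs at least 2 cell types")
    shared = beta.index.intersection(reference.index)
    need = min_overlap if min_overlap is not None else reference.shape[1]
    if len(shared) < need:
        raise ValueError(
            f"only {len(shared)} probes shared between beta matrix and reference "
            f"(need >= {need})"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    B = beta.loc[shared].to_numpy(dtype=float)

    k = R.shape[1]
    fracs = np.empty((beta.shape[1], k))
    resid = np.empty(beta.shape[1])
    for j in range(beta.shape[1]):
        y = B[:, j]
        ok = ~np.isnan(y)
        if constraint == "nonneg_sum_to_one":
            A = np.vstack([R[ok], np.full((1, k), sum_weight)])
            b = np.concatenate([y[ok], [sum_weight]])
            f, _ = nnls(A, b)
            s = f.sum()
            if s > 0:
                f = f / s
        else:
            f, _ = nnls(R[ok], y[ok])
        fracs[j] = f
        resid[j] = float(np.linalg.norm(R[ok] @ f - y[ok]))
    fr = pd.DataFrame(fracs, index=beta.columns, columns=reference.columns)
    return fr, pd.Series(resid, index=beta.columns, name="residual_norm")
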