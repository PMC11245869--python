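"""Seeded synthetic EPIC-like methylation cohorts.

Emulates the statistical structure the downstream analysis assumes: a matched
two-group cohort (survived / deceased), beta values generated as
logistic-transformed Gaussian M-values with the canonical bimodal methylome,
planted differentially methylated positions (group mean shifts calibrated on
the beta scale), variance-inflated positions, spatially clustered region
effects, bimodal probes, reference-mixed cell-composition probes, clock CpGs
driven by a latent per-sample aging acceleration, mild batch effects,
detection p-values with optional engineered failures, and
exponential-hazard survival times in which the log-hazard is linear in the
latent acceleration.

Everything derives deterministically from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .clocks import ClockModel, save_clock_model
from . import io as eio

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset", "make_toy_clock"]

LN2 = np.log(2.0)

CELL_TYPES = ("granulocytes", "CD4T", "CD8_naive", "CD8_exhausted", "NK", "plasma_blasts")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the matched type-2-diabetes cohort design the pipeline
    targets: 27 survived / 23 deceased samples followed 16.8 years, planted
    group effects of |delta beta| = 0.10, 16-fold variance inflation for
    variable positions, and 500 bp clustered regions.
    """

    n_survived: int = 27
    n_deceased: int = 23
    n_probes: int = 20_000
    n_dmp: int = 50
    dmp_delta_beta: float = 0.10
    n_dvp: int = 50
    dvp_variance_ratio: float = 16.0
    n_dmr_regions: int = 5
    dmr_probes_per_region: int = 5
    dmr_span_bp: int = 500
    dmr_within_region_corr: float = 0.5
    bimodal_fraction: float = 0.01
    n_celltypes: int = 6
    n_cell_probes: int = 200
    dirichlet_alpha: tuple[float, ...] = (6.0, 3.0, 1.5, 0.8, 2.5, 0.5)
    cell_noise_sd: float = 0.01
    batch_levels: int = 2
    batch_effect_sd: float = 0.05
    clock_n_cpgs: int = 50
    clock_beta_noise_sd: float = 0.01
    clock_gain_years: float = 5.0
    clock_mean_years: float = 60.0
    hazard_per_accel_unit: float = 0.75
    baseline_hazard: float = 0.037
    followup_years: float = 16.8
    n_failed_samples: int = 0
    probe_fail_fraction: float = 0.0
    sex_chromosome_fraction: float = 0.0
    blacklist_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_survived": self.n_survived,
            "n_deceased": self.n_deceased,
            "n_probes": self.n_probes,
            "n_dmp": self.n_dmp,
            "n_dvp": self.n_dvp,
            "n_dmr_regions": self.n_dmr_regions,
            "dmr_probes_per_region": self.dmr_probes_per_region,
            "clock_n_cpgs": self.clock_n_cpgs,
            "n_cell_probes": self.n_cell_probes,
            "n_failed_samples": self.n_failed_samples,
        }
        for k, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{k} must be >= 0, got {v}")
        if not (0.0 < self.dmp_delta_beta < 1.0):
            raise ConfigurationError(f"dmp_delta_beta must be in (0,1), got {self.dmp_delta_beta}")
        if self.dvp_variance_ratio <= 0:
            raise ConfigurationError("dvp_variance_ratio must be positive")
        if len(self.dirichlet_alpha) != self.n_celltypes:
            raise ConfigurationError(
                f"dirichlet_alpha length {len(self.dirichlet_alpha)} != n_celltypes {self.n_celltypes}"
            )
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigurationError("dirichlet_alpha entries must be positive")
        if self._probe_budget() > self.n_probes:
            raise ConfigurationError(
                f"probe budget {self._probe_budget()} exceeds n_probes {self.n_probes}"
            )

    def _probe_budget(self) -> int:
        return (
            self.n_dmp
            + self.n_dvp
            + self.n_dmr_regions * self.dmr_probes_per_region
            + int(round(self.bimodal_fraction * self.n_probes))
            + self.clock_n_cpgs
            + self.n_cell_probes
        )


@dataclass
class SyntheticDataset:
    """One simulated cohort plus its ground truth."""

    config: SimulationConfig
    beta: pd.DataFrame                    # probes x samples, in (0,1)
    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detp: pd.DataFrame
    phenotype: pd.DataFrame               # indexed by sample_id
    annotation: pd.DataFrame              # indexed by probe_id
    probe_truth: pd.DataFrame             # label / region / true effect per probe
    sample_truth: pd.DataFrame            # latent acceleration + true cell fractions
    cell_reference: pd.DataFrame          # probes x cell types
    clock: ClockModel

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("beta", self.beta), ("detp", self.detp),
            ("methylated", self.methylated), ("unmethylated", self.unmethylated),
            ("cell_reference", self.cell_reference),
            ("probe_truth", self.probe_truth), ("sample_truth", self.sample_truth),
        ]:
            p = out / f"{name}.tsv"
            eio.write_matrix_tsv(df, p) if name in ("beta", "detp", "methylated", "unmethylated", "cell_reference") else df.to_csv(p, sep="\t")
            paths[name] = str(p)
        eio.write_phenotype_csv(self.phenotype, out / "phenotype.csv")
        paths["phenotype"] = str(out / "phenotype.csv")
        eio.write_annotation_bed(self.annotation, out / "annotation.bed.tsv")
        paths["annotation"] = str(out / "annotation.bed.tsv")
        save_clock_model(self.clock, out / "toy_clock.csv")
        paths["clock"] = str(out / "toy_clock.csv")
        return paths


# ---------------------------------------------------------------------------
# beta-scale calibration of M-value shifts

_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _mean_beta(mu_m: float, sd_m: float) -> float:
    """E[expit(ln2 * M)] for M ~ N(mu, sd^2), by Gauss-Hermite quadrature."""
    return float(_GH_WEIGHTS @ expit(LN2 * (mu_m + sd_m * _GH_NODES)))


def _calibrate_m_shift(mu_m: float, sd_m: float, target_delta: float) -> float:
    """Shift d on the M scale so the induced beta-scale mean difference is target_delta."""
    base = _mean_beta(mu_m, sd_m)
    target = base + target_delta
    if not (0.0 < target < 1.0):
        raise ConfigurationError(
            f"delta beta {target_delta:+.3f} infeasible from baseline mean beta {base:.3f}"
        )
    f = lambda d: _mean_beta(mu_m + d, sd_m) - target
    lo, hi = (0.0, 1.0) if target_delta > 0 else (-1.0, 0.0)
    while f(hi) < 0 if target_delta > 0 else f(lo) > 0:
        lo, hi = (lo, hi * 2) if target_delta > 0 else (lo * 2, hi)
        if abs(hi) > 60 or abs(lo) > 60:
            raise ConfigurationError("M-shift calibration diverged")
    return brentq(f, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------


def _probe_blocks(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Deterministic index blocks for each planted-probe class."""
    n_bimodal = int(round(config.bimodal_fraction * config.n_probes))
    sizes = {
        "dmp": config.n_dmp,
        "dvp": config.n_dvp,
        "dmr": config.n_dmr_regions * config.dmr_probes_per_region,
        "bimodal": n_bimodal,
        "clock": config.clock_n_cpgs,
        "cell": config.n_cell_probes,
    }
    blocks, start = {}, 0
    for name, size in sizes.items():
        blocks[name] = np.arange(start, start + size)
        start += size
    blocks["null"] = np.arange(start, config.n_probes)
    return blocks


def _clock_architecture(config: SimulationConfig):
    """Deterministic clock-probe basal betas, slopes and weights (own substream)."""
    rng = np.random.default_rng([config.seed, 2])
    k = config.clock_n_cpgs
    b0 = rng.uniform(0.3, 0.7, size=k)
    c = rng.uniform(0.01, 0.03, size=k) * rng.choice([-1.0, 1.0], size=k)
    if k:
        w = c * (config.clock_gain_years / np.sum(c**2))
        intercept = config.clock_mean_years - float(w @ b0)
    else:
        w = np.zeros(0)
        intercept = config.clock_mean_years
    return b0, c, w, intercept


def make_toy_clock(config: SimulationConfig) -> ClockModel:
    """A linear clock whose value is affine in the cohort's latent acceleration.

    With zero probe noise the clock equals clock_mean_years +
    clock_gain_years * acceleration exactly on simulated samples.
    """
    config.validate()
    if config.clock_n_cpgs > config.n_probes:
        raise ConfigurationError("clock_n_cpgs exceeds n_probes")
    blocks = _probe_blocks(config)
    probe_ids = [f"cg{i:08d}" for i in blocks["clock"]]
    b0, c, w, intercept = _clock_architecture(config)
    return ClockModel(
        name="toy_accel_clock",
        intercept=intercept,
        coefficients=dict(zip(probe_ids, w)),
        transform="identity",
        missing_policy="impute_cohort_mean",
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    n_core = config.n_survived + config.n_deceased
    n_total = n_core + config.n_failed_samples
    P = config.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(P)], name="probe_id")

    blocks = _probe_blocks(config)

    # ---- latent survival structure on the core cohort -----------------------
    accel = rng.normal(size=n_core)
    rate = config.baseline_hazard * np.exp(config.hazard_per_accel_unit * accel)
    latent_t = rng.exponential(1.0 / rate)
    order = np.argsort(latent_t)
    deceased_idx = np.sort(order[: config.n_deceased])
    is_deceased = np.zeros(n_core, dtype=bool)
    is_deceased[deceased_idx] = True
    times = np.full(n_core, config.followup_years)
    if config.n_deceased:
        tmax = latent_t[deceased_idx].max()
        scale = min(1.0, 0.99 * config.followup_years / tmax) if tmax > 0 else 1.0
        times[deceased_idx] = np.maximum(latent_t[deceased_idx] * scale, 1e-3)
    events = is_deceased.astype(int)

    # engineered QC-failure samples appended after the core cohort
    group = np.where(is_deceased, "deceased", "survived")
    accel_all = np.concatenate([accel, rng.normal(size=config.n_failed_samples)])
    group_all = np.concatenate([group, np.array(["survived", "deceased"] * n_total)[: config.n_failed_samples]])
    times_all = np.concatenate([times, np.full(config.n_failed_samples, config.followup_years)])
    events_all = np.concatenate([events, np.zeros(config.n_failed_samples, dtype=int)])
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n_total)], name="sample_id")
    dec_mask = group_all == "deceased"

    # ---- phenotype sheet -----------------------------------------------------
    age = rng.integers(55, 71, size=n_total).astype(float)
    sex = rng.choice(["M", "F"], size=n_total)
    complications = rng.random(n_total) < 0.3
    batch = np.arange(n_total) % max(config.batch_levels, 1)
    phenotype = pd.DataFrame(
        {
            "group": group_all,
            "age": age,
            "sex": sex,
            "complications": complications.astype(int),
            "hba1c": np.round(rng.normal(7.1, 0.4, n_total), 2),
            "egfr": np.round(rng.normal(83, 12, n_total), 1),
            "hs_crp": np.round(np.exp(rng.normal(0.8, 0.6, n_total)), 2),
            "ldl_c": np.round(rng.normal(115, 20, n_total), 0),
            "disease_duration": np.round(rng.uniform(3, 25, n_total), 1),
            "bmi": np.round(rng.normal(27.5, 2.5, n_total), 1),
            "hypertension": (rng.random(n_total) < 0.5).astype(int),
            "smoking": np.zeros(n_total, dtype=int),
            "batch": batch,
            "followup_time": np.round(times_all, 4),
            "event": events_all,
        },
        index=sample_ids,
    )

    # ---- annotation ----------------------------------------------------------
    annotation = _make_annotation(config, probe_ids, blocks, rng)

    # ---- per-probe baseline M-value architecture ----------------------------
    mu = np.empty(P)
    comp = rng.choice(3, size=P, p=[0.45, 0.45, 0.10])
    mu[comp == 0] = rng.normal(-3.0, 1.0, np.sum(comp == 0))
    mu[comp == 1] = rng.normal(3.0, 1.0, np.sum(comp == 1))
    mu[comp == 2] = rng.normal(0.0, 1.0, np.sum(comp == 2))
    sd = rng.uniform(0.25, 0.6, size=P)
    # effect probes need intermediate methylation for beta-scale shifts to exist
    for key in ("dmp", "dvp", "dmr"):
        idx = blocks[key]
        mu[idx] = rng.normal(0.0, 0.8, size=idx.size)
        sd[idx] = rng.uniform(0.3, 0.5, size=idx.size)

    # ---- M-value noise + planted effects ------------------------------------
    M = mu[:, None] + sd[:, None] * rng.standard_normal((P, n_total))

    true_delta = np.zeros(P)
    sign = np.where(np.arange(config.n_dmp) % 3 == 0, 1.0, -1.0)  # ~1/3 hyper, 2/3 hypo
    for j, pi in enumerate(blocks["dmp"]):
        d = _calibrate_m_shift(mu[pi], sd[pi], sign[j] * config.dmp_delta_beta)
        M[pi, dec_mask] += d
        true_delta[pi] = sign[j] * config.dmp_delta_beta

    # variance inflation in the deceased group
    for pi in blocks["dvp"]:
        extra = np.sqrt(config.dvp_variance_ratio) - 1.0
        M[pi, dec_mask] = mu[pi] + (M[pi, dec_mask] - mu[pi]) * (1.0 + extra)

    # region effects: shared shift + correlated within-region residuals
    rho = config.dmr_within_region_corr
    k = config.dmr_probes_per_region
    for r in range(config.n_dmr_regions):
        members = blocks["dmr"][r * k : (r + 1) * k]
        u = rng.standard_normal(n_total)
        for pi in members:
            z = (M[pi] - mu[pi]) / sd[pi]  # existing iid noise
            M[pi] = mu[pi] + sd[pi] * (np.sqrt(1 - rho) * z + np.sqrt(rho) * u)
            d = _calibrate_m_shift(mu[pi], sd[pi], config.dmp_delta_beta)
            M[pi, dec_mask] += d
            true_delta[pi] = config.dmp_delta_beta

    # bimodal probes: two-mode mixture across samples
    for pi in blocks["bimodal"]:
        modes = rng.random(n_total) < 0.5
        M[pi] = np.where(modes, rng.normal(2.5, 0.4, n_total), rng.normal(-2.5, 0.4, n_total))

    # batch effect: small per-probe M shift for non-reference batches
    if config.batch_levels > 1 and config.batch_effect_sd > 0:
        beff = rng.normal(0.0, config.batch_effect_sd, size=(P, config.batch_levels))
        beff[:, 0] = 0.0
        M += beff[:, batch]

    beta = expit(LN2 * M)

    # ---- clock probes: beta affine in latent acceleration -------------------
    b0, c, w, intercept = _clock_architecture(config)
    clock_rows = blocks["clock"]
    if clock_rows.size:
        noise = config.clock_beta_noise_sd * rng.standard_normal((clock_rows.size, n_total))
        beta[clock_rows, :] = b0[:, None] + c[:, None] * accel_all[None, :] + noise

    # ---- cell-composition probes --------------------------------------------
    ref = rng.uniform(0.05, 0.95, size=(config.n_cell_probes, config.n_celltypes))
    fracs = rng.dirichlet(np.asarray(config.dirichlet_alpha), size=n_total)  # samples x types
    if config.n_cell_probes:
        mixed = ref @ fracs.T + config.cell_noise_sd * rng.standard_normal(
            (config.n_cell_probes, n_total)
        )
        beta[blocks["cell"], :] = mixed

    eps = 1e-4
    beta = np.clip(beta, eps, 1 - eps)

    if config.missing_fraction > 0:
        holes = rng.random(beta.shape) < config.missing_fraction
        beta = np.where(holes, np.nan, beta)

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)

    # ---- intensities consistent with beta = M/(M+U+100) ---------------------
    total = np.exp(rng.normal(8.5, 0.3, size=beta.shape))
    offset = 100.0
    meth = np.nan_to_num(beta, nan=0.5) * (total + offset)
    unmeth = total - meth
    unmeth = np.clip(unmeth, 0.0, None)
    meth_df = pd.DataFrame(meth, index=probe_ids, columns=sample_ids)
    unmeth_df = pd.DataFrame(unmeth, index=probe_ids, columns=sample_ids)

    # ---- detection p-values ---------------------------------------------------
    detp = np.minimum(rng.exponential(1e-5, size=beta.shape), 0.99)
    if config.n_failed_samples:
        detp[:, n_core:] = rng.uniform(0.05, 1.0, size=(P, config.n_failed_samples))
    if config.probe_fail_fraction > 0:
        n_fail = int(round(config.probe_fail_fraction * P))
        fail_probes = rng.choice(blocks["null"], size=min(n_fail, blocks["null"].size), replace=False)
        fail_sample = rng.integers(0, n_core, size=fail_probes.size)
        detp[fail_probes, fail_sample] = rng.uniform(0.02, 0.5, size=fail_probes.size)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)

    # ---- truth tables ---------------------------------------------------------
    label = np.full(P, "null", dtype=object)
    for key in ("dmp", "dvp", "dmr", "bimodal", "clock", "cell"):
        label[blocks[key]] = key
    region_id = np.full(P, -1)
    for r in range(config.n_dmr_regions):
        region_id[blocks["dmr"][r * k : (r + 1) * k]] = r
    probe_truth = pd.DataFrame(
        {
            "label": label,
            "region": region_id,
            "true_delta_beta": true_delta,
            "true_log2_variance_ratio": np.where(
                label == "dvp", np.log2(config.dvp_variance_ratio), 0.0
            ),
        },
        index=probe_ids,
    )
    sample_truth = pd.DataFrame(
        {"acceleration": accel_all, "qc_fail": np.arange(n_total) >= n_core},
        index=sample_ids,
    ).join(pd.DataFrame(fracs, index=sample_ids, columns=list(CELL_TYPES[: config.n_celltypes])))

    cell_reference = pd.DataFrame(
        ref, index=probe_ids[blocks["cell"]], columns=list(CELL_TYPES[: config.n_celltypes])
    )

    clock = ClockModel(
        name="toy_accel_clock",
        intercept=intercept,
        coefficients=dict(zip(probe_ids[clock_rows], w)),
        transform="identity",
        missing_policy="impute_cohort_mean",
    )

    return SyntheticDataset(
        config=config,
        beta=beta_df,
        methylated=meth_df,
        unmethylated=unmeth_df,
        detp=detp_df,
        phenotype=phenotype,
        annotation=annotation,
        probe_truth=probe_truth,
        sample_truth=sample_truth,
        cell_reference=cell_reference,
        clock=clock,
    )


def _make_annotation(config, probe_ids, blocks, rng) -> pd.DataFrame:
    P = config.n_probes
    chroms = np.empty(P, dtype=object)
    pos = np.empty(P, dtype=int)

    # DMR members live on their own contiguous stretch within dmr_span_bp
    dmr_set = set(blocks["dmr"].tolist())
    k = config.dmr_probes_per_region

    n_auto = 22
    per_chrom = int(np.ceil(P / n_auto))
    cursor = {}
    for i in range(P):
        chrom_i = f"chr{(i // per_chrom) + 1}"
        chroms[i] = chrom_i
        gap = int(rng.integers(1000, 5000))
        cursor[chrom_i] = cursor.get(chrom_i, 10_000) + gap
        pos[i] = cursor[chrom_i]
    for r in range(config.n_dmr_regions):
        members = blocks["dmr"][r * k : (r + 1) * k]
        if members.size < 2:
            continue
        chrom_i = chroms[members[0]]
        start = pos[members[0]]
        step = max(config.dmr_span_bp // max(members.size - 1, 1), 2)
        for j, pi in enumerate(members):
            chroms[pi] = chrom_i
            pos[pi] = start + j * step

    features = rng.choice(
        ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"],
        size=P,
        p=[0.15, 0.09, 0.15, 0.07, 0.40, 0.04, 0.10],
    )
    genes = np.where(
        features == "intergenic", None, [f"GENE{i % max(P // 8, 1)}" for i in range(P)]
    )
    ann = pd.DataFrame(
        {"chrom": chroms, "position": pos, "gene": genes, "feature": features},
        index=probe_ids,
    )
    null_idx = blocks["null"]
    for flag in eio.FLAG_COLUMNS:
        ann[flag] = False
    if config.sex_chromosome_fraction > 0:
        n_sex = int(round(config.sex_chromosome_fraction * P))
        sel = rng.choice(null_idx, size=min(n_sex, null_idx.size), replace=False)
        ann.iloc[sel, ann.columns.get_loc("chrom")] = "chrX"
        ann.iloc[sel, ann.columns.get_loc("on_sex_chromosome")] = True
    if config.blacklist_fraction > 0:
        n_bl = int(round(config.blacklist_fraction * P))
        sel = rng.choice(null_idx, size=min(n_bl, null_idx.size), replace=False)
        which = rng.choice(["cross_reactive", "non_specific", "variant_containing", "masked", "maps_to_snp"], size=sel.size)
        for pi, fl in zip(sel, which):
            ann.iloc[pi, ann.columns.get_loc(fl)] = True
    return ann
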