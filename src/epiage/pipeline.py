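"""End-to-end driver: simulate/ingest -> QC -> clocks+cells -> residual tests
-> DMP/DVP/DMR -> enrichment -> survival, with a provenance manifest.

Configuration is one YAML file of nested sections; unknown keys are
rejected. Stage toggles allow partial reruns on previously written outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clocks, deconv, diffmeth, inference, qc
from . import io as eio
from .synthetic import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class StageToggles:
    simulate: bool = True
    qc: bool = True
    estimates: bool = True
    residual_test: bool = True
    diffmeth: bool = True
    enrichment: bool = False
    cox: bool = True
    match: bool = False


@dataclass
class QCParams:
    sample_alpha: float = 0.05
    probe_detp_threshold: float = 0.01
    multimodality_method: str = "dip"
    multimodality_alpha: float = 0.05
    min_stratum: int = 5
    n_null: int = 1000
    beta_offset: float = 100.0


@dataclass
class DiffMethParams:
    covariates: tuple[str, ...] = ("age", "sex", "complications", "batch")
    include_cell_fractions: bool = True
    robust: bool = True
    moderate: bool = True
    bh_alpha: float = 0.05
    delta_beta_threshold: float = 0.05
    dvp_ratio_threshold: float = 2.0
    dvp_p_threshold: float = 1e-3
    dvp_log_base: float = 2.0
    combp_seed_p: float = 0.01
    combp_merge_dist_bp: int = 500
    combp_window_bp: int = 500


@dataclass
class InferenceParams:
    equal_var: bool = True
    iqr_k: float = 1.5
    cox_penalizer: float = 0.1
    fdr_flags: tuple[float, ...] = (0.05, 0.10)
    cox_covariates: tuple[str, ...] = (
        "age", "sex", "hypertension", "smoking", "bmi", "egfr",
        "hba1c", "hs_crp", "ldl_c", "disease_duration",
    )
    match_covariates: tuple[str, ...] = (
        "sex", "age", "hba1c", "egfr", "hs_crp", "ldl_c", "disease_duration", "bmi",
    )


@dataclass
class PipelineConfig:
    out_dir: str = "epiage_out"
    seed: int = 0
    stages: StageToggles = field(default_factory=StageToggles)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCParams = field(default_factory=QCParams)
    diffmeth: DiffMethParams = field(default_factory=DiffMethParams)
    inference: InferenceParams = field(default_factory=InferenceParams)
    # ingestion paths when simulation is off
    beta_path: str | None = None
    detp_path: str | None = None
    phenotype_path: str | None = None
    annotation_path: str | None = None
    clock_model_paths: tuple[str, ...] = ()
    cell_reference_path: str | None = None
    gmt_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc, d, where):
            if d is None:
                return dc()
            names = {f.name for f in fields(dc)}
            unknown = set(d) - names
            if unknown:
                raise ConfigError(f"unknown config keys in {where}: {sorted(unknown)}")
            kwargs = {}
            for f in fields(dc):
                if f.name not in d:
                    continue
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            return dc(**kwargs)

        nested = {
            "stages": StageToggles,
            "simulation": SimulationConfig,
            "qc": QCParams,
            "diffmeth": DiffMethParams,
            "inference": InferenceParams,
        }
        names = {f.name for f in fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        for key, val in raw.items():
            if key in nested:
                kwargs[key] = build(nested[key], val, key)
            else:
                kwargs[key] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, manifest: dict, key: str, cfg_hash: str,
                 index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)
    manifest["outputs"][key] = {"path": str(path), "rows": int(df.shape[0])}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order; returns the provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }

    def stage_done(name, t0, **info):
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3), **info})

    try:
        # ---- acquire data ---------------------------------------------------
        t0 = time.time()
        if config.stages.simulate:
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                from dataclasses import replace
                sim_cfg = replace(sim_cfg, seed=config.seed)
            ds = simulate_dataset(sim_cfg)
            beta, detp, phenotype, annotation = ds.beta, ds.detp, ds.phenotype, ds.annotation
            clock_models = [ds.clock]
            cell_reference = ds.cell_reference
            ds.write(out / "simulated")
            stage_done("simulate", t0, n_probes=beta.shape[0], n_samples=beta.shape[1])
        else:
            for req in ("beta_path", "phenotype_path", "annotation_path"):
                if getattr(config, req) is None:
                    raise ConfigError(f"simulation disabled and {req} not provided")
            beta = eio.read_matrix_tsv(config.beta_path)
            detp = eio.read_matrix_tsv(config.detp_path) if config.detp_path else None
            phenotype = eio.read_phenotype_csv(config.phenotype_path)
            annotation = eio.read_annotation_bed(config.annotation_path)
            clock_models = [clocks.load_clock_model(p) for p in config.clock_model_paths]
            cell_reference = (
                eio.read_matrix_tsv(config.cell_reference_path)
                if config.cell_reference_path
                else None
            )
            stage_done("ingest", t0, n_probes=beta.shape[0], n_samples=beta.shape[1])

        # ---- QC -------------------------------------------------------------
        if config.stages.qc:
            t0 = time.time()
            reports = {}
            if detp is not None:
                kept_samples, rep_s = qc.sample_qc(detp, alpha=config.qc.sample_alpha)
                reports["samples"] = rep_s.to_dict()
                beta = beta[kept_samples]
                detp = detp[kept_samples]
                phenotype = phenotype.loc[kept_samples]
                kept_probes, rep_p = qc.probe_filter(
                    detp, annotation, detp_threshold=config.qc.probe_detp_threshold
                )
                reports["probes"] = rep_p.to_dict()
                beta = beta.loc[kept_probes]
            kept_mm, rep_m = qc.multimodality_filter(
                beta,
                phenotype,
                method=config.qc.multimodality_method,
                alpha=config.qc.multimodality_alpha,
                min_stratum=config.qc.min_stratum,
                n_null=config.qc.n_null,
                seed=config.seed,
            )
            reports["multimodality"] = rep_m.to_dict()
            beta = beta.loc[kept_mm]
            eio.write_json_report(reports, out / "filter_report.json")
            manifest["outputs"]["filter_report"] = {
                "path": str(out / "filter_report.json"), "rows": len(reports)
            }
            _write_table(beta, out / "beta_filtered.tsv", manifest, "beta_filtered", cfg_hash, "probe_id")
            stage_done("qc", t0, n_probes=beta.shape[0], n_samples=beta.shape[1])

        # ---- estimates: clocks + cells --------------------------------------
        estimates = pd.DataFrame(index=beta.columns)
        cell_fracs = None
        if config.stages.estimates:
            t0 = time.time()
            for model in clock_models:
                estimates[model.name] = clocks.compute_linear_estimate(beta, model)
                accel = clocks.age_acceleration(estimates[model.name], phenotype["age"])
                estimates[f"{model.name}_accel"] = accel
            if cell_reference is not None:
                cell_fracs, _ = deconv.estimate_cell_fractions(beta, cell_reference)
                for c in cell_fracs.columns:
                    estimates[f"cell_{c}"] = cell_fracs[c]
            _write_table(estimates, out / "estimates.tsv", manifest, "estimates", cfg_hash, "sample_id")
            stage_done("estimates", t0, n_estimators=estimates.shape[1])

        # ---- residual-outcome tests ------------------------------------------
        if config.stages.residual_test and estimates.shape[1]:
            t0 = time.time()
            battery = inference.residual_outcome_battery(
                estimates, phenotype, equal_var=config.inference.equal_var
            )
            for q in config.inference.fdr_flags:
                battery[f"significant_q{q:g}"] = battery["bh_p_value"] < q
            _write_table(battery, out / "residual_tests.tsv", manifest, "residual_tests", cfg_hash, "estimator")
            stage_done("residual_test", t0, n_estimators=battery.shape[0])

        # ---- differential methylation ----------------------------------------
        if config.stages.diffmeth:
            t0 = time.time()
            covs = [c for c in config.diffmeth.covariates if c in phenotype.columns]
            pheno_dm = phenotype.copy()
            if config.diffmeth.include_cell_fractions and cell_fracs is not None:
                drop_last = cell_fracs.columns[-1]  # fractions sum to 1: drop one
                for c in cell_fracs.columns.drop(drop_last):
                    pheno_dm[f"cell_{c}"] = cell_fracs[c]
                    covs.append(f"cell_{c}")
            if "batch" in covs and pheno_dm["batch"].nunique() < 2:
                covs.remove("batch")
            if "batch" in covs:
                pheno_dm["batch"] = pheno_dm["batch"].astype(str).astype("category")
            dmp = diffmeth.dmp_test(
                beta, pheno_dm, covariates=covs,
                robust=config.diffmeth.robust, moderate=config.diffmeth.moderate,
                bh_alpha=config.diffmeth.bh_alpha,
                delta_beta_threshold=config.diffmeth.delta_beta_threshold,
            )
            _write_table(dmp, out / "dmp.tsv", manifest, "dmp", cfg_hash, "probe_id")
            dvp = diffmeth.dvp_test(
                beta, phenotype,
                log_base=config.diffmeth.dvp_log_base,
                ratio_threshold=config.diffmeth.dvp_ratio_threshold,
                p_threshold=config.diffmeth.dvp_p_threshold,
            )
            _write_table(dvp, out / "dvp.tsv", manifest, "dvp", cfg_hash, "probe_id")
            params = diffmeth.CombPParams(
                seed_p=config.diffmeth.combp_seed_p,
                merge_dist_bp=config.diffmeth.combp_merge_dist_bp,
                smooth_window_bp=config.diffmeth.combp_window_bp,
            )
            dmr = diffmeth.dmr_combp(dmp["p_value"], annotation.loc[beta.index], params)
            _write_table(dmr, out / "dmr.tsv", manifest, "dmr", cfg_hash)
            dmr_bed = dmr[["chrom", "start", "end", "sidak_p"]]
            dmr_bed.to_csv(out / "dmr.bed", sep="\t", header=False, index=False)
            genic = diffmeth.summarize_genic_distribution(dmp.index[dmp["is_dmp"]], annotation)
            _write_table(genic, out / "dmp_genic_distribution.tsv", manifest, "genic", cfg_hash, "feature")
            stage_done(
                "diffmeth", t0,
                n_dmp=int(dmp["is_dmp"].sum()), n_dvp=int(dvp["is_dvp"].sum()),
                n_dmr=int(dmr["is_significant"].sum()) if len(dmr) else 0,
            )

            if config.stages.enrichment and config.gmt_path:
                t0 = time.time()
                sets = eio.read_gmt(config.gmt_path)
                universe = annotation["gene"].dropna().unique().tolist()
                genes = (
                    annotation.loc[dmp.index[dmp["is_dmp"]], "gene"].dropna().unique().tolist()
                )
                enr = diffmeth.fisher_enrichment(genes, sets, universe)
                _write_table(enr, out / "enrichment.tsv", manifest, "enrichment", cfg_hash, "set")
                stage_done("enrichment", t0, n_sets=enr.shape[0])

        # ---- survival ---------------------------------------------------------
        if config.stages.cox and estimates.shape[1]:
            t0 = time.time()
            covs = [c for c in config.inference.cox_covariates if c in phenotype.columns]
            cox_out = {}
            for name in estimates.columns:
                if estimates[name].std() == 0:
                    continue
                try:
                    cox_out[name] = inference.cox_association(
                        estimates[name], phenotype, name, covariates=covs,
                        penalizer=config.inference.cox_penalizer,
                    )
                except RuntimeError as e:
                    cox_out[name] = {"error": str(e)}
            eio.write_json_report(cox_out, out / "cox.json")
            manifest["outputs"]["cox"] = {"path": str(out / "cox.json"), "rows": len(cox_out)}
            stage_done("cox", t0, n_estimators=len(cox_out))

        # ---- matching ---------------------------------------------------------
        if config.stages.match:
            t0 = time.time()
            covs = [c for c in config.inference.match_covariates if c in phenotype.columns]
            pheno_m = phenotype.copy()
            if "sex" in covs and pheno_m["sex"].dtype == object:
                pheno_m["sex"] = pheno_m["sex"].map({"M": 1, "F": 0})
            match = inference.propensity_match(pheno_m, covs)
            match.pairs.to_csv(out / "matched_pairs.csv", index=False)
            manifest["outputs"]["matched_pairs"] = {
                "path": str(out / "matched_pairs.csv"), "rows": int(match.pairs.shape[0])
            }
            smd = pd.DataFrame({"before": match.smd_before, "after": match.smd_after})
            _write_table(smd, out / "matching_smd.tsv", manifest, "matching_smd", cfg_hash, "covariate")
            stage_done("match", t0, n_pairs=int(match.pairs.shape[0]))

    except Exception as e:
        manifest["failed"] = {"error": f"{type(e).__name__}: {e}"}
        eio.write_json_report(manifest, out / "manifest.json")
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    eio.write_json_report(manifest, out / "manifest.json")
    return manifest
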