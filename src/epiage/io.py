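"""Readers and writers for the delimited formats used across the pipeline.

Conventions:
- matrices (beta, detection-p, intensities, cell reference) are TSV with
  probes as rows and a header of sample (or cell-type) ids;
- phenotype sheets are CSV indexed by sample id;
- probe annotation travels as BED-like TSV (chrom, 0-based half-open start,
  end, probe id, gene, feature, semicolon flag list); in memory the position
  is 1-based, matching array manifests;
- gene sets are GMT (set name, description, member genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_VOCABULARY = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")
FLAG_COLUMNS = (
    "on_sex_chromosome",
    "maps_to_snp",
    "cross_reactive",
    "non_specific",
    "variant_containing",
    "masked",
)


class FormatError(ValueError):
    """Malformed input file; message carries the offending line/ids."""


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix (first column = probe ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate probe ids {dups}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df


def write_phenotype_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="sample_id")


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write annotation as BED-like TSV; in-memory 1-based position -> 0-based start."""
    out = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["position"].astype(int) - 1,
            "end": annotation["position"].astype(int),
            "probe_id": annotation.index,
            "gene": annotation["gene"].fillna("."),
            "feature": annotation["feature"],
            "flags": [
                ";".join(f for f in FLAG_COLUMNS if row[f]) or "."
                for _, row in annotation[list(FLAG_COLUMNS)].iterrows()
            ],
        }
    )
    out.to_csv(path, sep="\t", header=True, index=False)


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    """Read BED-like annotation back into the 1-based in-memory form."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "probe_id", "feature"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df["feature"][~df["feature"].isin(FEATURE_VOCABULARY)]
    if len(bad):
        raise FormatError(f"{path}: unknown feature classes {bad.unique().tolist()[:5]}")
    ann = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "position": df["start"].astype(int) + 1,
            "gene": df.get("gene", pd.Series(["."] * len(df))).replace(".", np.nan),
            "feature": df["feature"],
        }
    )
    flags = df.get("flags", pd.Series(["."] * len(df))).fillna(".")
    for f in FLAG_COLUMNS:
        ann[f] = [f in str(s).split(";") for s in flags]
    ann.index = pd.Index(df["probe_id"], name="probe_id")
    if ann.index.duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    return ann


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_blacklist(path: str | Path) -> set[str]:
    """Newline-delimited probe-id list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_json_report(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
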