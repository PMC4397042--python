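"""Plain-TSV interchange layer shared by all pipeline stages.

Every long-format table has a fixed, ordered header declared in
:data:`SCHEMAS`.  Matrices (genotype dosages, expression, eigengenes,
phenotypes) are written wide: first column is the sample id, remaining
columns are SNP/probe/module/trait ids.  Missing values are encoded as
``"NA"`` on disk and ``NaN`` in memory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

SCHEMAS: dict[str, list[str]] = {
    "snp_map": ["snp", "chrom", "pos_bp", "mapped"],
    "probe_map": ["probe", "gene", "chrom", "start_bp", "end_bp", "mapped"],
    "covariates": ["sample", "sex", "sire", "ryr1", "weight", "batch"],
    "qc_report": ["id", "type", "reason", "statistic"],
    "assignment": ["probe", "module"],
    "connectivity": ["probe", "gene", "module", "mm", "k", "rank"],
    "module_trait": ["module", "trait", "r", "p"],
    "eqtl": [
        "snp", "snp_chrom", "snp_pos", "probe", "gene",
        "gene_chrom", "gene_start", "gene_end",
        "p", "variance_explained", "cis_trans",
    ],
    "eqtl_summary": [
        "threshold", "total", "cis", "trans", "unmapped",
        "n_probes", "n_genes",
    ],
    "eqtl_drops": [
        "loose_threshold", "strict_threshold", "class",
        "pct_drop", "pct_drop_rounded",
    ],
    "eigengene_qtl": ["module", "snp", "chrom", "pos", "p", "variance_explained"],
    "hotspots": [
        "module", "chrom", "region_start", "region_end",
        "n_eqtl", "n_genes", "eigengene_min_p", "snps", "genes",
    ],
    "candidates": [
        "module", "gene", "probe", "chrom", "pos", "r", "p", "passes", "rank",
    ],
    "ct": ["experiment", "group", "gene", "replicate", "ct"],
    "knockdown": [
        "gene", "relative_expression", "p_value", "n_treatment", "n_control",
    ],
    "truth_genes": [
        "probe", "gene", "chrom", "start_bp", "end_bp", "module", "loading",
    ],
    "truth_eqtl": ["snp", "probe", "gene", "effect", "cis_trans"],
    "truth_modules": [
        "module", "regulator_probe", "regulator_gene", "cis_snp",
        "chrom", "cis_snp_pos",
    ],
    "truth_traits": ["trait", "module", "coef", "noise_sd", "target_r"],
}

# Columns parsed as plain strings even when they look numeric.
_STRING_COLUMNS = {
    "snp", "chrom", "probe", "gene", "module", "sample", "id", "type",
    "reason", "sex", "sire", "ryr1", "batch", "experiment", "group",
    "cis_trans", "snps", "genes", "snp_chrom", "gene_chrom",
    "regulator_probe", "regulator_gene", "cis_snp", "trait",
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a long-format TSV, enforcing the declared header exactly."""
    cols = SCHEMAS[schema]
    head = pd.read_csv(path, sep="\t", nrows=0)
    found = list(head.columns)
    if found != cols:
        extra = [c for c in found if c not in cols]
        missing = [c for c in cols if c not in found]
        raise SchemaError(
            f"{path}: header does not match schema '{schema}'; "
            f"extra columns {extra}, missing columns {missing}"
        )
    dtype = {c: str for c in cols if c in _STRING_COLUMNS}
    return pd.read_csv(
        path, sep="\t", dtype=dtype, na_values=["NA"], keep_default_na=False
    )


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write '{schema}': missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_matrix(path, index_name: str = "sample") -> pd.DataFrame:
    """Read a wide sample-by-feature matrix; first column is the sample id."""
    head = pd.read_csv(path, sep="\t", nrows=0)
    if len(head.columns) == 0 or head.columns[0] != index_name:
        raise SchemaError(
            f"{path}: first column must be '{index_name}', "
            f"got {list(head.columns[:1])}"
        )
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={index_name: str},
    )
    return df.set_index(index_name)


def write_matrix(df: pd.DataFrame, path, index_name: str = "sample") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA")
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
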