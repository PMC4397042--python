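"""Genotype quality control: sample call-rate and SNP minor-allele
frequency filters.

Filters are applied in that order -- samples first, then SNP MAF
recomputed on the retained samples -- and both thresholds are strict
(``<``), so boundary values are retained.  No Hardy-Weinberg filter is
applied: in a multi-way crossbreed population HWE deviations are
expected from discordant parental allele frequencies and are not a
genotyping-quality signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import AllMissingError, ConfigError, EmptyAfterQcError


@dataclass
class QcConfig:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    maf_after_sample_removal: bool = True  # recompute MAF on retained samples

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")


class QcResult(NamedTuple):
    genotypes: pd.DataFrame
    report: pd.DataFrame  # id, type, reason, statistic


def compute_maf(dosages) -> float:
    """Minor-allele frequency of a dosage vector with values {0,1,2,NaN}.

    Returns ``min(f, 1-f)`` where ``f`` is the frequency of the counted
    allele among non-missing calls; invariant under recoding ``d -> 2-d``.
    """
    d = np.asarray(dosages, dtype=float)
    obs = d[np.isfinite(d)]
    if obs.size == 0:
        raise AllMissingError("cannot compute MAF: all dosages missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def call_rates(geno: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of non-missing genotype calls."""
    return geno.notna().mean(axis=1)


def apply_qc(geno: pd.DataFrame, qc: QcConfig | None = None) -> QcResult:
    """Apply sample call-rate and SNP MAF filters.

    Samples with call rate below ``min_call_rate`` are removed first;
    SNPs with MAF below ``min_maf`` (computed on the retained samples
    unless configured otherwise) are removed second.  The report lists
    every removed id with its reason and the offending statistic.
    """
    qc = qc or QcConfig()
    qc.validate()
    if geno.empty:
        raise EmptyAfterQcError("empty genotype matrix")

    rows = []
    cr = call_rates(geno)
    bad_samples = cr.index[cr < qc.min_call_rate]
    for s in bad_samples:
        rows.append((s, "sample", "call_rate", float(cr[s])))
    kept = geno.drop(index=bad_samples)
    if kept.empty:
        raise EmptyAfterQcError("all samples removed by call-rate filter")

    maf_source = kept if qc.maf_after_sample_removal else geno
    mafs = {}
    for snp in maf_source.columns:
        try:
            mafs[snp] = compute_maf(maf_source[snp])
        except AllMissingError:
            mafs[snp] = -1.0  # all-missing SNP: below any threshold, dropped
    bad_snps = [snp for snp, m in mafs.items() if m < qc.min_maf]
    for snp in bad_snps:
        rows.append((snp, "snp", "maf", mafs[snp]))
    kept = kept.drop(columns=bad_snps)

    report = pd.DataFrame(rows, columns=["id", "type", "reason", "statistic"])
    return QcResult(kept, report)
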