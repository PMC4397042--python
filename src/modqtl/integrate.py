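"""Module-regulator integration: eigengene QTL mapping, 1-Mb window
binning of module-gene eQTL, hotspot declaration where eigengene QTL
and member-gene eQTL co-localize, and correlation-based ranking of
in-window regulator candidates.

A window is a hotspot when it holds eQTL of at least
``min_distinct_genes`` distinct module genes AND an eigengene
association below ``eigengene_p_max``; adjacent qualifying windows are
merged into one region.  Candidate regulators are the mapped
transcripts intersecting the region padded by ``region_pad_bp``, kept
when ``|r| > candidate_r_min`` and ``p < candidate_p_max`` (both
strict) against the module eigengene and ranked by |r| descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .eqtl import ScanConfig, scan_eqtl
from .genome import genomic_window, window_bounds
from .network import correlation_test


@dataclass
class IntegrationConfig:
    window_bp: int = 1_000_000
    eigengene_p_max: float = 1e-4
    min_distinct_genes: int = 3
    candidate_r_min: float = 0.20   # strict: |r| must exceed this
    candidate_p_max: float = 0.001  # strict: p must be below this
    region_pad_bp: int = 1_000_000

    def validate(self) -> None:
        for name in ("window_bp", "eigengene_p_max", "min_distinct_genes",
                     "candidate_p_max", "region_pad_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.candidate_r_min < 1:
            raise ConfigError("candidate_r_min must lie in (0, 1)")


class WindowCounts(NamedTuple):
    windows: pd.DataFrame   # chrom, window, n_eqtl, n_distinct_genes, snps, genes
    n_skipped_unmapped: int


def eigengene_qtl_scan(me: pd.Series, geno: pd.DataFrame,
                       cov: pd.DataFrame | None, snp_map: pd.DataFrame,
                       config: IntegrationConfig,
                       scan_config: ScanConfig | None = None) -> pd.DataFrame:
    """Association of a module eigengene with every SNP; records below
    ``eigengene_p_max`` retained, ordered by p."""
    config.validate()
    scan_config = scan_config or ScanConfig()
    trait = pd.DataFrame({"ME": me.to_numpy(dtype=float)}, index=me.index)
    pseudo_probe_map = pd.DataFrame(
        {"probe": ["ME"], "gene": ["ME"], "chrom": [pd.NA],
         "start_bp": [np.nan], "end_bp": [np.nan], "mapped": [False]}
    )
    loose = ScanConfig(
        p_thresholds=(config.eigengene_p_max,),
        cis_window_bp=scan_config.cis_window_bp,
        genotype_coding=scan_config.genotype_coding,
    )
    rec = scan_eqtl(trait, geno, cov, snp_map, pseudo_probe_map, loose)
    rec = rec.rename(columns={"snp_chrom": "chrom", "snp_pos": "pos"})
    rec = rec[["snp", "chrom", "pos", "p", "variance_explained"]]
    return rec.sort_values(["p", "snp"], kind="mergesort").reset_index(drop=True)


def window_counts(module_gene_records: pd.DataFrame, snp_map: pd.DataFrame,
                  window_bp: int = 1_000_000) -> WindowCounts:
    """Bin eQTL records into half-open genomic windows by SNP position.

    Each record lands in window ``floor(pos / window_bp)`` on its SNP's
    chromosome; records whose SNP lacks coordinates are skipped and
    counted.  Distinct genes fall back to the probe id when unannotated.
    """
    rec = module_gene_records.copy()
    if "snp_chrom" not in rec.columns or "snp_pos" not in rec.columns:
        smap = snp_map.rename(
            columns={"chrom": "snp_chrom", "pos_bp": "snp_pos"}
        )[["snp", "snp_chrom", "snp_pos"]]
        rec = rec.merge(smap, on="snp", how="left")
    mapped = rec["snp_chrom"].notna() & rec["snp_pos"].notna()
    skipped = int((~mapped).sum())
    rec = rec[mapped].copy()
    if rec.empty:
        empty = pd.DataFrame(
            columns=["chrom", "window", "n_eqtl", "n_distinct_genes",
                     "snps", "genes"]
        )
        return WindowCounts(empty, skipped)
    rec["window"] = genomic_window(rec["snp_pos"].to_numpy(), window_bp)
    gene_col = rec["gene"] if "gene" in rec.columns else pd.Series(index=rec.index)
    rec["_gene"] = gene_col.fillna(rec["probe"]) if "probe" in rec.columns else gene_col
    grouped = rec.groupby(["snp_chrom", "window"], sort=True)
    rows = [
        {
            "chrom": chrom,
            "window": int(win),
            "n_eqtl": len(sub),
            "n_distinct_genes": sub["_gene"].nunique(),
            "snps": ",".join(sorted(sub["snp"].unique())),
            "genes": ",".join(sorted(sub["_gene"].unique())),
        }
        for (chrom, win), sub in grouped
    ]
    return WindowCounts(pd.DataFrame(rows), skipped)


def detect_hotspots(wc: WindowCounts | pd.DataFrame,
                    eigengene_records: pd.DataFrame,
                    config: IntegrationConfig | None = None) -> pd.DataFrame:
    """Declare hotspot regions and sort them by eigengene minimum p.

    Qualifying windows (enough distinct module genes plus a co-localized
    eigengene association) that are adjacent on a chromosome are merged
    into a single region with half-open bp bounds.
    """
    config = config or IntegrationConfig()
    config.validate()
    windows = wc.windows if isinstance(wc, WindowCounts) else wc
    cols = ["chrom", "region_start", "region_end", "n_eqtl", "n_genes",
            "eigengene_min_p", "snps", "genes"]
    if windows.empty or eigengene_records.empty:
        return pd.DataFrame(columns=cols)

    eig = eigengene_records[
        eigengene_records["p"] < config.eigengene_p_max
    ].dropna(subset=["chrom", "pos"]).copy()
    if eig.empty:
        return pd.DataFrame(columns=cols)
    eig["window"] = genomic_window(eig["pos"].to_numpy(), config.window_bp)
    eig_min = eig.groupby(["chrom", "window"])["p"].min()

    qual = windows[windows["n_distinct_genes"] >= config.min_distinct_genes].copy()
    qual["eigengene_min_p"] = [
        eig_min.get((r.chrom, r.window), np.nan) for r in qual.itertuples()
    ]
    qual = qual[qual["eigengene_min_p"].notna()]
    if qual.empty:
        return pd.DataFrame(columns=cols)

    qual = qual.sort_values(["chrom", "window"])
    regions = []
    current = None
    for r in qual.itertuples():
        if (
            current is not None
            and r.chrom == current["chrom"]
            and r.window == current["last_window"] + 1
        ):
            current["last_window"] = r.window
            current["n_eqtl"] += r.n_eqtl
            current["snps"] |= set(r.snps.split(","))
            current["genes"] |= set(r.genes.split(","))
            current["eigengene_min_p"] = min(
                current["eigengene_min_p"], r.eigengene_min_p
            )
        else:
            if current is not None:
                regions.append(current)
            current = {
                "chrom": r.chrom, "first_window": r.window,
                "last_window": r.window, "n_eqtl": int(r.n_eqtl),
                "snps": set(r.snps.split(",")), "genes": set(r.genes.split(",")),
                "eigengene_min_p": float(r.eigengene_min_p),
            }
    regions.append(current)

    rows = []
    for reg in regions:
        start, _ = window_bounds(reg["first_window"], config.window_bp)
        _, end = window_bounds(reg["last_window"], config.window_bp)
        rows.append(
            {
                "chrom": reg["chrom"], "region_start": start, "region_end": end,
                "n_eqtl": reg["n_eqtl"], "n_genes": len(reg["genes"]),
                "eigengene_min_p": reg["eigengene_min_p"],
                "snps": ",".join(sorted(reg["snps"])),
                "genes": ",".join(sorted(reg["genes"])),
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(
        ["eigengene_min_p", "chrom", "region_start"], kind="mergesort"
    ).reset_index(drop=True)


def apply_candidate_filter(table: pd.DataFrame,
                           config: IntegrationConfig | None = None) -> pd.DataFrame:
    """Apply the strict (|r| > r_min AND p < p_max) filter to a table with
    ``r`` and ``p`` columns and rank passing rows by |r| descending."""
    config = config or IntegrationConfig()
    config.validate()
    out = table.copy()
    out["passes"] = (out["r"].abs() > config.candidate_r_min) & (
        out["p"] < config.candidate_p_max
    )
    out["_abs_r"] = out["r"].abs()
    sort_cols = ["passes", "_abs_r", "p"]
    ascending = [False, False, True]
    if "gene" in out.columns:
        sort_cols.append("gene")
        ascending.append(True)
    out = out.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    out["rank"] = np.where(
        out["passes"], np.arange(1, len(out) + 1), np.nan
    )
    return out.drop(columns="_abs_r").reset_index(drop=True)


def candidate_regulators(region: pd.Series | dict, probe_map: pd.DataFrame,
                         expr: pd.DataFrame, me: pd.Series,
                         config: IntegrationConfig | None = None) -> pd.DataFrame:
    """Correlation-ranked regulator candidates inside a padded hotspot
    region.

    Every mapped transcript whose gene interval intersects
    ``[region_start - pad, region_end + pad)`` is correlated with the
    eigengene; the strict filter and |r| ranking come from
    :func:`apply_candidate_filter`.
    """
    config = config or IntegrationConfig()
    config.validate()
    chrom = region["chrom"]
    lo = float(region["region_start"]) - config.region_pad_bp
    hi = float(region["region_end"]) + config.region_pad_bp
    pm = probe_map[probe_map["mapped"].astype(bool)]
    pm = pm[
        (pm["chrom"].astype(str) == str(chrom))
        & (pm["end_bp"] >= lo + 1)
        & (pm["start_bp"] <= hi)
    ]
    rows = []
    for r in pm.itertuples():
        if r.probe not in expr.columns:
            continue
        corr, p = correlation_test(expr[r.probe], me)
        rows.append(
            {
                "gene": r.gene, "probe": r.probe, "chrom": r.chrom,
                "pos": float(r.start_bp), "r": corr, "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "probe", "chrom", "pos", "r", "p", "passes", "rank"]
        )
    return apply_candidate_filter(pd.DataFrame(rows), config)
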