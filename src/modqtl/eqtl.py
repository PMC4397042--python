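"""Genome-wide association of transcript abundances (or any trait
vector) with SNP dosages, cis/trans classification, threshold
summaries, and per-module FDR.

The association model is an F-test of the genotype term: a full linear
model [intercept, covariates, batch, genotype] against the reduced
covariates-only model.  Genotype enters as a categorical factor by
default (df = observed levels - 1) or additively.  The slaughter-day
batch is modeled as a fixed factor; with (near-)balanced batches this
leaves the genotype F-test unbiased while avoiding REML machinery.
Variance explained is the incremental R^2 of the genotype term relative
to the covariate-adjusted trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    ConfigError,
    DesignError,
    EmptyInputError,
    InputError,
    InsufficientDataError,
    MonomorphicError,
)
from .genome import interval_distance
from .network import P_FLOOR, build_design, _orth

DEFAULT_CATEGORICAL = ("sex", "sire", "ryr1", "batch")
DEFAULT_NUMERIC = ("weight",)


@dataclass
class ScanConfig:
    p_thresholds: tuple[float, ...] = (1e-5, 1e-6)
    cis_window_bp: int = 1_000_000     # strict: distance must be < window
    genotype_coding: str = "categorical"  # or "additive"
    report_variance_explained: bool = True

    def validate(self) -> None:
        if not self.p_thresholds:
            raise ConfigError("need at least one p threshold")
        if any(not 0 < t < 1 for t in self.p_thresholds):
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.cis_window_bp < 0:
            raise ConfigError("cis window must be >= 0")
        if self.genotype_coding not in ("categorical", "additive"):
            raise ConfigError(f"unknown genotype coding {self.genotype_coding!r}")


class AssocResult(NamedTuple):
    p: float
    variance_explained: float
    f: float
    df1: int
    df2: int


def _genotype_columns(g: np.ndarray, coding: str) -> np.ndarray:
    levels = np.unique(g)
    if levels.size < 2:
        raise MonomorphicError("genotype has fewer than two observed levels")
    if coding == "additive":
        return g.reshape(-1, 1).astype(float)
    return np.column_stack([(g == lv).astype(float) for lv in levels[1:]])


def _ftest_against_reduced(y_r: np.ndarray, Qg: np.ndarray, n_eff: int,
                           rank_red: int) -> AssocResult:
    """F-test given covariate-residualized response(s) and an orthonormal
    basis of the covariate-residualized genotype columns."""
    d = Qg.shape[1]
    sse_red = float(y_r @ y_r)
    b = Qg.T @ y_r
    ss_g = float(b @ b)
    sse_full = max(sse_red - ss_g, 0.0)
    df2 = n_eff - rank_red - d
    if df2 < 1:
        raise DesignError("no residual degrees of freedom for the F-test")
    if sse_red <= 0:
        raise DesignError("covariate-adjusted response has zero variance")
    if sse_full <= 1e-12 * sse_red:
        return AssocResult(P_FLOOR, min(ss_g / sse_red, 1.0), np.inf, d, df2)
    f = (ss_g / d) / (sse_full / df2)
    p = float(max(stats.f.sf(f, d, df2), P_FLOOR))
    ve = float(min(max(ss_g / sse_red, 0.0), 1.0))
    return AssocResult(p, ve, float(f), d, df2)


def association_test(y, g, cov: pd.DataFrame | None = None,
                     coding: str = "categorical") -> AssocResult:
    """Single trait-vs-SNP association under the covariate model.

    Complete cases only; requires at least covariate df + genotype df + 2
    observations and two observed genotype levels.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape:
        raise AlignmentError("trait and genotype vectors differ in length")
    mask = np.isfinite(y) & np.isfinite(g)
    if cov is not None:
        mask &= cov.notna().all(axis=1).to_numpy()
        D = build_design(cov.iloc[mask.nonzero()[0]],
                         categorical=DEFAULT_CATEGORICAL,
                         numeric=DEFAULT_NUMERIC)
    else:
        D = np.ones((int(mask.sum()), 1))
    ym, gm = y[mask], g[mask]
    G = _genotype_columns(gm, coding)
    Qd = _orth(D)
    rank_red = Qd.shape[1]
    if len(ym) < rank_red + G.shape[1] + 2:
        raise InsufficientDataError("too few complete cases for the model")
    y_r = ym - Qd @ (Qd.T @ ym)
    G_r = G - Qd @ (Qd.T @ G)
    Qg = _orth_or_empty(G_r)
    if Qg.shape[1] == 0:
        raise DesignError("genotype columns collinear with covariates")
    return _ftest_against_reduced(y_r, Qg, len(ym), rank_red)


def _orth_or_empty(X: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 1e-12:
        return U[:, :0]
    return U[:, s > rtol * s[0]]


def scan_eqtl(expr: pd.DataFrame, geno: pd.DataFrame,
              cov: pd.DataFrame | None,
              snp_map: pd.DataFrame, probe_map: pd.DataFrame,
              config: ScanConfig | None = None) -> pd.DataFrame:
    """Association of every (probe, SNP) pair; retains pairs below the
    loosest threshold, classified cis/trans/unmapped, ordered by
    (probe, snp).

    Vectorized per SNP: the response matrix is residualized on the
    covariate design once per missingness pattern, then the genotype
    term's sum of squares is obtained by projecting onto an orthonormal
    basis of the covariate-residualized genotype columns.
    """
    config = config or ScanConfig()
    config.validate()
    if set(expr.index) != set(geno.index):
        raise AlignmentError("expression and genotype sample ids differ")
    geno = geno.reindex(expr.index)
    if cov is not None:
        if set(cov.index) != set(expr.index):
            raise AlignmentError("covariate sample ids differ from expression")
        cov = cov.reindex(expr.index)

    p_max = max(config.p_thresholds)
    Y = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise InputError("expression matrix contains non-finite values")
    n, n_probes = Y.shape
    probes = np.asarray(expr.columns)

    if cov is not None:
        D_all = build_design(cov, categorical=DEFAULT_CATEGORICAL,
                             numeric=DEFAULT_NUMERIC)
    else:
        D_all = np.ones((n, 1))

    # complete-genotype fast path shares one residualization
    Qd_full = _orth(D_all)
    Yr_full = Y - Qd_full @ (Qd_full.T @ Y)
    sse_red_full = (Yr_full ** 2).sum(axis=0)

    rows = []
    for snp in geno.columns:
        g = geno[snp].to_numpy(dtype=float)
        mask = np.isfinite(g)
        n_eff = int(mask.sum())
        if n_eff < 3:
            continue
        try:
            if mask.all():
                Qd, Yr, sse_red = Qd_full, Yr_full, sse_red_full
                gm = g
            else:
                Dm = D_all[mask]
                Qd = _orth(Dm)
                Ym = Y[mask]
                Yr = Ym - Qd @ (Qd.T @ Ym)
                sse_red = (Yr ** 2).sum(axis=0)
                gm = g[mask]
            G = _genotype_columns(gm, config.genotype_coding)
        except MonomorphicError:
            continue
        rank_red = Qd.shape[1]
        G_r = G - Qd @ (Qd.T @ G)
        Qg = _orth_or_empty(G_r)
        d = Qg.shape[1]
        df2 = n_eff - rank_red - d
        if d == 0 or df2 < 1:
            continue
        B = Qg.T @ Yr
        ss_g = (B ** 2).sum(axis=0)
        sse_full = np.maximum(sse_red - ss_g, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_g / d) / (sse_full / df2)
        p = np.where(
            sse_full <= 1e-12 * sse_red, P_FLOOR,
            np.maximum(stats.f.sf(f, d, df2), P_FLOOR),
        )
        ve = np.clip(np.divide(ss_g, sse_red, out=np.zeros_like(ss_g),
                               where=sse_red > 0), 0.0, 1.0)
        hit = np.where(p < p_max)[0]
        for j in hit:
            rows.append((snp, probes[j], float(p[j]), float(ve[j])))

    records = pd.DataFrame(rows, columns=["snp", "probe", "p", "variance_explained"])
    records = annotate_records(records, snp_map, probe_map, config.cis_window_bp)
    return records.sort_values(["probe", "snp"], kind="mergesort").reset_index(drop=True)


def classify_cis_trans(snp_chrom, snp_pos, gene_chrom, gene_start, gene_end,
                       cis_window_bp: int = 1_000_000) -> str:
    """"cis" when SNP and gene share a chromosome and the SNP lies
    strictly closer than ``cis_window_bp`` to the gene interval,
    "trans" otherwise, "unmapped" when either side lacks coordinates."""
    if (
        pd.isna(snp_chrom) or pd.isna(snp_pos)
        or pd.isna(gene_chrom) or pd.isna(gene_start) or pd.isna(gene_end)
    ):
        return "unmapped"
    if str(snp_chrom) != str(gene_chrom):
        return "trans"
    dist = interval_distance(float(snp_pos), float(gene_start), float(gene_end))
    return "cis" if dist < cis_window_bp else "trans"


def annotate_records(records: pd.DataFrame, snp_map: pd.DataFrame,
                     probe_map: pd.DataFrame,
                     cis_window_bp: int = 1_000_000) -> pd.DataFrame:
    """Attach SNP/gene coordinates and the cis/trans/unmapped class."""
    out = records.merge(
        snp_map.rename(columns={"chrom": "snp_chrom", "pos_bp": "snp_pos"})[
            ["snp", "snp_chrom", "snp_pos"]
        ],
        on="snp", how="left",
    ).merge(
        probe_map.rename(
            columns={"chrom": "gene_chrom", "start_bp": "gene_start",
                     "end_bp": "gene_end"}
        )[["probe", "gene", "gene_chrom", "gene_start", "gene_end"]],
        on="probe", how="left",
    )
    out["cis_trans"] = [
        classify_cis_trans(r.snp_chrom, r.snp_pos, r.gene_chrom,
                           r.gene_start, r.gene_end, cis_window_bp)
        for r in out.itertuples()
    ]
    return out


def percent_drop(count_loose: float, count_strict: float) -> tuple[float, int]:
    """Percent decrease from a loose to a strict threshold: exact value
    and the nearest-integer display value."""
    if count_loose == 0:
        return float("nan"), 0
    exact = 100.0 * (1.0 - count_strict / count_loose)
    return exact, int(round(exact))


def summarize_counts(records: pd.DataFrame,
                     thresholds=(1e-5, 1e-6)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-threshold eQTL counts and percent drops between consecutive
    thresholds (loosest to strictest)."""
    thresholds = sorted(thresholds, reverse=True)
    counts_rows = []
    for t in thresholds:
        if records.empty:
            sub = records
        else:
            sub = records[records["p"] < t]
        row = {"threshold": t, "total": len(sub)}
        for cls in ("cis", "trans", "unmapped"):
            row[cls] = int((sub["cis_trans"] == cls).sum()) if len(sub) else 0
        row["n_probes"] = sub["probe"].nunique() if len(sub) else 0
        if len(sub) and "gene" in sub.columns:
            row["n_genes"] = sub["gene"].dropna().nunique()
        else:
            row["n_genes"] = 0
        counts_rows.append(row)
    counts = pd.DataFrame(counts_rows)

    drop_rows = []
    for loose, strict in zip(counts_rows[:-1], counts_rows[1:]):
        for cls in ("total", "cis", "trans", "unmapped"):
            exact, rounded = percent_drop(loose[cls], strict[cls])
            drop_rows.append(
                {
                    "loose_threshold": loose["threshold"],
                    "strict_threshold": strict["threshold"],
                    "class": cls,
                    "pct_drop": exact,
                    "pct_drop_rounded": rounded,
                }
            )
    drops = pd.DataFrame(
        drop_rows,
        columns=["loose_threshold", "strict_threshold", "class",
                 "pct_drop", "pct_drop_rounded"],
    )
    return counts, drops


def module_fdr(pvalues, p_cutoff: float) -> float:
    """Benjamini-Hochberg adjusted value of the largest p-value at or
    below ``p_cutoff`` within a module's test set; NaN when no test
    reaches the cutoff."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise EmptyInputError("empty p-value set")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    adj = multipletests(p, method="fdr_bh")[1]
    sel = p <= p_cutoff
    if not sel.any():
        return float("nan")
    idx = np.argmax(np.where(sel, p, -np.inf))
    return float(adj[idx])
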