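"""qPCR knockdown statistics: geometric-mean reference normalization,
relative expression by the 2^-ddCt model, and two-tailed Student
t-tests across replicates.

Normalization uses the geometric mean of the raw threshold cycles (Ct)
of the reference genes within each replicate; per-replicate
``dCt = Ct_target - Ct_reference``; the group contrast
``ddCt = mean(dCt, treatment) - mean(dCt, control)`` gives relative
expression ``2^-ddCt`` (control is 1 by construction).  Amplification
efficiency is fixed at 2 per cycle.  The control pool may combine
non-silencing siRNA, mock and untreated replicates; replicates are
pooled directly rather than averaged per sub-group first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    GroupMissingError,
    InsufficientReplicatesError,
    MissingReferenceError,
)

_REP_KEYS = ["experiment", "group", "replicate"]


@dataclass
class KnockdownResult:
    gene: str
    relative_expression: float  # treatment level as a fraction of control
    p_value: float
    n_treatment: int
    n_control: int

    def as_row(self) -> dict:
        return {
            "gene": self.gene,
            "relative_expression": self.relative_expression,
            "p_value": self.p_value,
            "n_treatment": self.n_treatment,
            "n_control": self.n_control,
        }


def reference_ct(ct: pd.DataFrame, ref_genes) -> pd.DataFrame:
    """Per-replicate geometric mean of the reference-gene Ct values."""
    ref_genes = list(ref_genes)
    refs = ct[ct["gene"].isin(ref_genes)]
    rows = []
    for key, sub in refs.groupby(_REP_KEYS, sort=True):
        present = set(sub["gene"])
        missing = [g for g in ref_genes if g not in present]
        if missing:
            raise MissingReferenceError(
                f"replicate {key}: missing reference gene(s) {missing}"
            )
        vals = sub.set_index("gene").loc[ref_genes, "ct"].to_numpy(dtype=float)
        rows.append(dict(zip(_REP_KEYS, key), ref_ct=float(stats.gmean(vals))))
    out = pd.DataFrame(rows, columns=_REP_KEYS + ["ref_ct"])
    # replicates that measured the target but no reference at all
    target_reps = set(map(tuple, ct[_REP_KEYS].drop_duplicates().to_numpy()))
    have = set(map(tuple, out[_REP_KEYS].to_numpy())) if len(out) else set()
    lacking = target_reps - have
    if lacking:
        raise MissingReferenceError(
            f"replicates without reference measurements: {sorted(lacking)}"
        )
    return out


def relative_expression(ct: pd.DataFrame, target_gene: str,
                        ref_genes) -> pd.DataFrame:
    """Per-replicate dCt and relative expression for one target gene.

    Returns a frame with experiment/group/replicate, ``delta_ct`` and
    ``rel_expr`` (``2^-(dCt - mean control dCt)``), so the summarized
    control level is exactly 1.
    """
    refs = reference_ct(ct, ref_genes)
    tgt = ct[ct["gene"] == target_gene]
    if tgt.empty:
        raise GroupMissingError(f"no Ct rows for target gene {target_gene!r}")
    merged = tgt.merge(refs, on=_REP_KEYS, how="left")
    if merged["ref_ct"].isna().any():
        raise MissingReferenceError(
            f"target {target_gene!r}: replicates lack reference values"
        )
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]
    for grp in ("treatment", "control"):
        if not (merged["group"] == grp).any():
            raise GroupMissingError(f"no {grp} replicates for {target_gene!r}")
    mean_control = merged.loc[merged["group"] == "control", "delta_ct"].mean()
    merged["rel_expr"] = 2.0 ** -(merged["delta_ct"] - mean_control)
    return merged[_REP_KEYS + ["delta_ct", "rel_expr"]]


def knockdown_test(treatment_values, control_values,
                   welch: bool = False) -> float:
    """Two-tailed Student t-test (equal variance unless ``welch``)."""
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise InsufficientReplicatesError(
            "need >= 2 replicates per group for a t-test"
        )
    res = stats.ttest_ind(t, c, equal_var=not welch)
    return float(res.pvalue)


def analyze_knockdown(ct: pd.DataFrame, target_gene: str, ref_genes,
                      welch: bool = False) -> KnockdownResult:
    """Relative expression and significance of a knockdown target.

    The p-value comes from a t-test on the per-replicate dCt values
    (i.e. on log2 expression, the standard scale for qPCR contrasts);
    relative expression is ``2^-ddCt`` for the treatment group.
    """
    per_rep = relative_expression(ct, target_gene, ref_genes)
    d_t = per_rep.loc[per_rep["group"] == "treatment", "delta_ct"].to_numpy()
    d_c = per_rep.loc[per_rep["group"] == "control", "delta_ct"].to_numpy()
    ddct = float(d_t.mean() - d_c.mean())
    p = knockdown_test(d_t, d_c, welch=welch)
    return KnockdownResult(
        gene=target_gene,
        relative_expression=float(2.0 ** -ddct),
        p_value=p,
        n_treatment=len(d_t),
        n_control=len(d_c),
    )
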