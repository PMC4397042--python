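"""Genomic coordinate conventions used throughout the package.

Positions in maps are 1-based; probe/gene intervals ``[start_bp, end_bp]``
are 1-based inclusive.  Window binning for hotspot detection uses half-open
windows ``[i*w, (i+1)*w)`` in base pairs, so a SNP at position exactly
1,000,000 with 1-Mb windows falls into window 1, i.e. [1 Mb, 2 Mb).
All conversions live here so no stage re-derives them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def genomic_window(pos_bp, window_bp: int):
    """Index of the half-open window ``[i*window_bp, (i+1)*window_bp)``.

    Accepts scalars or arrays; NaN positions yield -1.
    """
    pos = np.asarray(pos_bp, dtype=float)
    out = np.full(pos.shape, -1, dtype=int)
    ok = np.isfinite(pos)
    out[ok] = (pos[ok] // window_bp).astype(int)
    if np.ndim(pos_bp) == 0:
        return int(out[()])
    return out


def window_bounds(window_index: int, window_bp: int) -> tuple[int, int]:
    """Base-pair bounds ``(start, end)`` of a window, half-open."""
    return window_index * window_bp, (window_index + 1) * window_bp


def interval_distance(pos_bp: float, start_bp: float, end_bp: float) -> float:
    """Distance in bp from a point to a closed interval (0 if inside)."""
    if pos_bp < start_bp:
        return start_bp - pos_bp
    if pos_bp > end_bp:
        return pos_bp - end_bp
    return 0.0


def snp_map_from_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert a 4-column BED-like frame (chrom, start, end, name; 0-based
    half-open) into the internal 1-based SNP map."""
    out = pd.DataFrame(
        {
            "snp": bed.iloc[:, 3].astype(str),
            "chrom": bed.iloc[:, 0].astype(str),
            "pos_bp": bed.iloc[:, 1].astype(float) + 1.0,
        }
    )
    out["mapped"] = True
    return out
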