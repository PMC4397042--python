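"""Weighted co-expression network construction and module statistics.

The network is unsigned: adjacency ``a_iu = |cor(x_i, x_u)|^beta`` with a
soft-thresholding power beta (default 6).  Modules are detected by
average-linkage hierarchical clustering of the topological-overlap
dissimilarity ``1 - TOM`` with a static cut, then merged while their
eigengenes are more similar than a dissimilarity threshold.  The module
eigengene is the first principal component of the module's standardized
expression, signed so that it correlates non-negatively with the module
mean.  Per-gene statistics are module membership ``MM = cor(x_i, ME)``
and intramodular soft connectivity ``K_i = sum_{u != i} a_iu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import (
    ConfigError,
    DesignError,
    EmptyModuleError,
    InputError,
    InsufficientDataError,
    ZeroVarianceError,
)

P_FLOOR = 1e-300


@dataclass
class NetworkConfig:
    beta: int = 6
    power_grid: list[int] = field(default_factory=lambda: list(range(1, 13)))
    scale_free_r2_min: float = 0.80
    min_module_size: int = 30
    # Static cut on the 1-TOM dendrogram.  With beta = 6, TOM values for
    # modules of moderately correlated genes (|r| ~ 0.5) are on the order
    # of |r|^beta ~ 0.02, so merge heights sit just below 1; the cut must
    # sit between those heights (~0.97-0.99) and the ~0.9999 heights of
    # unrelated genes.
    cut_height: float = 0.995
    merge_dissim_threshold: float = 0.25

    def validate(self) -> None:
        if self.beta < 1:
            raise ConfigError("beta must be >= 1")
        for name in ("scale_free_r2_min", "cut_height", "merge_dissim_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1]")


@dataclass
class ModuleSet:
    assignment: pd.Series          # probe -> module label; "unassigned" reserved
    eigengenes: pd.DataFrame       # samples x modules

    def modules(self) -> list[str]:
        return [m for m in self.assignment.unique() if m != "unassigned"]

    def probes_in(self, module: str) -> list[str]:
        return self.assignment.index[self.assignment == module].tolist()


class PowerPick(NamedTuple):
    beta: int
    fallback: bool               # True when no candidate met the R^2 bar
    r2: dict[int, float]


def _check_variance(values: np.ndarray, probes) -> None:
    sd = values.std(axis=0, ddof=1)
    bad = np.where(~(sd > 0))[0]
    if bad.size:
        raise ZeroVarianceError(f"zero-variance probe(s): {list(np.asarray(probes)[bad])}")


def residualize_expression(expr: pd.DataFrame, cov: pd.DataFrame,
                           categorical: tuple[str, ...] = ("sex", "sire", "ryr1", "batch"),
                           numeric: tuple[str, ...] = ("weight",)) -> pd.DataFrame:
    """Per-probe least-squares residuals on the covariate design.

    The design holds an intercept, dummy-coded categorical covariates and
    the numeric covariates; collinear columns are pruned before fitting.
    Residuals are orthogonal to every retained design column.
    """
    if not expr.index.equals(cov.index):
        cov = cov.reindex(expr.index)
    if cov.isna().any().any():
        raise DesignError("covariates incomplete for some samples")
    D = build_design(cov, categorical=categorical, numeric=numeric)
    Q = _orth(D)
    if Q.shape[1] >= len(expr):
        raise DesignError("covariate design leaves no residual degrees of freedom")
    X = expr.to_numpy(dtype=float)
    resid = X - Q @ (Q.T @ X)
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)


def build_design(cov: pd.DataFrame, categorical=(), numeric=(),
                 intercept: bool = True) -> np.ndarray:
    cols = [np.ones((len(cov), 1))] if intercept else []
    for c in categorical:
        if c in cov.columns:
            d = pd.get_dummies(cov[c].astype(str), drop_first=True)
            if d.shape[1]:
                cols.append(d.to_numpy(dtype=float))
    for c in numeric:
        if c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float).reshape(-1, 1))
    if not cols:
        raise DesignError("empty covariate design")
    return np.hstack(cols)


def _orth(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space (collinear columns pruned)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise DesignError("design matrix has rank zero")
    return U[:, s > rtol * s[0]]


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta; diagonal fixed at 1."""
    X = expr.to_numpy(dtype=float)
    _check_variance(X, expr.columns)
    A = np.abs(np.corrcoef(X, rowvar=False)) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=expr.columns, columns=expr.columns)


def scale_free_fit_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log fit of the binned connectivity distribution."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k.min(), k.max()):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    freq, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (freq > 0) & (centers > 0)
    if keep.sum() < 2:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(freq[keep] / freq.sum())
    if np.allclose(x, x[0]):
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def pick_soft_power(expr: pd.DataFrame, config: NetworkConfig) -> PowerPick:
    """Smallest power in the grid whose whole-network connectivity
    distribution fits a power law with R^2 >= ``scale_free_r2_min``;
    falls back to ``config.beta`` (flagged) when none qualifies."""
    if not config.power_grid:
        raise ConfigError("empty power grid")
    if expr.shape[1] < 20:
        raise ConfigError("need >= 20 probes to assess scale-free fit")
    r2 = {}
    for beta in sorted(config.power_grid):
        A = adjacency(expr, beta).to_numpy()
        k = A.sum(axis=0) - 1.0
        r2[beta] = scale_free_fit_r2(k)
        if r2[beta] >= config.scale_free_r2_min:
            return PowerPick(beta, False, r2)
    return PowerPick(config.beta, True, r2)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap:
    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu``; diagonal defined as 1."""
    A = adj.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise InputError("adjacency matrix must be symmetric")
    k = A.sum(axis=0) - np.diag(A)
    L = A @ A
    # remove the u = i and u = j terms from the path-count product
    shared = L - np.diag(A)[:, None] * A - A * np.diag(A)[None, :]
    num = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Average-linkage clustering of ``1 - TOM`` with a static cut.

    Clusters smaller than ``min_module_size`` are relabeled "unassigned".
    Module labels M1, M2, ... are assigned by decreasing size, ties broken
    by first probe position, so output is deterministic.
    """
    probes = list(tom.index)
    if len(probes) < config.min_module_size:
        return pd.Series("unassigned", index=tom.index, name="module")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=config.cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    order = sorted(
        keep,
        key=lambda c: (-sizes[c], int(np.argmax(labels.to_numpy() == c))),
    )
    rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
    out = labels.map(lambda c: rename.get(c, "unassigned"))
    out.name = "module"
    return out


def module_eigengene(expr: pd.DataFrame, probes) -> pd.Series:
    """First principal component across samples of the z-scored module
    expression, scaled to unit sample variance and signed so that
    ``cor(ME, module mean) >= 0``."""
    probes = list(probes)
    if not probes:
        raise EmptyModuleError("empty module")
    if len(expr) < 3:
        raise InsufficientDataError("need >= 3 samples for an eigengene")
    X = expr[probes].to_numpy(dtype=float)
    _check_variance(X, probes)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    me = U[:, 0]
    me = me / me.std(ddof=1)
    mean_profile = Z.mean(axis=1)
    sign = np.sign(np.dot(me - me.mean(), mean_profile - mean_profile.mean()))
    if sign < 0:
        me = -me
    return pd.Series(me, index=expr.index, name="ME")


def build_module_set(expr: pd.DataFrame, assignment: pd.Series) -> ModuleSet:
    modules = sorted({m for m in assignment.unique() if m != "unassigned"})
    eg = {
        m: module_eigengene(expr, assignment.index[assignment == m])
        for m in modules
    }
    eigengenes = pd.DataFrame(eg, index=expr.index)
    return ModuleSet(assignment.copy(), eigengenes)


def merge_modules(expr: pd.DataFrame, module_set: ModuleSet,
                  merge_dissim_threshold: float = 0.25) -> ModuleSet:
    """Iteratively merge the closest pair of modules (eigengene
    dissimilarity ``1 - cor``) while the smallest dissimilarity is below
    the threshold, recomputing the merged eigengene each step."""
    assignment = module_set.assignment.copy()
    eigengenes = module_set.eigengenes.copy()
    while True:
        mods = sorted(eigengenes.columns)
        if len(mods) < 2:
            break
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                d = 1.0 - float(
                    np.corrcoef(eigengenes[a], eigengenes[b])[0, 1]
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        if d >= merge_dissim_threshold:
            break
        assignment[assignment == b] = a
        eigengenes = eigengenes.drop(columns=[b])
        eigengenes[a] = module_eigengene(
            expr, assignment.index[assignment == a]
        )
    return ModuleSet(assignment, eigengenes.sort_index(axis=1))


def module_membership(x: pd.Series, me: pd.Series) -> float:
    """Pearson correlation between a probe profile and a module eigengene."""
    xv = np.asarray(x, dtype=float)
    mv = np.asarray(me, dtype=float)
    if len(xv) != len(mv):
        raise InputError("profile and eigengene lengths differ")
    if not (xv.std(ddof=1) > 0 and mv.std(ddof=1) > 0):
        raise ZeroVarianceError("zero-variance input to module membership")
    return float(np.corrcoef(xv, mv)[0, 1])


def soft_connectivity(adj: pd.DataFrame, module_probes) -> pd.Series:
    """K_i = sum of adjacencies of probe i to the other module members."""
    probes = list(module_probes)
    missing = [p for p in probes if p not in adj.index]
    if missing:
        raise KeyError(f"probes outside adjacency matrix: {missing}")
    sub = adj.loc[probes, probes].to_numpy(dtype=float)
    k = sub.sum(axis=0) - np.diag(sub)
    return pd.Series(k, index=probes, name="k")


def connectivity_table(expr: pd.DataFrame, adj: pd.DataFrame,
                       module_set: ModuleSet,
                       probe_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-probe MM and K for every assigned module member."""
    gene_of = (
        probe_map.set_index("probe")["gene"]
        if probe_map is not None else None
    )
    rows = []
    for m in module_set.modules():
        probes = module_set.probes_in(m)
        me = module_set.eigengenes[m]
        k = soft_connectivity(adj, probes)
        for p in probes:
            gene = gene_of.get(p, p) if gene_of is not None else p
            rows.append((p, gene, m, module_membership(expr[p], me), float(k[p])))
    return pd.DataFrame(rows, columns=["probe", "gene", "module", "mm", "k"])


def rank_hubs(connectivity: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Collapse probes to genes (keeping the probe with the highest |MM|)
    and rank by |MM| descending, then K descending, then gene symbol."""
    if connectivity.empty:
        raise EmptyModuleError("no connectivity records to rank")
    df = connectivity.copy()
    df["abs_mm"] = df["mm"].abs()
    df = (
        df.sort_values(["abs_mm", "k", "probe"], ascending=[False, False, True])
        .drop_duplicates(subset="gene", keep="first")
        .sort_values(["abs_mm", "k", "gene"], ascending=[False, False, True])
        .drop(columns="abs_mm")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    if top_n is not None:
        df = df.head(top_n)
    return df


def correlation_test(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from ``t = r sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom; p floored at 1e-300."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    n = len(xv)
    if n < 4:
        raise InsufficientDataError("need >= 4 complete pairs")
    if not (xv.std(ddof=1) > 0 and yv.std(ddof=1) > 0):
        raise ZeroVarianceError("zero-variance input to correlation test")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, P_FLOOR
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(max(min(p, 1.0), P_FLOOR))


def module_trait_correlation(me: pd.Series, trait) -> tuple[float, float]:
    """Correlation between a module eigengene and a phenotype."""
    return correlation_test(me, trait)
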