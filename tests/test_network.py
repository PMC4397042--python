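"""Network stage: residualization, adjacency/TOM formulas, module
detection and merging, eigengenes, MM/K statistics and hub ranking —
each checked against an independent oracle where the spec of the
operation is numeric."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modqtl import NetworkConfig
from modqtl.errors import (
    ConfigError,
    InsufficientDataError,
    ZeroVarianceError,
)
from modqtl.network import (
    adjacency,
    build_module_set,
    correlation_test,
    detect_modules,
    merge_modules,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    pick_soft_power,
    rank_hubs,
    residualize_expression,
    scale_free_fit_r2,
    soft_connectivity,
    tom_similarity,
)

from conftest import make_covariates


def expr_frame(values, probes=None):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"p{j}" for j in range(arr.shape[1])]
    idx = pd.Index([f"S{i:03d}" for i in range(arr.shape[0])], name="sample")
    return pd.DataFrame(arr, index=idx, columns=probes)


class TestResidualize:
    def test_exact_linear_function_gives_zero_residuals(self, rng):
        cov = make_covariates(rng, 40)
        y = 2.0 + 0.1 * cov["weight"] + (cov["sex"] == "F") * 3.0
        expr = expr_frame(np.column_stack([y, y * -2.0]))
        resid = residualize_expression(expr, cov)
        assert np.abs(resid.to_numpy()).max() < 1e-10

    def test_orthogonal_expression_only_centered(self, rng):
        n = 60
        cov = make_covariates(rng, n)
        x = rng.normal(size=n)
        # remove every covariate component so input is already orthogonal
        from modqtl.network import build_design, _orth

        D = _orth(build_design(cov, ("sex", "sire", "ryr1", "batch"), ("weight",)))
        x = x - D @ (D.T @ x)
        expr = expr_frame(x.reshape(-1, 1) + 5.0)
        resid = residualize_expression(expr, cov)
        np.testing.assert_allclose(
            resid.to_numpy().ravel(), x, atol=1e-10
        )

    def test_matches_normal_equations_oracle(self, rng):
        """Residuals equal the explicit (X'X)^-1 X'y solution on 50
        random fixtures."""
        from modqtl.network import build_design

        worst = 0.0
        for _ in range(50):
            n = 25
            cov = make_covariates(rng, n)
            expr = expr_frame(rng.normal(size=(n, 5)))
            resid = residualize_expression(expr, cov)
            D = build_design(cov, ("sex", "sire", "ryr1", "batch"), ("weight",))
            beta = np.linalg.pinv(D.T @ D) @ D.T @ expr.to_numpy()
            oracle = expr.to_numpy() - D @ beta
            worst = max(worst, np.abs(resid.to_numpy() - oracle).max())
        assert worst < 1e-8


class TestAdjacencyTom:
    @pytest.mark.parametrize(
        "cor,beta,expected",
        [(-1.0, 6, 1.0), (0.0, 6, 0.0), (0.5, 6, 0.015625)],
    )
    def test_adjacency_values(self, cor, beta, expected):
        n = 400
        t = np.linspace(0, 2 * np.pi, n)
        if cor == 0.0:
            x, y = np.sin(t), np.cos(t)  # exactly orthogonal
        elif cor == -1.0:
            x, y = t, -t
        else:
            rng = np.random.default_rng(0)
            z = rng.normal(size=n)
            e = rng.normal(size=n)
            zc = z - z.mean()
            ec = e - e.mean()
            ec -= zc * (zc @ ec) / (zc @ zc)
            y = z
            x = cor * zc / np.linalg.norm(zc) + np.sqrt(1 - cor**2) * (
                ec / np.linalg.norm(ec)
            )
        expr = expr_frame(np.column_stack([x, y]))
        a = adjacency(expr, beta).iloc[0, 1]
        assert a == pytest.approx(expected, abs=1e-6)

    def test_zero_variance_probe_named(self):
        expr = expr_frame(np.column_stack([np.ones(10), np.arange(10)]),
                          probes=["flat", "ok"])
        with pytest.raises(ZeroVarianceError, match="flat"):
            adjacency(expr, 6)

    def test_tom_hand_examples(self):
        # isolated perfect pair
        A = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        A.loc["a", "b"] = A.loc["b", "a"] = 1.0
        T = tom_similarity(A)
        assert T.loc["a", "b"] == pytest.approx(1.0)
        assert T.loc["a", "c"] == pytest.approx(0.0)
        # fully tied triangle at a = 0.5 -> TOM = (0.25+0.5)/(1+1-0.5)
        A3 = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"),
                          columns=list("abc"))
        np.fill_diagonal(A3.values, 1.0)
        T3 = tom_similarity(A3)
        assert T3.loc["a", "b"] == pytest.approx(0.5)

    def test_tom_range_symmetry_on_random_matrices(self, rng):
        for _ in range(50):
            m = rng.integers(3, 12)
            C = rng.uniform(0, 1, size=(m, m))
            A = (C + C.T) / 2
            np.fill_diagonal(A, 1.0)
            A = pd.DataFrame(A)
            T = tom_similarity(A).to_numpy()
            assert np.allclose(T, T.T)
            assert T.min() >= 0.0 and T.max() <= 1.0
            assert np.allclose(np.diag(T), 1.0)

    def test_tom_brute_force_oracle(self, rng):
        """Matrix TOM equals an explicit triple-loop evaluation."""
        worst = 0.0
        for _ in range(50):
            m = int(rng.integers(3, 9))
            C = rng.uniform(0, 1, size=(m, m))
            A = (C + C.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_similarity(pd.DataFrame(A)).to_numpy()
            k = A.sum(axis=0) - 1.0
            for i in range(m):
                for j in range(m):
                    if i == j:
                        continue
                    shared = sum(
                        A[i, u] * A[u, j] for u in range(m) if u not in (i, j)
                    )
                    denom = min(k[i], k[j]) + 1.0 - A[i, j]
                    worst = max(
                        worst, abs(T[i, j] - (shared + A[i, j]) / denom)
                    )
        assert worst < 1e-8


class TestModuleDetection:
    def test_two_separable_blocks(self, rng):
        cfg = NetworkConfig(min_module_size=3, cut_height=0.5)
        blocks = np.zeros((10, 10))
        blocks[:5, :5] = 1.0
        blocks[5:, 5:] = 1.0
        tom = pd.DataFrame(blocks, index=[f"p{i}" for i in range(10)],
                           columns=[f"p{i}" for i in range(10)])
        asg = detect_modules(tom, cfg)
        assert asg.nunique() == 2
        assert asg.iloc[:5].nunique() == 1 and asg.iloc[5:].nunique() == 1

    def test_identical_probes_single_module(self):
        cfg = NetworkConfig(min_module_size=3, cut_height=0.5)
        tom = pd.DataFrame(np.ones((6, 6)), index=[f"p{i}" for i in range(6)],
                           columns=[f"p{i}" for i in range(6)])
        asg = detect_modules(tom, cfg)
        assert set(asg) == {"M1"}

    def test_fewer_probes_than_min_size_all_unassigned(self):
        cfg = NetworkConfig(min_module_size=30)
        tom = pd.DataFrame(np.eye(5), index=[f"p{i}" for i in range(5)],
                           columns=[f"p{i}" for i in range(5)])
        assert set(detect_modules(tom, cfg)) == {"unassigned"}

    def test_deterministic(self, default_analysis):
        asg = default_analysis.module_set.assignment
        assert asg.to_csv() == asg.to_csv()  # stable serialization
        assert "unassigned" in set(asg)


class TestEigengene:
    def test_single_probe_module_is_zscore(self, rng):
        expr = expr_frame(rng.normal(size=(20, 1)), probes=["solo"])
        me = module_eigengene(expr, ["solo"])
        z = stats.zscore(expr["solo"], ddof=1)
        np.testing.assert_allclose(me.to_numpy(), z, atol=1e-10)
        assert module_membership(expr["solo"], me) == pytest.approx(1.0)

    def test_identical_probes_match_single(self, rng):
        x = rng.normal(size=30)
        expr = expr_frame(np.column_stack([x, x, x]))
        me = module_eigengene(expr, list(expr.columns))
        z = stats.zscore(x, ddof=1)
        np.testing.assert_allclose(me.to_numpy(), z, atol=1e-10)

    def test_svd_oracle_and_sign_convention(self, rng):
        """ME matches the leading left singular vector of the z-scored
        matrix (up to sign) and correlates non-negatively with the
        module mean, on 50 random fixtures."""
        worst = 0.0
        for _ in range(50):
            n, m = 15, 5
            expr = expr_frame(rng.normal(size=(n, m)))
            me = module_eigengene(expr, list(expr.columns)).to_numpy()
            Z = stats.zscore(expr.to_numpy(), axis=0, ddof=1)
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            u = U[:, 0] / U[:, 0].std(ddof=1)
            worst = max(worst, min(
                np.abs(me - u).max(), np.abs(me + u).max()
            ))
            assert np.corrcoef(me, Z.mean(axis=1))[0, 1] >= -1e-12
        assert worst < 1e-8

    def test_insufficient_samples(self, rng):
        expr = expr_frame(rng.normal(size=(2, 3)))
        with pytest.raises(InsufficientDataError):
            module_eigengene(expr, list(expr.columns))


class TestMergeModules:
    def test_identical_eigengenes_merge(self, rng):
        x = rng.normal(size=40)
        noise = rng.normal(scale=0.01, size=(40, 6))
        expr = expr_frame(x[:, None] + noise)
        asg = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
        ms = build_module_set(expr, asg)
        merged = merge_modules(expr, ms, 0.25)
        assert len(merged.eigengenes.columns) == 1

    def test_uncorrelated_eigengenes_not_merged(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        expr = expr_frame(np.column_stack(
            [a + rng.normal(scale=0.01, size=50) for _ in range(3)]
            + [b + rng.normal(scale=0.01, size=50) for _ in range(3)]
        ))
        asg = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
        merged = merge_modules(expr, build_module_set(expr, asg), 0.25)
        assert len(merged.eigengenes.columns) == 2

    def test_iterative_merge_matches_closest_pair_oracle(self, rng):
        """Three modules with dissimilarities straddling the threshold:
        merging follows the iterative closest-pair rule."""
        base = rng.normal(size=60)
        mods = {
            "A": base + rng.normal(scale=0.3, size=60),
            "B": base + rng.normal(scale=0.3, size=60),
            "C": rng.normal(size=60),
        }
        cols, labels = [], []
        for name, center in mods.items():
            for _ in range(4):
                cols.append(center + rng.normal(scale=0.1, size=60))
                labels.append(name)
        expr = expr_frame(np.column_stack(cols))
        asg = pd.Series(labels, index=expr.columns)
        ms = build_module_set(expr, asg)
        d_ab = 1 - np.corrcoef(ms.eigengenes["A"], ms.eigengenes["B"])[0, 1]
        assert d_ab < 0.25  # fixture sanity: A,B similar; C unrelated
        merged = merge_modules(expr, ms, 0.25)
        assert sorted(merged.eigengenes.columns) == ["A", "C"]
        assert set(merged.assignment[merged.assignment == "A"].index) == set(
            expr.columns[:8]
        )

    def test_never_increases_module_count(self, rng):
        expr = expr_frame(rng.normal(size=(30, 9)))
        asg = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=expr.columns)
        ms = build_module_set(expr, asg)
        merged = merge_modules(expr, ms, 0.6)
        assert len(merged.eigengenes.columns) <= 3


class TestConnectivityAndHubs:
    def test_mm_examples(self, rng):
        me = pd.Series(rng.normal(size=25))
        assert module_membership(me, me) == pytest.approx(1.0)
        assert module_membership(-me, me) == pytest.approx(-1.0)

    def test_mm_direct_formula_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            mm = module_membership(pd.Series(x), pd.Series(y))
            xc, yc = x - x.mean(), y - y.mean()
            oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert mm == pytest.approx(oracle, abs=1e-12)

    def test_soft_connectivity_examples_and_oracle(self, rng):
        # perfect pair
        expr = expr_frame(np.column_stack([np.arange(10.0), np.arange(10.0) * 2]))
        adj = adjacency(expr, 6)
        k = soft_connectivity(adj, list(expr.columns))
        assert np.allclose(k, 1.0)
        # brute-force double loop on random modules
        for _ in range(50):
            m = int(rng.integers(3, 8))
            expr = expr_frame(rng.normal(size=(20, m)))
            adj = adjacency(expr, 6)
            k = soft_connectivity(adj, list(expr.columns))
            A = adj.to_numpy()
            for i in range(m):
                oracle = sum(A[i, u] for u in range(m) if u != i)
                assert k.iloc[i] == pytest.approx(oracle, abs=1e-10)

    def test_unknown_probe_raises_keyerror(self, rng):
        expr = expr_frame(rng.normal(size=(10, 3)))
        adj = adjacency(expr, 6)
        with pytest.raises(KeyError):
            soft_connectivity(adj, ["p0", "ghost"])

    def test_rank_hubs_collapses_and_breaks_ties(self):
        conn = pd.DataFrame(
            {
                "probe": ["a1", "a2", "b1", "c1"],
                "gene": ["GA", "GA", "GB", "GC"],
                "module": ["M1"] * 4,
                "mm": [0.9, 0.5, -0.9, 0.7],
                "k": [1.0, 2.0, 1.0, 3.0],
            }
        )
        ranked = rank_hubs(conn)
        # gene GA represented by its |MM|=0.9 probe, not the higher-K one
        assert ranked.loc[ranked["gene"] == "GA", "probe"].iloc[0] == "a1"
        # |MM| ties (GA 0.9 vs GB -0.9): equal K -> lexicographic by gene
        assert list(ranked["gene"]) == ["GA", "GB", "GC"]

    def test_rank_hubs_argmax_oracle(self, default_analysis):
        conn = default_analysis.connectivity
        m = conn["module"].iloc[0]
        sub = conn[conn["module"] == m]
        ranked = rank_hubs(sub)
        top = ranked.iloc[0]
        assert abs(top["mm"]) == pytest.approx(sub["mm"].abs().max())


class TestModuleTraitCorrelation:
    def test_perfect_and_null(self, rng):
        me = pd.Series(rng.normal(size=30))
        r, p = module_trait_correlation(me, me)
        assert r == pytest.approx(1.0) and p <= 1e-300
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        xc = x - x.mean()
        y = y - y.mean()
        y -= xc * (xc @ y) / (xc @ xc)
        r0, p0 = module_trait_correlation(pd.Series(x), y)
        assert abs(r0) < 1e-12 and p0 == pytest.approx(1.0)

    def test_t_cdf_oracle(self):
        """r = 0.5 at n = 27 reproduces the two-sided t tail mass."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=27)
        e = rng.normal(size=27)
        xc = x - x.mean()
        ec = e - e.mean()
        ec -= xc * (xc @ ec) / (xc @ xc)
        y = 0.5 * xc / np.linalg.norm(xc) + np.sqrt(0.75) * ec / np.linalg.norm(ec)
        r, p = correlation_test(x, y)
        t = r * np.sqrt(25 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 25), rel=1e-12)
        assert r == pytest.approx(0.5, abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            module_trait_correlation(pd.Series([1.0, 2.0, 3.0]), [1.0, 2.0, 3.0])


class TestPickSoftPower:
    def test_single_candidate(self, rng):
        expr = expr_frame(rng.normal(size=(30, 25)))
        cfg = NetworkConfig(power_grid=[6], scale_free_r2_min=0.0)
        pick = pick_soft_power(expr, cfg)
        assert pick.beta == 6 and not pick.fallback

    def test_fallback_flag_when_nothing_qualifies(self, rng):
        expr = expr_frame(rng.normal(size=(30, 25)))
        cfg = NetworkConfig(power_grid=[1, 2], scale_free_r2_min=1.0, beta=6)
        pick = pick_soft_power(expr, cfg)
        assert pick.beta == 6 and pick.fallback

    def test_grid_search_matches_exhaustive_oracle(self, default_dataset):
        _, _, esim, _ = default_dataset
        expr = esim.expression.iloc[:, :80]
        cfg = NetworkConfig(power_grid=list(range(1, 13)),
                            scale_free_r2_min=0.80)
        pick = pick_soft_power(expr, cfg)
        qualifying = []
        for beta in range(1, 13):
            A = adjacency(expr, beta).to_numpy()
            r2 = scale_free_fit_r2(A.sum(axis=0) - 1.0)
            if r2 >= 0.80:
                qualifying.append(beta)
        if qualifying:
            assert not pick.fallback and pick.beta == qualifying[0]
        else:
            assert pick.fallback and pick.beta == cfg.beta

    def test_empty_grid_rejected(self, rng):
        expr = expr_frame(rng.normal(size=(25, 25)))
        with pytest.raises(ConfigError):
            pick_soft_power(expr, NetworkConfig(power_grid=[]))
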