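"""Co-expression: gene selection, soft power, module detection, NES, hubs."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tissueatlas import ExpressionAtlas
from tissueatlas.coexpression import (
    detect_modules,
    find_hubs,
    module_activity,
    select_genes,
    select_soft_power,
)


def _two_module_matrix(seed=7, n_noise=40, module_size=30, noise_sd=0.1):
    rng = np.random.default_rng(seed)
    S = 20
    G = 2 * module_size + n_noise
    X = noise_sd * rng.standard_normal((S, G))
    X[:, :module_size] += np.outer(rng.standard_normal(S),
                                   rng.uniform(0.8, 1.2, module_size))
    X[:, module_size:2 * module_size] += np.outer(rng.standard_normal(S),
                                                  rng.uniform(0.8, 1.2, module_size))
    return pd.DataFrame(X, columns=[f"g{i:03d}" for i in range(G)])


class TestSelectGenes:
    def test_all_genes_is_identity(self, rng):
        prof = pd.DataFrame(rng.uniform(0, 50, (30, 6)),
                            index=[f"g{i}" for i in range(30)])
        assert set(select_genes(prof, 30)) == set(prof.index)

    def test_constant_genes_ranked_last(self, rng):
        X = rng.uniform(1, 50, (20, 6))
        X[:5] = 7.0
        prof = pd.DataFrame(X, index=[f"g{i}" for i in range(20)])
        top = select_genes(prof, 15)
        assert not {"g0", "g1", "g2", "g3", "g4"} & set(top)

    def test_matches_variance_loop(self, rng):
        X = rng.uniform(0, 200, (150, 8))
        prof = pd.DataFrame(X, index=[f"g{i:03d}" for i in range(150)])
        top = select_genes(prof, 100)
        logx = np.log2(X + 1)
        variances = {}
        for g in range(150):
            v = logx[g]
            variances[f"g{g:03d}"] = ((v - v.mean()) ** 2).sum() / (len(v) - 1)
        expected = sorted(sorted(variances, key=lambda g: (-variances[g], g))[:100])
        assert top == expected

    def test_n_top_too_large_rejected(self, rng):
        prof = pd.DataFrame(rng.uniform(0, 1, (5, 4)))
        with pytest.raises(ValueError, match="n_top"):
            select_genes(prof, 6)


class TestSelectSoftPower:
    def test_identity_matrix_falls_back(self):
        assert select_soft_power(np.eye(40)) == 6

    def test_scale_free_blocks_pick_smallest_candidate(self):
        # many small blocks, one large one: a decreasing degree distribution
        # that perfect blocks keep identical at every power
        sizes = [3] * 30 + [30]
        corr = np.zeros((sum(sizes), sum(sizes)))
        i0 = 0
        for s in sizes:
            corr[i0:i0 + s, i0:i0 + s] = 1.0
            i0 += s
        assert select_soft_power(corr) == 1

    def test_deterministic(self):
        X = _two_module_matrix(seed=3)
        corr = np.corrcoef(X.values.T)
        assert select_soft_power(corr, n_samples=20) == select_soft_power(corr, n_samples=20)


class TestDetectModules:
    def test_two_planted_modules_recovered(self):
        expr = _two_module_matrix(seed=7)
        beta = select_soft_power(np.corrcoef(expr.values.T), n_samples=len(expr))
        modules, _ = detect_modules(expr, beta)
        assert len(modules) == 2
        truth = [0] * 30 + [1] * 30 + list(range(2, 42))
        assignment = {g: i + 1 for i, m in enumerate(modules) for g in m.genes}
        pred = [assignment.get(f"g{i:03d}", 1000 + i) for i in range(100)]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_modules_are_disjoint_and_min_sized(self):
        expr = _two_module_matrix(seed=1)
        modules, _ = detect_modules(expr, 10, min_module_size=10)
        seen = set()
        for m in modules:
            assert len(m) >= 10
            assert not set(m.genes) & seen
            seen |= set(m.genes)

    def test_pure_noise_yields_no_modules(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((20, 200)),
                            columns=[f"g{i}" for i in range(200)])
        beta = select_soft_power(np.corrcoef(expr.values.T), n_samples=20)
        modules, _ = detect_modules(expr, beta)
        assert modules == []

    def test_gene_order_invariance(self):
        expr = _two_module_matrix(seed=2)
        rng = np.random.default_rng(9)
        perm = rng.permutation(expr.shape[1])
        shuffled = expr.iloc[:, perm]
        m1, _ = detect_modules(expr, 10)
        m2, _ = detect_modules(shuffled, 10)
        assert [m.genes for m in m1] == [m.genes for m in m2]


class TestModuleActivity:
    def test_flat_module_not_significant(self):
        # exactly-uniform module genes inside a noisy universe: the module
        # score sits mid-null in every tissue
        rng = np.random.default_rng(8)
        tissues = [f"t{i}" for i in range(10)]
        design = pd.DataFrame({
            "sample_id": [f"{t}_r{j}" for t in tissues for j in (1, 2)],
            "tissue": [t for t in tissues for _ in (1, 2)],
        })
        tpm = 2.0 ** rng.normal(5, 1, (500, 20))
        tpm[:20] = 32.0
        atlas = ExpressionAtlas(
            expression=pd.DataFrame(tpm, index=[f"g{i}" for i in range(500)],
                                    columns=design["sample_id"]),
            design=design,
        )
        act = module_activity([f"g{i}" for i in range(20)], atlas,
                              n_perm=500, seed=1)
        for tissue, (nes, p) in act.items():
            assert p > 0.05
            assert abs(nes) < 2.5

    def test_planted_module_peaks_in_its_tissue(self, small_sim):
        _, atlas, _, truth, _ = small_sim
        for mod in truth.modules:
            act = module_activity(mod["genes"], atlas, n_perm=500, seed=2)
            best = max(act, key=lambda t: act[t][0])
            assert best == mod["tissue"]
            assert act[best][1] < 0.05

    def test_nes_stable_under_more_permutations(self, small_sim):
        _, atlas, _, truth, _ = small_sim
        genes = truth.modules[0]["genes"]
        a1 = module_activity(genes, atlas, n_perm=500, seed=3)
        a2 = module_activity(genes, atlas, n_perm=1000, seed=3)
        t = truth.modules[0]["tissue"]
        assert a1[t][0] == pytest.approx(a2[t][0], rel=0.2)

    def test_missing_genes_rejected(self, small_sim):
        _, atlas, _, _, _ = small_sim
        with pytest.raises(ValueError, match="absent"):
            module_activity(["nope1", "nope2"], atlas, n_perm=100, seed=0)


class TestFindHubs:
    @staticmethod
    def _star_adjacency():
        genes = ["centre", "a", "b", "c", "d"]
        A = np.full((5, 5), 0.5)
        A[0, :] = A[:, 0] = 0.95
        np.fill_diagonal(A, 0.0)
        return pd.DataFrame(A, index=genes, columns=genes), genes

    def test_star_centre_ranks_first(self):
        adj, genes = self._star_adjacency()
        hubs = find_hubs(genes, adj, k=3)
        assert hubs[0][0] == "centre"

    def test_k_equals_module_size_returns_all(self):
        adj, genes = self._star_adjacency()
        hubs = find_hubs(genes, adj, k=5)
        assert len(hubs) == 5
        conns = [c for _, c in hubs]
        assert conns == sorted(conns, reverse=True)

    def test_k_larger_than_module_warns_and_returns_all(self):
        adj, genes = self._star_adjacency()
        assert len(find_hubs(genes, adj, k=50)) == 5

    def test_connectivity_matches_double_loop(self, rng):
        n = 12
        genes = [f"g{i}" for i in range(n)]
        A = rng.uniform(0, 1, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        adj = pd.DataFrame(A, index=genes, columns=genes)
        module = genes[:8]
        hubs = dict(find_hubs(module, adj, k=8))
        for gi, g in enumerate(module):
            expected = sum(A[gi, gj] for gj in range(8) if gj != gi)
            assert hubs[g] == pytest.approx(expected, abs=1e-12)

    def test_ties_broken_by_gene_id(self):
        genes = ["z", "a", "m"]
        A = np.ones((3, 3)) - np.eye(3)
        adj = pd.DataFrame(A, index=genes, columns=genes)
        hubs = find_hubs(genes, adj, k=3)
        assert [g for g, _ in hubs] == ["a", "m", "z"]
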