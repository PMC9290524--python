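import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from foragenet import network as nw
from foragenet.errors import ConstantGeneError, DegenerateModuleError, InvalidConfigError
from tests.conftest import make_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the unsigned TOM formula (test oracle)."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            num += a[i, j]
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            tom[i, j] = num / denom if denom > 0 else 0.0
    return tom


def random_adjacency(rng, n=10):
    m = rng.uniform(0, 1, size=(n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return nw.AdjacencyMatrix(gene_ids=[f"g{i}" for i in range(n)], a=a, power=1.0)


class TestAdjacency:
    def test_power_arithmetic(self):
        # two genes with correlation 0.5 at power 2 -> adjacency 0.25
        x = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]])
        r = np.corrcoef(x)[0, 1]
        adj = nw.adjacency(make_expression(x), power=2.0)
        assert adj.a[0, 1] == pytest.approx(r**2)
        assert adj.a[0, 0] == 1.0

    def test_anticorrelated_pair_is_fully_connected_unsigned(self):
        x = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        adj = nw.adjacency(make_expression(x), power=1.0)
        assert adj.a[0, 1] == pytest.approx(1.0)

    def test_constant_gene_rejected(self):
        x = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ConstantGeneError):
            nw.adjacency(make_expression(x), power=2.0)


class TestTopologicalOverlap:
    def test_complete_graph_by_hand(self):
        # 3 genes, every a_ij = 1: TOM_12 = (1 + 1) / (min(2,2) + 1 - 1) = 1
        a = np.ones((3, 3))
        tom = nw.topological_overlap(
            nw.AdjacencyMatrix(gene_ids=["a", "b", "c"], a=a, power=1)
        )
        assert np.allclose(tom.tom, 1.0)

    def test_empty_graph(self):
        a = np.eye(4)
        tom = nw.topological_overlap(
            nw.AdjacencyMatrix(gene_ids=list("abcd"), a=a, power=1)
        )
        off = tom.tom[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(tom.tom), 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            adj = random_adjacency(rng)
            tom = nw.topological_overlap(adj)
            assert np.allclose(tom.tom, brute_force_tom(adj.a), atol=1e-12)


class TestSoftThreshold:
    def test_power_law_connectivity_scores_high(self):
        # connectivities drawn from a heavy-tailed power law should yield a
        # fit index near 1, agreeing with an independent log-log regression
        rng = np.random.default_rng(0)
        k = (1.0 - rng.uniform(0, 0.99, 3000)) ** (-1.0 / 1.5)  # Pareto tail
        fit = nw.scale_free_fit(k, n_bins=10)
        assert fit > 0.9
        # independent oracle: same statistic via pandas binning
        bins = pd.cut(pd.Series(k), bins=10)
        grouped = pd.Series(k).groupby(bins, observed=True)
        mean_k, freq = grouped.mean(), grouped.size()
        keep = freq > 0
        res = linregress(np.log10(mean_k[keep]), np.log10(freq[keep]))
        assert fit == pytest.approx(-np.sign(res.slope) * res.rvalue**2, abs=1e-10)

    def test_vacuous_target_picks_first_power(self, small_dataset):
        scan = nw.pick_soft_threshold(
            small_dataset["logexpr"], powers=[3, 6, 9], target_r2=-1.0
        )
        assert scan.chosen_power == 3

    def test_degenerate_equal_connectivity_does_not_crash(self):
        # two blocks of perfectly correlated genes: k is constant per block
        base = np.linspace(0, 1, 10)
        rows = [base + i * 0 for i in range(20)] + [base[::-1] for _ in range(20)]
        x = np.array(rows) + np.arange(40)[:, None] * 1e-9  # break exact constancy
        scan = nw.pick_soft_threshold(make_expression(x), powers=[1, 2])
        assert scan.chosen_power in (1.0, 2.0)

    def test_constant_gene_named_error(self):
        x = np.vstack([np.ones(10), np.random.default_rng(1).normal(size=(39, 10))])
        with pytest.raises(ConstantGeneError):
            nw.pick_soft_threshold(make_expression(x))


class TestClusterAndCut:
    def test_identical_genes_merge_at_height_zero(self):
        # genes with TOM 1 (dissimilarity 0) merge first, at height 0
        tom = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        tree = nw.cluster_genes(nw.TomMatrix(gene_ids=list("abc"), tom=tom))
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        adj = random_adjacency(rng, n=12)
        tree = nw.cluster_genes(nw.topological_overlap(adj))
        assert (np.diff(tree[:, 2]) >= -1e-12).all()

    def test_three_gene_average_linkage_by_hand(self):
        # dissimilarities: d(a,b)=0.1, d(a,c)=0.5, d(b,c)=0.7
        # average linkage: merge (a,b) at 0.1, then c at (0.5+0.7)/2 = 0.6
        tom = np.array(
            [[1.0, 0.9, 0.5], [0.9, 1.0, 0.3], [0.5, 0.3, 1.0]]
        )
        tree = nw.cluster_genes(nw.TomMatrix(gene_ids=list("abc"), tom=tom))
        assert tree[0, 2] == pytest.approx(0.1)
        assert tree[1, 2] == pytest.approx(0.6)

    def planted_two_block_tom(self):
        n = 10
        tom = np.zeros((n, n))
        tom[:5, :5] = 0.99
        tom[5:, 5:] = 0.99
        np.fill_diagonal(tom, 1.0)
        return nw.TomMatrix(gene_ids=[f"g{i}" for i in range(n)], tom=tom)

    def test_two_planted_blocks_found(self):
        tom = self.planted_two_block_tom()
        modules = nw.cut_modules(nw.cluster_genes(tom), tom.gene_ids, min_module_size=3)
        assert len(modules.module_names) == 2
        assert (modules.labels != nw.UNASSIGNED).all()

    def test_min_size_larger_than_gene_count_unassigns_all(self):
        tom = self.planted_two_block_tom()
        modules = nw.cut_modules(nw.cluster_genes(tom), tom.gene_ids, min_module_size=11)
        assert (modules.labels == nw.UNASSIGNED).all()

    def test_cut_height_zero_unassigns_all(self):
        rng = np.random.default_rng(3)
        adj = random_adjacency(rng, n=8)
        tom = nw.topological_overlap(adj)
        modules = nw.cut_modules(
            nw.cluster_genes(tom), tom.gene_ids, min_module_size=3, cut_height=0.0
        )
        assert (modules.labels == nw.UNASSIGNED).all()

    def test_min_module_size_validation(self):
        tom = self.planted_two_block_tom()
        with pytest.raises(InvalidConfigError):
            nw.cut_modules(nw.cluster_genes(tom), tom.gene_ids, min_module_size=1)


class TestEigengene:
    def test_identical_profiles_give_zscored_profile(self):
        profile = np.array([1.0, 4.0, 2.0, 8.0])
        x = np.tile(profile, (5, 1))
        expr = make_expression(x)
        eig, ev = nw.compute_eigengene(expr, expr.gene_ids)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(eig.to_numpy(), z, atol=1e-12)
        assert ev == pytest.approx(1.0)

    def test_orientation_invariant_to_global_negation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 10))
        expr = make_expression(x)
        eig, _ = nw.compute_eigengene(expr, expr.gene_ids)
        neg, _ = nw.compute_eigengene(make_expression(-x), expr.gene_ids)
        assert np.allclose(np.abs(eig.to_numpy()), np.abs(neg.to_numpy()), atol=1e-9)

    def test_matches_independent_svd_oracle(self):
        x = np.array(
            [[2.0, 1.0, 4.0, 3.0], [1.0, 1.5, 3.5, 4.0], [5.0, 2.0, 1.0, 2.0]]
        )
        expr = make_expression(x)
        eig, ev = nw.compute_eigengene(expr, expr.gene_ids)
        # oracle: eigendecomposition of the sample-by-sample covariance
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        cov = z.T @ z
        vals, vecs = np.linalg.eigh(cov)
        pc1 = vecs[:, -1]
        pc1 = pc1 / pc1.std()
        if np.corrcoef(pc1, eig.to_numpy())[0, 1] < 0:
            pc1 = -pc1
        assert np.allclose(eig.to_numpy(), pc1, atol=1e-9)
        assert ev == pytest.approx(vals[-1] / vals.sum())

    def test_zero_mean_unit_variance(self, small_dataset):
        expr = small_dataset["logexpr"]
        genes = [g for g in expr.gene_ids if g.startswith("planted1")]
        eig, ev = nw.compute_eigengene(expr, genes)
        assert eig.mean() == pytest.approx(0.0, abs=1e-10)
        assert eig.to_numpy().std() == pytest.approx(1.0)
        assert 0 < ev <= 1

    def test_constant_module_rejected(self):
        x = np.ones((3, 5))
        with pytest.raises(DegenerateModuleError):
            nw.compute_eigengene(make_expression(x), ["g1", "g2", "g3"])


class TestMergeModules:
    def make_modules(self, expr, mapping):
        labels = pd.Series(nw.UNASSIGNED, index=expr.values.index, dtype=object)
        for mod, genes in mapping.items():
            labels[genes] = mod
        return nw.attach_eigengenes(expr, nw.ModuleSet(labels=labels))

    def test_identical_eigengene_modules_merge(self):
        profile = np.linspace(0, 1, 8)
        rng = np.random.default_rng(0)
        x = np.vstack([profile + rng.normal(0, 0.01, 8) for _ in range(6)])
        expr = make_expression(x)
        modules = self.make_modules(
            expr, {"m1": expr.gene_ids[:3], "m2": expr.gene_ids[3:]}
        )
        merged = nw.merge_modules(expr, modules, merge_height=0.2)
        assert len(merged.module_names) == 1

    def test_distant_modules_stay_separate(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=8)
        b = rng.normal(size=8)  # independent profiles
        x = np.vstack([a + rng.normal(0, 0.01, 8) for _ in range(3)]
                      + [b + rng.normal(0, 0.01, 8) for _ in range(3)])
        expr = make_expression(x)
        modules = self.make_modules(
            expr, {"m1": expr.gene_ids[:3], "m2": expr.gene_ids[3:]}
        )
        merged = nw.merge_modules(expr, modules, merge_height=0.3)
        assert len(merged.module_names) == 2

    def test_chained_merging(self):
        # three modules with pairwise eigengene dissimilarities ~(0.1, 0.1,
        # 0.4): greedy iteration chains them into a single module
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        tilt = rng.normal(size=40)

        def noisy(vec, n=3, sd=0.01):
            return [vec + rng.normal(0, sd, vec.size) for _ in range(n)]

        va = base
        vb = 0.78 * base + np.sqrt(1 - 0.78**2) * tilt  # r ~ 0.78 with both
        vc = 0.9 * vb + rng.normal(0, 0.25, 40)
        x = np.vstack(noisy(va) + noisy(vb) + noisy(vc))
        expr = make_expression(x)
        modules = self.make_modules(
            expr,
            {"m1": expr.gene_ids[:3], "m2": expr.gene_ids[3:6], "m3": expr.gene_ids[6:]},
        )
        eig = modules.eigengenes.to_numpy()
        diss = 1 - np.corrcoef(eig)
        assert diss[0, 1] > 0.1  # a-c style far pair exists
        merged = nw.merge_modules(expr, modules, merge_height=0.35)
        assert len(merged.module_names) == 1


class TestConnectivity:
    def test_gene_equal_to_eigengene_has_kme_one(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(size=12)
        x = np.vstack([profile, profile * 2 + 1, rng.normal(size=12)])
        expr = make_expression(x)
        eig = pd.DataFrame([profile], index=["m"], columns=expr.sample_ids)
        kme = nw.module_connectivity(expr, eig)
        assert kme.loc["g1", "m"] == pytest.approx(1.0)
        assert kme.loc["g2", "m"] == pytest.approx(1.0)  # affine copy

    def test_noise_gene_has_small_kme(self):
        rng = np.random.default_rng(6)
        profile = rng.normal(size=100)
        noise = rng.normal(size=100)
        expr = make_expression(np.vstack([profile, noise]))
        eig = pd.DataFrame([profile], index=["m"], columns=expr.sample_ids)
        kme = nw.module_connectivity(expr, eig)
        assert abs(kme.loc["g2", "m"]) < 0.3

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2, 20))
        eig = pd.DataFrame([x[0]], index=["m"], columns=[f"s{j+1}" for j in range(20)])
        kme_pos = nw.module_connectivity(make_expression(x), eig)
        kme_neg = nw.module_connectivity(make_expression(-x), eig)
        assert kme_pos.loc["g2", "m"] == pytest.approx(-kme_neg.loc["g2", "m"])


class TestPercentileProfile:
    def build(self, n_genes=10):
        rng = np.random.default_rng(9)
        profile = rng.normal(size=20)
        x = np.vstack(
            [k * profile + np.sqrt(1 - k**2) * rng.normal(size=20)
             for k in np.linspace(0.99, 0.3, n_genes)]
        ) + 5.0
        expr = make_expression(x)
        labels = pd.Series("m", index=expr.values.index)
        modules = nw.attach_eigengenes(expr, nw.ModuleSet(labels=labels))
        return expr, modules

    def test_reference_against_itself_is_unity(self):
        expr, modules = self.build()
        top = nw.rank_by_connectivity(modules, "m")[0]
        table = nw.percentile_gene_profile(expr, modules, "m", top, percentiles=[1])
        assert np.allclose(table.iloc[:, 0], expr.values.loc[top] / expr.values.loc[top])

    def test_percentile_rank_arithmetic(self):
        expr, modules = self.build(n_genes=10)
        order = nw.rank_by_connectivity(modules, "m")
        table = nw.percentile_gene_profile(
            expr, modules, "m", order[0], percentiles=[1, 50, 100]
        )
        names = [c.split(":")[1] for c in table.columns]
        # ceil(0.01*10)=1, ceil(0.5*10)=5, ceil(1.0*10)=10
        assert names == [order[0], order[4], order[9]]

    def test_zero_reference_sample_yields_missing(self):
        expr, modules = self.build()
        ref = nw.rank_by_connectivity(modules, "m")[0]
        expr.values.loc[ref, expr.sample_ids[0]] = 0.0
        modules = nw.attach_eigengenes(expr, nw.ModuleSet(labels=modules.labels))
        table = nw.percentile_gene_profile(expr, modules, "m", ref, percentiles=[50])
        assert np.isnan(table.iloc[0, 0])


def test_gene_permutation_invariance(small_dataset):
    """Permuting gene order permutes labels consistently (same partition)."""
    from sklearn.metrics import adjusted_rand_score

    expr = small_dataset["logexpr"]
    rng = np.random.default_rng(10)
    perm = rng.permutation(expr.n_genes)
    permuted = make_expression(
        expr.values.to_numpy()[perm],
        genes=[expr.gene_ids[i] for i in perm],
        samples=expr.sample_ids,
    )
    m1, _ = nw.detect_modules(expr, power=6)
    m2, _ = nw.detect_modules(permuted, power=6)
    joined = pd.concat([m1.labels.rename("a"), m2.labels.rename("b")], axis=1)
    assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)
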