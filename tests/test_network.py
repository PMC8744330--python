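"""PCC edges, BH filtering, PMFG growth, multiscale modules, hubs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from senescape import network as net


def _expr(rng, n_genes=10, n_samples=20):
    return pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                        index=[f"g{i:02d}" for i in range(n_genes)])


def _rank_all_pairs(cands):
    """Rank candidates by |r| without the FDR gate (for graph fixtures)."""
    ranked = cands.sort_values(
        ["r", "gene_a", "gene_b"],
        key=lambda s: -s.abs() if s.name == "r" else s).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


class TestPairwisePcc:
    def test_exact_copy_and_negation(self, rng):
        base = rng.normal(size=30)
        expr = pd.DataFrame({"orig": base, "copy": base, "neg": -base}).T
        cands = net.pairwise_pcc(expr)
        lookup = {(a, b): r for a, b, r in
                  zip(cands.gene_a, cands.gene_b, cands.r)}
        assert lookup[("copy", "orig")] == pytest.approx(1.0)
        assert lookup[("copy", "neg")] == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self, rng):
        expr = _expr(rng)
        cands = net.pairwise_pcc(expr)
        for row in cands.itertuples():
            x = expr.loc[row.gene_a].to_numpy()
            y = expr.loc[row.gene_b].to_numpy()
            r = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sqrt(np.sum((x - x.mean()) ** 2)
                           * np.sum((y - y.mean()) ** 2)))
            assert row.r == pytest.approx(r, abs=1e-12)

    def test_zero_variance_gene_excluded(self, rng):
        expr = _expr(rng, n_genes=5)
        expr.iloc[0] = 3.0
        cands = net.pairwise_pcc(expr)
        assert cands.attrs["n_dropped"] == 1
        assert "g00" not in set(cands.gene_a) | set(cands.gene_b)

    def test_p_from_t_transform(self, rng):
        from scipy import stats
        expr = _expr(rng, n_genes=4, n_samples=15)
        cands = net.pairwise_pcc(expr)
        for row in cands.itertuples():
            t = row.r * np.sqrt(13 / (1 - row.r ** 2))
            assert row.p == pytest.approx(2 * stats.t.sf(abs(t), 13), rel=1e-10)


class TestFdrFilter:
    def test_all_ones_empty_and_single_pair_kept(self):
        ones = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"],
                             "r": [0.1], "p": [1.0]})
        assert len(net.fdr_filter_edges(ones)) == 0
        single = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"],
                               "r": [0.9], "p": [0.01]})
        assert len(net.fdr_filter_edges(single)) == 1

    def test_kept_set_matches_bh_definition(self, rng):
        n = 100
        p = rng.uniform(size=n) ** 2
        cands = pd.DataFrame({
            "gene_a": [f"a{i:03d}" for i in range(n)],
            "gene_b": [f"b{i:03d}" for i in range(n)],
            "r": rng.uniform(-1, 1, size=n), "p": p})
        kept = net.fdr_filter_edges(cands, alpha=0.05)
        # brute-force BH: largest i with p_(i) <= i*alpha/n
        order = np.argsort(p)
        cutoff_i = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i * 0.05 / n:
                cutoff_i = i
        expected = set(np.asarray(order[:cutoff_i]))
        assert set(int(g[1:]) for g in kept.gene_a) == expected

    def test_sorted_by_unsigned_strength(self, rng):
        cands = pd.DataFrame({
            "gene_a": ["a", "b", "c"], "gene_b": ["x", "y", "z"],
            "r": [0.5, -0.9, 0.7], "p": [1e-6, 1e-6, 1e-6]})
        kept = net.fdr_filter_edges(cands)
        assert list(kept.r) == [-0.9, 0.7, 0.5]
        assert list(kept["rank"]) == [1, 2, 3]


class TestBuildPfn:
    def _complete_candidates(self, n):
        nodes = [f"n{i}" for i in range(n)]
        rows = [{"gene_a": a, "gene_b": b, "r": 0.9, "p": 0.0}
                for a, b in itertools.combinations(nodes, 2)]
        cands = pd.DataFrame(rows)
        return _rank_all_pairs(cands), nodes

    def test_k4_fully_kept(self):
        ranked, nodes = self._complete_candidates(4)
        g = net.build_pfn(ranked, nodes)
        assert g.number_of_edges() == 6

    def test_k5_drops_exactly_one_edge(self):
        ranked, nodes = self._complete_candidates(5)
        g = net.build_pfn(ranked, nodes)
        assert g.number_of_edges() == 9  # 3*5-6
        ok, _ = nx.check_planarity(g)
        assert ok
        # the rejected edge is the lowest-ranked one (ties broken lexically,
        # so insertion order is deterministic and the last edge fails)
        missing = [e for e in itertools.combinations(nodes, 2)
                   if not g.has_edge(*e)]
        assert missing == [("n3", "n4")]

    def test_matches_naive_greedy_oracle(self, rng):
        expr = _expr(rng, n_genes=30, n_samples=12)
        ranked = _rank_all_pairs(net.pairwise_pcc(expr))
        g = net.build_pfn(ranked, nodes=list(expr.index))
        oracle = _greedy_pfn_oracle(ranked, list(expr.index))
        assert set(map(frozenset, g.edges())) == oracle
        ok, _ = nx.check_planarity(g)
        assert ok
        assert g.number_of_edges() <= 3 * g.number_of_nodes() - 6

    def test_unsigned_contract_negation_invariance(self, rng):
        expr = _expr(rng, n_genes=15, n_samples=25)
        g1 = net.build_tissue_network(expr, alpha=1.0)
        flipped = expr.copy()
        flipped.iloc[3] = -flipped.iloc[3]
        g2 = net.build_tissue_network(flipped, alpha=1.0)
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))


def _greedy_pfn_oracle(ranked, nodes):
    """Re-test planarity from scratch at every insertion."""
    kept = []
    for row in ranked.itertuples(index=False):
        trial = nx.Graph()
        trial.add_nodes_from(nodes)
        trial.add_edges_from(kept + [(row.gene_a, row.gene_b)])
        if nx.check_planarity(trial)[0]:
            kept.append((row.gene_a, row.gene_b))
    return set(map(frozenset, kept))


class TestDetectModules:
    def _two_block_graph(self, rng, block=25):
        """Two dense planar blocks joined by one bridge edge."""
        expr = pd.DataFrame(np.zeros((2 * block, 60)),
                            index=[f"g{i:02d}" for i in range(2 * block)])
        for b in range(2):
            f = rng.normal(size=60)
            for i in range(block):
                expr.iloc[b * block + i] = (np.sqrt(0.8) * f
                                            + np.sqrt(0.2) * rng.normal(size=60))
        return expr

    def test_recovers_two_planted_blocks(self, rng):
        expr = self._two_block_graph(rng)
        g = net.build_tissue_network(expr, alpha=0.05)
        # ensure a single component: add a bridge if the blocks are separate
        comps = list(nx.connected_components(g))
        if len(comps) > 1:
            g.add_edge("g00", "g25", weight=0.1)
        h = net.detect_modules(g, seed=0)
        truth = [0] * 25 + [1] * 25
        best = 0.0
        for depth in range(h.max_depth() + 1):
            lab = h.labels_at_depth(depth)
            pred = [lab[f"g{i:02d}"] for i in range(50)]
            best = max(best, adjusted_rand_score(truth, pred))
        assert best == pytest.approx(1.0)

    def test_small_component_yields_root_only(self):
        g = nx.complete_graph(10)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(10)})
        h = net.detect_modules(g, seed=0)
        assert len(h.modules) == 1
        assert h.modules[0].parent is None

    def test_no_split_on_structure_free_networks(self):
        """Rewire-null calibration: shuffled expression yields no splits."""
        n_with_split = 0
        for seed in range(10):
            r = np.random.default_rng(300 + seed)
            expr = pd.DataFrame(r.normal(size=(40, 30)),
                                index=[f"g{i:02d}" for i in range(40)])
            ranked = _rank_all_pairs(net.pairwise_pcc(expr))
            pfn = net.build_pfn(ranked, nodes=list(expr.index))
            h = net.detect_modules(pfn, seed=seed)
            n_with_split += any(m.depth > 0 for m in h.modules)
        assert n_with_split <= 1

    def test_children_subset_parent_and_min_size(self, rng):
        expr = self._two_block_graph(rng)
        g = net.build_tissue_network(expr, alpha=0.05)
        h = net.detect_modules(g, min_module_size=10, seed=1)
        by_id = h.by_id()
        for m in h.modules:
            assert len(m.members) >= 10
            if m.parent is not None:
                assert set(m.members) <= set(by_id[m.parent].members)


class TestDetectHubs:
    def test_star_center_is_only_hub(self):
        g = nx.star_graph(10)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in range(11)})
        h = net.ModuleHierarchy(modules=[net.Module(
            "M1", None, 0, sorted(g.nodes()))])
        net.detect_hubs(g, h)
        assert h.modules[0].hubs == ["g00"]

    def test_regular_ring_has_no_hubs(self):
        g = nx.cycle_graph(8)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(8)})
        h = net.ModuleHierarchy(modules=[net.Module(
            "M1", None, 0, sorted(g.nodes()))])
        net.detect_hubs(g, h)
        assert h.modules[0].hubs == []

    def test_matches_mean_plus_two_sd_recomputation(self, rng):
        expr = _expr(rng, n_genes=40, n_samples=15)
        g = net.build_tissue_network(expr, alpha=1.0)
        h = net.detect_modules(g, seed=2)
        net.detect_hubs(g, h)
        for m in h.modules:
            sub = g.subgraph(m.members)
            deg = np.array([sub.degree(x) for x in m.members], float)
            expected = sorted(x for x, d in zip(m.members, deg)
                              if d > deg.mean() + 2 * deg.std())
            assert m.hubs == expected

    def test_tiny_module_gets_no_hubs(self):
        g = nx.path_graph(2)
        h = net.ModuleHierarchy(modules=[net.Module("M1", None, 0, [0, 1])])
        net.detect_hubs(g, h)
        assert h.modules[0].hubs == []
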