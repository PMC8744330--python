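"""Unsigned planar-filtered co-expression networks and multiscale modules.

Edges are all-pairs Pearson correlations, FDR-filtered (Benjamini-Hochberg
q <= 0.05), ranked by |r| (unsigned: sign is ignored), and inserted
greedily into a planar maximally filtered graph (PMFG): an edge is kept
iff the graph stays planar, with the exact combinatorial test of
networkx.check_planarity, until all candidates are processed or the planar
bound |E| = 3|V|-6 is reached.

Module detection is a multiscale stand-in built from first principles:
recursive Louvain splitting where a split is accepted only if its
modularity exceeds mean+2SD of modularity over degree-preserving edge
rewires of the same subgraph.  Hubs are genes whose within-module degree
exceeds mean+2SD of the module's degree distribution.  The hierarchy JSON
carries a method tag so these results are not conflated with other
multiscale pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from scipy import stats
from statsmodels.stats.multitest import multipletests

METHOD_TAG = "recursive-modularity+rewire-null"


# --------------------------------------------------------------------------
# Edge candidates
# --------------------------------------------------------------------------

def pairwise_pcc(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlations with two-sided t-transform p-values.

    Returns a DataFrame with columns gene_a, gene_b (a < b lexicographic),
    r and p.  Zero-variance genes are excluded (their correlations are
    undefined); the number removed is recorded in ``df.attrs['n_dropped']``.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sd = expr.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    sub = expr.loc[keep].sort_index()
    genes = list(sub.index)
    mat = sub.to_numpy(dtype=float)
    m = mat.shape[1]
    r = np.corrcoef(mat)
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = np.clip(r[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((m - 2) / np.maximum(1.0 - rv ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    df = pd.DataFrame({
        "gene_a": np.array(genes, dtype=object)[iu],
        "gene_b": np.array(genes, dtype=object)[ju],
        "r": rv,
        "p": np.minimum(p, 1.0),
    })
    df.attrs["n_dropped"] = n_dropped
    return df


def fdr_filter_edges(cands: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-filter edge candidates and rank by |r| (unsigned), strongest first.

    Ties in |r| are broken by (gene_a, gene_b) lexicographic order so the
    ranking, and hence the PMFG, is reproducible.
    """
    if cands.empty:
        out = cands.assign(q=pd.Series(dtype=float), rank=pd.Series(dtype=int))
        return out
    _, q, _, _ = multipletests(cands["p"].to_numpy(), method="fdr_bh")
    out = cands.assign(q=q)
    out = out[out["q"] <= alpha].copy()
    out = out.sort_values(["r", "gene_a", "gene_b"],
                          key=lambda s: -s.abs() if s.name == "r" else s,
                          ascending=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# Planar maximally filtered graph
# --------------------------------------------------------------------------

def build_pfn(ranked_edges: pd.DataFrame, nodes: list[str] | None = None,
              tissue: str | None = None) -> nx.Graph:
    """Grow the planar filtered network by greedy rank-order insertion.

    Each candidate edge is added and the whole graph re-tested with the
    exact planarity check; non-planar insertions are rolled back.  Stops
    early once |E| = 3|V|-6.
    """
    g = nx.Graph(tissue=tissue, is_planar=True)
    if nodes is not None:
        g.add_nodes_from(nodes)
    else:
        g.add_nodes_from(pd.unique(
            ranked_edges[["gene_a", "gene_b"]].to_numpy().ravel()))
    n = g.number_of_nodes()
    max_edges = max(3 * n - 6, 0)
    # planarity is component-wise: an edge joining two components is a
    # bridge and can never create a Kuratowski subgraph, so only
    # intra-component insertions need re-testing (on that component alone).
    comp_of = {node: node for node in g.nodes()}

    def find(x):
        root = x
        while comp_of[root] != root:
            root = comp_of[root]
        while comp_of[x] != root:
            comp_of[x], x = root, comp_of[x]
        return root

    for row in ranked_edges.itertuples(index=False):
        if g.number_of_edges() >= max_edges:
            break
        ra, rb = find(row.gene_a), find(row.gene_b)
        g.add_edge(row.gene_a, row.gene_b, r=row.r, weight=abs(row.r),
                   rank=int(row.rank))
        if ra == rb:
            comp = nx.node_connected_component(g, row.gene_a)
            ok, _ = nx.check_planarity(g.subgraph(comp))
            if not ok:
                g.remove_edge(row.gene_a, row.gene_b)
        else:
            comp_of[ra] = rb
    return g


def build_tissue_network(expr: pd.DataFrame, alpha: float = 0.05,
                         tissue: str | None = None) -> nx.Graph:
    """Convenience: residual expression -> PCCs -> FDR filter -> PMFG."""
    cands = pairwise_pcc(expr)
    ranked = fdr_filter_edges(cands, alpha=alpha)
    return build_pfn(ranked, nodes=sorted(expr.index), tissue=tissue)


# --------------------------------------------------------------------------
# Multiscale modules
# --------------------------------------------------------------------------

@dataclass
class Module:
    id: str
    parent: str | None
    depth: int
    members: list[str]
    hubs: list[str] = field(default_factory=list)


@dataclass
class ModuleHierarchy:
    modules: list[Module]
    method: str = METHOD_TAG

    def by_id(self) -> dict[str, Module]:
        return {m.id: m for m in self.modules}

    def labels_at_depth(self, depth: int) -> dict[str, str]:
        """Gene -> id of its deepest containing module at depth <= ``depth``."""
        label: dict[str, str] = {}
        for mod in sorted(self.modules, key=lambda m: m.depth):
            if mod.depth <= depth:
                for g in mod.members:
                    label[g] = mod.id
        return label

    def max_depth(self) -> int:
        return max((m.depth for m in self.modules), default=0)

    def leaf_label(self) -> dict[str, str]:
        """Map each gene to its deepest containing module id."""
        label: dict[str, str] = {}
        for mod in sorted(self.modules, key=lambda m: m.depth):
            for g in mod.members:
                label[g] = mod.id
        return label

    def to_records(self) -> list[dict]:
        return [{"id": m.id, "parent": m.parent, "depth": m.depth,
                 "members": list(m.members), "hubs": list(m.hubs)}
                for m in self.modules]


def _canonical(g: nx.Graph) -> tuple[nx.Graph, list]:
    """Sorted integer-labelled copy of g (edge weights preserved).

    Louvain and the rewire null must see a graph whose iteration order is a
    pure function of its contents; string-keyed set/view iteration would
    leak the process hash seed into community detection.
    """
    nodes = sorted(g.nodes())
    pos = {n: i for i, n in enumerate(nodes)}
    h = nx.Graph()
    h.add_nodes_from(range(len(nodes)))
    edges = sorted(((pos[a], pos[b]) if pos[a] < pos[b] else (pos[b], pos[a]))
                   + (float(d.get("weight", 1.0)),)
                   for a, b, d in g.edges(data=True))
    h.add_weighted_edges_from(edges)
    return h, nodes


def _null_modularity(g: nx.Graph, n_rewires: int, rng: np.random.Generator,
                     resolution: float) -> np.ndarray:
    """Modularity of Louvain partitions on degree-preserving rewires of g."""
    out = np.empty(n_rewires)
    weighted, _ = _canonical(g)
    base = nx.Graph()
    base.add_nodes_from(weighted.nodes())
    base.add_edges_from(weighted.edges())  # null is topology-only
    n_edges = base.number_of_edges()
    for i in range(n_rewires):
        h = base.copy()
        try:
            nx.double_edge_swap(h, nswap=2 * n_edges,
                                max_tries=40 * n_edges,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXError:
            pass  # too few swappable edges; score the graph as-is
        part = louvain_communities(h, weight=None, resolution=resolution,
                                   seed=int(rng.integers(2 ** 31)))
        out[i] = modularity(h, part, weight=None, resolution=resolution)
    return out


def _split(g: nx.Graph, min_module_size: int, resolution: float,
           n_rewires: int, rng: np.random.Generator) -> list[set] | None:
    """Louvain split accepted iff modularity beats the rewire null (mean+2SD)."""
    if g.number_of_nodes() < 2 * min_module_size or g.number_of_edges() < 4:
        return None
    gi, names = _canonical(g)
    # partition search uses edge weights (|r|): planted co-expression is
    # carried by strong edges, while the acceptance gate below stays
    # topology-only so it is comparable with the degree-preserving null
    part_int = louvain_communities(gi, weight="weight", resolution=resolution,
                                   seed=int(rng.integers(2 ** 31)))
    part = [{names[i] for i in c} for c in part_int]
    # merge undersized children into the largest community
    part = sorted((set(c) for c in part), key=len, reverse=True)
    big = [c for c in part if len(c) >= min_module_size]
    if len(big) < 2:
        return None
    merged = list(big)
    for c in part:
        if len(c) < min_module_size:
            merged[0] |= c
    q_obs = modularity(g, merged, weight=None, resolution=resolution)
    null = _null_modularity(g, n_rewires, rng, resolution)
    if q_obs <= null.mean() + 2.0 * null.std(ddof=1):
        return None
    return merged


def detect_modules(pfn: nx.Graph, min_module_size: int = 10, max_depth: int = 4,
                   resolution_ladder: list[float] | None = None,
                   n_rewires: int = 100, seed: int = 0) -> ModuleHierarchy:
    """Recursive modularity splitting with a rewire-null acceptance test.

    Each connected component of size >= min_module_size is a root module;
    accepted Louvain splits become children, recursively, down to
    ``max_depth``.  ``resolution_ladder[d]`` is the Louvain resolution used
    at depth d (last entry reused beyond the ladder); the default ladder
    runs coarse to fine so successive levels refine compactness, which is
    what makes the hierarchy multiscale.
    """
    if resolution_ladder is None:
        resolution_ladder = [0.15, 0.5, 1.0]
    rng = np.random.default_rng(seed)
    modules: list[Module] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"M{counter}"

    components = sorted(nx.connected_components(pfn),
                        key=lambda c: (-len(c), min(c)))
    queue: list[tuple[set, str | None, int]] = []
    for comp in components:
        if len(comp) >= min_module_size:
            queue.append((comp, None, 0))
    while queue:
        nodes, parent, depth = queue.pop(0)
        mod = Module(id=next_id(), parent=parent, depth=depth,
                     members=sorted(nodes))
        modules.append(mod)
        if depth >= max_depth:
            continue
        res = resolution_ladder[min(depth, len(resolution_ladder) - 1)]
        sub = pfn.subgraph(nodes)
        children = _split(sub, min_module_size, res, n_rewires, rng)
        if children is not None:
            for child in sorted(children, key=lambda c: (-len(c), min(c))):
                queue.append((child, mod.id, depth + 1))
    return ModuleHierarchy(modules=modules)


def detect_hubs(pfn: nx.Graph, hierarchy: ModuleHierarchy) -> ModuleHierarchy:
    """Flag genes whose within-module degree exceeds mean+2SD (per module).

    Modules of fewer than 3 genes get no hubs.  Hub lists are written back
    onto the hierarchy and also returned.
    """
    for mod in hierarchy.modules:
        if len(mod.members) < 3:
            mod.hubs = []
            continue
        sub = pfn.subgraph(mod.members)
        degrees = np.array([sub.degree(g) for g in mod.members], dtype=float)
        threshold = degrees.mean() + 2.0 * degrees.std(ddof=0)
        mod.hubs = sorted(g for g, d in zip(mod.members, degrees) if d > threshold)
    return hierarchy


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def edges_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [(a, b, d.get("weight", abs(d.get("r", np.nan))))
            for a, b, d in g.edges(data=True)]
    rows = [(min(a, b), max(a, b), w) for a, b, w in rows]
    return (pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
            .sort_values(["gene_a", "gene_b"]).reset_index(drop=True))


def hierarchy_to_json(hierarchy: ModuleHierarchy) -> dict:
    return {"method": hierarchy.method, "modules": hierarchy.to_records()}
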