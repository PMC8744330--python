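"""Conservation-weighted aggregation of tissue subnetworks and seed-gene
consensus neighborhoods.

For each tissue, the subnetwork induced by that tissue's SnG-enriched
module genes on its planar co-expression network is extracted.  Merging
subnetworks across tissues gives every gene a node conservation weight
(number of tissues whose subnetwork contains it) and every link an edge
conservation weight (number of subnetworks containing it); nodes below the
weight threshold (default 5 tissues) are dropped, along with their edges.
The same machinery merges per-tissue 3-layer neighborhoods of a seed gene
into a consensus neighborhood network, with the seed always retained so
the consensus stays anchored.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


def tissue_subnetworks(pfns: Mapping[str, nx.Graph],
                       flagged_modules: pd.DataFrame) -> dict[str, nx.Graph]:
    """Per tissue, the subgraph of its PFN induced by flagged-module genes.

    Tissues without flagged modules are absent from the result.
    """
    out: dict[str, nx.Graph] = {}
    for tissue, group in flagged_modules.groupby("tissue"):
        genes: set[str] = set()
        for members in group["members"]:
            genes |= set(members)
        pfn = pfns[tissue]
        sub = nx.Graph(pfn.subgraph(n for n in genes if n in pfn))
        missing = genes - set(sub.nodes())
        sub.add_nodes_from(missing)  # flagged genes absent from the PFN node set
        out[tissue] = sub
    return out


def aggregate(subnetworks: Mapping[str, nx.Graph], min_node_weight: int = 5,
              min_edge_weight: int = 1,
              always_keep: Iterable[str] = ()) -> nx.Graph:
    """Merge subnetworks into a conservation-weighted aggregate.

    Node weight = number of tissues whose subnetwork contains the gene;
    edge weight = number of subnetworks containing the link.  Nodes with
    weight < min_node_weight are dropped (except ``always_keep``), then
    edges with a dropped endpoint or weight < min_edge_weight.
    Node/edge attributes record the supporting tissue lists.
    """
    if not subnetworks:
        raise ValueError("need at least one subnetwork")
    keep_anyway = set(always_keep)
    node_support: dict[str, list[str]] = {}
    edge_support: dict[tuple[str, str], list[str]] = {}
    for tissue in sorted(subnetworks):
        g = subnetworks[tissue]
        for n in g.nodes():
            node_support.setdefault(n, []).append(tissue)
        for a, b in g.edges():
            key = (a, b) if a <= b else (b, a)
            edge_support.setdefault(key, []).append(tissue)
    agg = nx.Graph()
    for n, tissues in node_support.items():
        if len(tissues) >= min_node_weight or n in keep_anyway:
            agg.add_node(n, weight=len(tissues), tissues=tissues)
    for (a, b), tissues in edge_support.items():
        if a in agg and b in agg and len(tissues) >= min_edge_weight:
            agg.add_edge(a, b, weight=len(tissues), tissues=tissues)
    return agg


def neighborhood(pfn: nx.Graph, seed_gene: str, layers: int = 3) -> nx.Graph:
    """Genes within graph distance <= layers of the seed, with induced edges.

    A seed absent from the network yields an empty graph.
    """
    if seed_gene not in pfn:
        return nx.Graph()
    dists = nx.single_source_shortest_path_length(pfn, seed_gene, cutoff=layers)
    return nx.Graph(pfn.subgraph(dists.keys()))


def consensus_neighborhood(pfns: Mapping[str, nx.Graph], seed_gene: str,
                           layers: int = 3, min_node_weight: int = 5,
                           min_edge_weight: int = 1) -> nx.Graph:
    """Merge per-tissue seed neighborhoods into a conservation-weighted
    consensus; the seed gene is retained regardless of its weight."""
    hoods = {}
    for tissue, pfn in pfns.items():
        hood = neighborhood(pfn, seed_gene, layers=layers)
        if hood.number_of_nodes():
            hoods[tissue] = hood
    if not hoods:
        raise ValueError(f"seed gene {seed_gene!r} absent from every network")
    return aggregate(hoods, min_node_weight=min_node_weight,
                     min_edge_weight=min_edge_weight,
                     always_keep={seed_gene})


def node_table(agg: nx.Graph) -> pd.DataFrame:
    rows = [{"gene": n, "weight": d["weight"], "n_tissues": len(d["tissues"]),
             "tissues": ",".join(d["tissues"])}
            for n, d in agg.nodes(data=True)]
    return (pd.DataFrame(rows, columns=["gene", "weight", "n_tissues", "tissues"])
            .sort_values(["weight", "gene"], ascending=[False, True])
            .reset_index(drop=True))


def edge_table(agg: nx.Graph) -> pd.DataFrame:
    rows = [{"gene_a": min(a, b), "gene_b": max(a, b), "weight": d["weight"]}
            for a, b, d in agg.edges(data=True)]
    return (pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
            .sort_values(["gene_a", "gene_b"]).reset_index(drop=True))
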