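"""Single-cell normalization, clustering, marker detection, per-cell GSEA.

Counts are depth-normalized per cell to a fixed scale (10,000 by default)
and natural-log transformed (the LogNormalize convention; log fold changes
below are therefore on the natural-log scale).  Cells are clustered by
Louvain on a KNN graph over the top principal components of the scaled
variable genes.  Markers come from one-vs-rest Wilcoxon rank-sum tests
with the standard thresholds (BH FDR < 0.05, log fold change >= 0.25,
expressed in >= 25% of in-type cells, upregulated only).  Per-cell
senescence-gene enrichment uses the shared weighted-KS GSEA with
gene-label permutations.
"""

from __future__ import annotations

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import gsea
from .module_stats import bh_adjust

LOGNORM_LAYER = "lognorm"


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def lognormalize(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Add ``layers['lognorm']`` = ln(1 + count / cell_total * scale)."""
    counts = _dense(adata.X).astype(float)
    totals = counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        bad = list(adata.obs_names[zero])
        raise ValueError(f"cells with zero total counts: {bad}")
    adata.layers[LOGNORM_LAYER] = np.log1p(counts / totals[:, None] * scale)
    return adata


def cluster_cells(adata: ad.AnnData, n_var_genes: int = 2000, n_pcs: int = 30,
                  knn_pcs: int = 10, resolution: float = 0.05,
                  n_neighbors: int = 20, seed: int = 0) -> pd.Series:
    """Louvain clustering of cells on a KNN graph of top principal components.

    Variable genes are ranked by variance of the log-normalized values;
    PCA runs on the per-gene z-scored variable-gene matrix; the KNN graph
    uses Euclidean distance over the first ``knn_pcs`` components; Louvain
    modularity optimization uses the given resolution (granularity).
    """
    if LOGNORM_LAYER not in adata.layers:
        lognormalize(adata)
    X = np.asarray(adata.layers[LOGNORM_LAYER])
    n_cells, n_genes = X.shape
    if n_cells <= n_neighbors:
        raise ValueError("need more cells than KNN neighbors")
    variances = X.var(axis=0)
    n_var = min(n_var_genes, n_genes)
    var_idx = np.argsort(-variances, kind="stable")[:n_var]
    sub = X[:, var_idx]
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (sub - sub.mean(axis=0)) / sd
    n_comp = min(n_pcs, n_var, n_cells - 1)
    pcs = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=seed).fit_transform(scaled)
    emb = pcs[:, :min(knn_pcs, n_comp)]
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    for i in range(n_cells):
        for j in idx[i, 1:]:
            g.add_edge(i, int(j))
    communities = louvain_communities(g, resolution=resolution, seed=seed)
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    labels = np.empty(n_cells, dtype=int)
    for lab, comm in enumerate(communities):
        labels[comm] = lab
    out = pd.Series(pd.Categorical(labels.astype(str)),
                    index=adata.obs_names, name="cluster")
    adata.obs["cluster"] = out
    return out


def find_markers(adata: ad.AnnData, labels: pd.Series | str = "cell_type",
                 lfc_min: float = 0.25, min_frac: float = 0.25,
                 q_max: float = 0.05, min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table with the standard retention rule.

    Per cell type and gene: Wilcoxon rank-sum on the log-normalized values,
    log fold change ln(mean(expm1)+1) in-type minus out-type, fraction of
    in-type cells expressing the gene.  BH is applied across all tested
    gene x type combinations; only upregulated genes passing all three
    filters (q < q_max, lfc >= lfc_min, frac_in >= min_frac) are kept.
    """
    if LOGNORM_LAYER not in adata.layers:
        lognormalize(adata)
    if isinstance(labels, str):
        labels = adata.obs[labels]
    labels = pd.Series(labels, index=adata.obs_names).astype(str)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 cell types for marker detection")
    X = np.asarray(adata.layers[LOGNORM_LAYER])
    genes = np.asarray(adata.var_names)
    rows = []
    for ctype in sorted(labels.unique()):
        mask = (labels == ctype).to_numpy()
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            continue
        inside, outside = X[mask], X[~mask]
        with np.errstate(invalid="ignore"):
            _, p = stats.mannwhitneyu(inside, outside, axis=0,
                                      alternative="two-sided",
                                      method="asymptotic")
        p = np.nan_to_num(p, nan=1.0)
        lfc = (np.log(np.expm1(inside).mean(axis=0) + 1.0)
               - np.log(np.expm1(outside).mean(axis=0) + 1.0))
        frac_in = (inside > 0).mean(axis=0)
        frac_out = (outside > 0).mean(axis=0)
        rows.append(pd.DataFrame({
            "gene": genes, "cell_type": ctype, "log_fold_change": lfc,
            "frac_expressing_in_type": frac_in,
            "frac_expressing_out": frac_out, "p": p,
        }))
    table = pd.concat(rows, ignore_index=True)
    table["q"] = bh_adjust(table["p"].to_numpy())
    kept = table[(table["q"] < q_max)
                 & (table["log_fold_change"] >= lfc_min)
                 & (table["frac_expressing_in_type"] >= min_frac)]
    return kept.sort_values(["cell_type", "q", "gene"]).reset_index(drop=True)


def cell_gsea(adata: ad.AnnData, gene_set, n_perm: int = 1000, seed: int = 0,
              min_overlap: int = 5, alpha: float = 0.01) -> pd.DataFrame:
    """Per-cell weighted-KS enrichment of a gene set, permutation p-values.

    Genes are ranked per cell by log-normalized expression (descending,
    ties broken by a fixed hash of the symbol so tied blocks carry no
    set-composition bias); hit increments are the expression values
    themselves (weight exponent 1).  ``enriched`` means p < alpha.  Cells
    whose expressed genes overlap the set by fewer than ``min_overlap``
    genes get NaN scores.
    """
    if LOGNORM_LAYER not in adata.layers:
        lognormalize(adata)
    X = np.asarray(adata.layers[LOGNORM_LAYER])
    genes = np.asarray(adata.var_names)
    gene_set = set(gene_set)
    hits_full = np.array([g in gene_set for g in genes])
    if not hits_full.any():
        raise ValueError("gene set does not overlap the gene universe")
    rng = np.random.default_rng(seed)
    keys = gsea.tie_keys(genes)
    records = []
    for i in range(X.shape[0]):
        values = X[i]
        overlap = int(((values > 0) & hits_full).sum())
        if overlap < min_overlap:
            records.append((adata.obs_names[i], np.nan, np.nan, False))
            continue
        order = gsea.rank_genes(values, genes, keys)
        es, p = gsea.gsea_permutation(values[order], hits_full[order],
                                      n_perm, rng)
        records.append((adata.obs_names[i], es, p, p < alpha))
    out = pd.DataFrame(records, columns=["cell_id", "es", "p", "enriched"])
    return out.set_index("cell_id")


def sng_cell_fractions(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-type enrichment tallies.

    ``fraction_of_type_enriched`` is the share of that type's cells that
    are enriched; ``share_of_enriched_cells`` is the type's share of all
    enriched cells (both framings are conventional).
    """
    labels = pd.Series(labels).astype(str).loc[scores.index]
    total_enriched = int(scores["enriched"].sum())
    rows = []
    for ctype in sorted(labels.unique()):
        mask = labels == ctype
        n_cells = int(mask.sum())
        n_enr = int(scores.loc[mask.to_numpy(), "enriched"].sum())
        rows.append({
            "cell_type": ctype, "n_cells": n_cells, "n_enriched": n_enr,
            "fraction_of_type_enriched": n_enr / n_cells if n_cells else 0.0,
            "share_of_enriched_cells":
                n_enr / total_enriched if total_enriched else 0.0,
        })
    return pd.DataFrame(rows)
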