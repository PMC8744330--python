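"""Coexistence-proportion statistics and ligand-receptor permutation tests.

Coexistence proportion — the share of cells in which two genes both have
normalized expression above zero — is a dropout-robust co-expression proxy
in single cells.  The coexistence test compares, per cell type, the
proportions of a senescence marker with a query gene list against the
proportions with random background genes (two-sided Wilcoxon/Mann-Whitney
with tie correction, since many proportions tie at zero).

Cell-type communication counts ligand-receptor pairs whose ligand is a
marker of the source type and receptor a marker of the target type; the
null replaces both marker sets by uniform draws of matching sizes from the
expressed genes, and p = (1 + #{null >= observed}) / (1 + n_perm).
Ordered pairs are directional (ligand flows source -> target).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .single_cell import LOGNORM_LAYER, lognormalize


@dataclass
class CoexistenceRecord:
    marker_gene: str
    partner_gene: str
    cell_type: str
    n_cells: int
    n_both_expressed: int
    proportion: float


def _norm_matrix(adata: ad.AnnData) -> np.ndarray:
    if LOGNORM_LAYER not in adata.layers:
        lognormalize(adata)
    return np.asarray(adata.layers[LOGNORM_LAYER])


def _gene_index(adata: ad.AnnData, gene: str) -> int:
    try:
        return int(adata.var_names.get_loc(gene))
    except KeyError:
        raise KeyError(f"gene {gene!r} not in the expression matrix") from None


def coexistence_proportion(adata: ad.AnnData, gene_a: str, gene_b: str,
                           cell_mask: np.ndarray | None = None,
                           cell_type: str = "all") -> CoexistenceRecord:
    """Share of cells (optionally restricted) expressing both genes."""
    X = _norm_matrix(adata)
    ia, ib = _gene_index(adata, gene_a), _gene_index(adata, gene_b)
    if cell_mask is None:
        cell_mask = np.ones(X.shape[0], dtype=bool)
    n_cells = int(cell_mask.sum())
    if n_cells == 0:
        raise ValueError("cell subset is empty")
    both = int(((X[cell_mask, ia] > 0) & (X[cell_mask, ib] > 0)).sum())
    return CoexistenceRecord(gene_a, gene_b, cell_type, n_cells, both,
                             both / n_cells)


def _proportions(X: np.ndarray, marker_col: int, gene_cols: np.ndarray,
                 cell_mask: np.ndarray) -> np.ndarray:
    marker_on = X[cell_mask, marker_col] > 0
    sub = X[np.ix_(cell_mask, gene_cols)] > 0
    return (sub & marker_on[:, None]).mean(axis=0)


def coexistence_test(adata: ad.AnnData, marker_gene: str,
                     query_genes: Sequence[str],
                     labels: pd.Series | str = "cell_type",
                     n_background: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per cell type: marker-query coexistence vs random background genes.

    Background genes are sampled without replacement from all matrix genes
    excluding the marker and the query set.  Returns median proportions of
    both groups and the two-sided Mann-Whitney p-value per cell type.
    """
    X = _norm_matrix(adata)
    if isinstance(labels, str):
        labels = adata.obs[labels]
    labels = pd.Series(labels, index=adata.obs_names).astype(str)
    if not query_genes:
        raise ValueError("query gene list is empty")
    marker_col = _gene_index(adata, marker_gene)
    query_cols = np.array([_gene_index(adata, g) for g in query_genes])
    excluded = set(query_genes) | {marker_gene}
    pool = [g for g in adata.var_names if g not in excluded]
    if not pool:
        raise ValueError("no background genes available")
    rng = np.random.default_rng(seed)
    n_bg = min(n_background, len(pool))
    bg_genes = rng.choice(pool, size=n_bg, replace=False)
    bg_cols = np.array([_gene_index(adata, g) for g in bg_genes])
    rows = []
    for ctype in sorted(labels.unique()):
        mask = (labels == ctype).to_numpy()
        if mask.sum() == 0:
            continue
        q_props = _proportions(X, marker_col, query_cols, mask)
        b_props = _proportions(X, marker_col, bg_cols, mask)
        if np.all(q_props == q_props[0]) and np.all(b_props == q_props[0]):
            p = 1.0  # all proportions identical: no evidence either way
        else:
            _, p = stats.mannwhitneyu(q_props, b_props,
                                      alternative="two-sided",
                                      method="asymptotic")
        rows.append({"cell_type": ctype, "n_cells": int(mask.sum()),
                     "median_query_proportion": float(np.median(q_props)),
                     "median_background_proportion": float(np.median(b_props)),
                     "p": float(p)})
    return pd.DataFrame(rows)


def lr_communication(markers: pd.DataFrame, lr_db: pd.DataFrame,
                     expressed_genes: Sequence[str], n_perm: int = 10_000,
                     seed: int = 0, alpha: float = 0.05,
                     cell_types: Sequence[str] | None = None) -> pd.DataFrame:
    """Permutation test of ligand-receptor communication per ordered type pair.

    ``markers`` is a marker table with columns gene and cell_type.  For an
    ordered pair (source, target), the observed statistic counts db pairs
    with ligand in markers(source) and receptor in markers(target); the
    null redraws both marker sets uniformly (without replacement, matching
    sizes) from ``expressed_genes``.
    """
    if lr_db.empty:
        raise ValueError("ligand-receptor table is empty")
    expressed = pd.Index(pd.unique(np.asarray(expressed_genes, dtype=object)))
    n_genes = len(expressed)
    gene_pos = {g: i for i, g in enumerate(expressed)}
    db = lr_db[lr_db["ligand"].isin(gene_pos) & lr_db["receptor"].isin(gene_pos)]
    lig_idx = db["ligand"].map(gene_pos).to_numpy()
    rec_idx = db["receptor"].map(gene_pos).to_numpy()
    marker_sets = {str(t): set(g for g in grp["gene"] if g in gene_pos)
                   for t, grp in markers.groupby("cell_type")}
    types = sorted(marker_sets if cell_types is None else cell_types)
    for t in types:  # a known type with no markers has an empty set
        marker_sets.setdefault(t, set())
    rng = np.random.default_rng(seed)
    rows = []
    for source in types:
        for target in types:
            if source == target:
                continue
            src, tgt = marker_sets[source], marker_sets[target]
            pairs = [(l, r) for l, r in zip(db["ligand"], db["receptor"])
                     if l in src and r in tgt]
            observed = len(pairs)
            if not src or not tgt:
                rows.append({"source_type": source, "target_type": target,
                             "observed_pairs": 0, "pairs": [], "p": 1.0,
                             "significant": False, "empty_marker_set": True})
                continue
            null = _null_pair_counts(lig_idx, rec_idx, n_genes, len(src),
                                     len(tgt), n_perm, rng)
            p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
            rows.append({"source_type": source, "target_type": target,
                         "observed_pairs": observed, "pairs": pairs,
                         "p": float(p), "significant": p < alpha,
                         "empty_marker_set": False})
    return pd.DataFrame(rows)


def _null_pair_counts(lig_idx: np.ndarray, rec_idx: np.ndarray, n_genes: int,
                      n_src: int, n_tgt: int, n_perm: int,
                      rng: np.random.Generator,
                      block: int = 2000) -> np.ndarray:
    """Vectorized null counts for random marker sets of fixed sizes."""
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        in_src = _random_membership(rng, b, n_genes, n_src)
        in_tgt = _random_membership(rng, b, n_genes, n_tgt)
        out[done:done + b] = (in_src[:, lig_idx] & in_tgt[:, rec_idx]).sum(axis=1)
        done += b
    return out


def _random_membership(rng: np.random.Generator, n_rows: int, n_genes: int,
                       size: int) -> np.ndarray:
    keys = rng.random((n_rows, n_genes))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    member = np.zeros((n_rows, n_genes), dtype=bool)
    member[np.arange(n_rows)[:, None], idx] = True
    return member


def expressed_gene_pool(adata: ad.AnnData, min_cell_fraction: float = 0.01) -> list[str]:
    """Genes with nonzero counts in at least the given fraction of cells."""
    X = adata.X
    dense = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    frac = (dense > 0).mean(axis=0)
    return [g for g, f in zip(adata.var_names, frac) if f >= min_cell_fraction]
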