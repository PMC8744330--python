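"""Per-voxel module enrichment on spatial slides, and composition contrasts.

Each voxel's expressed genes are ranked by normalized, scaled expression
(log-normalize per voxel, then per-gene z-score across voxels); the module
gene set is scored along that ranking with the shared weighted-KS GSEA
(running sum rises at module hits, falls at misses; ES is the maximum
deviation from zero) and a gene-label permutation p-value.  Voxels with
p < 0.01 are called module-enriched, and cell-type composition weights are
compared between enriched and non-enriched voxels by two-sided
Mann-Whitney tests.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from . import gsea

SCALED_LAYER = "scaled"


def normalize_and_scale(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Log-normalize per voxel, then z-score each gene across voxels.

    Stores the result in ``layers['scaled']``.  Genes with zero variance
    across voxels get all-zero scaled values.
    """
    counts = np.asarray(adata.X, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = list(adata.obs_names[np.where(totals == 0)[0]])
        raise ValueError(f"voxels with zero total counts: {bad}")
    lognorm = np.log1p(counts / totals[:, None] * scale)
    mean = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0)
    sd[sd == 0] = 1.0
    adata.layers[SCALED_LAYER] = (lognorm - mean) / sd
    return adata


def rank_voxel_genes(adata: ad.AnnData, voxel: str,
                     min_expressed: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """A voxel's expressed genes ranked by scaled expression (descending).

    Expressed means raw count > 0 in that voxel.  Ties are broken by a
    fixed hash of the gene symbol (see :func:`senescape.gsea.tie_keys`).
    Returns (genes, scaled values) in rank order; raises if fewer
    than ``min_expressed`` genes are expressed.
    """
    if SCALED_LAYER not in adata.layers:
        normalize_and_scale(adata)
    i = int(adata.obs_names.get_loc(voxel))
    counts = np.asarray(adata.X)[i]
    expressed = counts > 0
    if int(expressed.sum()) < min_expressed:
        raise ValueError(f"voxel {voxel!r} expresses fewer than "
                         f"{min_expressed} genes")
    genes = np.asarray(adata.var_names)[expressed]
    values = np.asarray(adata.layers[SCALED_LAYER])[i, expressed]
    order = gsea.rank_genes(values, genes)
    return genes[order], values[order]


def voxel_gsea(adata: ad.AnnData, module_genes, n_perm: int = 1000,
               seed: int = 0, min_overlap: int = 5, alpha: float = 0.01,
               min_expressed: int = 50) -> pd.DataFrame:
    """Weighted-KS module enrichment per voxel with permutation p-values.

    Hit increments are |scaled expression| so a gene's weight reflects how
    far it deviates from its across-voxel mean.  Voxels with too few
    expressed genes, or too little overlap with the module, get NaN.
    """
    if SCALED_LAYER not in adata.layers:
        normalize_and_scale(adata)
    module = set(module_genes)
    rng = np.random.default_rng(seed)
    records = []
    for voxel in adata.obs_names:
        try:
            genes, values = rank_voxel_genes(adata, voxel,
                                             min_expressed=min_expressed)
        except ValueError:
            records.append((voxel, np.nan, np.nan, False))
            continue
        hits = np.array([g in module for g in genes])
        if int(hits.sum()) < min_overlap or hits.all():
            records.append((voxel, np.nan, np.nan, False))
            continue
        es, p = gsea.gsea_permutation(np.abs(values), hits, n_perm, rng)
        records.append((voxel, es, p, p < alpha))
    out = pd.DataFrame(records, columns=["voxel_id", "es", "p", "enriched"])
    out = out.set_index("voxel_id")
    for col in ("x", "y"):
        if col in adata.obs:
            out[col] = adata.obs[col].to_numpy()
    return out


def compare_compositions(voxel_scores: pd.DataFrame,
                         compositions: pd.DataFrame) -> pd.DataFrame:
    """Composition weights in enriched vs non-enriched voxels, per cell type.

    Two-sided Mann-Whitney per cell type; requires at least one voxel in
    each group (NaN p otherwise).
    """
    scores = voxel_scores.loc[compositions.index]
    enr = scores["enriched"].fillna(False).to_numpy(dtype=bool)
    rows = []
    for ctype in compositions.columns:
        w = compositions[ctype].to_numpy(dtype=float)
        a, b = w[enr], w[~enr]
        if a.size == 0 or b.size == 0:
            rows.append({"cell_type": ctype, "median_enriched": np.nan,
                         "median_non_enriched": np.nan, "p": np.nan})
            continue
        if np.all(w == w[0]):
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic")
        rows.append({"cell_type": ctype,
                     "median_enriched": float(np.median(a)),
                     "median_non_enriched": float(np.median(b)),
                     "p": float(p)})
    return pd.DataFrame(rows)
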