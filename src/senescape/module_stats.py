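"""Module scoring: gene-set enrichment, eigengenes, age correlation.

Enrichment is a one-tailed Fisher exact (hypergeometric) test of module
members against a gene set within the tissue network's gene universe, with
Benjamini-Hochberg correction applied per tissue (configurable to a global
scope).  Module eigengenes are the first principal component of the
per-gene standardized expression submatrix, oriented to correlate
positively with the mean module profile, and age association is Spearman
correlation of the eigengene with donor age (decade-bin midpoints, hence
heavy midrank ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import ModuleHierarchy


@dataclass
class EnrichmentResult:
    module_id: str
    set_name: str
    overlap: int
    module_size: int
    set_size: int
    universe_size: int
    fold_enrichment: float
    p: float
    q: float = np.nan


def fisher_enrichment(module_genes: Iterable[str], gene_set: Iterable[str],
                      universe: Iterable[str], module_id: str = "",
                      set_name: str = "") -> EnrichmentResult:
    """One-tailed hypergeometric enrichment of a module against a gene set.

    p = P(X >= overlap) for X ~ Hypergeom(universe, set, module).  Both the
    module and the set are intersected with the universe first.  An empty
    module or set yields p = 1 and undefined (NaN) fold enrichment.
    """
    uni = set(universe)
    mod = set(module_genes) & uni
    gs = set(gene_set) & uni
    n_uni, n_mod, n_set = len(uni), len(mod), len(gs)
    overlap = len(mod & gs)
    if n_mod == 0 or n_set == 0:
        return EnrichmentResult(module_id, set_name, overlap, n_mod, n_set,
                                n_uni, np.nan, 1.0)
    p = float(stats.hypergeom.sf(overlap - 1, n_uni, n_set, n_mod))
    fe = (overlap / n_mod) / (n_set / n_uni)
    return EnrichmentResult(module_id, set_name, overlap, n_mod, n_set, n_uni,
                            fe, min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, preserving input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class Eigengene:
    module_id: str
    scores: pd.Series
    variance_explained: float
    flipped: bool


def module_eigengene(expr: pd.DataFrame, module_genes: Iterable[str],
                     module_id: str = "") -> Eigengene:
    """First principal component of the per-gene z-scored module submatrix.

    The sign is fixed so the score correlates positively with the mean
    standardized module profile.  Zero-variance genes are dropped.
    """
    genes = [g for g in module_genes if g in expr.index]
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    sub = sub.loc[sd > 0]
    if sub.shape[0] < 2:
        raise ValueError("module needs >= 2 genes with variance")
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=0)).T.to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    score = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    mean_profile = z.mean(axis=0)
    flipped = False
    if np.dot(score, mean_profile) < 0:
        score = -score
        flipped = True
    return Eigengene(module_id=module_id,
                     scores=pd.Series(score, index=sub.columns),
                     variance_explained=var_explained, flipped=flipped)


def age_correlation(eigengene: pd.Series, ages: pd.Series) -> tuple[float, float]:
    """Spearman correlation (midrank ties) of an eigengene with donor age."""
    ages = ages.loc[eigengene.index]
    if len(eigengene) < 5:
        raise ValueError("need >= 5 samples for age correlation")
    if eigengene.nunique() <= 1 or ages.nunique() <= 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(eigengene.to_numpy(), ages.to_numpy())
    return float(rho), float(p)


def flag_sng_modules(hierarchies: Mapping[str, ModuleHierarchy],
                     sng_set: Iterable[str],
                     universes: Mapping[str, Iterable[str]],
                     alpha_q: float = 0.05,
                     scope: str = "per-tissue") -> pd.DataFrame:
    """SnG-enriched modules across tissues at BH q < alpha_q.

    ``universes[tissue]`` is the enrichment universe (that tissue's network
    genes).  BH scope is per tissue by default; ``scope='global'`` adjusts
    across all tissues jointly.  Returns one row per flagged module with
    all counts needed to recompute FE and p externally, plus the member
    list.
    """
    if scope not in ("per-tissue", "global"):
        raise ValueError("scope must be 'per-tissue' or 'global'")
    sng = set(sng_set)
    rows = []
    for tissue, hierarchy in hierarchies.items():
        universe = set(universes[tissue])
        for mod in hierarchy.modules:
            res = fisher_enrichment(mod.members, sng, universe,
                                    module_id=mod.id, set_name="SnG")
            rows.append({"tissue": tissue, "module_id": mod.id,
                         "depth": mod.depth,
                         "module_size": res.module_size,
                         "overlap": res.overlap, "set_size": res.set_size,
                         "universe_size": res.universe_size,
                         "fold_enrichment": res.fold_enrichment, "p": res.p,
                         "members": list(mod.members)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(q=pd.Series(dtype=float), flagged=pd.Series(dtype=bool))
    if scope == "global":
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = np.nan
        for tissue, idx in table.groupby("tissue").groups.items():
            table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["flagged"] = table["q"] < alpha_q
    table.attrs["bh_scope"] = scope
    flagged = table[table["flagged"]].drop(columns="flagged")
    return flagged.sort_values(["tissue", "module_id"]).reset_index(drop=True)
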