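"""SnG x module presence matrix, consensus k-means, conserved-SnG selection.

The landscape of senescence-gene co-expression is summarized by a binary
matrix with SnGs as rows and SnG-enriched modules (tissue-qualified) as
columns; entry 1 means the SnG is a member of that module.  Both axes are
clustered by consensus k-means: k-means (Euclidean, k-means++ init) is run
many times with distinct sub-seeds, the co-assignment matrix records how
often two items land together, and the final labels cut an average-linkage
tree of (1 - co-assignment) into k groups.  SnG clusters whose members
appear in flagged modules of more than half the surveyed tissues supply
the conserved SnG list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans


def build_presence_matrix(flagged_modules: pd.DataFrame,
                          sng_set: Iterable[str]) -> pd.DataFrame:
    """Binary SnG x module matrix from the flagged-module table.

    ``flagged_modules`` needs columns tissue, module_id and members (list);
    columns are labelled ``tissue:module_id``.  All-zero rows (SnGs absent
    from every flagged module) and all-zero columns are dropped.
    """
    if flagged_modules.empty:
        raise ValueError("no flagged modules: cannot build presence matrix")
    sngs = sorted(set(sng_set))
    cols = {}
    for row in flagged_modules.itertuples(index=False):
        members = set(row.members)
        cols[f"{row.tissue}:{row.module_id}"] = [1 if g in members else 0
                                                 for g in sngs]
    mat = pd.DataFrame(cols, index=sngs, dtype=np.int8)
    mat = mat.loc[mat.sum(axis=1) > 0, mat.sum(axis=0) > 0]
    if mat.empty:
        raise ValueError("presence matrix is empty after dropping zero rows/cols")
    return mat


@dataclass
class ConsensusClusters:
    labels: pd.Series           # item -> cluster id (1..k)
    co_assignment: pd.DataFrame
    k: int
    runs: int
    axis: str


def consensus_kmeans(matrix: pd.DataFrame, k: int = 4, runs: int = 100,
                     axis: str = "rows", seed: int = 0) -> ConsensusClusters:
    """Consensus k-means over rows or columns of a (binary) matrix.

    Runs k-means ``runs`` times with distinct sub-seeds; co_assignment(i,j)
    is the fraction of runs placing i and j in one cluster; final labels
    come from average-linkage hierarchical clustering of 1-co_assignment
    cut into k clusters.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    data = matrix if axis == "rows" else matrix.T
    items = list(data.index)
    X = data.to_numpy(dtype=float)
    n = len(items)
    if k > n:
        raise ValueError(f"k={k} exceeds number of items ({n})")
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    with warnings.catch_warnings():
        # duplicate rows are routine in binary presence matrices; k-means
        # then finds fewer than k distinct centers, which is fine here
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(runs):
            km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                        random_state=int(rng.integers(2 ** 31)))
            lab = km.fit_predict(X)
            co += (lab[:, None] == lab[None, :])
    co /= runs
    np.fill_diagonal(co, 1.0)
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        dist = squareform(1.0 - co, checks=False)
        tree = linkage(dist, method="average")
        labels = fcluster(tree, t=k, criterion="maxclust")
    return ConsensusClusters(
        labels=pd.Series(labels, index=items, name="cluster"),
        co_assignment=pd.DataFrame(co, index=items, columns=items),
        k=k, runs=runs, axis=axis)


def select_conserved_sngs(clusters: ConsensusClusters,
                          presence: pd.DataFrame,
                          tissue_of: Mapping[str, str],
                          n_tissues_surveyed: int,
                          min_tissue_fraction: float = 0.5,
                          ) -> tuple[list[str], pd.DataFrame]:
    """Conserved SnGs: members of row-clusters spanning more than
    ``min_tissue_fraction`` of the surveyed tissues.

    A cluster's tissue breadth is the number of distinct tissues whose
    flagged modules contain at least one cluster member.  Clusters with
    breadth > min_tissue_fraction * n_tissues_surveyed contribute all
    their members.  Returns the conserved list plus a per-cluster summary.
    """
    threshold = min_tissue_fraction * n_tissues_surveyed
    summaries = []
    conserved: list[str] = []
    for cluster_id, members in clusters.labels.groupby(clusters.labels).groups.items():
        genes = sorted(members)
        sub = presence.loc[genes]
        present_cols = sub.columns[(sub > 0).any(axis=0)]
        tissues = {tissue_of[c] for c in present_cols}
        selected = len(tissues) > threshold
        summaries.append({"cluster": cluster_id, "n_genes": len(genes),
                          "tissue_breadth": len(tissues),
                          "selected": selected})
        if selected:
            conserved.extend(genes)
    return sorted(conserved), pd.DataFrame(summaries)
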