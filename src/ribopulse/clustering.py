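"""Activity clusters: correlation distance + complete-linkage agglomeration.

Taxa with similar temporal %RP profiles are grouped by (i) the pairwise
Pearson correlation r of their profiles over samples, (ii) the distance
transform d = (1 − r)/2 mapping r ∈ [−1, 1] onto d ∈ [0, 1], and
(iii) complete-linkage hierarchical clustering of d, cut into k flat
clusters (k = 7 by default). Because Pearson correlation is invariant to
per-taxon affine rescaling, the clusters reflect the *shape* of a taxon's
activity profile, not its magnitude.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .datamodel import ActivityMatrix, ClusterAssignment, SampleFrame

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_distance",
    "cluster_taxa",
    "rank_order_profiles",
    "silhouette_profile",
    "linkage_to_newick",
]


def correlation_distance(acts: ActivityMatrix, min_defined: int = 3) -> pd.DataFrame:
    """Pairwise taxon distance d = (1 − r)/2 from Pearson correlations.

    Correlations use pairwise-complete samples (cells where both taxa have a
    defined %RP). Taxa with fewer than ``min_defined`` defined samples or
    zero profile variance have no defined correlation and are excluded with
    a warning.
    """
    mat = acts.pct_rp
    defined = mat.notna().sum(axis=1)
    variance = mat.var(axis=1, ddof=0)
    keep = (defined >= min_defined) & (variance > 0)
    excluded = list(mat.index[~keep])
    if excluded:
        logger.warning(
            "excluding %d taxa from clustering (too few defined samples or "
            "zero variance): %s",
            len(excluded),
            excluded,
        )
    mat = mat.loc[keep]
    r = mat.T.corr(min_periods=2)  # pairwise-complete Pearson
    if r.isna().to_numpy().any():
        bad = [
            (i, j)
            for i in r.index
            for j in r.columns
            if i < j and pd.isna(r.loc[i, j])
        ]
        raise ValueError(
            f"correlation undefined for taxon pair(s) {bad[:5]}; "
            "profiles share too few defined samples"
        )
    d = (1.0 - r) / 2.0
    np.fill_diagonal(d.values, 0.0)
    return d


def cluster_taxa(dist: pd.DataFrame, k: int = 7) -> ClusterAssignment:
    """Complete-linkage dendrogram over taxa, cut into exactly-k flat labels.

    Labels are renumbered 1..k in order of first appearance along the input
    taxon list, so the assignment is deterministic and stable under
    relabeling of scipy's internal cluster ids.
    """
    taxa = list(dist.index)
    n = len(taxa)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[i] = relabel[lab]
    return ClusterAssignment(
        labels=pd.Series(labels, index=pd.Index(taxa, name="taxon_id"), name="cluster"),
        linkage=Z,
        taxa=taxa,
    )


def silhouette_profile(dist: pd.DataFrame, k_range=range(2, 13)) -> pd.DataFrame:
    """Mean silhouette width of the complete-linkage cut for each k.

    The flat cut count is a free analysis choice; this table makes it
    inspectable alongside the dendrogram.
    """
    rows = []
    D = dist.to_numpy()
    for k in k_range:
        if k >= len(dist):
            break
        labels = cluster_taxa(dist, k).labels.to_numpy()
        rows.append({"k": k, "mean_silhouette": float(
            silhouette_score(D, labels, metric="precomputed")
        )})
    return pd.DataFrame(rows)


def rank_order_profiles(acts: ActivityMatrix, frame: SampleFrame) -> pd.DataFrame:
    """Per taxon, samples ranked ascending by %RP with temporal annotations.

    This is the structure behind rank-ordered activity-profile plots: for
    each taxon the samples from lowest to highest %RP, labeled by season and
    photoperiod. Ties break by sample id; undefined cells are omitted.
    Returns a long table (taxon_id, rank, sample_id, pct_rp, season,
    photoperiod).
    """
    meta = frame.data
    out = []
    for taxon in acts.taxa:
        row = acts.pct_rp.loc[taxon].dropna()
        ordered = sorted(row.index, key=lambda s: (row[s], s))
        for rank, sid in enumerate(ordered, start=1):
            out.append(
                {
                    "taxon_id": taxon,
                    "rank": rank,
                    "sample_id": sid,
                    "pct_rp": row[sid],
                    "season": meta.loc[sid, "season"],
                    "photoperiod": meta.loc[sid, "photoperiod"],
                }
            )
    return pd.DataFrame(out)


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Newick string of a scipy linkage, branch lengths from merge heights.

    Each node's branch length is its parent's merge height minus its own
    (leaves sit at height 0), so root-to-leaf path lengths equal the root
    merge height.
    """
    tree = hierarchy.to_tree(Z)

    def escape(name: str) -> str:
        return name.replace(" ", "_")

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{escape(leaf_names[node.id])}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"
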