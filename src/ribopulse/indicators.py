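"""Hit-based indicator-value analysis of KEGG-ortholog expression.

For each KO and activity cluster an indicator value (IV) combines

* **specificity** — the cluster's share of the KO's taxon-count-normalized
  expression hits: H_c = Σ over cluster members and samples of the hit
  count, N_c = H_c / |c|, specificity_c = N_c / Σ_{c'} N_{c'};
* **fidelity** — how pervasively the cluster expresses the KO: the number
  of (taxon, sample) cells with detection, divided by |c| × n_samples;

IV = specificity × fidelity × 100, so IV = 100 exactly when a KO is
detected in every sample of every cluster member and nowhere else. The hit
count may exceed the number of samples for a taxon-KO (several genes of one
taxon binning to one KO each count as hits), but detection is binary per
(taxon, sample) cell, so such multiplicity raises specificity weight
without inflating fidelity.

Significance comes from a size-preserving permutation null: taxa are
randomly reassigned to clusters (cluster sizes fixed) and the IV recomputed;
p is the proportion of null IVs at least as large as the observed one
(add-one convention).

A day/night variant asks the same question *within* one cluster with the
two sample groups (day, night) playing the role of clusters, and a
pathway-level step tests whether a cluster's significant indicator KOs
concentrate in particular KEGG pathways against a KO-resampling null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import ClusterAssignment, KOHitTable, SampleFrame

logger = logging.getLogger(__name__)

__all__ = [
    "compute_indicator_values",
    "indicator_significance",
    "day_night_indicator",
    "pathway_enrichment",
]

_TIE_RTOL = 1e-9


def _iv_components(
    hits_kt: np.ndarray,  # (n_ko, n_units) summed hit counts
    det_kt: np.ndarray,  # (n_ko, n_units) detection-cell counts
    member: np.ndarray,  # (n_units, k) 0/1 membership
    cell_denom: np.ndarray,  # (k,) fidelity denominator per cluster
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalized hits, specificity, fidelity, IV — all (n_ko, k)."""
    sizes = member.sum(axis=0)
    H = hits_kt @ member
    N = H / sizes
    tot = N.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(tot > 0, N / np.where(tot > 0, tot, 1.0), np.nan)
    fid = (det_kt @ member) / cell_denom
    iv = 100.0 * np.where(np.isnan(spec), 0.0, spec) * fid
    return N, spec, fid, iv


def compute_indicator_values(
    hits: KOHitTable,
    clusters: ClusterAssignment,
    n_samples: int = 20,
) -> pd.DataFrame:
    """Observed specificity, fidelity and IV per (KO, cluster).

    ``n_samples`` is the study's sample count; fidelity's denominator is
    |cluster| × n_samples regardless of whether every taxon recruited reads
    in every sample. KOs with zero hits everywhere get an all-zero IV row
    (specificity undefined).
    """
    taxa = list(clusters.labels.index)
    samples = sorted(hits.data["sample_id"].unique())
    missing = set(hits.data["taxon_id"]) - set(taxa)
    if missing:
        raise ValueError(f"KO table references unclustered taxa: {sorted(missing)[:5]}")
    kos, hits_kt, det_kt, _ = hits.hit_and_detection_matrices(taxa, samples)
    labels = clusters.labels.to_numpy()
    cluster_ids = np.unique(labels)
    member = (labels[:, None] == cluster_ids[None, :]).astype(float)
    sizes = member.sum(axis=0)
    N, spec, fid, iv = _iv_components(hits_kt, det_kt, member, sizes * n_samples)

    rows = []
    for ki, ko in enumerate(kos):
        for ci, c in enumerate(cluster_ids):
            rows.append(
                {
                    "ko_id": ko,
                    "cluster": int(c),
                    "normalized_hits": N[ki, ci],
                    "specificity": spec[ki, ci],
                    "fidelity": fid[ki, ci],
                    "iv": iv[ki, ci],
                }
            )
    return pd.DataFrame(rows)


def indicator_significance(
    hits: KOHitTable,
    clusters: ClusterAssignment,
    n_samples: int = 20,
    n_iter: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    add_one: bool = True,
) -> pd.DataFrame:
    """Observed IVs plus permutation p-values.

    Null: taxa randomly reassigned to clusters with sizes preserved; p is
    the proportion of null IVs ≥ observed (ties count as exceedances; the
    literal strictly-greater rule is ``add_one=False`` with a strict
    comparison and is deliberately not offered, as it returns p = 0 for
    perfect indicators).
    """
    if (clusters.sizes() == 0).any():
        raise ValueError("empty cluster in assignment")
    taxa = list(clusters.labels.index)
    samples = sorted(hits.data["sample_id"].unique())
    kos, hits_kt, det_kt, _ = hits.hit_and_detection_matrices(taxa, samples)
    labels = clusters.labels.to_numpy()
    cluster_ids = np.unique(labels)
    member = (labels[:, None] == cluster_ids[None, :]).astype(float)
    sizes = member.sum(axis=0)
    cell_denom = sizes * n_samples
    _, _, _, iv_obs = _iv_components(hits_kt, det_kt, member, cell_denom)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(iv_obs, dtype=np.int64)
    thresh = iv_obs - _TIE_RTOL * np.maximum(1.0, np.abs(iv_obs))
    n_taxa = len(taxa)
    for _ in range(n_iter):
        perm = rng.permutation(n_taxa)
        _, _, _, iv_null = _iv_components(
            hits_kt[:, perm], det_kt[:, perm], member, cell_denom
        )
        exceed += iv_null >= thresh

    denom = n_iter + 1 if add_one else n_iter
    p = (exceed + (1 if add_one else 0)) / denom
    table = compute_indicator_values(hits, clusters, n_samples)
    table["p_value"] = p.reshape(-1)
    table["n_iter"] = n_iter
    return table


def day_night_indicator(
    hits: KOHitTable,
    clusters: ClusterAssignment,
    cluster: int,
    frame: SampleFrame,
    n_iter: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    add_one: bool = True,
) -> pd.DataFrame:
    """Day-vs-night indicator analysis within one activity cluster.

    The two "clusters" of the IV computation are the day-sample and
    night-sample groups: hits are summed over the cluster's taxa per sample,
    normalized by the group's sample count, and fidelity's denominator is
    |cluster taxa| × |group samples|. Significance permutes the sample
    day/night labels.
    """
    member_taxa = clusters.members(cluster)
    if not member_taxa:
        raise ValueError(f"cluster {cluster} has no members")
    samples = list(frame.data.index)
    photo = frame.data["photoperiod"]
    if photo.nunique() < 2:
        raise ValueError("need both day and night samples")

    # per-sample summaries over the cluster's taxa
    kos, _, _, det_full = hits.hit_and_detection_matrices(member_taxa, samples)
    ko_ix = {k: i for i, k in enumerate(kos)}
    s_ix = {s: i for i, s in enumerate(samples)}
    member_set = set(member_taxa)
    hits_ks = np.zeros((len(kos), len(samples)))
    for taxon, ko, sample, h in zip(
        hits.data["taxon_id"], hits.data["ko_id"], hits.data["sample_id"], hits.data["hits"]
    ):
        if taxon in member_set and sample in s_ix and h > 0:
            hits_ks[ko_ix[ko], s_ix[sample]] += h
    det_ks = det_full.sum(axis=1).astype(float)  # (n_ko, n_samples) detected cells per sample

    group_ids = np.array(["day", "night"])
    member = (photo.to_numpy()[:, None] == group_ids[None, :]).astype(float)
    group_sizes = member.sum(axis=0)
    cell_denom = group_sizes * len(member_taxa)
    _, _, _, iv_obs = _iv_components(hits_ks, det_ks, member, cell_denom)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(iv_obs, dtype=np.int64)
    thresh = iv_obs - _TIE_RTOL * np.maximum(1.0, np.abs(iv_obs))
    for _ in range(n_iter):
        perm = rng.permutation(len(samples))
        _, _, _, iv_null = _iv_components(
            hits_ks[:, perm], det_ks[:, perm], member, cell_denom
        )
        exceed += iv_null >= thresh
    denom = n_iter + 1 if add_one else n_iter
    p = (exceed + (1 if add_one else 0)) / denom

    N, spec, fid, iv = _iv_components(hits_ks, det_ks, member, cell_denom)
    rows = []
    for ki, ko in enumerate(kos):
        for gi, g in enumerate(group_ids):
            rows.append(
                {
                    "ko_id": ko,
                    "cluster": cluster,
                    "group": g,
                    "normalized_hits": N[ki, gi],
                    "specificity": spec[ki, gi],
                    "fidelity": fid[ki, gi],
                    "iv": iv[ki, gi],
                    "p_value": p[ki, gi],
                    "n_iter": n_iter,
                }
            )
    return pd.DataFrame(rows)


def pathway_enrichment(
    sig_indicators: pd.DataFrame,
    hits: KOHitTable,
    clusters: ClusterAssignment,
    n_iter: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    alpha: float = 0.05,
    add_one: bool = True,
) -> pd.DataFrame:
    """Pathway-level enrichment of a cluster's significant indicator KOs.

    For each (pathway, cluster): the observed count of significant indicator
    KOs annotated to the pathway, against a null that redraws the same
    number of KOs uniformly (without replacement) from the cluster's
    expressed-KO universe. A KO annotated to several pathways counts once
    per pathway.
    """
    pmap = hits.pathway_map()
    pathways = sorted({p for ps in pmap.values() for p in ps})
    if not pathways:
        logger.warning("no pathway annotations present; enrichment skipped")
        return pd.DataFrame(
            columns=["pathway_id", "cluster", "n_significant_indicator_kos",
                     "n_universe_kos", "p_value"]
        )
    rng = np.random.default_rng(seed)
    rows = []
    for c in sorted(clusters.labels.unique()):
        member_taxa = set(clusters.members(c))
        expressed = hits.data[hits.data["taxon_id"].isin(member_taxa) & (hits.data["hits"] > 0)]
        universe = sorted(expressed["ko_id"].unique())
        if not universe:
            continue
        sig = sig_indicators[
            (sig_indicators["cluster"] == c) & (sig_indicators["p_value"] < alpha)
        ]
        sig_kos = [k for k in sig["ko_id"].unique() if k in universe]
        n_sig = len(sig_kos)
        # pathway membership over the universe
        P = np.zeros((len(universe), len(pathways)))
        pw_ix = {p: i for i, p in enumerate(pathways)}
        for ki, ko in enumerate(universe):
            for p in pmap.get(ko, ()):
                P[ki, pw_ix[p]] = 1.0
        observed = P[[universe.index(k) for k in sig_kos]].sum(axis=0) if n_sig else np.zeros(len(pathways))

        null_counts = np.zeros((n_iter, len(pathways)))
        if n_sig:
            for it in range(n_iter):
                draw = rng.permutation(len(universe))[:n_sig]
                null_counts[it] = P[draw].sum(axis=0)
        exceed = (null_counts >= observed[None, :]).sum(axis=0)
        denom = n_iter + 1 if add_one else n_iter
        pvals = (exceed + (1 if add_one else 0)) / denom
        for pi, pw in enumerate(pathways):
            if P[:, pi].sum() == 0:
                continue  # pathway not expressed in this cluster's universe
            rows.append(
                {
                    "pathway_id": pw,
                    "cluster": int(c),
                    "n_significant_indicator_kos": int(observed[pi]),
                    "n_universe_kos": int(P[:, pi].sum()),
                    "p_value": pvals[pi],
                }
            )
    return pd.DataFrame(rows)
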