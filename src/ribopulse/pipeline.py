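"""End-to-end orchestration: simulate/read -> activity -> tests -> clusters
-> indicators, with deterministic seeding and TSV outputs per stage.

Randomized stages draw their generators from per-stage children of a single
master ``numpy.random.SeedSequence(seed)``, spawned in a fixed order, so a
pipeline run is byte-reproducible from its config alone and no stage's
consumption of random numbers perturbs another's.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .activity import bootstrap_ci, compute_pct_rp, compute_rp_per_L
from .clustering import (
    cluster_taxa,
    correlation_distance,
    linkage_to_newick,
    rank_order_profiles,
    silhouette_profile,
)
from .datamodel import (
    SEASONS,
    ActivityMatrix,
    BinCountMatrix,
    ClusterAssignment,
    KOHitTable,
    SampleFrame,
    average_technical_replicates,
)
from .indicators import day_night_indicator, indicator_significance, pathway_enrichment
from .simulate import SimConfig, simulate, write_truth
from .temporal import run_temporal_battery

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_max_season"]

# fixed spawn order of the master seed's per-stage substreams
_STAGES = ("simulate", "bootstrap", "temporal", "indicator", "diel_indicator", "pathway")


@dataclass
class PipelineConfig:
    """Flat configuration of a full pipeline run (YAML: one key per field)."""

    counts: str | None = None
    samples: str | None = None
    ko_hits: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields
    out_dir: str = "ribopulse_out"
    k_clusters: int = 7
    n_boot: int = 1000
    ci_level: float = 0.95
    temporal_iters: int = 10000
    indicator_iters: int = 1000
    diel_indicator_iters: int = 10000
    pathway_iters: int = 1000
    alpha: float = 0.05
    tail: str = "two-sided"
    add_one: bool = True
    null: str = "repartition"
    diel_cluster: int | None = None  # None: cluster with most day-enriched taxa
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("n_boot", "temporal_iters", "indicator_iters",
                     "diel_indicator_iters", "pathway_iters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.simulate and (self.counts is None or self.samples is None):
            raise ValueError("provide counts+samples paths or set simulate: true")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # where results land is not provenance
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


def summarize_max_season(
    acts: ActivityMatrix, frame: SampleFrame, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Season-of-maximum-%RP counts per cluster (cluster x season table).

    Each taxon is attributed to the season of its highest-%RP sample; ties
    resolve to the earliest season in the fixed seasonal order (then by
    sample id) and are logged. Column sums over seasons equal cluster sizes.
    """
    meta = frame.data
    season_rank = {s: i for i, s in enumerate(SEASONS)}
    rows = []
    for taxon in clusters.labels.index:
        prof = acts.pct_rp.loc[taxon].dropna()
        if prof.empty:
            continue
        best = prof.max()
        argmax = sorted(
            prof.index[prof == best],
            key=lambda s: (season_rank[meta.loc[s, "season"]], s),
        )
        if len(argmax) > 1:
            logger.info("taxon %r: tie for maximum %%RP; earliest season used", taxon)
        rows.append(
            {
                "taxon_id": taxon,
                "cluster": int(clusters.labels[taxon]),
                "season": meta.loc[argmax[0], "season"],
            }
        )
    long = pd.DataFrame(rows)
    table = (
        long.pivot_table(index="cluster", columns="season", values="taxon_id",
                         aggfunc="count", fill_value=0)
        .reindex(columns=list(SEASONS), fill_value=0)
    )
    table.columns.name = "season"
    return table


def run_pipeline(
    cfg: PipelineConfig,
) -> dict:
    """Execute the full analysis; returns a result bundle (also written to
    ``cfg.out_dir`` as TSVs plus ``tree.nwk`` and ``summary.tsv``)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    stamp = f"config={cfg.config_hash()} seed={cfg.seed}"
    truth = None

    def _path(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    # --- inputs -----------------------------------------------------------
    if cfg.simulate:
        sim_kwargs = dict(cfg.sim)
        sim_kwargs.setdefault("seed", int(np.random.default_rng(seeds["simulate"]).integers(2**31)))
        simcfg = SimConfig(**sim_kwargs)
        counts, frame, hits, truth = simulate(simcfg)
        rio.write_dataset(counts, frame, hits, _path("counts.tsv"),
                          _path("samples.tsv"), _path("ko_hits.tsv"))
        write_truth(truth, _path("truth.tsv"))
    else:
        counts, frame, hits = rio.read_dataset(cfg.counts, cfg.samples, cfg.ko_hits)

    # --- activity ---------------------------------------------------------
    acts_ci = bootstrap_ci(counts, cfg.n_boot, cfg.ci_level, seeds["bootstrap"])
    rp_per_L = compute_rp_per_L(counts, frame)
    rio.write_activity_table(acts_ci, _path("activity.tsv"), rp_per_L, stamp)

    acts_avg, frame_avg = average_technical_replicates(
        ActivityMatrix(pct_rp=acts_ci.pct_rp), frame
    )
    # rp_per_L is collapsed with the same replicate-averaging rule as %RP
    groups: dict[str, list[str]] = {}
    for sid in frame.data.index:
        primary = frame.data.loc[sid, "replicate_of"]
        groups.setdefault(primary if pd.notna(primary) else sid, []).append(sid)
    abs_mat = pd.DataFrame(
        {p: rp_per_L[members].mean(axis=1) for p, members in groups.items()}
    )[list(frame_avg.data.index)]

    # --- temporal tests ---------------------------------------------------
    temporal_table, temporal_summary = run_temporal_battery(
        acts_avg, abs_mat, frame_avg, cfg.temporal_iters, seeds["temporal"],
        cfg.alpha, cfg.tail, cfg.add_one, cfg.null,
    )
    rio.write_table(temporal_table, _path("temporal.tsv"), stamp)

    # --- clustering -------------------------------------------------------
    dist = correlation_distance(acts_avg)
    clusters = cluster_taxa(dist, cfg.k_clusters)
    rio.write_table(clusters.labels.rename("cluster").reset_index(), _path("clusters.tsv"), stamp)
    with open(_path("tree.nwk"), "w") as fh:
        fh.write(linkage_to_newick(clusters.linkage, clusters.taxa) + "\n")
    rio.write_table(silhouette_profile(dist), _path("silhouette.tsv"), stamp)
    rio.write_table(rank_order_profiles(acts_avg, frame_avg), _path("rank_profiles.tsv"), stamp)

    # --- indicator analyses -----------------------------------------------
    indicator_table = None
    diel_table = None
    pathway_table = None
    if hits is not None:
        n_samples = len(frame_avg.data)
        indicator_table = indicator_significance(
            hits, clusters, n_samples, cfg.indicator_iters, seeds["indicator"],
            cfg.add_one,
        )
        rio.write_table(indicator_table, _path("indicators.tsv"), stamp)

        diel_cluster = cfg.diel_cluster
        if diel_cluster is None:
            dn = temporal_table[
                (temporal_table["test"] == "day_night")
                & (temporal_table["metric"] == "pct_rp")
                & (temporal_table["direction"] == "day_enriched")
            ]
            by_cluster = clusters.labels.reindex(dn["taxon_id"]).value_counts()
            diel_cluster = int(by_cluster.idxmax()) if len(by_cluster) else int(clusters.labels.iloc[0])
        diel_table = day_night_indicator(
            hits, clusters, diel_cluster, frame_avg,
            cfg.diel_indicator_iters, seeds["diel_indicator"], cfg.add_one,
        )
        rio.write_table(diel_table, _path("diel_indicators.tsv"), stamp)

        pathway_table = pathway_enrichment(
            indicator_table, hits, clusters, cfg.pathway_iters, seeds["pathway"],
            cfg.alpha, cfg.add_one,
        )
        rio.write_table(pathway_table, _path("pathways.tsv"), stamp)

    # --- summary ----------------------------------------------------------
    max_season = summarize_max_season(acts_avg, frame_avg, clusters)
    rio.write_table(max_season, _path("max_season.tsv"), stamp, index=True)

    summary = dict(temporal_summary)
    summary["n_taxa"] = len(acts_avg.taxa)
    summary["n_samples"] = len(frame_avg.data)
    summary["k_clusters"] = clusters.k
    for c, size in clusters.sizes().items():
        summary[f"cluster_{c}_size"] = int(size)
    if indicator_table is not None:
        summary["significant_indicator_kos"] = int(
            (indicator_table["p_value"] < cfg.alpha).sum()
        )
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        common = clusters.labels.index.intersection(truth.cluster_of.index)
        summary["ari_vs_truth"] = float(
            adjusted_rand_score(truth.cluster_of[common], clusters.labels[common])
        )
    srows = pd.DataFrame(
        {"key": list(summary.keys()), "value": [summary[k] for k in summary]}
    )
    rio.write_table(srows, _path("summary.tsv"), stamp)

    return {
        "counts": counts,
        "frame": frame,
        "frame_averaged": frame_avg,
        "activity": acts_ci,
        "activity_averaged": acts_avg,
        "rp_per_L": rp_per_L,
        "rp_per_L_averaged": abs_mat,
        "temporal": temporal_table,
        "clusters": clusters,
        "distance": dist,
        "indicators": indicator_table,
        "diel_indicators": diel_table,
        "pathways": pathway_table,
        "max_season": max_season,
        "summary": summary,
        "truth": truth,
    }
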