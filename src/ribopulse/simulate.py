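"""Synthetic community metatranscriptome generator with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes, starting at the binned-count level (no reads or annotation are
simulated):

* a quarterly sampling design — five seasonal campaigns (summer1, fall,
  winter, spring, summer2), each contributing consecutive day-night pairs;
* ~200 taxon bins partitioned into k activity clusters, each cluster with
  its own season profile of mean %RP (three cold-biased and four warm-biased
  profiles by default, spanning roughly 1–15 %RP);
* one designated cluster with a planted diel effect (day %RP elevated over
  night), mimicking a community whose heterotrophs run a strong day-night
  activity rhythm;
* logit-normal biological noise on %RP, negative-binomially overdispersed
  bin depths, binomial read sampling of RP reads within a bin;
* an internal RNA standard spiked at a known copy number, recovered in
  proportion to each sample's sequencing fraction, which makes absolute
  RP transcripts per litre recoverable downstream;
* planted indicator KOs per cluster (detected with high probability in
  member taxa, low elsewhere) over a background of uninformative KOs.

Every draw is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SEASONS, BinCountMatrix, KOHitTable, SampleFrame

__all__ = ["SimConfig", "SyntheticTruth", "generate_samples", "generate_counts",
           "generate_ko_hits", "simulate"]

#: Default per-cluster mean %RP by season. Rows are clusters 1..7, columns
#: follow :data:`ribopulse.datamodel.SEASONS`. Clusters 1–3 peak in the cold
#: seasons, 4–7 in the warm ones; profiles were chosen mutually distinct
#: under Pearson correlation (max pairwise r ≈ 0.55) so the planted clusters
#: are resolvable by correlation-distance clustering.
DEFAULT_SEASON_PROFILES: dict[int, tuple[float, ...]] = {
    1: (3.0, 8.0, 13.0, 6.0, 3.0),
    2: (3.0, 10.0, 4.0, 3.0, 5.0),
    3: (2.0, 3.0, 7.0, 10.0, 2.0),
    4: (4.0, 2.0, 2.0, 9.0, 7.0),
    5: (10.0, 3.0, 2.0, 5.0, 11.0),
    6: (2.0, 5.0, 2.0, 3.0, 12.0),
    7: (9.0, 6.0, 2.0, 8.0, 5.0),
}

#: Seasonal mean water temperature (deg C) and daytime PAR used for the
#: optional environmental covariates.
_SEASON_TEMP = {"summer1": 29.0, "fall": 18.0, "winter": 10.0, "spring": 22.0, "summer2": 30.0}
_SEASON_PAR = {"summer1": 1400.0, "fall": 800.0, "winter": 600.0, "spring": 1200.0, "summer2": 1500.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the shape of the motivating field design: 20 samples
    (5 seasons x 2 day-night pairs), 200 taxon bins in 7 activity clusters,
    %RP between ~1 and ~15, one cluster (``diel_cluster``) with a +5 %RP
    day-night offset, and 5 planted indicator KOs per cluster over 100
    background KOs.
    """

    n_taxa: int = 200
    pairs_per_season: int = 2
    k_clusters: int = 7
    season_profiles: dict[int, tuple[float, ...]] | None = None
    library_depth_mean: float = 20000.0
    library_depth_shape: float = 4.0  # NB shape; variance = mu + mu^2/shape
    noise_sd: float = 0.25  # logit-scale SD of biological %RP noise
    diel_cluster: int | None = 2
    diel_fraction: float = 1.0  # fraction of the diel cluster's taxa affected
    diel_delta: float = 5.0  # day-minus-night %RP offset for affected taxa
    n_indicator_kos: int = 5  # per cluster
    n_background_kos: int = 100
    indicator_p_in: float = 0.9  # per-sample detection prob in member taxa
    indicator_p_out: float = 0.1  # ... in non-member taxa
    background_p: float = 0.3
    volume_range: tuple[float, float] = (6.0, 8.0)
    standard_copies: float = 4.7e10  # spike-in copies added per sample
    seq_fraction_range: tuple[float, float] = (2e-8, 8e-8)
    n_replicate_samples: int = 0  # technical re-sequencing of the first samples
    seed: int = 20080806

    def __post_init__(self) -> None:
        if self.n_taxa < self.k_clusters:
            raise ValueError("n_taxa must be >= k_clusters")
        if self.pairs_per_season < 1 or self.k_clusters < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.diel_fraction <= 1.0):
            raise ValueError("diel_fraction must lie in [0, 1]")
        for p in (self.indicator_p_in, self.indicator_p_out, self.background_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("detection probabilities must lie in [0, 1]")
        profiles = self.season_profiles or DEFAULT_SEASON_PROFILES
        if self.season_profiles is None and self.k_clusters > len(profiles):
            raise ValueError(
                f"no default season profiles beyond k={len(profiles)}; "
                "pass season_profiles explicitly"
            )
        self.season_profiles = {c: tuple(profiles[c]) for c in range(1, self.k_clusters + 1)}
        for c, prof in self.season_profiles.items():
            if len(prof) != len(SEASONS):
                raise ValueError(f"cluster {c}: profile must have {len(SEASONS)} seasons")
            if any(not (0.0 < v < 100.0) for v in prof):
                raise ValueError(f"cluster {c}: season profile %RP must lie in (0, 100)")
            if self.diel_cluster == c and any(
                not (0.0 < v + self.diel_delta < 100.0) for v in prof
            ):
                raise ValueError(
                    f"cluster {c}: %RP plus diel_delta leaves (0, 100)"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    cluster_of: pd.Series  # taxon -> 1..k
    diel_effect: pd.Series  # taxon -> signed day-minus-night %RP offset
    season_profile: pd.DataFrame  # cluster x season mean %RP
    true_rp_conc: pd.DataFrame  # taxon x sample RP transcripts per litre
    seq_fraction: pd.Series  # sample -> fraction of transcripts sequenced
    expected_pct_rp: pd.DataFrame  # taxon x sample latent %RP (pre-counting)
    planted_indicators: dict[int, set[str]] = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(
        {"samples": 1, "counts": 2, "ko": 3}[stream]
    )[0])


def generate_samples(cfg: SimConfig) -> SampleFrame:
    """Sampling design: one day and one night sample per pair, per season.

    Sample ids encode season and pair (e.g. ``fall_p1_day``). When
    ``n_replicate_samples`` > 0, the first samples gain a technical replicate
    (suffix ``_rep``) sharing all metadata but an independent library.
    """
    rng = _rng(cfg, "samples")
    rows = []
    for season in SEASONS:
        for p in range(1, cfg.pairs_per_season + 1):
            pair_id = f"{season}_p{p}"
            for photo in ("day", "night"):
                rows.append(
                    {
                        "sample_id": f"{pair_id}_{photo}",
                        "season": season,
                        "photoperiod": photo,
                        "pair_id": pair_id,
                        "replicate_of": np.nan,
                        "temperature": _SEASON_TEMP[season] + rng.normal(0.0, 1.0),
                        "par": (_SEASON_PAR[season] if photo == "day" else 0.0)
                        + rng.normal(0.0, 20.0) * (photo == "day"),
                    }
                )
    for row in rows[: cfg.n_replicate_samples]:
        rep = dict(row)
        rep["sample_id"] = row["sample_id"] + "_rep"
        rep["replicate_of"] = row["sample_id"]
        rep["pair_id"] = np.nan  # the pair is represented by the primary
        rows.append(rep)
    df = pd.DataFrame(rows).set_index("sample_id")
    n = len(df)
    df["volume_L"] = rng.uniform(*cfg.volume_range, size=n).round(2)
    df["standard_copies"] = cfg.standard_copies
    df["standard_reads"] = 0  # filled by generate_counts
    ordered = ["season", "photoperiod", "pair_id", "replicate_of", "volume_L",
               "standard_copies", "standard_reads", "temperature", "par"]
    return SampleFrame(df[ordered])


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_counts(cfg: SimConfig, frame: SampleFrame) -> tuple[BinCountMatrix, SyntheticTruth]:
    """Draw the taxon-bin count matrix and its ground truth.

    Per taxon-sample cell the latent %RP is the cluster's season profile,
    plus the taxon's diel offset in day samples, perturbed by logit-normal
    noise (one draw per taxon and *pair*, shared by technical replicates of
    a library but independent between samples). Bin depth is negative
    binomial around ``library_depth_mean``; RP reads are Binomial(depth,
    %RP/100). The internal standard is recovered deterministically as
    ``round(standard_copies x seq_fraction)``, so spike-in normalization is
    exactly invertible and the only counting noise is in the taxon counts.
    """
    rng = _rng(cfg, "counts")
    df = frame.data
    samples = list(df.index)
    n_s = len(samples)
    taxa = [f"bin{i:03d}" for i in range(1, cfg.n_taxa + 1)]

    # round-robin cluster assignment in shuffled taxon order: sizes balanced
    labels = np.array([(i % cfg.k_clusters) + 1 for i in range(cfg.n_taxa)])
    rng.shuffle(labels)
    cluster_of = pd.Series(labels, index=taxa, name="cluster")

    diel = np.zeros(cfg.n_taxa)
    if cfg.diel_cluster is not None and cfg.diel_delta != 0.0:
        members = np.flatnonzero(labels == cfg.diel_cluster)
        n_affected = int(round(cfg.diel_fraction * len(members)))
        affected = rng.choice(members, size=n_affected, replace=False)
        diel[affected] = cfg.diel_delta
    diel_effect = pd.Series(diel, index=taxa, name="diel_effect")

    prof = pd.DataFrame(
        {s: [cfg.season_profiles[c][j] for c in range(1, cfg.k_clusters + 1)]
         for j, s in enumerate(SEASONS)},
        index=pd.RangeIndex(1, cfg.k_clusters + 1, name="cluster"),
    )

    season_of = df["season"].to_numpy()
    is_day = (df["photoperiod"] == "day").to_numpy()
    base = prof.loc[labels, season_of].to_numpy(dtype=float)  # taxa x samples
    base = base + np.outer(diel, is_day.astype(float))
    if (base <= 0).any() or (base >= 100).any():
        raise ValueError("expected %RP outside (0, 100) after planted effects")

    # biological noise shared within a replicate group (same RNA library)
    group_key = np.where(df["replicate_of"].notna(), df["replicate_of"], df.index)
    groups, group_ix = np.unique(group_key, return_inverse=True)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_taxa, len(groups)))
    p = _expit(_logit(base / 100.0) + noise[:, group_ix])

    depth = rng.negative_binomial(
        cfg.library_depth_shape,
        cfg.library_depth_shape / (cfg.library_depth_shape + cfg.library_depth_mean),
        size=(cfg.n_taxa, n_s),
    )
    rp = rng.binomial(depth, p)

    seq_frac = pd.Series(rng.uniform(*cfg.seq_fraction_range, size=n_s),
                         index=samples, name="seq_fraction")
    std_reads = np.round(df["standard_copies"].to_numpy() * seq_frac.to_numpy()).astype(int)
    frame.data["standard_reads"] = std_reads

    # truth concentration = RP transcripts actually sampled into the library,
    # scaled back through the sequencing fraction and filtered volume
    conc = rp / (seq_frac.to_numpy()[None, :] * df["volume_L"].to_numpy()[None, :])

    counts = BinCountMatrix(
        total=pd.DataFrame(depth, index=taxa, columns=samples),
        rp=pd.DataFrame(rp, index=taxa, columns=samples),
    )
    truth = SyntheticTruth(
        cluster_of=cluster_of,
        diel_effect=diel_effect,
        season_profile=prof,
        true_rp_conc=pd.DataFrame(conc, index=taxa, columns=samples),
        seq_fraction=seq_frac,
        expected_pct_rp=pd.DataFrame(100.0 * p, index=taxa, columns=samples),
    )
    return counts, truth


def generate_ko_hits(cfg: SimConfig, truth: SyntheticTruth, frame: SampleFrame) -> KOHitTable:
    """Plant indicator KOs per cluster over a uniform KO background.

    Indicator KOs of cluster c are detected per (member taxon, sample) with
    probability ``indicator_p_in`` and ``indicator_p_out`` elsewhere;
    background KOs with ``background_p`` everywhere. Hit counts per detection
    are 1 + Poisson(0.5), so a detection occasionally carries multiple gene
    copies, as when several genes of a taxon bin to one KO. Indicator KOs
    carry a per-cluster pathway id; background KOs draw one of ten background
    pathways. Fills ``truth.planted_indicators``.
    """
    rng = _rng(cfg, "ko")
    taxa = list(truth.cluster_of.index)
    samples = list(frame.data.index)
    labels = truth.cluster_of.to_numpy()

    kos: list[tuple[str, str, np.ndarray]] = []  # (ko_id, pathway_ids, prob per taxon)
    truth.planted_indicators = {}
    for c in range(1, cfg.k_clusters + 1):
        truth.planted_indicators[c] = set()
        for j in range(cfg.n_indicator_kos):
            ko = f"K_c{c}_{j:02d}"
            probs = np.where(labels == c, cfg.indicator_p_in, cfg.indicator_p_out)
            kos.append((ko, f"path_c{c}", probs))
            truth.planted_indicators[c].add(ko)
    bg_paths = [f"path_bg{j}" for j in range(10)]
    for j in range(cfg.n_background_kos):
        ko = f"K_bg_{j:03d}"
        kos.append((ko, bg_paths[int(rng.integers(len(bg_paths)))],
                    np.full(len(taxa), cfg.background_p)))

    records = []
    for ko, path, probs in kos:
        det = rng.random((len(taxa), len(samples))) < probs[:, None]
        extra = rng.poisson(0.5, size=det.shape)
        for ti, si in zip(*np.nonzero(det)):
            records.append((taxa[ti], ko, path, samples[si], 1 + int(extra[ti, si])))
    df = pd.DataFrame(records, columns=list(KOHitTable.REQUIRED))
    return KOHitTable(df)


def simulate(cfg: SimConfig) -> tuple[BinCountMatrix, SampleFrame, KOHitTable, SyntheticTruth]:
    """Full generator: sampling design, counts, and KO hits."""
    frame = generate_samples(cfg)
    counts, truth = generate_counts(cfg, frame)
    hits = generate_ko_hits(cfg, truth, frame)
    return counts, frame, hits, truth


def write_truth(truth: SyntheticTruth, path: str) -> None:
    """Per-taxon ground-truth table (cluster label and diel offset)."""
    df = pd.DataFrame({
        "cluster": truth.cluster_of,
        "diel_effect": truth.diel_effect,
    })
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")
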