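"""Shared domain types for taxon-resolved metatranscriptome activity analysis.

The analysis operates on three aligned structures:

* :class:`SampleFrame` — per-sample metadata (seasonal grouping, day/night
  flag, day-night pair linkage, technical-replicate linkage, volume filtered,
  internal-standard spike-in bookkeeping, optional environmental covariates).
* :class:`BinCountMatrix` — per taxon bin and sample, the total number of
  annotated reads and the number of ribosomal-protein (RP) annotated reads.
* :class:`KOHitTable` — long-form KEGG-ortholog hit counts per
  (taxon, KO, sample), the raw material of the indicator analysis.

All containers wrap pandas objects and validate their invariants eagerly so
that downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed seasonal ordering of the five sampling campaigns.
SEASONS = ("summer1", "fall", "winter", "spring", "summer2")

PHOTOPERIODS = ("day", "night")

#: Required columns of a sample metadata table, in canonical order.
SAMPLE_COLUMNS = (
    "season",
    "photoperiod",
    "pair_id",
    "replicate_of",
    "volume_L",
    "standard_copies",
    "standard_reads",
)


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class FormatError(ValueError):
    """An input file does not match the expected tabular layout."""


@dataclass
class SampleFrame:
    """Per-sample metadata, indexed by unique sample id.

    ``data`` holds the canonical columns (:data:`SAMPLE_COLUMNS`); any
    additional columns are treated as environmental covariates (temperature,
    PAR, chlorophyll a, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            raise FormatError("sample table index must be named 'sample_id'")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing column(s): {missing}")

        bad_season = set(df["season"]) - set(SEASONS)
        if bad_season:
            raise ValidationError(f"unknown season label(s): {sorted(bad_season)}")
        bad_photo = set(df["photoperiod"]) - set(PHOTOPERIODS)
        if bad_photo:
            raise ValidationError(f"unknown photoperiod label(s): {sorted(bad_photo)}")

        if (df["volume_L"] <= 0).any():
            bad = df.index[df["volume_L"] <= 0].tolist()
            raise ValidationError(f"volume_L must be > 0 (samples {bad})")
        if (df["standard_copies"] <= 0).any():
            bad = df.index[df["standard_copies"] <= 0].tolist()
            raise ValidationError(f"standard_copies must be > 0 (samples {bad})")
        if (df["standard_reads"] < 0).any():
            bad = df.index[df["standard_reads"] < 0].tolist()
            raise ValidationError(f"standard_reads must be >= 0 (samples {bad})")

        # each pair_id links exactly one day and one night sample
        paired = df[df["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            photos = sorted(grp["photoperiod"])
            if photos != ["day", "night"]:
                raise ValidationError(
                    f"pair_id {pid!r} must link exactly one day and one night "
                    f"sample, got {photos}"
                )

        # replicate links point at existing samples with matching metadata
        reps = df[df["replicate_of"].notna()]
        for sid, row in reps.iterrows():
            primary = row["replicate_of"]
            if primary not in df.index:
                raise ValidationError(
                    f"replicate_of of {sid!r} names unknown sample {primary!r}"
                )
            prow = df.loc[primary]
            if (
                prow["season"] != row["season"]
                or prow["photoperiod"] != row["photoperiod"]
            ):
                raise ValidationError(
                    f"technical replicate {sid!r} disagrees with {primary!r} "
                    "on season/photoperiod"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in SAMPLE_COLUMNS]

    def pairs(self) -> pd.DataFrame:
        """Complete day-night pairs as a frame with columns day, night."""
        paired = self.data[self.data["pair_id"].notna()]
        rows = {}
        for pid, grp in paired.groupby("pair_id"):
            by_photo = grp["photoperiod"]
            rows[pid] = {
                "day": by_photo.index[by_photo == "day"][0],
                "night": by_photo.index[by_photo == "night"][0],
            }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("pair_id")

    def subset(self, sample_ids) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)].copy())


@dataclass
class BinCountMatrix:
    """Total and RP-annotated read counts per taxon bin and sample."""

    total: pd.DataFrame  # taxa x samples
    rp: pd.DataFrame  # taxa x samples, same shape

    def __post_init__(self) -> None:
        if not self.total.index.equals(self.rp.index) or not self.total.columns.equals(
            self.rp.columns
        ):
            raise FormatError("total and rp matrices must share taxa and samples")
        if self.total.index.duplicated().any():
            raise ValidationError("duplicate taxon ids in count matrix")
        if (self.total.to_numpy() < 0).any() or (self.rp.to_numpy() < 0).any():
            raise ValidationError("read counts must be non-negative")
        bad = self.rp.to_numpy() > self.total.to_numpy()
        if bad.any():
            ti, si = np.argwhere(bad)[0]
            raise ValidationError(
                f"rp_reads > total_reads for taxon {self.total.index[ti]!r}, "
                f"sample {self.total.columns[si]!r}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.total.index)

    @property
    def samples(self) -> list[str]:
        return list(self.total.columns)

    def check_samples(self, frame: SampleFrame) -> None:
        unknown = set(self.samples) - set(frame.sample_ids)
        if unknown:
            raise ValidationError(
                f"count matrix references unknown sample(s): {sorted(unknown)}"
            )


@dataclass
class ActivityMatrix:
    """Taxon x sample %RP values, optionally with bootstrap CI bounds.

    Cells where a bin recruited no reads at all (total_reads = 0) are NaN:
    an undefined activity index is distinct from a measured 0 %RP.
    """

    pct_rp: pd.DataFrame
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.pct_rp.to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        if ((vals[defined] < 0) | (vals[defined] > 100)).any():
            raise ValidationError("pct_rp values must lie in [0, 100]")
        for name, ci in (("ci_low", self.ci_low), ("ci_high", self.ci_high)):
            if ci is not None and (
                not ci.index.equals(self.pct_rp.index)
                or not ci.columns.equals(self.pct_rp.columns)
            ):
                raise FormatError(f"{name} must be aligned with pct_rp")
        if self.ci_low is not None and self.ci_high is not None:
            lo = self.ci_low.to_numpy(dtype=float)
            hi = self.ci_high.to_numpy(dtype=float)
            ok = np.isnan(lo) | np.isnan(hi) | ((lo <= vals + 1e-12) & (vals <= hi + 1e-12))
            if not ok.all():
                raise ValidationError("CI bounds must bracket the point estimate")

    @property
    def taxa(self) -> list[str]:
        return list(self.pct_rp.index)

    @property
    def samples(self) -> list[str]:
        return list(self.pct_rp.columns)


@dataclass
class KOHitTable:
    """Long-form (taxon, KO, sample) hit counts.

    A *hit count* may exceed one per sample when a taxon has several genes
    binning to the same KO; *detection* is the binarized hits > 0.
    ``pathway_ids`` is a semicolon-joined (possibly empty) pathway set.
    """

    data: pd.DataFrame

    REQUIRED = ("taxon_id", "ko_id", "pathway_ids", "sample_id", "hits")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"KO hit table missing column(s): {missing}")
        if (self.data["hits"] < 0).any():
            raise ValidationError("hits must be non-negative")
        key = self.data[["taxon_id", "ko_id", "sample_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"duplicate (taxon, ko, sample) record: {tuple(dup)}"
            )
        self.data = self.data.copy()
        self.data["pathway_ids"] = self.data["pathway_ids"].fillna("")

    @property
    def kos(self) -> list[str]:
        return sorted(self.data["ko_id"].unique())

    def pathway_map(self) -> dict[str, set[str]]:
        """KO id -> set of pathway ids (union over records)."""
        out: dict[str, set[str]] = {}
        for ko, paths in zip(self.data["ko_id"], self.data["pathway_ids"]):
            out.setdefault(ko, set()).update(p for p in str(paths).split(";") if p)
        return out

    def hit_and_detection_matrices(
        self, taxa: list[str], samples: list[str]
    ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Dense per-KO summaries over a fixed taxon and sample universe.

        Returns ``(kos, hits_ts, det_ts, det_tks)`` where ``hits_ts[k, t]``
        sums hit counts over samples, ``det_ts[k, t]`` counts samples with
        detection, and ``det_tks[k, t, s]`` is the 0/1 detection tensor.
        """
        kos = self.kos
        ko_ix = {k: i for i, k in enumerate(kos)}
        t_ix = {t: i for i, t in enumerate(taxa)}
        s_ix = {s: i for i, s in enumerate(samples)}
        det = np.zeros((len(kos), len(taxa), len(samples)), dtype=np.int64)
        hits = np.zeros_like(det)
        for taxon, ko, sample, h in zip(
            self.data["taxon_id"], self.data["ko_id"], self.data["sample_id"], self.data["hits"]
        ):
            if taxon not in t_ix or sample not in s_ix:
                continue
            if h > 0:
                hits[ko_ix[ko], t_ix[taxon], s_ix[sample]] += int(h)
                det[ko_ix[ko], t_ix[taxon], s_ix[sample]] = 1
        return kos, hits.sum(axis=2), det.sum(axis=2), det


@dataclass
class ClusterAssignment:
    """Flat activity-cluster labels plus the dendrogram they were cut from."""

    labels: pd.Series  # taxon_id -> integer label 1..k
    linkage: np.ndarray | None = None  # scipy (n-1, 4) linkage matrix
    taxa: list[str] = field(default_factory=list)  # leaf order of `linkage`

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValidationError("duplicate taxon in cluster assignment")
        if self.linkage is not None:
            heights = self.linkage[:, 2]
            if np.any(np.diff(heights) < -1e-12):
                raise ValidationError("linkage merge heights must be non-decreasing")

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def average_technical_replicates(
    acts: ActivityMatrix, frame: SampleFrame
) -> tuple[ActivityMatrix, SampleFrame]:
    """Collapse technical-replicate samples by averaging their %RP profiles.

    Each replicate group (a primary sample plus the samples whose
    ``replicate_of`` points at it) becomes a single pseudo-sample carrying the
    primary's metadata, with per-taxon %RP the arithmetic mean over the
    members where it is defined.  Averaging the derived %RP statistic, rather
    than summing the raw reads, weights the replicate libraries equally
    instead of by sequencing depth.  When %RP is undefined (no reads) in some
    but not all members, the mean over the defined members is used and a
    warning logged.
    """
    df = frame.data
    group_of: dict[str, str] = {}
    for sid in df.index:
        primary = df.loc[sid, "replicate_of"]
        group_of[sid] = primary if pd.notna(primary) else sid

    keep_order = [sid for sid in df.index if group_of[sid] == sid]
    pct = pd.DataFrame(index=acts.pct_rp.index, columns=keep_order, dtype=float)
    for primary in keep_order:
        members = [s for s, g in group_of.items() if g == primary and s in acts.samples]
        block = acts.pct_rp[members]
        if len(members) > 1:
            partial = block.isna().any(axis=1) & block.notna().any(axis=1)
            if partial.any():
                for taxon in block.index[partial]:
                    logger.warning(
                        "replicate group %r: %%RP undefined in some members for "
                        "taxon %r; averaging the defined values",
                        primary,
                        taxon,
                    )
        pct[primary] = block.mean(axis=1)  # skips NaN; all-NaN stays NaN

    new_frame = SampleFrame(df.loc[keep_order].copy())
    return ActivityMatrix(pct_rp=pct), new_frame
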