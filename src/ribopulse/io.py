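"""Readers and writers for the tab-separated interchange formats.

Three input tables drive the pipeline:

* ``counts.tsv`` — column ``taxon_id``, then per sample a pair of columns
  ``<sample_id>.total`` and ``<sample_id>.rp`` holding read counts.
* ``samples.tsv`` — ``sample_id, season, photoperiod, pair_id, replicate_of,
  volume_L, standard_copies, standard_reads`` plus optional covariate columns.
* ``ko_hits.tsv`` — long format ``taxon_id, ko_id, pathway_ids, sample_id,
  hits`` with semicolon-separated (possibly empty) pathway sets.

Writers emit canonical column order and stable float formatting so that
read -> write -> read round-trips are byte-identical on canonicalized input.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import (
    SAMPLE_COLUMNS,
    ActivityMatrix,
    BinCountMatrix,
    FormatError,
    KOHitTable,
    SampleFrame,
)

_NA = "NA"


def read_sample_table(path: str | os.PathLike) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=[_NA],
                     keep_default_na=False, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df.set_index("sample_id")
    df["volume_L"] = df["volume_L"].astype(float)
    df["standard_copies"] = df["standard_copies"].astype(float)
    df["standard_reads"] = df["standard_reads"].astype(int)
    for col in df.columns:
        if col not in SAMPLE_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleFrame(df)


def read_count_matrix(path: str | os.PathLike) -> BinCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str}, float_precision="round_trip")
    if "taxon_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'taxon_id'")
    df = df.set_index("taxon_id")
    totals, rps, samples = {}, {}, []
    for col in df.columns:
        if col.endswith(".total"):
            sid = col[: -len(".total")]
            if f"{sid}.rp" not in df.columns:
                raise FormatError(f"{path}: sample {sid!r} has .total but no .rp column")
            samples.append(sid)
            totals[sid] = df[col].astype(np.int64)
            rps[sid] = df[f"{sid}.rp"].astype(np.int64)
        elif not col.endswith(".rp"):
            raise FormatError(f"{path}: unrecognized column {col!r}")
    for col in df.columns:
        if col.endswith(".rp") and col[: -len(".rp")] not in samples:
            raise FormatError(f"{path}: sample column {col!r} has no matching .total")
    total = pd.DataFrame(totals, index=df.index)[samples]
    rp = pd.DataFrame(rps, index=df.index)[samples]
    total.columns.name = rp.columns.name = "sample_id"
    return BinCountMatrix(total=total, rp=rp)


def read_ko_hits(path: str | os.PathLike) -> KOHitTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"taxon_id": str, "ko_id": str, "pathway_ids": str, "sample_id": str},
        na_values=[_NA],
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in KOHitTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df["hits"] = df["hits"].astype(np.int64)
    return KOHitTable(df[list(KOHitTable.REQUIRED)])


def read_dataset(
    count_path: str | os.PathLike,
    sample_path: str | os.PathLike,
    ko_path: str | os.PathLike | None = None,
) -> tuple[BinCountMatrix, SampleFrame, KOHitTable | None]:
    """Read and cross-validate the three input tables."""
    frame = read_sample_table(sample_path)
    counts = read_count_matrix(count_path)
    counts.check_samples(frame)
    hits = None
    if ko_path is not None:
        hits = read_ko_hits(ko_path)
        unknown = set(hits.data["sample_id"]) - set(frame.sample_ids)
        if unknown:
            raise FormatError(
                f"{ko_path}: unknown sample id(s) {sorted(unknown)}"
            )
    return counts, frame, hits


def write_sample_table(frame: SampleFrame, path: str | os.PathLike) -> None:
    df = frame.data.copy()
    ordered = [c for c in SAMPLE_COLUMNS if c in df.columns] + frame.env_columns
    df = df[ordered]
    df.to_csv(path, sep="\t", na_rep=_NA)


def write_count_matrix(counts: BinCountMatrix, path: str | os.PathLike) -> None:
    out = pd.DataFrame(index=counts.total.index)
    out.index.name = "taxon_id"
    for sid in counts.samples:
        out[f"{sid}.total"] = counts.total[sid]
        out[f"{sid}.rp"] = counts.rp[sid]
    out.to_csv(path, sep="\t")


def write_ko_hits(hits: KOHitTable, path: str | os.PathLike) -> None:
    hits.data[list(KOHitTable.REQUIRED)].to_csv(path, sep="\t", index=False)


def write_dataset(
    counts: BinCountMatrix,
    frame: SampleFrame,
    hits: KOHitTable | None,
    count_path: str | os.PathLike,
    sample_path: str | os.PathLike,
    ko_path: str | os.PathLike | None = None,
) -> None:
    write_count_matrix(counts, count_path)
    write_sample_table(frame, sample_path)
    if hits is not None and ko_path is not None:
        write_ko_hits(hits, ko_path)


def write_activity_table(
    acts: ActivityMatrix,
    path: str | os.PathLike,
    rp_per_L: pd.DataFrame | None = None,
    header_comment: str | None = None,
) -> None:
    """Long-form activity table: taxon, sample, pct_rp, ci_low, ci_high[, rp_per_L]."""
    rows = acts.pct_rp.stack(future_stack=True).rename("pct_rp").reset_index()
    rows.columns = ["taxon_id", "sample_id", "pct_rp"]
    for name, mat in (("ci_low", acts.ci_low), ("ci_high", acts.ci_high)):
        if mat is not None:
            rows[name] = mat.stack(future_stack=True).to_numpy()
    if rp_per_L is not None:
        rows["rp_per_L"] = rp_per_L.stack(future_stack=True).to_numpy()
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        rows.to_csv(fh, sep="\t", index=False, na_rep=_NA, float_format="%.10g")


def read_activity_table(path: str | os.PathLike) -> tuple[ActivityMatrix, pd.DataFrame | None]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[_NA], keep_default_na=False,
                     dtype={"taxon_id": str, "sample_id": str}, float_precision="round_trip")
    taxa = df["taxon_id"].drop_duplicates().tolist()
    samples = df["sample_id"].drop_duplicates().tolist()

    def pivot(col: str) -> pd.DataFrame:
        wide = df.pivot(index="taxon_id", columns="sample_id", values=col)
        wide = wide.loc[taxa, samples].astype(float)
        wide.index.name, wide.columns.name = "taxon_id", "sample_id"
        return wide

    acts = ActivityMatrix(
        pct_rp=pivot("pct_rp"),
        ci_low=pivot("ci_low") if "ci_low" in df.columns else None,
        ci_high=pivot("ci_high") if "ci_high" in df.columns else None,
    )
    rp = pivot("rp_per_L") if "rp_per_L" in df.columns else None
    return acts, rp


def write_table(df: pd.DataFrame, path: str | os.PathLike, header_comment: str | None = None,
                index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=_NA, float_format="%.10g")
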