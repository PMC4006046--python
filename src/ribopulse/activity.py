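"""The %RP activity index, bootstrap confidence intervals, and absolute
RP transcript concentrations from internal-standard normalization.

%RP — the percentage of a taxon bin's annotated reads that are ribosomal
protein transcripts — serves as a relative, within-taxon proxy for in-situ
activity: cells couple translation machinery synthesis to growth, so a bin's
temporal %RP profile tracks the activity of the population behind it.

The internal standard converts relative counts to absolute units: a known
number of artificial mRNA copies is spiked into each sample before
extraction, and the ratio of copies added to standard reads recovered scales
any read count to transcripts, which the filtered volume turns into
transcripts per litre.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import ActivityMatrix, BinCountMatrix, SampleFrame

logger = logging.getLogger(__name__)

__all__ = ["compute_pct_rp", "bootstrap_ci", "compute_rp_per_L"]


def compute_pct_rp(counts: BinCountMatrix) -> ActivityMatrix:
    """%RP = 100 x rp_reads / total_reads per taxon-sample cell.

    Cells with zero total reads are undefined (NaN), never 0: a bin that
    recruited no reads carries no activity information.
    """
    total = counts.total.to_numpy(dtype=float)
    rp = counts.rp.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * rp / np.where(total > 0, total, 1.0), np.nan)
    return ActivityMatrix(
        pct_rp=pd.DataFrame(pct, index=counts.total.index, columns=counts.total.columns)
    )


def bootstrap_ci(
    counts: BinCountMatrix,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
) -> ActivityMatrix:
    """Percentile bootstrap CI of %RP per cell.

    The resampling unit is the read: drawing ``total`` reads with replacement
    from a bin in which ``rp`` were RP-annotated is equivalent to drawing
    ``rp* ~ Binomial(total, rp/total)``, so each replicate %RP is
    ``100 rp*/total`` and the CI is the percentile interval over ``n_boot``
    replicates. Undefined cells (zero total reads) get undefined bounds.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    total = counts.total.to_numpy()
    rp = counts.rp.to_numpy()
    alpha = (1.0 - level) / 2.0

    lo = np.full(total.shape, np.nan)
    hi = np.full(total.shape, np.nan)
    defined = total > 0
    p = np.zeros(total.shape, dtype=float)
    p[defined] = rp[defined] / total[defined]
    # one vectorized binomial draw per bootstrap replicate
    draws = rng.binomial(
        np.broadcast_to(np.where(defined, total, 1), (n_boot,) + total.shape),
        np.broadcast_to(p, (n_boot,) + total.shape),
    )
    pct = 100.0 * draws / np.where(defined, total, 1)[None, :, :]
    lo_q, hi_q = np.quantile(pct, [alpha, 1.0 - alpha], axis=0)
    lo[defined] = lo_q[defined]
    hi[defined] = hi_q[defined]

    base = compute_pct_rp(counts)
    idx, cols = counts.total.index, counts.total.columns
    # percentile interval of a discrete resample can sit strictly inside the
    # point estimate only through quantile interpolation; clip to bracket it
    point = base.pct_rp.to_numpy()
    lo = np.where(defined, np.minimum(lo, point), np.nan)
    hi = np.where(defined, np.maximum(hi, point), np.nan)
    return ActivityMatrix(
        pct_rp=base.pct_rp,
        ci_low=pd.DataFrame(lo, index=idx, columns=cols),
        ci_high=pd.DataFrame(hi, index=idx, columns=cols),
    )


def compute_rp_per_L(counts: BinCountMatrix, frame: SampleFrame) -> pd.DataFrame:
    """Absolute RP transcripts per litre via the internal standard.

    rp_per_L[t, s] = rp_reads[t, s] x (copies_added[s] / standard_reads[s])
    / volume_L[s].  Samples whose standard was not recovered
    (standard_reads = 0) cannot be normalized; their column is undefined and
    a warning is logged.  The statistic is invariant to sequencing-depth
    changes that scale rp_reads and standard_reads together — the defining
    property of spike-in normalization.
    """
    df = frame.data.loc[counts.samples]
    std_reads = df["standard_reads"].to_numpy(dtype=float)
    copies = df["standard_copies"].to_numpy(dtype=float)
    vol = df["volume_L"].to_numpy(dtype=float)

    bad = std_reads == 0
    if bad.any():
        logger.warning(
            "no internal-standard reads recovered in sample(s) %s; "
            "rp_per_L undefined there",
            list(df.index[bad]),
        )
    scale = np.where(bad, np.nan, copies / np.where(bad, 1.0, std_reads) / vol)
    out = counts.rp.to_numpy(dtype=float) * scale[None, :]
    return pd.DataFrame(out, index=counts.rp.index, columns=counts.rp.columns)
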