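"""Permutation tests for diel and seasonal differences in per-taxon activity.

Two tests, both label permutations of a per-sample statistic (%RP or
absolute RP transcripts per litre) for one taxon:

* **day-night test** — observed statistic is the mean day-minus-night
  difference over complete day-night pairs. Under the null the participating
  samples are pooled and randomly repartitioned into pairs, one member of
  each new pair arbitrarily designated "day". Randomly re-pairing 2m values
  and designating one member of each pair is equivalent to drawing a
  uniformly random m-subset as the "day" set, which is how the null is
  sampled here.
* **seasonal test** — observed statistic is the between-season sum of
  squares Σ_g n_g (mean_g − grand_mean)²; the null permutes sample-to-season
  labels preserving group sizes.

p-values use the add-one convention p = (b + 1)/(n_iter + 1) with ties
counted as exceedances; the raw-proportion rule is available via
``add_one=False``. The day-night test is two-sided on |mean difference| by
default (day- and night-enriched calls are symmetric); ``tail="greater"``
restores the one-sided rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import SEASONS, ActivityMatrix, SampleFrame

logger = logging.getLogger(__name__)

__all__ = ["TemporalTestResult", "day_night_test", "seasonal_test", "run_temporal_battery"]

# relative tolerance when counting null draws at least as extreme as the
# observed statistic: permutations reproducing the observed partition must
# count as ties despite float summation-order jitter
_TIE_RTOL = 1e-9


@dataclass
class TemporalTestResult:
    taxon_id: str
    test: str  # "day_night" | "seasonal"
    metric: str  # "pct_rp" | "rp_per_L"
    statistic: float
    p_value: float
    n_iter: int
    n_used: int  # pairs (day_night) or samples (seasonal) entering the test
    direction: str  # "day_enriched" | "night_enriched" | "none"
    testable: bool


def _p_from_exceedances(b: int, n_iter: int, add_one: bool) -> float:
    return (b + 1) / (n_iter + 1) if add_one else b / n_iter


def day_night_test(
    values: pd.Series,
    frame: SampleFrame,
    n_iter: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    tail: str = "two-sided",
    add_one: bool = True,
    null: str = "repartition",
    alpha: float = 0.05,
    taxon_id: str = "",
    metric: str = "pct_rp",
) -> TemporalTestResult:
    """Paired day-night permutation test for one taxon.

    ``values`` is indexed by sample id. Only complete pairs in which both
    members have a defined value participate; unpaired samples are ignored.
    With fewer than two usable pairs the result is flagged untestable
    (p = NaN) rather than raising.
    """
    if tail not in ("two-sided", "greater"):
        raise ValueError(f"unknown tail {tail!r}")
    if null not in ("repartition", "signflip"):
        raise ValueError(f"unknown null {null!r}")
    pairs = frame.pairs()
    day_v = values.reindex(pairs["day"]).to_numpy(dtype=float)
    night_v = values.reindex(pairs["night"]).to_numpy(dtype=float)
    ok = ~np.isnan(day_v) & ~np.isnan(night_v)
    day_v, night_v = day_v[ok], night_v[ok]
    m = len(day_v)

    untestable = TemporalTestResult(
        taxon_id, "day_night", metric, np.nan, np.nan, n_iter, m, "none", False
    )
    if m < 2:
        return untestable

    obs = float(np.mean(day_v - night_v))
    rng = np.random.default_rng(seed)
    if null == "repartition":
        pooled = np.concatenate([day_v, night_v])
        mat = np.tile(pooled, (n_iter, 1))
        mat = rng.permuted(mat, axis=1)
        # random re-pairing with random day designation == uniform m-subset
        null_stats = (2.0 * mat[:, :m].sum(axis=1) - pooled.sum()) / m
    else:  # signflip: keep original pairs, randomize which member is "day"
        diffs = day_v - night_v
        signs = rng.integers(0, 2, size=(n_iter, m)) * 2 - 1
        null_stats = (signs * diffs).mean(axis=1)

    scale = max(1.0, abs(obs))
    if tail == "two-sided":
        b = int(np.sum(np.abs(null_stats) >= abs(obs) - _TIE_RTOL * scale))
    else:
        b = int(np.sum(null_stats >= obs - _TIE_RTOL * scale))
    p = _p_from_exceedances(b, n_iter, add_one)

    direction = "none"
    if p < alpha and obs != 0.0:
        direction = "day_enriched" if obs > 0 else "night_enriched"
    return TemporalTestResult(
        taxon_id, "day_night", metric, obs, p, n_iter, m, direction, True
    )


def _between_group_ss(values: np.ndarray, group_ix: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss = 0.0
    for g in range(n_groups):
        member = values[group_ix == g]
        ss += len(member) * (member.mean() - grand) ** 2
    return float(ss)


def seasonal_test(
    values: pd.Series,
    frame: SampleFrame,
    n_iter: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    add_one: bool = True,
    alpha: float = 0.05,
    taxon_id: str = "",
    metric: str = "pct_rp",
) -> TemporalTestResult:
    """Between-season sum-of-squares permutation test for one taxon.

    Samples with undefined values are dropped; a season left with no defined
    values is dropped with a warning. Requires at least two seasons with
    data, else the result is flagged untestable.
    """
    season = frame.data["season"].reindex(values.index)
    vals = values.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    vals, season = vals[ok], season[ok]

    present = [s for s in SEASONS if (season == s).any()]
    dropped = [s for s in SEASONS if s in set(frame.data["season"]) and s not in present]
    if dropped:
        logger.warning("season(s) %s have no defined values; dropped", dropped)
    if len(present) < 2:
        return TemporalTestResult(
            taxon_id, "seasonal", metric, np.nan, np.nan, n_iter, len(vals), "none", False
        )

    group_ix = np.array([present.index(s) for s in season])
    n_g = len(present)
    obs = _between_group_ss(vals, group_ix, n_g)

    rng = np.random.default_rng(seed)
    mat = rng.permuted(np.tile(vals, (n_iter, 1)), axis=1)
    # group means via one matmul: indicator matrix weighted by 1/group size
    sizes = np.bincount(group_ix, minlength=n_g).astype(float)
    G = np.zeros((len(vals), n_g))
    G[np.arange(len(vals)), group_ix] = 1.0
    means = mat @ (G / sizes)
    grand = vals.mean()
    null_ss = ((means - grand) ** 2 * sizes).sum(axis=1)

    scale = max(1.0, abs(obs))
    b = int(np.sum(null_ss >= obs - _TIE_RTOL * scale))
    p = _p_from_exceedances(b, n_iter, add_one)
    return TemporalTestResult(
        taxon_id, "seasonal", metric, obs, p, n_iter, len(vals), "none", True
    )


def run_temporal_battery(
    acts: ActivityMatrix,
    abs_m: pd.DataFrame | None,
    frame: SampleFrame,
    n_iter: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    alpha: float = 0.05,
    tail: str = "two-sided",
    add_one: bool = True,
    null: str = "repartition",
) -> tuple[pd.DataFrame, dict]:
    """Both tests, per taxon, on %RP and (optionally) RP transcripts per litre.

    Returns the long result table and a summary dict with per-metric counts
    of day-/night-enriched and seasonally variable taxa, plus the
    cross-metric concordance of day-night calls (how many taxa significant
    on the relative index stay significant on the absolute one).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    metrics: list[tuple[str, pd.DataFrame]] = [("pct_rp", acts.pct_rp)]
    if abs_m is not None:
        metrics.append(("rp_per_L", abs_m))

    results: list[TemporalTestResult] = []
    children = ss.spawn(len(metrics) * 2)
    for mi, (metric, mat) in enumerate(metrics):
        dn_rng = np.random.default_rng(children[2 * mi])
        se_rng = np.random.default_rng(children[2 * mi + 1])
        for taxon in mat.index:
            row = mat.loc[taxon]
            results.append(
                day_night_test(row, frame, n_iter, dn_rng, tail, add_one, null,
                               alpha, taxon, metric)
            )
            results.append(
                seasonal_test(row, frame, n_iter, se_rng, add_one, alpha, taxon, metric)
            )

    table = pd.DataFrame([vars(r) for r in results])
    summary: dict = {"alpha": alpha}
    sig_dn: dict[str, set] = {}
    for metric, _ in metrics:
        sub = table[(table["metric"] == metric) & (table["test"] == "day_night") & table["testable"]]
        sig = sub[sub["p_value"] < alpha]
        sig_dn[metric] = set(sig["taxon_id"])
        summary[f"{metric}_day_enriched"] = int((sig["direction"] == "day_enriched").sum())
        summary[f"{metric}_night_enriched"] = int((sig["direction"] == "night_enriched").sum())
        ssub = table[(table["metric"] == metric) & (table["test"] == "seasonal") & table["testable"]]
        summary[f"{metric}_seasonal_significant"] = int((ssub["p_value"] < alpha).sum())
    if abs_m is not None:
        both = sig_dn["pct_rp"] & sig_dn["rp_per_L"]
        summary["day_night_sig_pct_rp"] = len(sig_dn["pct_rp"])
        summary["day_night_sig_rp_per_L"] = len(sig_dn["rp_per_L"])
        summary["day_night_sig_both"] = len(both)
    return table, summary
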