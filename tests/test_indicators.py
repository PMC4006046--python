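"""Indicator-value arithmetic against hand computations, permutation
significance against exhaustive enumeration, the day/night variant, and
pathway enrichment accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ribopulse import (
    ClusterAssignment,
    KOHitTable,
    compute_indicator_values,
    day_night_indicator,
    indicator_significance,
    pathway_enrichment,
)

from conftest import make_sample_frame


def hit_table(records):
    """records: (taxon, ko, pathways, sample, hits)"""
    return KOHitTable(
        pd.DataFrame(records, columns=["taxon_id", "ko_id", "pathway_ids", "sample_id", "hits"])
    )


def assignment(mapping):
    return ClusterAssignment(
        labels=pd.Series(mapping, name="cluster").rename_axis("taxon_id")
    )


def detections(taxon, ko, samples, hits=1, path=""):
    return [(taxon, ko, path, s, hits) for s in samples]


SAMPLES = [f"s{i:02d}" for i in range(20)]


def test_perfect_indicator_is_100_exactly():
    clusters = assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    recs = detections("a1", "K1", SAMPLES) + detections("a2", "K1", SAMPLES)
    table = compute_indicator_values(hit_table(recs), clusters, n_samples=20)
    row = table[(table.ko_id == "K1") & (table.cluster == 1)].iloc[0]
    assert row.specificity == 1.0
    assert row.fidelity == 1.0
    assert row.iv == 100.0
    other = table[(table.ko_id == "K1") & (table.cluster == 2)].iloc[0]
    assert other.iv == 0.0


def test_hand_computed_partial_indicator():
    """Cluster A: 2 taxa detected in 10 of 20 samples each; cluster B: 2 taxa
    in 5 samples each -> N_A=10, N_B=5, spec_A=2/3, fid_A=0.5, IV_A=100/3."""
    clusters = assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    recs = (
        detections("a1", "K1", SAMPLES[:10])
        + detections("a2", "K1", SAMPLES[:10])
        + detections("b1", "K1", SAMPLES[:5])
        + detections("b2", "K1", SAMPLES[:5])
    )
    table = compute_indicator_values(hit_table(recs), clusters, n_samples=20)
    a = table[(table.ko_id == "K1") & (table.cluster == 1)].iloc[0]
    b = table[(table.ko_id == "K1") & (table.cluster == 2)].iloc[0]
    assert a.normalized_hits == pytest.approx(10.0)
    assert b.normalized_hits == pytest.approx(5.0)
    assert a.specificity == pytest.approx(2 / 3)
    assert a.fidelity == pytest.approx(0.5)
    assert a.iv == pytest.approx(100 * (2 / 3) * 0.5)
    # specificity sums to one across clusters for any KO with hits
    assert a.specificity + b.specificity == pytest.approx(1.0)


def test_multiple_genes_inflate_hits_not_fidelity():
    """A taxon with 3 genes binning to one KO in one sample raises the
    normalized hit count by 3 but the fidelity numerator by only 1."""
    clusters = assignment({"a1": 1, "b1": 2})
    single = hit_table(detections("a1", "K1", ["s00"], hits=1))
    triple = hit_table(detections("a1", "K1", ["s00"], hits=3))
    t1 = compute_indicator_values(single, clusters, n_samples=20)
    t3 = compute_indicator_values(triple, clusters, n_samples=20)
    a1 = t1[(t1.cluster == 1)].iloc[0]
    a3 = t3[(t3.cluster == 1)].iloc[0]
    assert a3.normalized_hits == 3 * a1.normalized_hits
    assert a3.fidelity == a1.fidelity
    assert a3.specificity == a1.specificity == 1.0


def test_zero_hit_ko_gets_zero_iv():
    clusters = assignment({"a1": 1, "b1": 2})
    recs = detections("a1", "K1", ["s00"]) + [("b1", "K2", "", "s00", 0)]
    table = compute_indicator_values(hit_table(recs), clusters, n_samples=20)
    k2 = table[table.ko_id == "K2"]
    assert (k2.iv == 0.0).all()
    assert k2.specificity.isna().all()


def iv_for_labels(det_by_taxon, labels, n_samples):
    """Oracle IV of one KO for cluster ids 1..k under a given labeling.

    det_by_taxon: taxon -> number of samples with detection (1 hit each).
    """
    taxa = list(det_by_taxon)
    k = max(labels.values())
    ivs = {}
    for c in range(1, k + 1):
        members = [t for t in taxa if labels[t] == c]
        H = sum(det_by_taxon[t] for t in members)
        N = H / len(members)
        tot = sum(
            sum(det_by_taxon[t] for t in taxa if labels[t] == cc)
            / len([t for t in taxa if labels[t] == cc])
            for cc in range(1, k + 1)
        )
        spec = N / tot if tot > 0 else 0.0
        fid = H / (len(members) * n_samples)
        ivs[c] = 100 * spec * fid
    return ivs


@pytest.mark.parametrize(
    "det_counts",
    [
        {"a1": 20, "a2": 20, "b1": 0, "b2": 0},   # perfect indicator
        {"a1": 12, "a2": 8, "b1": 3, "b2": 1},    # graded signal
        {"a1": 6, "a2": 6, "b1": 6, "b2": 6},     # exchangeable
    ],
)
def test_significance_matches_enumeration(det_counts):
    """Permutation p for a 2+2-cluster toy matches exhaustive enumeration of
    all taxa-to-cluster reassignments."""
    taxa = list(det_counts)
    clusters = assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    recs = []
    for t, n in det_counts.items():
        recs += detections(t, "K1", SAMPLES[:n])
    n_iter = 4000
    table = indicator_significance(
        hit_table(recs), clusters, n_samples=20, n_iter=n_iter, seed=21, add_one=False
    )
    obs_labels = {"a1": 1, "a2": 1, "b1": 2, "b2": 2}
    obs_iv = iv_for_labels(det_counts, obs_labels, 20)
    for c in (1, 2):
        exceed = 0
        perms = list(itertools.permutations(taxa))
        for perm in perms:
            labels = {t: obs_labels[o] for t, o in zip(perm, taxa)}
            null_iv = iv_for_labels(det_counts, labels, 20)
            if null_iv[c] >= obs_iv[c] - 1e-9:
                exceed += 1
        p_exact = exceed / len(perms)
        p_mc = table[(table.ko_id == "K1") & (table.cluster == c)].p_value.iloc[0]
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_iter)
        assert abs(p_mc - p_exact) <= 3 * se


def test_significance_three_clusters_enumeration():
    det_counts = {"a": 15, "b": 12, "c": 2, "d": 1, "e": 0, "f": 5}
    labels0 = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3}
    clusters = assignment(labels0)
    recs = []
    for t, n in det_counts.items():
        recs += detections(t, "K1", SAMPLES[:n])
    n_iter = 4000
    table = indicator_significance(
        hit_table(recs), clusters, n_samples=20, n_iter=n_iter, seed=33, add_one=False
    )
    taxa = list(det_counts)
    obs_iv = iv_for_labels(det_counts, labels0, 20)
    for c in (1, 2, 3):
        exceed, total = 0, 0
        for perm in itertools.permutations(taxa):
            labels = {t: labels0[o] for t, o in zip(perm, taxa)}
            total += 1
            if iv_for_labels(det_counts, labels, 20)[c] >= obs_iv[c] - 1e-9:
                exceed += 1
        p_exact = exceed / total
        p_mc = table[(table.ko_id == "K1") & (table.cluster == c)].p_value.iloc[0]
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_iter)
        assert abs(p_mc - p_exact) <= 3 * se


def test_identical_expression_gives_p_one():
    clusters = assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    recs = []
    for t in ("a1", "a2", "b1", "b2"):
        recs += detections(t, "K1", SAMPLES[:7])
    table = indicator_significance(hit_table(recs), clusters, n_iter=500, seed=2)
    assert (table[table.ko_id == "K1"].p_value == 1.0).all()


def test_significance_determinism():
    clusters = assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    recs = detections("a1", "K1", SAMPLES[:9]) + detections("b1", "K1", SAMPLES[:2])
    t1 = indicator_significance(hit_table(recs), clusters, n_iter=300, seed=4)
    t2 = indicator_significance(hit_table(recs), clusters, n_iter=300, seed=4)
    pd.testing.assert_frame_equal(t1, t2)


def test_day_night_indicator_one_sided_expression():
    frame = make_sample_frame(seasons=("fall", "winter"))  # 2 day + 2 night
    day = [s for s in frame.sample_ids if "day" in s]
    night = [s for s in frame.sample_ids if "night" in s]
    clusters = assignment({"a1": 1, "a2": 1})
    recs = detections("a1", "KD", day) + detections("a2", "KD", day)
    recs += detections("a1", "KB", day + night) + detections("a2", "KB", day + night)
    table = day_night_indicator(hit_table(recs), clusters, 1, frame, n_iter=2000, seed=6)
    kd_day = table[(table.ko_id == "KD") & (table.group == "day")].iloc[0]
    kd_night = table[(table.ko_id == "KD") & (table.group == "night")].iloc[0]
    assert kd_day.iv == 100.0 and kd_night.iv == 0.0
    kb = table[table.ko_id == "KB"]
    assert (kb.p_value == 1.0).all()  # balanced detection: exchangeable null


def test_day_night_indicator_matches_enumeration():
    frame = make_sample_frame(seasons=("fall", "winter"))
    sids = frame.sample_ids
    day = [s for s in sids if "day" in s]
    clusters = assignment({"a1": 1})
    # KO detected in both day samples and one night sample
    det_samples = day + [s for s in sids if "night" in s][:1]
    recs = detections("a1", "K1", det_samples)
    n_iter = 4000
    table = day_night_indicator(
        hit_table(recs), clusters, 1, frame, n_iter=n_iter, seed=11, add_one=False
    )

    det = {s: (1 if s in det_samples else 0) for s in sids}
    photo = {s: ("day" if "day" in s else "night") for s in sids}

    def iv_groups(perm):
        lab = {s: photo[o] for s, o in zip(perm, sids)}
        out = {}
        for g in ("day", "night"):
            members = [s for s in sids if lab[s] == g]
            H = sum(det[s] for s in members)
            N = H / len(members)
            tot = sum(
                sum(det[s] for s in sids if lab[s] == gg)
                / len([s for s in sids if lab[s] == gg])
                for gg in ("day", "night")
            )
            spec = N / tot if tot else 0.0
            fid = H / (len(members) * 1)  # one taxon in the cluster
            out[g] = 100 * spec * fid
        return out

    obs = iv_groups(sids)
    for g in ("day", "night"):
        perms = list(itertools.permutations(sids))
        exceed = sum(iv_groups(p)[g] >= obs[g] - 1e-9 for p in perms)
        p_exact = exceed / len(perms)
        p_mc = table[table.group == g].p_value.iloc[0]
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_iter)
        assert abs(p_mc - p_exact) <= 3 * se


def test_day_night_indicator_requires_both_photoperiods():
    frame = make_sample_frame(seasons=("fall",))
    df = frame.data[frame.data["photoperiod"] == "day"].copy()
    df["pair_id"] = np.nan
    from ribopulse import SampleFrame

    day_only = SampleFrame(df)
    clusters = assignment({"a1": 1})
    recs = detections("a1", "K1", list(df.index))
    with pytest.raises(ValueError, match="day and night"):
        day_night_indicator(hit_table(recs), clusters, 1, day_only, n_iter=10, seed=0)


def test_pathway_enrichment_extremes_and_accounting():
    rng = np.random.default_rng(0)
    clusters = assignment({f"t{i}": 1 + i % 2 for i in range(8)})
    members1 = [t for t, c in clusters.labels.items() if c == 1]
    recs = []
    # 4 indicator KOs of cluster 1, all in pathway pwA
    for j in range(4):
        for t in members1:
            recs += detections(t, f"KI{j}", SAMPLES[:18], path="pwA")
    # 30 background KOs spread over 10 pathways, expressed everywhere
    for j in range(30):
        for t in clusters.labels.index:
            recs += detections(t, f"KB{j}", SAMPLES[:10], path=f"pw{j % 10}")
    hits = hit_table(recs)
    sig = indicator_significance(hits, clusters, n_samples=20, n_iter=400, seed=9)
    enr = pathway_enrichment(sig, hits, clusters, n_iter=1000, seed=10)
    top = enr[(enr.pathway_id == "pwA") & (enr.cluster == 1)].iloc[0]
    assert top.n_significant_indicator_kos == 4
    assert top.p_value <= 0.05  # concentrated in one small pathway
    # counts bounded by pathway universe size
    assert (enr.n_significant_indicator_kos <= enr.n_universe_kos).all()
    # accounting: per-cluster sum over pathways >= significant KOs with >=1 pathway
    for c, grp in enr.groupby("cluster"):
        sig_c = sig[(sig.cluster == c) & (sig.p_value < 0.05)]
        annotated = [k for k in sig_c.ko_id.unique() if hits.pathway_map().get(k)]
        assert grp.n_significant_indicator_kos.sum() >= len(annotated)
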