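"""Correlation distance, complete-linkage agglomeration versus a brute-force
oracle, dendrogram export, and rank-ordered profiles."""

import numpy as np
import pandas as pd
import pytest

from ribopulse import (
    ActivityMatrix,
    cluster_taxa,
    correlation_distance,
    linkage_to_newick,
    rank_order_profiles,
    silhouette_profile,
)

from conftest import make_sample_frame


def acts_from(profiles: dict) -> ActivityMatrix:
    df = pd.DataFrame(profiles).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ActivityMatrix(pct_rp=df)


def test_distance_formula_endpoints():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    acts = acts_from({
        "up": base,
        "up2": 2 * base + 1,          # r = +1
        "down": 10 - base,            # r = -1 vs up
        "orth": np.array([2.0, 0.0, 0.0, 2.0]),  # r = 0 vs up
    })
    d = correlation_distance(acts, min_defined=3)
    assert d.loc["up", "up2"] == pytest.approx(0.0)
    assert d.loc["up", "down"] == pytest.approx(1.0)
    assert d.loc["up", "orth"] == pytest.approx(0.5)
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
    assert ((d.to_numpy() >= -1e-12) & (d.to_numpy() <= 1 + 1e-12)).all()


def test_zero_variance_taxon_excluded(caplog):
    import logging

    acts = acts_from({"a": [1, 2, 3, 4], "b": [2, 3, 4, 5], "flat": [3, 3, 3, 3]})
    with caplog.at_level(logging.WARNING):
        d = correlation_distance(acts)
    assert list(d.index) == ["a", "b"]
    assert any("flat" in r.message for r in caplog.records)


def test_affine_invariance_of_clustering():
    rng = np.random.default_rng(0)
    profiles = {f"t{i}": rng.uniform(1, 15, 10) for i in range(12)}
    d1 = correlation_distance(acts_from(profiles))
    scaled = {k: 5.0 * v + 10.0 for k, v in profiles.items()}
    d2 = correlation_distance(acts_from(scaled))
    assert np.allclose(d1.to_numpy(), d2.to_numpy())
    a1 = cluster_taxa(d1, 3).labels
    a2 = cluster_taxa(d2, 3).labels
    assert (a1 == a2).all()


def test_two_block_recovery_and_degenerate_cut():
    base = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
    profiles = {}
    for i in range(4):
        profiles[f"a{i}"] = base * (i + 1)        # within-block r = 1
        profiles[f"b{i}"] = -base * (i + 1) + 20  # anti-correlated block
    acts = acts_from(profiles)
    d = correlation_distance(acts)
    two = cluster_taxa(d, 2)
    labels = two.labels
    assert labels[[f"a{i}" for i in range(4)]].nunique() == 1
    assert labels[[f"b{i}" for i in range(4)]].nunique() == 1
    assert labels["a0"] != labels["b0"]

    everyone_alone = cluster_taxa(d, len(profiles))
    assert everyone_alone.labels.nunique() == len(profiles)


def brute_force_complete_linkage_heights(D: np.ndarray) -> list[float]:
    """Oracle: repeatedly merge the pair of clusters with the smallest
    maximum inter-cluster distance, recomputed from scratch each step."""
    clusters = [[i] for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


@pytest.mark.parametrize("seed", range(10))
def test_linkage_heights_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = 8
    profiles = {f"t{i}": rng.uniform(1, 15, 6) for i in range(n)}
    d = correlation_distance(acts_from(profiles))
    Z = cluster_taxa(d, 2).linkage
    oracle = brute_force_complete_linkage_heights(d.to_numpy())
    assert sorted(np.round(Z[:, 2], 12)) == sorted(np.round(oracle, 12))


def test_linkage_heights_monotone(default_sim):
    from ribopulse import compute_pct_rp

    _, counts, _, _, _ = default_sim
    d = correlation_distance(compute_pct_rp(counts))
    Z = cluster_taxa(d, 7).linkage
    assert (np.diff(Z[:, 2]) >= -1e-12).all()


def test_newick_export_roundtrip():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(3)
    profiles = {f"t{i}": rng.uniform(1, 15, 5) for i in range(6)}
    d = correlation_distance(acts_from(profiles))
    assign = cluster_taxa(d, 2)
    nwk = linkage_to_newick(assign.linkage, assign.taxa)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert leaves == set(profiles)
    root_height = assign.linkage[-1, 2]
    for leaf in tree.leaf_node_iter():
        assert leaf.distance_from_root() == pytest.approx(root_height, rel=1e-6)


def test_rank_order_profiles_properties():
    frame = make_sample_frame(seasons=("fall", "winter"))
    sids = frame.sample_ids
    pct = pd.DataFrame(
        {
            sids[0]: [1.0, 2.0],
            sids[1]: [2.0, 2.0],
            sids[2]: [3.0, 2.0],
            sids[3]: [4.0, 2.0],
        },
        index=["inc", "tied"],
    )
    ranked = rank_order_profiles(ActivityMatrix(pct_rp=pct), frame)
    inc = ranked[ranked.taxon_id == "inc"].sort_values("rank")
    assert list(inc.sample_id) == sids  # strictly increasing input keeps order
    tied = ranked[ranked.taxon_id == "tied"].sort_values("rank")
    assert list(tied.sample_id) == sorted(sids)  # ties break by sample id
    for taxon in ("inc", "tied"):
        sub = ranked[ranked.taxon_id == taxon]
        assert sorted(sub.sample_id) == sorted(sids)  # a permutation of samples
        assert set(sub.season) <= {"fall", "winter"}


def test_silhouette_profile_covers_k_range(small_sim):
    from ribopulse import compute_pct_rp

    _, counts, _, _, _ = small_sim
    d = correlation_distance(compute_pct_rp(counts))
    prof = silhouette_profile(d, range(2, 6))
    assert list(prof["k"]) == [2, 3, 4, 5]
    assert prof["mean_silhouette"].between(-1, 1).all()


from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    arrays(np.float64, shape=(5, 6), elements=st.floats(0.5, 99.5)),
)
def test_distance_and_ranking_properties(mat):
    """For any %RP matrix: d is a dissimilarity with values in [0,1] (on the
    taxa that survive exclusion), and every taxon's rank list is a
    permutation of the samples."""
    frame = make_sample_frame(seasons=("fall", "winter", "spring"))
    taxa = [f"t{i}" for i in range(mat.shape[0])]
    acts = ActivityMatrix(
        pct_rp=pd.DataFrame(mat, index=taxa, columns=frame.sample_ids)
    )
    try:
        d = correlation_distance(acts)
    except ValueError:
        return  # degenerate overlap structure is allowed to be rejected
    arr = d.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0.0)
    assert (arr >= -1e-9).all() and (arr <= 1 + 1e-9).all()

    ranked = rank_order_profiles(acts, frame)
    for taxon in taxa:
        sub = ranked[ranked.taxon_id == taxon]
        assert sorted(sub.sample_id) == sorted(frame.sample_ids)
        assert (sub.sort_values("rank").pct_rp.diff().dropna() >= 0).all()
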