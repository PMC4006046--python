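import numpy as np
import pandas as pd
import pytest

from ribopulse import BinCountMatrix, SampleFrame, SimConfig, simulate
from ribopulse.datamodel import SEASONS


def make_sample_frame(n_pairs_per_season=1, seasons=SEASONS, replicates=(), extra=None):
    """Hand-rolled sample metadata: one day+night pair per season by default."""
    rows = []
    for season in seasons:
        for p in range(1, n_pairs_per_season + 1):
            pid = f"{season}_p{p}"
            for photo in ("day", "night"):
                rows.append(
                    dict(sample_id=f"{pid}_{photo}", season=season, photoperiod=photo,
                         pair_id=pid, replicate_of=np.nan, volume_L=6.0,
                         standard_copies=4.7e10, standard_reads=500)
                )
    for primary in replicates:
        base = next(r for r in rows if r["sample_id"] == primary)
        rep = dict(base)
        rep["sample_id"] = primary + "_rep"
        rep["replicate_of"] = primary
        rep["pair_id"] = np.nan
        rows.append(rep)
    df = pd.DataFrame(rows).set_index("sample_id")
    if extra:
        for k, v in extra.items():
            df[k] = v
    return SampleFrame(df)


def make_counts(taxa, samples, total, rp):
    return BinCountMatrix(
        total=pd.DataFrame(np.asarray(total), index=taxa, columns=samples),
        rp=pd.DataFrame(np.asarray(rp), index=taxa, columns=samples),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic dataset exercising all planted structure."""
    cfg = SimConfig(n_taxa=60, k_clusters=4, n_indicator_kos=3, n_background_kos=20,
                    library_depth_mean=8000, seed=42)
    counts, frame, hits, truth = simulate(cfg)
    return cfg, counts, frame, hits, truth


@pytest.fixture(scope="session")
def default_sim():
    """The full default study design (200 taxa, 7 clusters, 20 samples)."""
    cfg = SimConfig(seed=7)
    counts, frame, hits, truth = simulate(cfg)
    return cfg, counts, frame, hits, truth
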