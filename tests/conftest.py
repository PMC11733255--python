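import numpy as np
import pandas as pd
import pytest

from paleoloss import synthdata
from paleoloss.tables import ASVTable, TaxonTable


@pytest.fixture(scope="session")
def small_record():
    """A modest record with detection heterogeneity and no pulses."""
    cfg = synthdata.SimConfig(
        n_cores=4,
        samples_per_core=28,
        n_true_taxa=80,
        n_noise_asvs=60,
        extra_asv_fraction=0.0,
        seed=3,
    )
    return synthdata.generate_record(cfg)


@pytest.fixture(scope="session")
def strong_record():
    """Strong-signal record: homogeneous high detection, clean communities."""
    cfg = synthdata.SimConfig(
        n_cores=6,
        samples_per_core=42,
        n_true_taxa=100,
        n_noise_asvs=80,
        detection_beta=None,
        detection_prob=0.95,
        seed=7,
    )
    return synthdata.generate_record(cfg)


def toy_asv_table(counts: dict, info_rows: dict) -> ASVTable:
    """Build a small ASVTable from dicts keyed by asv_id."""
    ids = list(counts)
    counts_df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    counts_df = counts_df.loc[ids]
    info = pd.DataFrame.from_dict(info_rows, orient="index").loc[ids]
    info = info.reindex(
        columns=["identity_pct", "taxon_name", "rank", "family", "genus"]
    )
    info["genus"] = info["genus"].fillna("")
    return ASVTable(info, counts_df)


@pytest.fixture
def balanced_toy():
    """Two cores, one sample per slice each, equal depth everywhere.

    With nothing to resample, occupancy must be identical across
    iterations.
    """
    n_slices = 14
    samples = []
    for core in ("coreA", "coreB"):
        for sl in range(n_slices):
            age = 28000 - sl * 2000 - 1000
            samples.append(
                {
                    "sample_id": f"{core}_{sl}",
                    "core_id": core,
                    "age_cal_bp": age,
                }
            )
    meta = pd.DataFrame(samples).set_index("sample_id")
    rng = np.random.default_rng(0)
    taxa_ids = [f"T{i}" for i in range(6)]
    counts = pd.DataFrame(0, index=taxa_ids, columns=meta.index)
    for j, sid in enumerate(meta.index):
        # fixed per-sample composition with equal total depth 60
        alloc = rng.multinomial(60, np.full(6, 1 / 6))
        counts[sid] = alloc
    info = pd.DataFrame(
        {
            "name": taxa_ids,
            "rank": "genus",
            "family": "Poaceae",
            "genus": taxa_ids,
            "db_flag": [True, True, True, False, False, False],
            "community_id": 0,
            "member_asvs": taxa_ids,
        },
        index=pd.Index(taxa_ids, name="taxon_id"),
    )
    return TaxonTable(info, counts), meta
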