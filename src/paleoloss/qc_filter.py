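"""Replicate-level quality control and ASV filtering.

PCR replicates of a sample are screened for failed amplifications, the
survivors are merged by summing read counts, and the merged table is
filtered to ASVs with at least 90% reference identity that occur in at
least ten samples with at least 100 reads in total. ASVs at exactly 100%
identity are flagged as dbASVs, the rest as non-dbASVs.

A replicate is removed when its total read count is below ``min_reads``
AND it contains fewer than ``min_asvs`` distinct ASVs. Before applying
the count rule, replicates whose composition diverges strongly from
their sample's centroid (Bray-Curtis distance > ``divergence_threshold``)
are flagged for inspection; the flag is diagnostic and recorded, the
removal itself is fully determined by the count rule so that the QC is
numeric and reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .tables import ASVTable, ReplicateMatrix


def flag_divergent_replicates(
    rep: ReplicateMatrix, divergence_threshold: float = 0.9
) -> pd.Series:
    """Bray-Curtis distance of each replicate to its sample centroid > threshold.

    Replicates that are the sole member of their sample are never flagged.
    """
    flags = {}
    meta = rep.meta.loc[list(rep.counts.columns)]
    for sid, group in meta.groupby("sample_id"):
        rids = list(group.index)
        if len(rids) < 2:
            for rid in rids:
                flags[rid] = False
            continue
        for rid in rids:
            # leave-one-out centroid, so one bad replicate cannot mask itself
            others = [r for r in rids if r != rid]
            centroid = rep.counts[others].mean(axis=1).to_numpy()
            vec = rep.counts[rid].to_numpy()
            if vec.sum() == 0 and centroid.sum() == 0:
                flags[rid] = False
            elif vec.sum() == 0 or centroid.sum() == 0:
                flags[rid] = True
            else:
                flags[rid] = bool(braycurtis(vec, centroid) > divergence_threshold)
    return pd.Series(flags).reindex(rep.counts.columns)


def drop_bad_replicates(
    rep: ReplicateMatrix,
    min_reads: int = 100,
    min_asvs: int = 3,
    divergence_threshold: float = 0.9,
) -> ReplicateMatrix:
    """Remove failed replicates; surviving replicates are unchanged.

    Removal rule: total reads < ``min_reads`` AND distinct ASVs <
    ``min_asvs``. Samples that lose all their replicates are excluded
    downstream with a warning.
    """
    divergent = flag_divergent_replicates(rep, divergence_threshold)
    if divergent.any():
        warnings.warn(
            f"{int(divergent.sum())} replicate(s) compositionally divergent "
            f"from their sample centroid (Bray-Curtis > {divergence_threshold})"
        )
    totals = rep.counts.sum(axis=0)
    richness = (rep.counts > 0).sum(axis=0)
    bad = (totals < min_reads) & (richness < min_asvs)
    keep = list(rep.counts.columns[~bad])

    lost_samples = set(rep.sample_ids()) - set(
        rep.meta.loc[keep, "sample_id"]
    )
    if lost_samples:
        warnings.warn(
            f"all replicates removed for sample(s) {sorted(lost_samples)}; "
            "excluded downstream"
        )
    return ReplicateMatrix(rep.info.copy(), rep.counts[keep].copy(), rep.meta.copy())


def merge_replicates(rep: ReplicateMatrix) -> tuple[ASVTable, pd.DataFrame]:
    """Sum surviving replicate counts into sample-level counts.

    Returns the merged ASV table and a sample metadata frame (``core_id``
    per sample) for the samples that retain at least one replicate. Total
    reads are conserved.
    """
    meta = rep.meta.loc[list(rep.counts.columns)]
    sample_of = meta["sample_id"]
    merged = rep.counts.T.groupby(sample_of).sum().T
    # preserve first-appearance sample order
    order = list(dict.fromkeys(sample_of))
    merged = merged[order]
    sample_meta = (
        meta.reset_index()
        .drop_duplicates("sample_id")
        .set_index("sample_id")[["core_id"]]
        .loc[order]
    )
    return ASVTable(rep.info.copy(), merged), sample_meta


def filter_asvs(
    table: ASVTable,
    min_samples: int = 10,
    min_total_reads: int = 100,
    identity_floor: float = 90.0,
) -> ASVTable:
    """Retain ASVs by identity floor, sample occupancy and total reads.

    An ASV survives when identity >= ``identity_floor``, it occurs (>= 1
    read) in at least ``min_samples`` samples, and its total read count is
    at least ``min_total_reads``. An empty result is returned as an empty
    table, not an exception. Filtering is idempotent.
    """
    ident_ok = table.info["identity_pct"] >= identity_floor
    occ_ok = table.occupancy() >= min_samples
    reads_ok = table.counts.sum(axis=1) >= min_total_reads
    keep = table.asv_ids[ident_ok & occ_ok & reads_ok]
    return table.subset(keep)
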