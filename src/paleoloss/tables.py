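"""Core tabular containers shared across the pipeline.

The pipeline operates on three tables:

* an ASV table — amplicon sequence variants (rows) by samples (columns),
  with per-ASV metadata (best-identity to the reference database, the
  assigned name and rank, and lineage fields used when collapsing);
* sample metadata — sample id, sediment core id and calibrated age;
* a taxon table — the result of collapsing ASVs into community-validated
  taxa, carrying the db/non-db flag that drives all loss inference.

All tables round-trip through plain TSV/CSV so that every intermediate of
the analysis is inspectable with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ranks from most to least specific, as used for name matching
RANKS = ("species", "genus", "family")

_RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}

#: per-ASV metadata columns of the TSV dialect, in order
INFO_COLUMNS = ["identity_pct", "taxon_name", "rank", "family", "genus"]


def rank_level(rank: str) -> int:
    """Numeric specificity of a rank (0 = species, 2 = family)."""
    try:
        return _RANK_LEVEL[rank]
    except KeyError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")


def coarser_rank(a: str, b: str) -> str:
    """The less specific of two ranks."""
    return a if rank_level(a) >= rank_level(b) else b


@dataclass
class ASVTable:
    """ASV-by-sample read counts plus per-ASV metadata.

    Parameters
    ----------
    info
        Indexed by ``asv_id``; columns ``identity_pct`` (percent identity
        of the best reference match, in [90, 100]), ``taxon_name``,
        ``rank`` (species/genus/family), ``family`` and ``genus`` (lineage
        of the assignment; ``genus`` empty for family-rank assignments).
    counts
        Indexed by ``asv_id`` (same order as ``info``), one integer column
        per sample.
    """

    info: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.info.index.equals(self.counts.index):
            raise ValueError("info and counts must share the same ASV index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def asv_ids(self) -> pd.Index:
        return self.info.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def db_flag(self) -> pd.Series:
        """True for dbASVs (100% identity to the reference database)."""
        return self.info["identity_pct"] == 100

    @property
    def n_asvs(self) -> int:
        return len(self.info)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def occupancy(self) -> pd.Series:
        """Number of samples in which each ASV has at least one read."""
        return (self.counts > 0).sum(axis=1)

    def subset(self, asv_ids) -> "ASVTable":
        return ASVTable(self.info.loc[asv_ids].copy(), self.counts.loc[asv_ids].copy())

    def to_tsv(self, path) -> None:
        wide = pd.concat([self.info, self.counts], axis=1)
        wide.index.name = "asv_id"
        wide.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ASVTable":
        wide = pd.read_csv(path, sep="\t", index_col="asv_id")
        info = wide[INFO_COLUMNS].copy()
        info["genus"] = info["genus"].fillna("")
        counts = wide.drop(columns=INFO_COLUMNS).astype(int)
        return cls(info, counts)


@dataclass
class ReplicateMatrix:
    """PCR-replicate level counts before merging into samples.

    ``counts`` is ASV x replicate; ``meta`` is indexed by replicate id with
    ``sample_id`` and ``core_id`` columns (every replicate maps to exactly
    one sample). ``info`` carries the same per-ASV metadata as
    :class:`ASVTable`.
    """

    info: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.meta.index):
            missing = set(self.counts.columns) - set(self.meta.index)
            raise ValueError(f"replicates without metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def replicate_ids(self) -> pd.Index:
        return self.counts.columns

    def replicates_of(self, sample_id: str) -> list:
        m = self.meta.loc[list(self.counts.columns)]
        return list(m.index[m["sample_id"] == sample_id])

    def sample_ids(self) -> list:
        return list(dict.fromkeys(self.meta.loc[list(self.counts.columns), "sample_id"]))


@dataclass
class TaxonTable:
    """Community-validated taxa after collapsing ASVs.

    ``info`` is indexed by ``taxon_id`` with columns ``name``, ``rank``,
    ``family``, ``genus``, ``db_flag``, ``community_id`` and
    ``member_asvs`` (semicolon-joined ASV ids); ``counts`` is taxon x
    sample (sum over member ASVs).
    """

    info: pd.DataFrame
    counts: pd.DataFrame

    @property
    def taxon_ids(self) -> pd.Index:
        return self.info.index

    @property
    def db_flag(self) -> pd.Series:
        return self.info["db_flag"]

    @property
    def n_taxa(self) -> int:
        return len(self.info)

    def to_tsv(self, path) -> None:
        wide = pd.concat([self.info, self.counts], axis=1)
        wide.index.name = "taxon_id"
        wide.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TaxonTable":
        wide = pd.read_csv(path, sep="\t", index_col="taxon_id")
        meta_cols = ["name", "rank", "family", "genus", "db_flag", "community_id", "member_asvs"]
        info = wide[meta_cols].copy()
        info["genus"] = info["genus"].fillna("")
        counts = wide.drop(columns=meta_cols).astype(int)
        return cls(info, counts)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    meta = meta.set_index("sample_id")
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
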