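"""Co-occurrence network, community detection, and ASV-to-taxon collapsing.

Lowering the reference-matching threshold to 90% identity recovers
candidate taxa missing from the database, but also admits chimeras and
PCR/sequencing artefacts. Real taxa, unlike artefacts, share spatio-
temporal co-occurrence structure with the communities they belong to. We
therefore build a Spearman co-occurrence network over ASVs (positive rho
above a threshold, Holm-adjusted p below alpha), detect communities by
Louvain modularity optimisation, and within each sufficiently large
community collapse ASVs into taxa:

i.   dbASVs (100% identity) with identical assigned names merge into one
     dbtaxon;
ii.  a non-dbASV merges into a dbtaxon of its community when the names
     match at the coarser of the two ranks (e.g. a family-rank
     "Salicaceae" non-dbASV joins a "Salix" dbtaxon of the same family);
iii. remaining non-dbASVs with identical names merge into one non-dbtaxon.

ASVs outside the reported communities are discarded as putative
artefacts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import ASVTable, TaxonTable, coarser_rank, rank_level

logger = logging.getLogger(__name__)


def correlation_network(
    table: ASVTable, rho_min: float = 0.4, alpha: float = 0.05
) -> nx.Graph:
    """All-pairs Spearman co-occurrence network over ASVs.

    Edges connect ASV pairs with rho > ``rho_min`` and Holm-adjusted
    p < ``alpha`` (the Holm family is all unordered ASV pairs). ASVs with
    constant counts across samples have undefined correlations and stay
    isolated. Every ASV is a node; edges carry ``rho`` and ``p_adj``.
    """
    if table.n_asvs < 2:
        raise ValueError("need at least 2 ASVs")
    if len(table.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    X = table.counts.to_numpy(dtype=float).T  # samples x asvs
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        logger.info(
            "%d constant-count ASV(s) left isolated (undefined correlation)",
            int(constant.sum()),
        )
    g = nx.Graph()
    ids = list(table.asv_ids)
    g.add_nodes_from(ids)
    keep = np.flatnonzero(~constant)
    if len(keep) < 2:
        return g
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.spearmanr(X[:, keep])
    if np.ndim(res.statistic) == 0:  # exactly two variables
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        pval = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        rho, pval = np.asarray(res.statistic), np.asarray(res.pvalue)

    iu = np.triu_indices(len(keep), k=1)
    p_flat = pval[iu]
    ok = np.isfinite(p_flat)
    p_adj = np.full_like(p_flat, np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p_flat[ok], method="holm")[1]

    for (i, j), r, pa in zip(zip(*iu), rho[iu], p_adj):
        if np.isfinite(r) and np.isfinite(pa) and r > rho_min and pa < alpha:
            g.add_edge(ids[keep[i]], ids[keep[j]], rho=float(r), p_adj=float(pa))
    return g


@dataclass
class CommunityPartition:
    """ASV -> community assignment from modularity optimisation.

    ``membership`` covers every networked ASV; ``reported`` lists the
    community ids meeting the minimum-size rule (communities below
    ``min_size`` are retained in ``membership`` for diagnostics but not
    reported).
    """

    membership: dict
    min_size: int = 5

    @property
    def sizes(self) -> pd.Series:
        return pd.Series(self.membership).value_counts().sort_index()

    @property
    def reported(self) -> list[int]:
        s = self.sizes
        return sorted(s.index[s >= self.min_size])

    def members(self, community_id: int) -> list:
        return sorted(a for a, c in self.membership.items() if c == community_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"asv_id": list(self.membership), "community_id": list(self.membership.values())}
        ).set_index("asv_id")
        df["reported"] = df["community_id"].isin(self.reported)
        return df


def detect_communities(
    net: nx.Graph, min_size: int = 5, seed: int = 0, n_restarts: int = 8
) -> CommunityPartition:
    """Louvain modularity-maximising partition of the network.

    Edges are treated as unweighted (resolution 1). The Louvain heuristic
    is run ``n_restarts`` times with seeds derived from ``seed`` and the
    highest-modularity partition is kept, so the result is deterministic
    given ``seed`` and node ordering. Isolated nodes become singleton
    communities (never reported at ``min_size`` > 1). An empty network
    yields an empty partition. Community ids are assigned in decreasing
    size order.
    """
    if net.number_of_nodes() == 0:
        return CommunityPartition({}, min_size=min_size)
    best_q = -np.inf
    comms = None
    for k in range(max(1, n_restarts)):
        cand = nx.community.louvain_communities(
            net, weight=None, resolution=1, seed=seed + k
        )
        q = nx.community.modularity(net, cand, weight=None)
        if q > best_q:
            best_q, comms = q, cand
    comms = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    membership = {}
    for cid, members in enumerate(comms):
        for node in members:
            membership[node] = cid
    return CommunityPartition(membership, min_size=min_size)


def partition_modularity(net: nx.Graph, partition: CommunityPartition) -> float:
    """Unweighted Newman modularity of a partition of the network."""
    groups: dict = {}
    for node, cid in partition.membership.items():
        groups.setdefault(cid, set()).add(node)
    return nx.community.modularity(net, groups.values(), weight=None)


def _name_at_rank(row: pd.Series, rank: str) -> str | None:
    """The ASV's assigned name viewed at ``rank``; None if not resolvable."""
    if rank_level(row["rank"]) > rank_level(rank):
        return None  # own assignment is coarser than the requested rank
    if rank == "family":
        return row["family"] or None
    if rank == "genus":
        return row["genus"] or None
    return row["taxon_name"]


@dataclass
class TaxonRecord:
    taxon_id: str
    name: str
    rank: str
    family: str
    genus: str
    db_flag: bool
    community_id: int
    member_asvs: list


def collapse_to_taxa(partition: CommunityPartition, table: ASVTable) -> TaxonTable:
    """Collapse ASVs of the reported communities into validated taxa.

    Within each reported community, dbASVs with identical names merge
    (rule i), non-dbASVs join a name-matching dbtaxon at the coarser of
    the two ranks (rule ii; ties broken by the candidate dbtaxon's higher
    best identity, then lexicographic name), and leftover non-dbASVs with
    identical names merge (rule iii). ASVs outside reported communities
    are discarded.
    """
    records: list[TaxonRecord] = []
    info = table.info
    db = table.db_flag
    for cid in partition.reported:
        members = [a for a in partition.members(cid) if a in info.index]
        db_members = [a for a in members if db[a]]
        nondb_members = [a for a in members if not db[a]]

        # rule i: identical-name dbASVs -> one dbtaxon
        dbtaxa: dict[tuple, list] = {}
        for a in sorted(db_members):
            key = (info.loc[a, "taxon_name"], info.loc[a, "rank"])
            dbtaxa.setdefault(key, []).append(a)

        # rule ii: collapse non-dbASVs into matching dbtaxa
        leftovers = []
        for a in sorted(nondb_members):
            row = info.loc[a]
            matches = []
            for (name, rank), asvs in dbtaxa.items():
                r = coarser_rank(row["rank"], rank)
                mine = _name_at_rank(row, r)
                theirs = _name_at_rank(info.loc[asvs[0]], r)
                if mine is not None and mine == theirs:
                    best_ident = max(info.loc[x, "identity_pct"] for x in asvs)
                    matches.append((-best_ident, name, (name, rank)))
            if matches:
                matches.sort()
                if len(matches) > 1 and matches[0][:1] == matches[1][:1]:
                    logger.info(
                        "non-dbASV %s matches several dbtaxa equally; "
                        "kept lexicographically first (%s)",
                        a,
                        matches[0][1],
                    )
                dbtaxa[matches[0][2]].append(a)
            else:
                leftovers.append(a)

        # rule iii: identical-name leftovers -> one non-dbtaxon
        nondbtaxa: dict[tuple, list] = {}
        for a in leftovers:
            key = (info.loc[a, "taxon_name"], info.loc[a, "rank"])
            nondbtaxa.setdefault(key, []).append(a)

        for (name, rank), asvs in sorted(dbtaxa.items()):
            lead = info.loc[asvs[0]]
            records.append(
                TaxonRecord(
                    taxon_id="",
                    name=name,
                    rank=rank,
                    family=lead["family"],
                    genus=lead["genus"],
                    db_flag=True,
                    community_id=cid,
                    member_asvs=asvs,
                )
            )
        for (name, rank), asvs in sorted(nondbtaxa.items()):
            lead = info.loc[asvs[0]]
            records.append(
                TaxonRecord(
                    taxon_id="",
                    name=name,
                    rank=rank,
                    family=lead["family"],
                    genus=lead["genus"],
                    db_flag=False,
                    community_id=cid,
                    member_asvs=asvs,
                )
            )

    rows = []
    counts_rows = []
    for k, rec in enumerate(records):
        rec.taxon_id = f"TX{k:04d}"
        rows.append(
            {
                "taxon_id": rec.taxon_id,
                "name": rec.name,
                "rank": rec.rank,
                "family": rec.family,
                "genus": rec.genus,
                "db_flag": rec.db_flag,
                "community_id": rec.community_id,
                "member_asvs": ";".join(rec.member_asvs),
            }
        )
        counts_rows.append(table.counts.loc[rec.member_asvs].sum(axis=0))
    if not rows:
        empty_info = pd.DataFrame(
            columns=[
                "name", "rank", "family", "genus", "db_flag", "community_id", "member_asvs"
            ]
        )
        return TaxonTable(empty_info, pd.DataFrame(columns=table.sample_ids))
    info_df = pd.DataFrame(rows).set_index("taxon_id")
    counts_df = pd.DataFrame(counts_rows, index=info_df.index)
    return TaxonTable(info_df, counts_df)
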