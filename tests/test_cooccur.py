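"""Network construction, community detection and taxon collapsing."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from paleoloss import cooccur
from paleoloss.cooccur import CommunityPartition

from conftest import toy_asv_table


def _spearman_bruteforce(x, y):
    """Rank (mid-rank ties) then Pearson via the explicit moment formula."""

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def simple_table(vectors: dict, identity=95.0):
    n = len(next(iter(vectors.values())))
    counts = {a: dict(zip([f"s{i}" for i in range(n)], v)) for a, v in vectors.items()}
    info = {
        a: {"identity_pct": identity, "taxon_name": a, "rank": "genus", "family": "F", "genus": a}
        for a in vectors
    }
    return toy_asv_table(counts, info)


class TestCorrelationNetwork:
    def test_identical_vectors_edge_rho_one(self):
        v = [0, 5, 2, 9, 1, 7, 3, 8, 4, 6]
        t = simple_table({"a": v, "b": v, "c": [1, 0, 0, 2, 0, 0, 1, 0, 3, 0]})
        g = cooccur.correlation_network(t)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["rho"] == pytest.approx(1.0)

    def test_independent_asvs_no_edge(self):
        rng = np.random.default_rng(11)
        t = simple_table({"a": rng.integers(0, 50, 100), "b": rng.integers(0, 50, 100),
                          "c": rng.integers(0, 50, 100)})
        g = cooccur.correlation_network(t)
        assert g.number_of_edges() == 0

    def test_rho_matches_bruteforce_rank_formula(self):
        vecs = {
            "a": [3, 0, 7, 7, 2, 9, 1, 0],
            "b": [1, 0, 5, 6, 2, 8, 0, 0],
            "c": [0, 9, 0, 1, 8, 0, 7, 6],
        }
        t = simple_table(vecs)
        g = cooccur.correlation_network(t, rho_min=-2, alpha=1.1)
        for x, y in itertools.combinations(vecs, 2):
            expected = _spearman_bruteforce(vecs[x], vecs[y])
            if g.has_edge(x, y):
                assert g.edges[x, y]["rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_asv_isolated(self):
        t = simple_table({"a": [5] * 8, "b": [0, 1, 2, 3, 4, 5, 6, 7],
                          "c": [0, 1, 2, 3, 4, 5, 6, 7]})
        g = cooccur.correlation_network(t)
        assert g.degree["a"] == 0
        assert g.has_edge("b", "c")

    def test_preconditions(self):
        t = simple_table({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            cooccur.correlation_network(t)


def _bell_partitions(nodes):
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first = nodes[0]
    for rest in _bell_partitions(nodes[1:]):
        for i in range(len(rest)):
            yield rest[:i] + [rest[i] + [first]] + rest[i + 1 :]
        yield [[first]] + rest


def brute_force_max_modularity(g):
    return max(
        nx.community.modularity(g, [set(b) for b in p], weight=None)
        for p in _bell_partitions(list(g.nodes))
    )


class TestDetectCommunities:
    def test_two_cliques_with_bridge_split(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        part = cooccur.detect_communities(g, min_size=5, seed=0)
        assert len(part.reported) == 2
        comms = {frozenset(part.members(c)) for c in part.reported}
        assert comms == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_complete_graph_single_community(self):
        part = cooccur.detect_communities(nx.complete_graph(6), min_size=5, seed=0)
        assert len(set(part.membership.values())) == 1

    def test_components_never_merged(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = cooccur.detect_communities(g, min_size=1, seed=0)
        for a in range(4):
            for b in range(4, 8):
                assert part.membership[a] != part.membership[b]

    def test_empty_network(self):
        part = cooccur.detect_communities(nx.Graph(), min_size=5, seed=0)
        assert part.membership == {} and part.reported == []

    def test_matches_bruteforce_on_small_graphs(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        q = cooccur.partition_modularity(g, cooccur.detect_communities(g, min_size=1, seed=0))
        assert q == pytest.approx(brute_force_max_modularity(g), abs=1e-12)

    def test_beats_singleton_partition(self, strong_record):
        from paleoloss import qc_filter

        table, _, _ = strong_record
        filt = qc_filter.filter_asvs(table)
        g = cooccur.correlation_network(filt)
        part = cooccur.detect_communities(g, seed=0)
        singletons = CommunityPartition({n: i for i, n in enumerate(g.nodes)}, min_size=1)
        assert cooccur.partition_modularity(g, part) >= cooccur.partition_modularity(
            g, singletons
        )

    def test_deterministic_given_seed(self):
        g = nx.les_miserables_graph()
        p1 = cooccur.detect_communities(g, seed=42).membership
        p2 = cooccur.detect_communities(g, seed=42).membership
        assert p1 == p2


class TestCollapseToTaxa:
    def _community(self, members, cid=0, extra=None):
        membership = {a: cid for a in members}
        membership.update(extra or {})
        return CommunityPartition(membership, min_size=5)

    def test_family_nondb_collapses_into_genus_dbtaxon(self):
        counts = {a: {"s0": 10, "s1": 5} for a in ["a1", "a2", "a3", "a4", "a5"]}
        info = {
            "a1": {"identity_pct": 100, "taxon_name": "Salix", "rank": "genus",
                   "family": "Salicaceae", "genus": "Salix"},
            "a2": {"identity_pct": 95, "taxon_name": "Salicaceae", "rank": "family",
                   "family": "Salicaceae", "genus": ""},
            "a3": {"identity_pct": 100, "taxon_name": "Dryas", "rank": "genus",
                   "family": "Rosaceae", "genus": "Dryas"},
            "a4": {"identity_pct": 92, "taxon_name": "Poaceae", "rank": "family",
                   "family": "Poaceae", "genus": ""},
            "a5": {"identity_pct": 93, "taxon_name": "Poaceae", "rank": "family",
                   "family": "Poaceae", "genus": ""},
        }
        table = toy_asv_table(counts, info)
        part = self._community(list(counts))
        taxa = cooccur.collapse_to_taxa(part, table)
        salix = taxa.info[taxa.info["name"] == "Salix"]
        assert len(salix) == 1
        assert set(salix.iloc[0]["member_asvs"].split(";")) == {"a1", "a2"}
        assert salix.iloc[0]["db_flag"]

    def test_identical_db_names_merge(self):
        counts = {a: {"s0": 3, "s1": 1} for a in ["d1", "d2", "x1", "x2", "x3"]}
        info = {
            "d1": {"identity_pct": 100, "taxon_name": "Dryas octopetala", "rank": "species",
                   "family": "Rosaceae", "genus": "Dryas"},
            "d2": {"identity_pct": 100, "taxon_name": "Dryas octopetala", "rank": "species",
                   "family": "Rosaceae", "genus": "Dryas"},
            "x1": {"identity_pct": 91, "taxon_name": "Carex", "rank": "genus",
                   "family": "Cyperaceae", "genus": "Carex"},
            "x2": {"identity_pct": 91, "taxon_name": "Carex", "rank": "genus",
                   "family": "Cyperaceae", "genus": "Carex"},
            "x3": {"identity_pct": 91, "taxon_name": "Juncus", "rank": "genus",
                   "family": "Juncaceae", "genus": "Juncus"},
        }
        taxa = cooccur.collapse_to_taxa(self._community(list(counts)), toy_asv_table(counts, info))
        dryas = taxa.info[taxa.info["name"] == "Dryas octopetala"]
        assert len(dryas) == 1
        assert set(dryas.iloc[0]["member_asvs"].split(";")) == {"d1", "d2"}

    def test_eight_asvs_collapse_to_three_taxa(self):
        """Hand-enumerated application of rules i-iii plus small-community
        discard: community 0 (6 ASVs) -> 3 taxa; community 1 (2 ASVs) dropped."""
        counts = {a: {"s0": 4, "s1": 2} for a in
                  ["a1", "a2", "a3", "a4", "a5", "a6", "b1", "b2"]}
        info = {
            "a1": {"identity_pct": 100, "taxon_name": "Salix", "rank": "genus",
                   "family": "Salicaceae", "genus": "Salix"},
            "a2": {"identity_pct": 100, "taxon_name": "Salix", "rank": "genus",
                   "family": "Salicaceae", "genus": "Salix"},
            "a3": {"identity_pct": 95, "taxon_name": "Salicaceae", "rank": "family",
                   "family": "Salicaceae", "genus": ""},
            "a4": {"identity_pct": 93, "taxon_name": "Dryas octopetala", "rank": "species",
                   "family": "Rosaceae", "genus": "Dryas"},
            "a5": {"identity_pct": 92, "taxon_name": "Dryas octopetala", "rank": "species",
                   "family": "Rosaceae", "genus": "Dryas"},
            "a6": {"identity_pct": 91, "taxon_name": "Poaceae", "rank": "family",
                   "family": "Poaceae", "genus": ""},
            "b1": {"identity_pct": 100, "taxon_name": "Betula", "rank": "genus",
                   "family": "Betulaceae", "genus": "Betula"},
            "b2": {"identity_pct": 90, "taxon_name": "Pinaceae", "rank": "family",
                   "family": "Pinaceae", "genus": ""},
        }
        part = self._community(
            ["a1", "a2", "a3", "a4", "a5", "a6"], cid=0, extra={"b1": 1, "b2": 1}
        )
        taxa = cooccur.collapse_to_taxa(part, toy_asv_table(counts, info))
        assert taxa.n_taxa == 3
        by_name = {r["name"]: set(r["member_asvs"].split(";")) for _, r in taxa.info.iterrows()}
        assert by_name == {
            "Salix": {"a1", "a2", "a3"},
            "Dryas octopetala": {"a4", "a5"},
            "Poaceae": {"a6"},
        }
        flags = dict(zip(taxa.info["name"], taxa.info["db_flag"]))
        assert flags == {"Salix": True, "Dryas octopetala": False, "Poaceae": False}

    def test_taxon_count_never_exceeds_asv_count(self, strong_record):
        from paleoloss import qc_filter

        table, _, _ = strong_record
        filt = qc_filter.filter_asvs(table)
        part = cooccur.detect_communities(cooccur.correlation_network(filt), seed=0)
        taxa = cooccur.collapse_to_taxa(part, filt)
        assert taxa.n_taxa <= filt.n_asvs
        # every taxon maps to exactly one (reported) community
        assert taxa.info["community_id"].isin(part.reported).all()
        # counts conserved within collapsed members
        for _, row in taxa.info.head(10).iterrows():
            members = row["member_asvs"].split(";")
            assert (
                taxa.counts.loc[row.name].to_numpy()
                == filt.counts.loc[members].sum(axis=0).to_numpy()
            ).all()


def test_planted_asvs_of_same_taxon_share_community(strong_record):
    """Multi-ASV taxa should land in one community (>= 85% co-membership)."""
    from paleoloss import qc_filter

    table, _, truth = strong_record
    filt = qc_filter.filter_asvs(table)
    part = cooccur.detect_communities(cooccur.correlation_network(filt), seed=0)
    taxon_of = truth.asv_to_taxon
    sizes = taxon_of.groupby(taxon_of).size()
    multi = sizes[sizes > 1].index
    together = []
    for t in multi:
        asvs = [a for a in taxon_of.index[taxon_of == t] if a in part.membership]
        if len(asvs) > 1:
            together.append(len({part.membership[a] for a in asvs}) == 1)
    assert len(together) >= 5
    assert np.mean(together) >= 0.85
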