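import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfsub import interactome as it
from tests.conftest import make_subs

MITAB_LINE = (
    "uniprotkb:P05412\tuniprotkb:Q8NDH6\t"
    "uniprotkb:JUN(display_short)\tuniprotkb:ICOSLG(display_short)\t"
    "uniprotkb:JUN(gene name)|uniprotkb:AP1(synonym)\t"
    "uniprotkb:C1orf131(gene name)\t"
    + "\t".join(["-"] * 9)
)
MITAB_NO_ALIAS = "\t".join(["uniprotkb:P1", "uniprotkb:P2"] + ["-"] * 13)


class TestParsing:
    def test_two_line_tsv(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("C1orf94\tC1orf109\nC1orf52\tCXorf56\n")
        parsed = it.parse_interactions(f, dialect="tsv_edges")
        assert len(parsed) == 2 and parsed.n_skipped == 0
        assert parsed.records[0] == it.InteractionRecord("C1ORF94", "C1ORF109", source="edges")

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        parsed = it.parse_interactions(f)
        assert parsed.records == [] and parsed.n_skipped == 0

    def test_header_row_ignored(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("gene_a\tgene_b\nA\tB\n")
        assert len(it.parse_interactions(f)) == 1

    def test_third_column_is_source(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("A\tB\tbioplex\n")
        assert it.parse_interactions(f).records[0].source == "BIOPLEX"

    def test_mitab_gene_name_aliases(self, tmp_path):
        f = tmp_path / "x.mitab"
        f.write_text(MITAB_LINE + "\n")
        parsed = it.parse_interactions(f, dialect="mitab")
        assert parsed.records[0].gene_a == "JUN"
        assert parsed.records[0].gene_b == "C1ORF131"

    def test_mitab_missing_alias_skipped(self, tmp_path):
        f = tmp_path / "x.mitab"
        f.write_text(MITAB_NO_ALIAS + "\n")
        parsed = it.parse_interactions(f, dialect="mitab")
        assert len(parsed) == 0 and parsed.n_skipped == 1

    def test_unreadable_file_fatal(self, tmp_path):
        with pytest.raises(OSError):
            it.parse_interactions(tmp_path / "missing.tsv")

    def test_record_rejects_non_physical(self):
        with pytest.raises(ValueError):
            it.InteractionRecord("A", "B", evidence="genetic")


class TestAggregate:
    def test_dedup_unions_sources(self):
        recs = [it.InteractionRecord("A", "B", source=s) for s in ("s1", "s2", "s3")]
        net = it.aggregate([recs], orf_roster={"A"})
        assert net.n_edges == 1
        assert net.edges[("A", "B")] == {"s1", "s2", "s3"}

    def test_unordered_symmetry(self):
        recs = [it.InteractionRecord("A", "B"), it.InteractionRecord("B", "A")]
        net = it.aggregate([recs], orf_roster={"A"})
        assert net.n_edges == 1

    def test_self_loops_dropped(self):
        net = it.aggregate([[it.InteractionRecord("A", "A")]], orf_roster={"A"})
        assert net.n_edges == 0 and net.n_self_loops_dropped == 1

    def test_case_insensitive_symbols(self):
        recs = [it.InteractionRecord("c1orf94", "C1ORF109"), it.InteractionRecord("C1orf94", "c1orf109")]
        net = it.aggregate([recs], orf_roster={"C1ORF94"})
        assert net.n_edges == 1

    def test_orf_orf_count_with_distractors(self):
        orf_pairs = [("R1", "R2"), ("R3", "R4"), ("R5", "R6"), ("R7", "R8"),
                     ("R1", "R3"), ("R2", "R9"), ("R4", "R10"), ("R5", "R7")]
        roster = {f"R{i}" for i in range(1, 11)}
        recs = [it.InteractionRecord(a, b) for a, b in orf_pairs]
        recs += [it.InteractionRecord(f"R{i}", f"X{i}") for i in range(1, 6)]
        net = it.aggregate([recs], orf_roster=roster)
        assert net.n_edges == 13
        assert len(net.orf_orf_edges()) == 8

    def test_idempotence(self, toy_network):
        rebuilt = it.aggregate(
            [[it.InteractionRecord(a, b, source=s) for (a, b), srcs in toy_network.edges.items() for s in srcs]],
            orf_roster=toy_network.orf_roster,
        )
        assert rebuilt.edges == toy_network.edges


class TestSubinteractome:
    def test_star_graph(self):
        recs = [it.InteractionRecord("HUB", f"L{i}") for i in range(7)]
        net = it.aggregate([recs], orf_roster={"HUB"})
        assert it.subinteractome(net, "HUB").size == 7

    def test_orphan_is_empty(self, toy_network):
        assert it.subinteractome(toy_network, "O4").size == 0

    def test_sharing_does_not_shrink(self, toy_network):
        # SHARED2 also binds O2; it still counts as O1's partner
        assert it.subinteractome(toy_network, "O1").partners == {"O2", "SHARED2", "SHARED3", "PRIV1"}

    def test_unknown_orf_errors(self, toy_network):
        with pytest.raises(KeyError):
            it.subinteractome(toy_network, "NOT_ON_ROSTER")

    def test_membership_symmetry(self, toy_network):
        for orf in ("O1", "O2", "O3"):
            for partner in it.subinteractome(toy_network, orf).partners:
                assert orf in toy_network.neighbors(partner)


class TestCensus:
    def test_toy_classification(self, toy_network):
        census = it.partner_census(toy_network)
        assert census.shared_by_two == {"SHARED2"}
        assert census.shared_by_three_plus == {"SHARED3"}
        assert census.orf_orf_edges == [("O1", "O2")]
        assert census.orphan_orfs == {"O4"}
        assert census.ppis_via_three_plus == 3

    def test_single_orf_partner_in_neither_set(self, toy_network):
        census = it.partner_census(toy_network)
        assert "PRIV1" not in census.shared_by_two | census.shared_by_three_plus

    def test_conservation(self, study_network):
        net, _ = study_network
        census = it.partner_census(net)
        non_roster = {n for n in net.nodes if n not in net.orf_roster}
        n_single = len(non_roster) - len(census.shared_by_two) - len(census.shared_by_three_plus)
        degrees = {}
        for (a, b) in net.edges:
            if a in net.orf_roster and b not in net.orf_roster:
                degrees[b] = degrees.get(b, 0) + 1
            elif b in net.orf_roster and a not in net.orf_roster:
                degrees[a] = degrees.get(a, 0) + 1
        assert n_single == sum(1 for d in degrees.values() if d == 1)


class TestSizeHistogramAndFilter:
    def test_reference_distribution(self, printed_distribution_sizes):
        counts = it.size_histogram(make_subs(printed_distribution_sizes))
        assert counts == [63, 30, 40, 27, 6, 11]

    def test_empty_input(self):
        assert it.size_histogram([]) == [0] * 6

    def test_half_open_convention(self):
        counts = it.size_histogram(make_subs([7] * 5))
        assert counts[1] == 5

    def test_last_finite_bin_closed(self):
        counts = it.size_histogram(make_subs([100, 101]))
        assert counts[4] == 1 and counts[5] == 1

    def test_non_monotone_edges_error(self):
        with pytest.raises(ValueError):
            it.size_histogram([], edges=(7, 7, 30))

    @settings(max_examples=50, deadline=None)
    @given(sizes=st.lists(st.integers(min_value=0, max_value=300), max_size=60))
    def test_conservation_property(self, sizes):
        assert sum(it.size_histogram(make_subs(sizes))) == len(sizes)

    def test_inclusive_bounds(self):
        kept = it.select_by_size(make_subs([6, 7, 100, 101]), 7, 100)
        assert sorted(s.size for s in kept) == [7, 100]

    def test_identity_bounds(self):
        subs = make_subs([0, 5, 500])
        assert it.select_by_size(subs, 0, 10**9) == subs

    def test_reference_selection(self, printed_distribution_sizes):
        assert len(it.select_by_size(make_subs(printed_distribution_sizes), 7, 100)) == 103


class TestShortestPaths:
    def test_direct_edge(self, toy_network):
        [res] = it.shortest_orf_paths(toy_network, [("O1", "O2")])
        assert res.length == 1

    def test_two_edge_chain(self, toy_network):
        [res] = it.shortest_orf_paths(toy_network, [("O2", "O3")])
        assert res.length == 2 and res.path[1] == "SHARED3"

    def test_disconnected_pair(self):
        recs = [it.InteractionRecord("A", "B"), it.InteractionRecord("C", "D")]
        net = it.aggregate([recs], orf_roster={"A", "C"})
        [res] = it.shortest_orf_paths(net, [("A", "C")])
        assert res.length == math.inf and res.path == ()

    def test_absent_endpoint_errors(self, toy_network):
        with pytest.raises(KeyError):
            it.shortest_orf_paths(toy_network, [("O1", "GHOST")])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bfs_matches_brute_force(self, seed):
        """Path lengths equal the adjacency-power minimum on random graphs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        adj = np.triu((rng.random((n, n)) < 0.3).astype(int), k=1)
        adj = adj + adj.T
        names = [f"N{i}" for i in range(n)]
        recs = [
            it.InteractionRecord(names[i], names[j])
            for i in range(n) for j in range(i + 1, n) if adj[i, j]
        ]
        if not recs:
            return
        net = it.aggregate([recs], orf_roster=set(names))
        present = sorted(net.nodes)
        # brute force: smallest k with (A^k)[i, j] > 0
        power = np.eye(n, dtype=np.int64)
        dist = np.full((n, n), math.inf)
        np.fill_diagonal(dist, 0)
        for k in range(1, n):
            power = power @ adj
            newly = (power > 0) & np.isinf(dist)
            dist[newly] = k
        idx = {name: i for i, name in enumerate(names)}
        pairs = [(a, b) for a in present for b in present if a < b]
        for res in it.shortest_orf_paths(net, pairs):
            assert res.length == dist[idx[res.orf_a], idx[res.orf_b]]
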