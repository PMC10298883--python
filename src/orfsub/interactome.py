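"""Aggregation and querying of physical protein-protein interaction records.

A *subinteractome* is the set of all known protein partners that physically
interact with a target protein.  Interactions are collected from multiple
tab-delimited sources (PSI-MITAB 2.5/2.7 or plain edge lists), deduplicated
into an undirected network with per-edge source provenance, and queried for
per-protein partner sets, partner-sharing censuses and shortest paths between
target (ORF) proteins.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Default subinteractome-size bin edges: <7, [7,15), [15,30), [30,70),
#: [70,100], >100.  Interior bins are half-open; the final edge is inclusive
#: so that the bin before the open tail is a closed interval.
DEFAULT_SIZE_EDGES: tuple[int, ...] = (7, 15, 30, 70, 100)

_GENE_NAME_ALIAS = re.compile(r"([^|:]+)\s*\(gene name\)")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped, uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One physical interaction between two gene products, with provenance."""

    gene_a: str
    gene_b: str
    source: str = "unknown"
    evidence: str = "physical"

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("interaction endpoints must be non-empty symbols")
        if self.evidence != "physical":
            raise ValueError(f"only physical interactions are accepted, got {self.evidence!r}")


@dataclass
class ParseResult:
    """Parsed records plus bookkeeping for skipped (malformed) lines."""

    records: list[InteractionRecord]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AggregatedNetwork:
    """Undirected deduplicated PPI network with per-edge source tags.

    ``edges`` maps a sorted gene-symbol pair to the set of source tags that
    reported it.  ``orf_roster`` is the designated set of target proteins
    whose subinteractomes are under study; roster members without any edge
    are retained in ``orf_roster`` but not in ``nodes``.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    orf_roster: set[str] = field(default_factory=set)
    n_self_loops_dropped: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> set[str]:
        gene = normalize_symbol(gene)
        out: set[str] = set()
        for (a, b) in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def orf_orf_edges(self) -> list[tuple[str, str]]:
        """Edges whose both endpoints are roster members, sorted."""
        return sorted(pair for pair in self.edges if pair[0] in self.orf_roster and pair[1] in self.orf_roster)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), sources in self.edges.items():
            g.add_edge(a, b, sources=sorted(sources))
        return g


@dataclass(frozen=True)
class Subinteractome:
    """A target protein and the set of its physical-interaction partners."""

    orf: str
    partners: frozenset[str]

    def __post_init__(self) -> None:
        if self.orf in self.partners:
            raise ValueError(f"{self.orf} cannot be its own partner")

    @property
    def size(self) -> int:
        return len(self.partners)


@dataclass
class PartnerCensus:
    """Classification of partners by how many roster proteins they touch.

    Partners adjacent to exactly two roster proteins are candidate bridges of
    heterotrimeric complexes; partners adjacent to three or more suggest
    higher-order multimeric complexes.  ``ppis_via_three_plus`` counts the
    roster-partner edges running through the latter group.
    """

    orf_orf_edges: list[tuple[str, str]]
    shared_by_two: set[str]
    shared_by_three_plus: set[str]
    orphan_orfs: set[str]
    ppis_via_three_plus: int = 0


def _parse_mitab_line(fields: Sequence[str]) -> tuple[str, str] | None:
    """Extract (gene_a, gene_b) from a PSI-MITAB row via the alias columns.

    Columns 5-6 (0-based 4-5) carry aliases of the form
    ``db:VALUE(gene name)|db:VALUE(other)``; the first alias annotated
    ``(gene name)`` wins.  Returns None when either side lacks one.
    """
    symbols = []
    for col in (4, 5):
        match = _GENE_NAME_ALIAS.search(fields[col])
        if match is None:
            return None
        symbols.append(normalize_symbol(match.group(1)))
    a, b = symbols
    if not a or not b:
        return None
    return a, b


_HEADER_TOKENS = {
    "gene_a", "gene_b", "genea", "geneb", "gene1", "gene2", "gene",
    "protein_a", "protein_b", "interactor_a", "interactor_b",
    "symbol_a", "symbol_b", "from", "to", "partner", "source",
}


def parse_interactions(
    path: str | Path,
    dialect: str = "tsv_edges",
    source: str | None = None,
) -> ParseResult:
    """Parse an interaction file into records.

    Parameters
    ----------
    path
        Tab-delimited input file.
    dialect
        ``"mitab"`` for PSI-MITAB 2.5/2.7 (>=15 columns, gene symbols read
        from the alias columns) or ``"tsv_edges"`` for a 2-3-column edge list
        (gene_a, gene_b, optional per-line source).
    source
        Source tag attached to every record; defaults to the file stem.

    Lines lacking a resolvable gene symbol on either side are skipped and
    counted in :attr:`ParseResult.n_skipped`.
    """
    path = Path(path)
    if dialect not in {"mitab", "tsv_edges"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    tag = source if source is not None else path.stem

    records: list[InteractionRecord] = []
    n_skipped = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "mitab":
                if len(fields) < 15:
                    logger.warning("%s:%d: mitab line has %d < 15 columns, skipped", path, lineno, len(fields))
                    n_skipped += 1
                    continue
                pair = _parse_mitab_line(fields)
                if pair is None:
                    logger.warning("%s:%d: no gene-name alias on one side, skipped", path, lineno)
                    n_skipped += 1
                    continue
                a, b = pair
                records.append(InteractionRecord(a, b, source=tag))
            else:
                if len(fields) < 2:
                    logger.warning("%s:%d: fewer than 2 columns, skipped", path, lineno)
                    n_skipped += 1
                    continue
                a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
                if lineno == 1 and (fields[0].strip().lower() in _HEADER_TOKENS or fields[1].strip().lower() in _HEADER_TOKENS):
                    continue  # header row
                if not a or not b:
                    logger.warning("%s:%d: empty gene symbol, skipped", path, lineno)
                    n_skipped += 1
                    continue
                line_tag = normalize_symbol(fields[2]) if len(fields) >= 3 and fields[2].strip() else tag
                records.append(InteractionRecord(a, b, source=line_tag))
    return ParseResult(records=records, n_skipped=n_skipped)


def aggregate(
    record_lists: Iterable[Iterable[InteractionRecord]],
    orf_roster: Iterable[str],
) -> AggregatedNetwork:
    """Merge record lists into a deduplicated undirected network.

    The same unordered pair reported by several sources collapses to a single
    edge whose source-tag set is the union.  Self-loops are dropped (and
    counted); the roster is stored for downstream subinteractome queries.
    """
    roster = {normalize_symbol(g) for g in orf_roster}
    if not roster:
        raise ValueError("ORF roster must be non-empty")

    net = AggregatedNetwork(orf_roster=roster)
    for records in record_lists:
        for rec in records:
            a = normalize_symbol(rec.gene_a)
            b = normalize_symbol(rec.gene_b)
            if a == b:
                net.n_self_loops_dropped += 1
                continue
            key = (a, b) if a < b else (b, a)
            net.edges.setdefault(key, set()).add(rec.source)
            net.nodes.update(key)
    return net


def subinteractome(net: AggregatedNetwork, orf: str) -> Subinteractome:
    """All network neighbors of a roster protein."""
    orf = normalize_symbol(orf)
    if orf not in net.orf_roster:
        raise KeyError(f"{orf!r} is not on the ORF roster")
    return Subinteractome(orf=orf, partners=frozenset(net.neighbors(orf)))


def partner_census(net: AggregatedNetwork) -> PartnerCensus:
    """Census of partner sharing across the roster.

    Every non-roster partner is classified by its number of roster neighbors
    (exactly 2, or >=3); roster-roster edges and partnerless roster members
    are listed separately.
    """
    roster_degree: dict[str, int] = {}
    connected_orfs: set[str] = set()
    for (a, b) in net.edges:
        a_in, b_in = a in net.orf_roster, b in net.orf_roster
        if a_in:
            connected_orfs.add(a)
        if b_in:
            connected_orfs.add(b)
        if a_in and not b_in:
            roster_degree[b] = roster_degree.get(b, 0) + 1
        elif b_in and not a_in:
            roster_degree[a] = roster_degree.get(a, 0) + 1

    shared_two = {p for p, d in roster_degree.items() if d == 2}
    shared_three = {p for p, d in roster_degree.items() if d >= 3}
    return PartnerCensus(
        orf_orf_edges=net.orf_orf_edges(),
        shared_by_two=shared_two,
        shared_by_three_plus=shared_three,
        orphan_orfs=net.orf_roster - connected_orfs,
        ppis_via_three_plus=sum(roster_degree[p] for p in shared_three),
    )


def size_histogram(
    subs: Sequence[Subinteractome],
    edges: Sequence[float] = DEFAULT_SIZE_EDGES,
) -> list[int]:
    """Bin subinteractome sizes.

    With edges ``(e1, ..., ek)`` the bins are ``<e1``, ``[e1, e2)``, ...,
    ``[e_{k-1}, ek]`` and ``>ek`` — interior bins half-open, the last finite
    bin closed on both ends.  The defaults reproduce the partner-count bins
    <7, [7,15), [15,30), [30,70), [70,100], >100.
    """
    edges = list(edges)
    if any(lo >= hi for lo, hi in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    from bisect import bisect_right

    k = len(edges)
    counts = [0] * (k + 1)
    for sub in subs:
        s = sub.size
        if s < edges[0]:
            counts[0] += 1
        elif s > edges[-1]:
            counts[k] += 1
        elif s == edges[-1]:
            counts[k - 1] += 1  # closing the last finite bin
        else:
            counts[bisect_right(edges, s)] += 1
    return counts


def select_by_size(
    subs: Sequence[Subinteractome],
    min_size: int,
    max_size: int,
) -> list[Subinteractome]:
    """Keep subinteractomes with min_size <= size <= max_size (inclusive)."""
    if not (0 <= min_size <= max_size):
        raise ValueError("require 0 <= min_size <= max_size")
    return [s for s in subs if min_size <= s.size <= max_size]


@dataclass(frozen=True)
class PathResult:
    """Unweighted shortest path between two roster proteins."""

    orf_a: str
    orf_b: str
    length: float  # math.inf when unreachable
    path: tuple[str, ...]


def shortest_orf_paths(
    net: AggregatedNetwork,
    pairs: Sequence[tuple[str, str]],
) -> list[PathResult]:
    """Breadth-first shortest paths between pairs of network proteins.

    Length 1 means a direct edge; unreachable pairs are reported with
    infinite length and an empty node sequence.
    """
    g = net.to_networkx()
    out: list[PathResult] = []
    for a, b in pairs:
        a, b = normalize_symbol(a), normalize_symbol(b)
        for endpoint in (a, b):
            if endpoint not in g:
                raise KeyError(f"{endpoint!r} is absent from the network")
        try:
            path = nx.shortest_path(g, a, b)
            out.append(PathResult(a, b, length=len(path) - 1, path=tuple(path)))
        except nx.NetworkXNoPath:
            out.append(PathResult(a, b, length=math.inf, path=()))
    return out
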