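"""Cancer-hallmark density scoring and over-representation analysis.

The CH-score of a subinteractome is the relative frequency of
hallmark-of-cancer-associated proteins per 10 protein partners:
``score = 10 * n_ch / n_partners``.  A score of 1 therefore means one
hallmark-associated protein among 10 partners.  Subinteractomes are
prioritized by a score threshold (default 2.0), and their partner sets can
be tested for gene-set over-representation with a hypergeometric test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from orfsub.interactome import Subinteractome, normalize_symbol

logger = logging.getLogger(__name__)

#: Genome-wide protein-coding background used as the default ORA universe.
DEFAULT_BACKGROUND = 19467


@dataclass
class HallmarkAnnotation:
    """Binary flag set: gene symbols associated with hallmarks of cancer."""

    associated: set[str]
    source_tag: str = "user"

    def __post_init__(self) -> None:
        self.associated = {normalize_symbol(g) for g in self.associated}

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.associated

    @classmethod
    def from_file(cls, path: str | Path, source_tag: str | None = None) -> "HallmarkAnnotation":
        """Read one-symbol-per-line text or a 2-column (symbol, tag) TSV."""
        path = Path(path)
        genes = set()
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            genes.add(normalize_symbol(line.split("\t")[0]))
        return cls(associated=genes, source_tag=source_tag or path.stem)


@dataclass(frozen=True)
class CHScoreReport:
    """CH-score of one subinteractome.

    ``core`` is the hallmark-associated subset of the partner set.  With
    ``count_self`` the target protein itself may add 1 to the numerator (if
    hallmark-associated) while the denominator stays the partner count, so
    the score lies in [0, 10 * (n_partners + 1) / n_partners].
    """

    orf: str
    n_partners: int
    n_ch: int
    score: float
    core: frozenset[str]


def ch_score(
    sub: Subinteractome,
    ann: HallmarkAnnotation,
    count_self: bool = True,
) -> CHScoreReport:
    """Hallmark-associated proteins per 10 partners of one subinteractome."""
    if sub.size == 0:
        raise ValueError(f"CH-score is undefined for the empty subinteractome of {sub.orf}")
    core = frozenset(p for p in sub.partners if p in ann)
    n_ch = len(core)
    if count_self and sub.orf in ann:
        n_ch += 1
    return CHScoreReport(
        orf=sub.orf,
        n_partners=sub.size,
        n_ch=n_ch,
        score=10.0 * n_ch / sub.size,
        core=core,
    )


@dataclass
class PrioritizationSummary:
    """Score distribution summary accompanying a threshold selection."""

    threshold: float
    n_total: int
    n_selected: int
    median: float
    percentile_25: float

    @property
    def fraction_selected(self) -> float:
        return self.n_selected / self.n_total


def prioritize(
    reports: Sequence[CHScoreReport],
    threshold: float = 2.0,
) -> tuple[list[CHScoreReport], PrioritizationSummary]:
    """Select reports with score >= threshold; summarize the distribution.

    Percentiles use linear interpolation between order statistics.
    """
    if not reports:
        raise ValueError("cannot prioritize an empty report list")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    scores = np.array([r.score for r in reports], dtype=float)
    selected = [r for r in reports if r.score >= threshold]
    summary = PrioritizationSummary(
        threshold=threshold,
        n_total=len(reports),
        n_selected=len(selected),
        median=float(np.median(scores)),
        percentile_25=float(np.percentile(scores, 25)),
    )
    return selected, summary


@dataclass(frozen=True)
class OraResult:
    """One gene-set term's over-representation result for a query list.

    ``coverage`` is the fraction of the query covered by the term; a term is
    called significant when FDR < fdr_cutoff *and* it covers more than the
    coverage cutoff (default >10%) of the query.
    """

    term_id: str
    term_size: int
    overlap: int
    p_value: float
    fdr: float
    coverage: float
    significant: bool
    overlap_genes: frozenset[str] = frozenset()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, member genes per line)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not fields[0].strip():
            continue
        sets[fields[0].strip()] = {normalize_symbol(g) for g in fields[2:] if g.strip()}
    return sets


def ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: int | Iterable[str] = DEFAULT_BACKGROUND,
    min_term_size: int = 4,
    fdr_cutoff: float = 0.1,
    coverage_cutoff: float = 0.10,
) -> list[OraResult]:
    """Hypergeometric over-representation of a query against gene sets.

    For a term of size m in a universe of N genes and a query of size n with
    overlap k, the p-value is the upper tail P(X >= k) of the hypergeometric
    distribution.  Benjamini-Hochberg adjustment runs across retained terms
    (term_size >= min_term_size).  ``background`` is either a universe size
    or an explicit universe gene list; with an explicit list, query genes
    outside the universe are dropped with a warning so N stays consistent.
    """
    query_set = {normalize_symbol(g) for g in query}
    if not query_set:
        raise ValueError("query must be non-empty")
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")

    universe: set[str] | None
    if isinstance(background, int):
        n_universe = background
        universe = None
    else:
        universe = {normalize_symbol(g) for g in background}
        n_universe = len(universe)
        missing = query_set - universe
        if missing:
            logger.warning("%d query genes absent from the background universe, ignored", len(missing))
            query_set = query_set & universe
        if not query_set:
            raise ValueError("no query gene is in the background universe")
    if n_universe < len(query_set):
        raise ValueError("background universe smaller than the query")

    n_query = len(query_set)
    rows: list[tuple[str, int, int, float, frozenset[str]]] = []
    for term_id, members in gene_sets.items():
        term = {normalize_symbol(g) for g in members}
        if universe is not None:
            term = term & universe
        m = len(term)
        if m < min_term_size:
            continue
        hit = frozenset(term & query_set)
        k = len(hit)
        # P(X >= k), X ~ Hypergeom(N, m, n)
        p = float(hypergeom.sf(k - 1, n_universe, m, n_query)) if k > 0 else 1.0
        rows.append((term_id, m, k, min(p, 1.0), hit))

    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for (term_id, m, k, p, hit), fdr in zip(rows, fdrs):
        coverage = k / n_query
        results.append(
            OraResult(
                term_id=term_id,
                term_size=m,
                overlap=k,
                p_value=p,
                fdr=float(fdr),
                coverage=coverage,
                significant=bool(fdr < fdr_cutoff and coverage > coverage_cutoff),
                overlap_genes=hit,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
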