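"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline consumes data shaped like the
resources the study design assumes — an aggregated physical-PPI network over
a designated target-protein (ORF) roster, hallmark annotations, paired
normal/tumor expression matrices with prescribed rank correlations,
proportional-hazards survival cohorts, and sparse gene x cancer
differential-expression matrices with cluster structure.  Each generator
returns its output together with a ground-truth ledger sufficient for
parameter-recovery tests, and is fully deterministic under a fixed seed:
each call derives an independent named substream from the master seed, so
adding one generator call never perturbs another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from orfsub.coexpression import ExpressionMatrix
from orfsub.expression import DECallMatrix
from orfsub.hallmark_scoring import HallmarkAnnotation
from orfsub.interactome import AggregatedNetwork, Subinteractome, subinteractome
from orfsub.survival import SurvivalCohort

DEFAULT_SEED = 20230615


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream keyed by (seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# PPI network


@dataclass
class PPINetworkConfig:
    """Shape of the synthetic aggregated PPI network.

    Defaults reproduce the study conditions: a 219-member roster of which
    177 have at least one partner, the partner-count distribution
    (63, 30, 40, 27, 6, 11) over the bins <7, [7,15), [15,30), [30,70),
    [70,100], >100, eight roster-roster edges, 517 partners shared by
    exactly two roster proteins and 768 partner-roster edges running through
    partners shared by three or more.
    """

    n_roster: int = 219
    size_distribution: tuple[tuple[tuple[int, int], int], ...] = (
        ((1, 6), 63),
        ((7, 14), 30),
        ((15, 29), 40),
        ((30, 69), 27),
        ((70, 100), 6),
        ((101, 140), 11),
    )
    n_orf_orf_edges: int = 8
    n_shared_two: int = 517
    n_shared_three_plus_ppis: int = 768
    n_sources: int = 10


def gen_ppi_network(
    cfg: PPINetworkConfig | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[AggregatedNetwork, dict]:
    """Generate a network whose subinteractome-size histogram matches
    ``cfg.size_distribution`` exactly, with planted roster-roster edges and
    shared partners recorded in the ground-truth ledger."""
    cfg = cfg or PPINetworkConfig()
    rng = substream(seed, "ppi_network")

    n_connected = sum(count for _, count in cfg.size_distribution)
    if n_connected > cfg.n_roster:
        raise ValueError("size distribution demands more ORFs than the roster holds")

    roster = [f"ORF{i:04d}" for i in range(1, cfg.n_roster + 1)]
    order = rng.permutation(cfg.n_roster)
    connected = [roster[i] for i in order[:n_connected]]
    orphans = [roster[i] for i in order[n_connected:]]

    sizes: dict[str, int] = {}
    pos = 0
    for (lo, hi), count in cfg.size_distribution:
        if not (1 <= lo <= hi):
            raise ValueError("size ranges must satisfy 1 <= lo <= hi")
        for s in rng.integers(lo, hi + 1, size=count):
            sizes[connected[pos]] = int(s)
            pos += 1

    budget = dict(sizes)
    edges: dict[tuple[str, str], set[str]] = {}
    sources = [f"source{i:02d}" for i in range(1, cfg.n_sources + 1)]

    def add_edge(a: str, b: str) -> None:
        key = (a, b) if a < b else (b, a)
        if key in edges:
            raise RuntimeError("generator produced a duplicate edge")
        n_src = int(rng.integers(1, min(3, cfg.n_sources) + 1))
        edges[key] = set(rng.choice(sources, size=n_src, replace=False))

    def draw_orfs(k: int) -> list[str]:
        pool = [o for o, b in budget.items() if b > 0]
        if len(pool) < k:
            raise ValueError("infeasible configuration: partner demand exceeds remaining ORF capacity")
        # favor high-budget ORFs so small subinteractomes are not exhausted early
        weights = np.array([budget[o] for o in pool], dtype=float)
        picks = rng.choice(len(pool), size=k, replace=False, p=weights / weights.sum())
        return [pool[i] for i in picks]

    orf_orf_pairs: list[tuple[str, str]] = []
    attempts = 0
    while len(orf_orf_pairs) < cfg.n_orf_orf_edges:
        attempts += 1
        if attempts > 100 * max(cfg.n_orf_orf_edges, 1):
            raise ValueError("infeasible configuration: cannot place roster-roster edges")
        a, b = draw_orfs(2)
        key = (a, b) if a < b else (b, a)
        if key in edges:
            continue
        add_edge(a, b)
        budget[a] -= 1
        budget[b] -= 1
        orf_orf_pairs.append(key)

    if 0 < cfg.n_shared_three_plus_ppis < 3:
        raise ValueError("a shared-by-three-plus partner needs at least 3 roster links")
    shared_three: dict[str, list[str]] = {}
    ppis_three = 0
    idx = 0
    while ppis_three < cfg.n_shared_three_plus_ppis:
        remaining = cfg.n_shared_three_plus_ppis - ppis_three
        # keep the leftover expressible as sums of partners with >= 3 links
        if remaining <= 7:
            k = remaining
        else:
            k = int(rng.integers(3, min(7, remaining - 3) + 1))
        idx += 1
        partner = f"SH3P{idx:04d}"
        owners = draw_orfs(k)
        for o in owners:
            add_edge(o, partner)
            budget[o] -= 1
        shared_three[partner] = sorted(owners)
        ppis_three += k

    shared_two: dict[str, list[str]] = {}
    for i in range(1, cfg.n_shared_two + 1):
        partner = f"SH2P{i:04d}"
        owners = draw_orfs(2)
        for o in owners:
            add_edge(o, partner)
            budget[o] -= 1
        shared_two[partner] = sorted(owners)

    unique_idx = 0
    for orf in connected:
        for _ in range(budget[orf]):
            unique_idx += 1
            add_edge(orf, f"UQP{unique_idx:05d}")
        budget[orf] = 0

    nodes: set[str] = set()
    for a, b in edges:
        nodes.update((a, b))
    net = AggregatedNetwork(nodes=nodes, edges=edges, orf_roster=set(roster))

    ledger = {
        "sizes": sizes,
        "orphans": sorted(orphans),
        "orf_orf_pairs": sorted(orf_orf_pairs),
        "shared_by_two": shared_two,
        "shared_by_three_plus": shared_three,
        "n_shared_three_plus_ppis": ppis_three,
        "n_unique_ppis": len(edges),
        "seed": seed,
    }
    return net, ledger


# ---------------------------------------------------------------------------
# Hallmark annotation


def flaggable_counts(net: AggregatedNetwork, subs: Sequence[Subinteractome]) -> dict[str, int]:
    """Per-ORF count of partners whose hallmark flag affects only that ORF
    (non-roster partners adjacent to exactly one roster protein)."""
    roster_degree: dict[str, int] = {}
    for (a, b) in net.edges:
        if a in net.orf_roster and b not in net.orf_roster:
            roster_degree[b] = roster_degree.get(b, 0) + 1
        elif b in net.orf_roster and a not in net.orf_roster:
            roster_degree[a] = roster_degree.get(a, 0) + 1
    return {
        sub.orf: sum(
            1 for p in sub.partners if p not in net.orf_roster and roster_degree.get(p, 0) == 1
        )
        for sub in subs
    }


def gen_hallmark_annotation(
    net: AggregatedNetwork,
    target_scores: Mapping[str, float],
    seed: int = DEFAULT_SEED,
) -> HallmarkAnnotation:
    """Flag partners so that each ORF's CH-score equals its target exactly.

    Only non-roster partners are flagged (so the self-count never shifts a
    score) and partner pools are disjoint across targets except where a
    shared partner's flag is consistent with both targets.  A target
    ``s`` for an ORF with ``n`` partners requires ``s * n / 10`` to be an
    integer no larger than the ORF's non-roster, non-shared partner count.
    """
    rng = substream(seed, "hallmark_annotation")
    flagged: set[str] = set()
    # partners adjacent to >1 target ORF could double-count; exclude them
    # from the candidate pools so each target is controlled independently.
    roster_degree: dict[str, int] = {}
    for (a, b) in net.edges:
        if a in net.orf_roster and b not in net.orf_roster:
            roster_degree[b] = roster_degree.get(b, 0) + 1
        elif b in net.orf_roster and a not in net.orf_roster:
            roster_degree[a] = roster_degree.get(a, 0) + 1

    for orf in sorted(target_scores):
        target = target_scores[orf]
        sub = subinteractome(net, orf)
        n = sub.size
        if n == 0:
            raise ValueError(f"ORF {orf} has no partners; CH-score target unachievable")
        k_float = target * n / 10.0
        k = round(k_float)
        if abs(k_float - k) > 1e-9:
            raise ValueError(f"target {target} for {orf} is not achievable with {n} partners (needs integer 10*k/n)")
        pool = sorted(p for p in sub.partners if p not in net.orf_roster and roster_degree.get(p, 0) == 1)
        if k > len(pool):
            raise ValueError(f"target {target} for {orf} needs {k} flaggable partners, only {len(pool)} available")
        flagged.update(rng.choice(pool, size=k, replace=False)) if k else None
    return HallmarkAnnotation(associated=flagged, source_tag="synthetic")


def draw_achievable_targets(
    subs: Sequence[Subinteractome],
    median_score: float = 2.8,
    sigma: float = 0.5,
    seed: int = DEFAULT_SEED,
    max_flaggable: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Per-ORF CH-score targets, lognormal around the requested median,
    rounded to the nearest achievable value 10*k/n for each partner count.

    ``max_flaggable`` (see :func:`flaggable_counts`) caps each ORF's
    hallmark-partner count so :func:`gen_hallmark_annotation` can always
    realize the target exactly.
    """
    rng = substream(seed, "ch_targets")
    targets: dict[str, float] = {}
    for sub in subs:
        raw = float(rng.lognormal(mean=math.log(median_score), sigma=sigma))
        cap = sub.size if max_flaggable is None else min(sub.size, max_flaggable.get(sub.orf, sub.size))
        k = int(np.clip(round(raw * sub.size / 10.0), 0, cap))
        targets[sub.orf] = 10.0 * k / sub.size
    return targets


# ---------------------------------------------------------------------------
# Paired expression matrices


@dataclass
class ExpressionPairConfig:
    """Bivariate co-expression targets for one ORF gene and its partners.

    ``rho_normal``/``rho_tumor`` give the target *Spearman* correlation of
    each partner with the ORF gene, either as a single value for all
    partners or a per-partner mapping.  Samples are drawn from a Gaussian
    copula whose latent correlation is solved from the bivariate-normal
    relation rho_s = (6/pi) * asin(rho/2), with log-normal marginals.
    """

    orf: str = "ORF0001"
    partners: tuple[str, ...] = ("PARTNER1",)
    rho_normal: float | Mapping[str, float] = 0.7
    rho_tumor: float | Mapping[str, float] = -0.6
    n_normal: int = 500
    n_tumor: int = 500
    tissue_normal: str = "synthetic-normal"
    tissue_tumor: str = "synthetic-tumor"


def latent_rho_for_spearman(rho_s: float) -> float:
    """Latent bivariate-normal correlation giving target Spearman rho_s."""
    if not -1 < rho_s < 1:
        raise ValueError("target Spearman correlation must lie in (-1, 1)")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _rho_for(partner: str, spec: float | Mapping[str, float]) -> float:
    return float(spec[partner]) if isinstance(spec, Mapping) else float(spec)


def gen_expression_pair(
    cfg: ExpressionPairConfig | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Paired normal/tumor matrices with prescribed ORF-partner rank correlations."""
    cfg = cfg or ExpressionPairConfig()
    ledger: dict = {"latent": {}, "seed": seed}
    matrices = {}
    for condition, n, rho_spec, tissue in (
        ("normal", cfg.n_normal, cfg.rho_normal, cfg.tissue_normal),
        ("tumor", cfg.n_tumor, cfg.rho_tumor, cfg.tissue_tumor),
    ):
        if n < 10:
            raise ValueError("need at least 10 samples per condition")
        rng = substream(seed, f"expression_{condition}")
        z_orf = rng.standard_normal(n)
        rows = {cfg.orf: np.exp(z_orf)}
        for partner in cfg.partners:
            rho_s = _rho_for(partner, rho_spec)
            rho = latent_rho_for_spearman(rho_s)
            z = rho * z_orf + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
            rows[partner] = np.exp(z)
            ledger["latent"][(partner, condition)] = rho
        df = pd.DataFrame(rows, index=[f"{condition[0].upper()}{i:04d}" for i in range(n)]).T
        matrices[condition] = ExpressionMatrix(data=df, condition=condition, tissue=tissue)
    return matrices["normal"], matrices["tumor"], ledger


# ---------------------------------------------------------------------------
# Survival cohort


@dataclass
class SurvivalCohortConfig:
    """Proportional-hazards cohort with a planted high-risk group.

    Event times are exponential with rate ``baseline_hazard`` for the low
    group and ``baseline_hazard * true_hr`` for the high group; censoring is
    administrative-uniform on [0, T_max] with T_max solved numerically for
    the requested overall censoring fraction.  Signature-gene expression is
    shifted upward in the high group so a median split on the signature
    score recovers the planted labels.
    """

    n_patients: int = 500
    true_hr: float = 2.0
    baseline_hazard: float = 1.0 / 24.0  # events per month; median ~16.6 months
    censor_fraction: float = 0.2
    group_shift: float = 3.0  # SD units separating high from low expression
    n_noise_genes: int = 5
    endpoint: str = "OS"


def _censoring_horizon(lam_low: float, lam_high: float, frac: float) -> float:
    """T_max of U(0, T_max) censoring giving the requested censor fraction."""

    def censored_prob(t_max: float) -> float:
        # P(T > C) with C ~ U(0, t_max), T an equal mixture of exponentials
        part = 0.0
        for lam in (lam_low, lam_high):
            part += 0.5 * (1.0 - math.exp(-lam * t_max)) / (lam * t_max)
        return part

    lo, hi = 1e-6, 1e7
    return brentq(lambda t: censored_prob(t) - frac, lo, hi)


def gen_survival_cohort(
    cfg: SurvivalCohortConfig | None = None,
    signature_genes: Sequence[str] = ("SIG1", "SIG2"),
    seed: int = DEFAULT_SEED,
) -> tuple[SurvivalCohort, dict]:
    cfg = cfg or SurvivalCohortConfig()
    rng = substream(seed, "survival_cohort")
    n = cfg.n_patients
    signature_genes = [g.upper() for g in signature_genes]

    high = np.zeros(n, dtype=bool)
    high[rng.permutation(n)[: n // 2]] = True

    lam_low = cfg.baseline_hazard
    lam_high = cfg.baseline_hazard * cfg.true_hr
    t_event = np.where(
        high,
        rng.exponential(1.0 / lam_high, size=n),
        rng.exponential(1.0 / lam_low, size=n),
    )
    if cfg.censor_fraction > 0:
        t_max = _censoring_horizon(lam_low, lam_high, cfg.censor_fraction)
        t_censor = rng.uniform(0.0, t_max, size=n)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
    else:
        t_max = math.inf
        time = t_event
        event = np.ones(n, dtype=int)

    patients = [f"PT{i:05d}" for i in range(n)]
    rows = {}
    for g in signature_genes:
        rows[g] = rng.standard_normal(n) + cfg.group_shift * high
    for i in range(cfg.n_noise_genes):
        rows[f"NOISE{i + 1}"] = rng.standard_normal(n)
    expression = pd.DataFrame(rows, index=patients).T

    cohort = SurvivalCohort(
        patient_ids=patients,
        time=time,
        event=event,
        expression=expression,
        endpoint=cfg.endpoint,
    )
    ledger = {
        "true_high": high,
        "true_hr": cfg.true_hr,
        "baseline_hazard": cfg.baseline_hazard,
        "censor_horizon": t_max,
        "signature_genes": signature_genes,
        "seed": seed,
    }
    return cohort, ledger


# ---------------------------------------------------------------------------
# DE matrix


@dataclass
class DEBlockSpec:
    """A block of genes sharing the same DE call in a set of cancers.

    ``direction`` is "up", "down" or "mixed" (alternating up/down across the
    listed cancers).
    """

    cancers: tuple[str, ...]
    n_genes: int
    direction: str = "up"
    name: str = ""


#: Cancer codes used by the default DE-matrix configuration.
DEFAULT_CANCERS: tuple[str, ...] = (
    "TGCT", "LAML", "DLBC", "THYM", "SKCM", "LUSC", "LUAD", "GBM", "UCEC",
    "UCS", "OV", "BRCA", "KICH", "KIRC", "KIRP", "COAD", "READ", "PAAD", "ESCA",
)


def _default_blocks() -> tuple[DEBlockSpec, ...]:
    return (
        DEBlockSpec(("DLBC", "THYM"), 68, "up", name="cluster1"),
        DEBlockSpec(("UCEC",), 16, "up", name="cluster2_ucec"),
        DEBlockSpec(("OV",), 11, "up", name="cluster2_ov"),
        DEBlockSpec(("COAD",), 9, "up", name="cluster2_coad"),
        DEBlockSpec(("READ",), 12, "up", name="cluster2_read"),
        DEBlockSpec(("TGCT",), 100, "down", name="tgct_exclusive"),
        DEBlockSpec(("TGCT", "SKCM"), 24, "down", name="tgct_shared"),
        DEBlockSpec(("LAML",), 23, "up", name="laml_up"),
        DEBlockSpec(("TGCT", "SKCM", "KICH", "KIRC", "KIRP", "PAAD"), 3, "down", name="pan_down"),
        DEBlockSpec(("DLBC", "THYM", "LAML", "UCEC", "OV", "COAD"), 4, "up", name="pan_up"),
        DEBlockSpec(("TGCT", "LAML", "DLBC", "SKCM", "UCEC", "OV"), 4, "mixed", name="pan_mixed"),
    )


@dataclass
class DEMatrixConfig:
    """Sparse gene x cancer DE matrix with planted block structure.

    Defaults emulate the study's pattern: one cancer pair sharing a large
    up-regulated block, several single-cancer blocks, one cancer with an
    exclusive 100-gene down-regulated block, and a small pan-cancer group
    (genes called in >= 5 cancers).  Missing cells are confined to
    otherwise non-significant cells so the planted structure stays intact.
    """

    cancers: tuple[str, ...] = DEFAULT_CANCERS
    blocks: tuple[DEBlockSpec, ...] = field(default_factory=_default_blocks)
    n_extra_genes: int = 10
    missing_fraction: float = 0.10
    fc_threshold: float = 2.0
    p_cut: float = 0.05


def gen_de_matrix(
    cfg: DEMatrixConfig | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[DECallMatrix, dict]:
    cfg = cfg or DEMatrixConfig()
    rng = substream(seed, "de_matrix")
    cancers = list(cfg.cancers)
    n_genes = sum(b.n_genes for b in cfg.blocks) + cfg.n_extra_genes
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]

    # background: guaranteed non-significant (p >= p_cut)
    log2fc = rng.uniform(-1.5, 1.5, size=(n_genes, len(cancers)))
    p = rng.uniform(cfg.p_cut, 1.0, size=(n_genes, len(cancers)))

    block_genes: dict[str, list[str]] = {}
    row = 0
    for bi, block in enumerate(cfg.blocks):
        name = block.name or f"block{bi}"
        members = genes[row : row + block.n_genes]
        block_genes[name] = members
        for gi in range(row, row + block.n_genes):
            for ci, cancer in enumerate(block.cancers):
                j = cancers.index(cancer)
                if block.direction == "mixed":
                    direction = "up" if ci % 2 == 0 else "down"
                else:
                    direction = block.direction
                magnitude = rng.uniform(cfg.fc_threshold + 0.5, cfg.fc_threshold + 4.0)
                log2fc[gi, j] = magnitude if direction == "up" else -magnitude
                p[gi, j] = rng.uniform(1e-8, cfg.p_cut / 5.0)
        row += block.n_genes

    if cfg.missing_fraction > 0:
        planted = np.zeros((n_genes, len(cancers)), dtype=bool)
        row = 0
        for block in cfg.blocks:
            for cancer in block.cancers:
                planted[row : row + block.n_genes, cancers.index(cancer)] = True
            row += block.n_genes
        candidates = np.argwhere(~planted)
        n_missing = int(round(cfg.missing_fraction * n_genes * len(cancers)))
        n_missing = min(n_missing, len(candidates))
        picks = candidates[rng.choice(len(candidates), size=n_missing, replace=False)]
        log2fc[picks[:, 0], picks[:, 1]] = np.nan
        p[picks[:, 0], picks[:, 1]] = np.nan

    matrix = DECallMatrix(
        genes=genes,
        cancers=cancers,
        log2fc=log2fc,
        p=p,
        fc_threshold=cfg.fc_threshold,
        p_cut=cfg.p_cut,
    )
    ledger = {"block_genes": block_genes, "seed": seed}
    return matrix, ledger
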