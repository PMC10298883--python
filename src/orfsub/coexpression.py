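"""Differential co-expression classification of protein-protein interactions.

For each target-protein / partner gene pair, Spearman rank correlations are
computed separately in a normal-tissue and a matched tumor expression matrix.
Interactions are then classified by the sign shift between conditions:

* ``cancer_dependent`` — strong positive co-expression appears in the tumor
  (r_tumor >= r_thr, significant) where the normal tissue showed none;
* ``perturbed_by_cancer`` — strong positive co-expression in normal tissue
  (r_normal >= r_thr, significant) collapses to near zero or negative in the
  tumor (r_tumor <= near_zero);
* ``concordant`` — strong and significant in both conditions;
* ``unclassified`` — anything else.

Very high correlation in either condition (r >= 0.85) is additionally
flagged as a hint of a direct physical interaction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Correlation magnitude taken as a hint of a direct physical interaction.
DIRECT_HINT_R = 0.85


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one (tissue, condition)."""

    data: pd.DataFrame  # index: gene symbols, columns: sample ids
    condition: str  # "normal" or "tumor"
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.condition not in {"normal", "tumor"}:
            raise ValueError(f"condition must be 'normal' or 'tumor', got {self.condition!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        self.data = self.data.copy()
        self.data.index = [g.strip().upper() for g in self.data.index]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_tsv(cls, path, condition: str, tissue: str = "") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=df, condition=condition, tissue=tissue)


@dataclass
class CoexpressionRecord:
    """One ORF-partner pair with per-condition correlations and a label."""

    orf: str
    partner: str
    r_normal: float
    r_tumor: float
    p_normal: float
    p_tumor: float
    n_normal: int
    n_tumor: int
    tissue_normal: str = ""
    tissue_tumor: str = ""
    label: str = "unclassified"
    direct_hint: bool = False


def spearman(x: Sequence[float], y: Sequence[float], method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties averaged).  With
    ``method="t"`` the p-value comes from the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom; with
    ``method="exact"`` (n <= 9 only) it is the exact permutation tail
    P(|rho_perm| >= |rho|).  |rho| = 1 is reported with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")

    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0 - 1e-12:
        return float(np.sign(rho)), 0.0

    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p-value is limited to n <= 9")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(_rank_pearson(rx, ry))
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            if abs(_rank_pearson(rx, np.array(perm))) >= observed - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if method != "t":
        raise ValueError(f"unknown p-value method {method!r}")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def classify_ppi(
    rec: CoexpressionRecord,
    r_thr: float = 0.5,
    near_zero: float = 0.2,
    p_thr: float = 0.05,
) -> CoexpressionRecord:
    """Assign a sign-shift label and the direct-interaction hint.

    Returns a new record; the four labels are exhaustive and mutually
    exclusive (checked in order: cancer_dependent, perturbed_by_cancer,
    concordant, unclassified — the first two cannot co-fire because
    near_zero < r_thr).
    """
    if rec.r_tumor >= r_thr and rec.p_tumor < p_thr and rec.r_normal < r_thr:
        label = "cancer_dependent"
    elif rec.r_normal >= r_thr and rec.p_normal < p_thr and rec.r_tumor <= near_zero:
        label = "perturbed_by_cancer"
    elif rec.r_normal >= r_thr and rec.p_normal < p_thr and rec.r_tumor >= r_thr and rec.p_tumor < p_thr:
        label = "concordant"
    else:
        label = "unclassified"
    return replace(
        rec,
        label=label,
        direct_hint=max(rec.r_normal, rec.r_tumor) >= DIRECT_HINT_R,
    )


def coexpr_table(
    orf: str,
    partners: Sequence[str],
    normal: ExpressionMatrix,
    tumor: ExpressionMatrix,
    r_thr: float = 0.5,
    near_zero: float = 0.2,
    p_thr: float = 0.05,
) -> list[CoexpressionRecord]:
    """Per-partner classified co-expression records for one target protein.

    Partners missing from either matrix are skipped with a warning; a target
    gene missing from a matrix is a fatal error.
    """
    orf = orf.strip().upper()
    for mat, name in ((normal, "normal"), (tumor, "tumor")):
        if orf not in mat.data.index:
            raise KeyError(f"target gene {orf!r} is absent from the {name} matrix")
    xn = normal.data.loc[orf].to_numpy(dtype=float)
    xt = tumor.data.loc[orf].to_numpy(dtype=float)

    records: list[CoexpressionRecord] = []
    for partner in partners:
        partner = partner.strip().upper()
        if partner not in normal.data.index or partner not in tumor.data.index:
            logger.warning("partner %s missing from an expression matrix, skipped", partner)
            continue
        rn, pn = spearman(xn, normal.data.loc[partner].to_numpy(dtype=float))
        rt, pt = spearman(xt, tumor.data.loc[partner].to_numpy(dtype=float))
        rec = CoexpressionRecord(
            orf=orf,
            partner=partner,
            r_normal=rn,
            r_tumor=rt,
            p_normal=pn,
            p_tumor=pt,
            n_normal=normal.n_samples,
            n_tumor=tumor.n_samples,
            tissue_normal=normal.tissue,
            tissue_tumor=tumor.tissue,
        )
        records.append(classify_ppi(rec, r_thr=r_thr, near_zero=near_zero, p_thr=p_thr))
    return records


def classification_summary(records: Sequence[CoexpressionRecord]) -> dict[str, float | int | dict[str, int]]:
    """Label counts per row and per unique unordered pair.

    Both per-row and per-unique-pair cancer-dependent fractions are reported
    because a pair may recur across tissue contexts with different labels.
    """
    per_row: dict[str, int] = {}
    for rec in records:
        per_row[rec.label] = per_row.get(rec.label, 0) + 1
    unique: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        key = tuple(sorted((rec.orf, rec.partner)))
        unique.setdefault(key, set()).add(rec.label)
    n_rows = len(records)
    n_pairs = len(unique)
    dep_rows = per_row.get("cancer_dependent", 0)
    dep_pairs = sum(1 for labels in unique.values() if "cancer_dependent" in labels)
    return {
        "n_records": n_rows,
        "n_unique_pairs": n_pairs,
        "counts": per_row,
        "cancer_dependent_fraction_rows": dep_rows / n_rows if n_rows else 0.0,
        "cancer_dependent_fraction_pairs": dep_pairs / n_pairs if n_pairs else 0.0,
    }
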