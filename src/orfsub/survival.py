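"""Kaplan-Meier evaluation of multi-gene expression signatures.

A cohort (per-patient follow-up time, event indicator and gene expression) is
scored with a signature (mean expression or mean z-score over the panel),
split at the median score into low/high groups, and compared with the
two-group log-rank test.  The hazard ratio is the observed/expected ratio
from the log-rank ledger, ``HR = (O_high/E_high) / (O_low/E_low)``, with a
log-scale normal confidence interval — the classic KM-plot-style estimate,
approximate relative to a Cox fit.  Quantile survival times (median,
upper-quartile) are read off the product-limit curve.  An ablation search
identifies a minimal "decisive" gene subset whose removal destroys the
signature's prognostic significance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Per-patient survival endpoints plus a gene x patient expression matrix."""

    patient_ids: list[str]
    time: np.ndarray  # months, >= 0
    event: np.ndarray  # 1 = event observed, 0 = censored
    expression: pd.DataFrame  # index: gene symbols, columns: patient ids
    endpoint: str = "OS"  # label only: OS or DFS

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        if not (self.time.shape == (n,) and self.event.shape == (n,)):
            raise ValueError("time/event length must match patient count")
        if (self.time < 0).any():
            raise ValueError("times must be >= 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if list(self.expression.columns) != list(self.patient_ids):
            self.expression = self.expression[self.patient_ids]

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @classmethod
    def from_tsv(cls, path, endpoint: str = "OS") -> "SurvivalCohort":
        """Read a TSV with columns patient, time_months, event, then genes."""
        df = pd.read_csv(path, sep="\t")
        required = {"patient", "time_months", "event"}
        if not required.issubset(df.columns):
            raise ValueError(f"survival TSV must have columns {sorted(required)}")
        gene_cols = [c for c in df.columns if c not in required]
        return cls(
            patient_ids=[str(p) for p in df["patient"]],
            time=df["time_months"].to_numpy(float),
            event=df["event"].to_numpy(int),
            expression=pd.DataFrame(
                df[gene_cols].to_numpy(float).T,
                index=[g.upper() for g in gene_cols],
                columns=[str(p) for p in df["patient"]],
            ),
            endpoint=endpoint,
        )


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class LogrankResult:
    chi2: float
    p: float
    o_low: float
    e_low: float
    o_high: float
    e_high: float


@dataclass
class SignatureResult:
    """KM/log-rank evaluation of one gene panel on one cohort."""

    genes: list[str]
    split_rule: str
    hr: float
    hr_ci: tuple[float, float]
    logrank_chi2: float
    p: float
    quantile_survival_low: float | None
    quantile_survival_high: float | None
    n_low: int
    n_high: int
    o_low: float = 0.0
    e_low: float = 0.0
    o_high: float = 0.0
    e_high: float = 0.0


def signature_score(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    method: str = "mean_z",
) -> np.ndarray:
    """Per-patient signature score: mean z-score or mean raw expression."""
    genes = [g.strip().upper() for g in genes]
    for g in genes:
        if g not in cohort.expression.index:
            raise KeyError(f"gene {g!r} is absent from the cohort expression matrix")
    mat = cohort.expression.loc[genes].to_numpy(dtype=float)
    if method == "mean_raw":
        return mat.mean(axis=0)
    if method == "mean_z":
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=0, keepdims=True)
        if (sd == 0).any():
            raise ValueError("constant gene expression: z-score undefined")
        return ((mat - mu) / sd).mean(axis=0)
    raise ValueError(f"unknown scoring method {method!r}")


def split_groups(score: Sequence[float], rule: str = "median") -> np.ndarray:
    """Median split into labels 'low'/'high'; median ties go to 'low'."""
    score = np.asarray(score, dtype=float)
    if score.size < 4:
        raise ValueError("need at least 4 patients to split")
    if rule != "median":
        raise ValueError(f"unknown split rule {rule!r}")
    med = float(np.median(score))
    labels = np.where(score > med, "high", "low")
    if len(set(labels)) < 2:
        raise ValueError("cannot split: score has no variation around the median")
    return labels


def km_curve(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Subjects censored exactly at an event time are still counted at risk for
    that event (standard convention).  An all-censored input yields a flat
    curve at 1 with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if event.sum() == 0:
        logger.warning("all subjects censored: survival curve is flat at 1")
        return KMCurve(
            event_times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([], dtype=int),
            events=np.array([], dtype=int),
        )
    etimes = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in etimes])
    deaths = np.array([((time == t) & (event == 1)).sum() for t in etimes])
    survival = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(event_times=etimes, survival=survival, at_risk=at_risk, events=deaths)


def quantile_survival(curve: KMCurve, q: float) -> float | None:
    """Smallest event time at which S(t) drops to 1-q or below.

    ``q`` is the cumulative event fraction: q=0.5 gives the median survival
    time (first t with S <= 0.5), q=0.25 the upper-quartile survival time
    (first t with S <= 0.75).  Returns None when the curve never crosses.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    threshold = 1.0 - q
    crossing = np.nonzero(curve.survival <= threshold + 1e-12)[0]
    if crossing.size == 0:
        return None
    return float(curve.event_times[crossing[0]])


def logrank(
    time: Sequence[float],
    event: Sequence[int],
    labels: Sequence[str],
) -> LogrankResult:
    """Two-group log-rank test with the O/E ledger.

    At each distinct event time the expected events per group are
    proportional to the group's share of subjects at risk; the statistic is
    (O - E)^2 / V with the hypergeometric variance summed over event times,
    referred to a chi-square with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {groups.size}")
    is_low = labels == ("low" if "low" in groups else groups[0])

    etimes = np.unique(time[event == 1])
    o_low = e_low = var = 0.0
    for t in etimes:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & is_low).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & is_low).sum()
        o_low += d1
        e_low += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    o_total = float(event.sum())
    o_high = o_total - o_low
    e_high = o_total - e_low
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_low - e_low) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi2=float(chi2), p=p, o_low=float(o_low), e_low=float(e_low), o_high=float(o_high), e_high=float(e_high))


def hazard_ratio(
    o_low: float,
    e_low: float,
    o_high: float,
    e_high: float,
    z: float = 1.96,
) -> tuple[float, float, float]:
    """O/E hazard ratio of high vs low with a log-scale normal CI.

    ``HR = (O_high/E_high) / (O_low/E_low)``;
    ``CI = exp(ln HR +/- z * sqrt(1/E_low + 1/E_high))``.
    """
    if e_low <= 0 or e_high <= 0:
        raise ValueError("hazard ratio undefined with zero expected events")
    if o_low == 0 or o_high == 0:
        raise ValueError("hazard ratio undefined with zero observed events in a group")
    hr = (o_high / e_high) / (o_low / e_low)
    se = math.sqrt(1.0 / e_low + 1.0 / e_high)
    return hr, hr * math.exp(-z * se), hr * math.exp(z * se)


def evaluate_signature(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    score_method: str = "mean_z",
    split_rule: str = "median",
    quantile: float = 0.25,
) -> SignatureResult:
    """Score -> median split -> log-rank -> HR -> per-group quantile survival."""
    score = signature_score(cohort, genes, method=score_method)
    labels = split_groups(score, rule=split_rule)
    lr = logrank(cohort.time, cohort.event, labels)
    hr, lo, hi = hazard_ratio(lr.o_low, lr.e_low, lr.o_high, lr.e_high)
    q_low = quantile_survival(km_curve(cohort.time[labels == "low"], cohort.event[labels == "low"]), quantile)
    q_high = quantile_survival(km_curve(cohort.time[labels == "high"], cohort.event[labels == "high"]), quantile)
    return SignatureResult(
        genes=[g.strip().upper() for g in genes],
        split_rule=split_rule,
        hr=hr,
        hr_ci=(lo, hi),
        logrank_chi2=lr.chi2,
        p=lr.p,
        quantile_survival_low=q_low,
        quantile_survival_high=q_high,
        n_low=int((labels == "low").sum()),
        n_high=int((labels == "high").sum()),
        o_low=lr.o_low,
        e_low=lr.e_low,
        o_high=lr.o_high,
        e_high=lr.e_high,
    )


@dataclass
class AblationResult:
    """Minimal decisive subset whose removal breaks significance."""

    decisive: list[str]
    p_full: float
    p_reduced: float | None
    status: str  # "found" or "not_found"


def ablation(
    cohort: SurvivalCohort,
    signature: Sequence[str],
    strategy: str = "greedy",
    alpha: float = 0.05,
    max_subset: int = 7,
    score_method: str = "mean_z",
) -> AblationResult:
    """Find a minimal gene subset D with evaluate(signature \\ D).p > alpha.

    ``greedy`` removes genes in decreasing order of single-gene log-rank
    strength, re-testing after each removal; ``exhaustive_k`` enumerates
    subsets up to ``max_subset`` genes by increasing size.  The full panel
    must itself be significant (p < alpha).
    """
    genes = [g.strip().upper() for g in signature]
    full = evaluate_signature(cohort, genes, score_method=score_method)
    if full.p >= alpha:
        raise ValueError(f"full signature is not significant (p={full.p:.3g} >= alpha={alpha})")

    def reduced_p(removed: Sequence[str]) -> float | None:
        rest = [g for g in genes if g not in set(removed)]
        if len(rest) == 0:
            return None
        try:
            return evaluate_signature(cohort, rest, score_method=score_method).p
        except (ValueError, KeyError):
            return None

    if strategy == "greedy":
        strength = []
        for g in genes:
            try:
                strength.append((evaluate_signature(cohort, [g], score_method=score_method).logrank_chi2, g))
            except ValueError:
                strength.append((0.0, g))
        order = [g for _, g in sorted(strength, reverse=True)]
        removed: list[str] = []
        for g in order[:max_subset]:
            removed.append(g)
            p = reduced_p(removed)
            if p is not None and p > alpha:
                return AblationResult(decisive=sorted(removed), p_full=full.p, p_reduced=p, status="found")
        return AblationResult(decisive=[], p_full=full.p, p_reduced=None, status="not_found")

    if strategy == "exhaustive_k":
        for k in range(1, min(max_subset, len(genes) - 1) + 1):
            for combo in itertools.combinations(genes, k):
                p = reduced_p(combo)
                if p is not None and p > alpha:
                    return AblationResult(decisive=sorted(combo), p_full=full.p, p_reduced=p, status="found")
        return AblationResult(decisive=[], p_full=full.p, p_reduced=None, status="not_found")

    raise ValueError(f"unknown ablation strategy {strategy!r}")
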