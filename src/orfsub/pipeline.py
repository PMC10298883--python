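"""End-to-end orchestration: aggregate -> score -> coexpr -> survive -> express.

``run_pipeline`` executes whichever stages its configuration provides inputs
for, either from files or from the synthetic generators, and assembles a
consolidated JSON-serializable report: the prioritized target-protein list,
the classified PPI table, signature evaluations and DE/PCA summaries.  Every
stage records its parameters and filter bookkeeping (input count = output
count + excluded count) so each reported number is auditable, and the whole
report is deterministic given the inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from orfsub import coexpression, expression, hallmark_scoring, interactome, survival
from orfsub import synthetic_data as synth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = synth.DEFAULT_SEED
    out_dir: str | None = None
    synthetic: bool = True
    # interactome stage
    interaction_files: list[dict] = field(default_factory=list)  # {path, dialect}
    roster_path: str | None = None
    min_size: int = 7
    max_size: int = 100
    # hallmark stage
    hallmark_path: str | None = None
    ch_threshold: float = 2.0
    count_self: bool = True
    # coexpression stage
    coexpr: dict = field(default_factory=dict)  # {orf, partners, normal_path, tumor_path}
    r_thr: float = 0.5
    near_zero: float = 0.2
    p_thr: float = 0.05
    # survival stage
    survival_path: str | None = None
    signature_genes: list[str] = field(default_factory=list)
    alpha: float = 0.05
    # expression stage
    de_path: str | None = None
    fc_threshold: float = 2.0
    p_cut: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _bookkeep(n_in: int, n_out: int) -> dict[str, int]:
    record = {"input": n_in, "output": n_out, "excluded": n_in - n_out}
    assert record["input"] == record["output"] + record["excluded"]
    return record


def _interactome_stage(cfg: PipelineConfig, report: dict) -> tuple[interactome.AggregatedNetwork, list]:
    if cfg.synthetic:
        net, ledger = synth.gen_ppi_network(seed=cfg.seed)
        n_records = sum(len(s) for s in net.edges.values())
        skipped = 0
    else:
        lists = []
        skipped = 0
        for spec in cfg.interaction_files:
            parsed = interactome.parse_interactions(spec["path"], dialect=spec.get("dialect", "tsv_edges"))
            lists.append(parsed.records)
            skipped += parsed.n_skipped
        roster = [
            line.strip()
            for line in Path(cfg.roster_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        net = interactome.aggregate(lists, roster)
        n_records = sum(len(r) for r in lists)

    census = interactome.partner_census(net)
    connected = sorted(net.orf_roster - census.orphan_orfs)
    subs = [interactome.subinteractome(net, orf) for orf in connected]
    hist = interactome.size_histogram(subs)
    selected = interactome.select_by_size(subs, cfg.min_size, cfg.max_size)

    report["interactome"] = {
        "params": {"min_size": cfg.min_size, "max_size": cfg.max_size, "synthetic": cfg.synthetic},
        "n_parsed_records": n_records,
        "n_skipped_lines": skipped,
        "n_unique_edges": net.n_edges,
        "n_orf_orf_edges": len(census.orf_orf_edges),
        "n_orphan_orfs": len(census.orphan_orfs),
        "n_shared_by_two": len(census.shared_by_two),
        "n_shared_by_three_plus": len(census.shared_by_three_plus),
        "size_histogram": hist,
        "size_filter": _bookkeep(len(subs), len(selected)),
    }
    return net, selected


def _hallmark_stage(cfg: PipelineConfig, net, selected, report: dict) -> None:
    if cfg.synthetic:
        targets = synth.draw_achievable_targets(
            selected, seed=cfg.seed, max_flaggable=synth.flaggable_counts(net, selected)
        )
        ann = synth.gen_hallmark_annotation(net, targets, seed=cfg.seed)
    elif cfg.hallmark_path:
        ann = hallmark_scoring.HallmarkAnnotation.from_file(cfg.hallmark_path)
    else:
        return
    reports = [hallmark_scoring.ch_score(s, ann, count_self=cfg.count_self) for s in selected if s.size > 0]
    if not reports:
        report["hallmark_scoring"] = {
            "params": {"threshold": cfg.ch_threshold, "count_self": cfg.count_self},
            "prioritization": _bookkeep(0, 0),
            "prioritized_orfs": [],
        }
        return
    chosen, summary = hallmark_scoring.prioritize(reports, threshold=cfg.ch_threshold)
    report["hallmark_scoring"] = {
        "params": {"threshold": cfg.ch_threshold, "count_self": cfg.count_self},
        "median_score": summary.median,
        "percentile_25": summary.percentile_25,
        "prioritization": _bookkeep(summary.n_total, summary.n_selected),
        "prioritized_orfs": sorted(r.orf for r in chosen),
    }


def _coexpression_stage(cfg: PipelineConfig, report: dict) -> None:
    if cfg.synthetic:
        normal, tumor, _ = synth.gen_expression_pair(seed=cfg.seed)
        orf, partners = "ORF0001", ["PARTNER1"]
    elif cfg.coexpr:
        normal = coexpression.ExpressionMatrix.from_tsv(cfg.coexpr["normal_path"], "normal")
        tumor = coexpression.ExpressionMatrix.from_tsv(cfg.coexpr["tumor_path"], "tumor")
        orf = cfg.coexpr["orf"]
        partners = cfg.coexpr.get("partners") or [g for g in normal.genes if g != orf.upper()]
    else:
        return
    records = coexpression.coexpr_table(
        orf, partners, normal, tumor, r_thr=cfg.r_thr, near_zero=cfg.near_zero, p_thr=cfg.p_thr
    )
    summary = coexpression.classification_summary(records)
    report["coexpression"] = {
        "params": {"r_thr": cfg.r_thr, "near_zero": cfg.near_zero, "p_thr": cfg.p_thr},
        "pairs": _bookkeep(len(partners), len(records)),
        **summary,
    }


def _survival_stage(cfg: PipelineConfig, report: dict) -> None:
    if cfg.synthetic:
        cohort, ledger = synth.gen_survival_cohort(seed=cfg.seed)
        genes = ledger["signature_genes"]
    elif cfg.survival_path:
        cohort = survival.SurvivalCohort.from_tsv(cfg.survival_path)
        genes = cfg.signature_genes or list(cohort.expression.index)
    else:
        return
    result = survival.evaluate_signature(cohort, genes)
    report["survival"] = {
        "params": {"genes": result.genes, "split_rule": result.split_rule, "alpha": cfg.alpha},
        "n_patients": cohort.n_patients,
        "hr": result.hr,
        "hr_ci": list(result.hr_ci),
        "logrank_chi2": result.logrank_chi2,
        "p": result.p,
        "significant": bool(result.p < cfg.alpha),
        "quantile_survival_low": result.quantile_survival_low,
        "quantile_survival_high": result.quantile_survival_high,
        "n_low": result.n_low,
        "n_high": result.n_high,
    }


def _expression_stage(cfg: PipelineConfig, report: dict) -> None:
    if cfg.synthetic:
        calls, _ = synth.gen_de_matrix(seed=cfg.seed)
    elif cfg.de_path:
        calls = expression.DECallMatrix.from_long_tsv(cfg.de_path, cfg.fc_threshold, cfg.p_cut)
    else:
        return
    groups = expression.pan_cancer_group(calls)
    pca = expression.pca_svd_impute(calls.signed_matrix().T, n_components=2)
    report["expression"] = {
        "params": {"fc_threshold": cfg.fc_threshold, "p_cut": cfg.p_cut, "encoding": "ternary"},
        "n_genes": len(calls.genes),
        "n_cancers": len(calls.cancers),
        "pan_cancer": _bookkeep(len(calls.genes), len(groups)),
        "pan_cancer_categories": {
            cat: sum(1 for v in groups.values() if v == cat)
            for cat in ("preferentially_up", "preferentially_down", "mixed")
        },
        "pca_variance_explained": [float(v) for v in pca.variance_explained],
        "pca_n_imputed": pca.n_imputed,
    }


def report_hash(report: dict) -> str:
    """SHA-256 of the canonical JSON serialization of a report."""
    blob = json.dumps(report, sort_keys=True, default=_jsonable).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages and return the consolidated report."""
    report: dict = {"seed": cfg.seed, "config": dataclasses.asdict(cfg)}
    stage = "interactome"
    try:
        net, selected = _interactome_stage(cfg, report)
        stage = "hallmark_scoring"
        _hallmark_stage(cfg, net, selected, report)
        stage = "coexpression"
        _coexpression_stage(cfg, report)
        stage = "survival"
        _survival_stage(cfg, report)
        stage = "expression"
        _expression_stage(cfg, report)
    except Exception as exc:
        report["failed_stage"] = stage
        _write_report(cfg, report)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["report_hash"] = report_hash(report)
    _write_report(cfg, report)
    return report


def _write_report(cfg: PipelineConfig, report: dict) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable), encoding="utf-8"
    )
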