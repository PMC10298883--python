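# orfsub

Subinteractome prioritization for uncharacterized human ORF proteins.

About 10% of predicted human proteins — many of them chromosome-specific
open-reading-frame (CxORFx, "ORF") gene products — have essentially no
functional annotation, yet a sizeable group of them is differentially
expressed across cancers. One productive way to study such a protein is
through its *subinteractome*: the set of all annotated protein partners
known to physically interact with it. If that neighborhood is dense in
proteins associated with the hallmarks of cancer, the uncharacterized
protein itself becomes a candidate cancer-associated gene.

`orfsub` implements that analysis as a tested, reusable pipeline for
computational biologists:

1. **Interactome aggregation** — parse PSI-MITAB or plain edge-list files
   from multiple interaction databases, deduplicate them into one undirected
   physical-PPI network with per-edge source provenance, extract per-protein
   subinteractomes, and run the partner-sharing censuses (ORF–ORF edges,
   partners shared by exactly two or by three-plus target proteins, orphan
   targets, subinteractome-size histogram and the [7, 100] size filter).
2. **Cancer-hallmark scoring** — the CH-score of a subinteractome with
   `n` partners of which `k` are hallmark-associated is
   `CH = 10 k / n`, the hallmark density per 10 partners; subinteractomes
   are prioritized at `CH >= 2`. Partner sets can be tested for gene-set
   over-representation with the hypergeometric upper tail,
   Benjamini–Hochberg FDR (< 0.1) and a > 10%-coverage rule.
3. **Differential co-expression** — Spearman correlation `r` of an ORF gene
   with each partner gene, computed separately in matched normal and tumor
   expression matrices; each protein pair is classified by the sign shift:
   *cancer-dependent* (`r_tumor >= 0.5`, significant, while
   `r_normal < 0.5`), *perturbed by cancer* (`r_normal >= 0.5`, significant,
   while `r_tumor <= 0.2`), *concordant*, or unclassified. `r >= 0.85` in
   either condition is flagged as a hint of a direct physical interaction.
4. **Survival signatures** — per-patient signature scores (mean z-score over
   a gene panel), a median split into low/high groups, the Kaplan–Meier
   product-limit curve `S(t) = prod (1 - d_i/n_i)`, the two-group log-rank
   test, the O/E hazard ratio
   `HR = (O_high/E_high)/(O_low/E_low)` with
   `CI = exp(ln HR ± 1.96 sqrt(1/E_low + 1/E_high))`, quantile (median and
   upper-quartile) survival times, and an ablation search for the minimal
   "decisive" gene subset whose removal destroys significance.
5. **Expression patterns** — ternary differential-expression calls
   (`|log2FC| >= 2` and `p < 0.05`), cancer-specific and pan-cancer
   (>= 5 cancers) gene grouping, and PCA of the gene × cancer call matrix by
   iterative SVD imputation of missing cells (columns centered, rows
   unscaled).
6. **Synthetic data** — deterministic generators for every input: a PPI
   network with an exact planted size distribution and sharing structure,
   hallmark annotations realizing exact CH-score targets, Gaussian-copula
   expression pairs with prescribed Spearman correlations, proportional-
   hazards survival cohorts with known hazard ratio and censoring, and
   sparse DE matrices with planted cancer clusters.

## Worked example

```python
from orfsub import interactome as it, hallmark_scoring as hs, survival as sv
from orfsub import synthetic_data as synth

net, ledger = synth.gen_ppi_network(seed=1)
census = it.partner_census(net)
connected = sorted(net.orf_roster - census.orphan_orfs)
subs = [it.subinteractome(net, orf) for orf in connected]
selected = it.select_by_size(subs, min_size=7, max_size=100)
print(f"{net.n_edges} unique PPIs, {len(census.orf_orf_edges)} ORF-ORF, "
      f"{len(census.orphan_orfs)} orphan ORFs, {len(selected)}/{len(subs)} kept by the [7,100] filter")

caps = synth.flaggable_counts(net, selected)
targets = synth.draw_achievable_targets(selected, median_score=2.8, seed=1, max_flaggable=caps)
ann = synth.gen_hallmark_annotation(net, targets, seed=1)
reports = [hs.ch_score(s, ann) for s in selected]
chosen, summary = hs.prioritize(reports, threshold=2.0)
print(f"CH-score median {summary.median:.2f}, 25th percentile {summary.percentile_25:.2f}, "
      f"{summary.n_selected}/{summary.n_total} prioritized at score >= 2")

cohort, surv_ledger = synth.gen_survival_cohort(
    synth.SurvivalCohortConfig(n_patients=500, true_hr=2.0), seed=1)
res = sv.evaluate_signature(cohort, surv_ledger["signature_genes"])
print(f"HR = {res.hr:.2f} ({res.hr_ci[0]:.2f}-{res.hr_ci[1]:.2f}), "
      f"log-rank p = {res.p:.2g}, upper-quartile survival "
      f"{res.quantile_survival_low:.1f} vs {res.quantile_survival_high:.1f} months")
```

prints

```
4605 unique PPIs, 8 ORF-ORF, 42 orphan ORFs, 103/177 kept by the [7,100] filter
CH-score median 2.82, 25th percentile 1.95, 77/103 prioritized at score >= 2
HR = 1.86 (1.53-2.27), log-rank p = 3e-11, upper-quartile survival 6.8 vs 3.1 months
```

The first line is the aggregation census of a synthetic network planted with
a 219-member target roster, 177 connected members and the reference
partner-count distribution; the size filter keeps the 103 subinteractomes
with 7–100 partners. The second line shows the CH-score distribution
(median ≈ 2.8 by construction) and the fraction prioritized at the default
threshold of 2. The third line evaluates a two-gene signature on a
500-patient proportional-hazards cohort simulated with a true hazard ratio
of 2: the O/E estimate, its 95% CI, the log-rank p-value and the
upper-quartile survival time of each expression group.

A command-line interface mirrors the stages:

```bash
orfsub simulate --seed 1 --out fixtures/
orfsub aggregate --tsv fixtures/network_edges.tsv --roster fixtures/roster.txt --out net.json
orfsub survive --cohort fixtures/survival_cohort.tsv --genes SIG1,SIG2 --out sig.json
orfsub run --seed 1 --out results/
```

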