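# Methods

This note documents the statistical conventions, parameter defaults and
design choices behind `orfsub`, and what the synthetic-data generators do
and do not emulate.

## Interactome aggregation

Interaction records carry two gene symbols, a free-text source tag and the
evidence type, which must be `physical` — genetic or predicted functional
associations are outside the model. Gene identity is a case-insensitive
symbol match after whitespace stripping and uppercasing; no alias
resolution is attempted beyond the `(gene name)` aliases of PSI-MITAB
columns 5–6 (first such alias wins, lines without one on both sides are
skipped and counted). How conflicting symbols across heterogeneous source
databases should be reconciled is genuinely ambiguous, so the package
deliberately does not guess: upstream identifier mapping is the caller's
responsibility.

Edges are undirected (physical binding has no natural direction at this
resolution) and deduplicated across sources by unordered pair, with source
tags unioned. Self-loops are dropped at aggregation and counted —
homodimerization is a structural question, not a partner-census one.

**Size histogram convention.** The partner-count bins are `<7`, `[7,15)`,
`[15,30)`, `[30,70)`, `[70,100]`, `>100`: interior bins half-open on the
right, the last finite bin closed. This is the unique convention under
which the reference distribution (63, 30, 40, 27, 6, 11 subinteractomes)
and the downstream selection of 103 subinteractomes by the inclusive
`[7, 100]` filter are mutually consistent. The filter bounds are inclusive
on both ends: the minimum of 7 partners gives enrichment analysis enough
genes to work with; the cap of 100 limits term redundancy for very large
neighborhoods.

Shortest paths between target proteins use unweighted breadth-first search
(via networkx); length 1 is a direct interaction, unreachable pairs report
infinite length.

## CH-score and prioritization

The cancer-hallmark score of a subinteractome with `n` partners, `k` of
them hallmark-associated, is `CH = 10 k / n` — hallmark-associated proteins
per 10 partners. Hallmark association is consumed as a binary annotation
list; the graph-path inference that produces such lists in public resources
is not reimplemented.

The target protein itself may be hallmark-associated; by default
(`count_self=True`) it then adds 1 to the numerator while the denominator
remains the partner count, so the score can slightly exceed 10. Both
settings reproduce the canonical worked example (one associated protein
among 10 partners → score exactly 1), and the flag exists because the
self-count is an interpretive choice, not a mathematical necessity.

Prioritization keeps reports with score ≥ threshold (default 2.0, treated
as a free parameter). The summary reports the median and 25th percentile
using linear interpolation between order statistics (numpy's default,
type-7); only a convention had to be fixed, and results are tested to a
tolerance (±0.1) far looser than inter-convention differences.

**Over-representation analysis.** For a query of size `n` in a universe of
`N` genes and a term of size `m` with overlap `k`, the p-value is the
hypergeometric upper tail `P(X ≥ k)`. Terms smaller than 4 genes are
discarded before Benjamini–Hochberg adjustment; a term is significant when
`FDR < 0.1` *and* it covers more than 10% of the query. The default
universe is the 19,467 high-confidence protein-coding genes; an explicit
universe gene list may be supplied instead, in which case query genes
outside it are dropped with a warning to keep `N` consistent. Redundancy
reduction between overlapping terms (affinity-propagation clustering, as
some enrichment servers apply) is intentionally not performed; results are
reported uncollapsed.

## Differential co-expression

Spearman's rho is the Pearson correlation of mid-ranks (ties averaged,
computed via scipy); the two-sided p-value uses the t approximation
`t = rho sqrt((n-2)/(1-rho^2))` with `n-2` degrees of freedom, adequate for
the intended regime of tens-to-hundreds of samples. An exact permutation
p-value is available for `n ≤ 9`; `|rho| = 1` is reported with `p = 0`.
Constant vectors raise an error rather than returning NaN.

Classification thresholds: strong co-expression means `r ≥ 0.5` with
`p < 0.05`. The "near-zero" bound below which a formerly strong tumor
correlation counts as lost is not standardized; the default of 0.2 is
conservative (comfortably above the exemplar tumor correlations of
perturbed pairs, which cluster near or below 0.06) and is exposed as a
parameter. The four labels are assigned in a fixed order
(cancer-dependent, perturbed, concordant, unclassified) and are mutually
exclusive because `near_zero < r_thr`. Correlations of 0.85 or higher in
either condition set a separate direct-interaction hint flag.

Which normal tissue matches which tumor cohort is user-supplied
configuration; no automatic tissue matching is attempted. Because a pair
can recur across tissue contexts with different labels, classification
summaries report both per-row and per-unique-pair label fractions.

## Survival analysis

Signature scores are the per-patient mean of per-gene z-scores (or raw
means); groups are split at the median with ties assigned to the low group.
An optimized cutoff scan, as some survival servers perform, is deliberately
not reproduced — it inflates type-I error and its cutoffs are rarely
documented.

The Kaplan–Meier estimator uses the standard convention that subjects
censored exactly at an event time remain at risk for that event. The
log-rank statistic is `(O - E)^2 / V` summed over distinct event times with
the hypergeometric variance, referred to chi-square with 1 df. The hazard
ratio is the O/E (Mantel–Haenszel-style) estimate
`HR = (O_high/E_high)/(O_low/E_low)` with
`CI = exp(ln HR ± 1.96 sqrt(1/E_low + 1/E_high))`, chosen over a Cox fit to
match KM-plot-style reporting and keep the module dependency-free. It is
documented as approximate: simulations in the test suite show median
recovery within 10% for true HR up to 2, with attenuation (~15% low) at
HR = 3 — the known conservatism of the O/E estimate for large effects. The
quantile survival time for cumulative event fraction `q` is the smallest
event time with `S(t) ≤ 1 - q` (median at `q = 0.5`, upper-quartile at
`q = 0.25`), undefined when the curve never crosses.

The ablation search returns a minimal gene subset whose removal lifts the
panel's log-rank p above alpha. `greedy` removes genes in decreasing order
of single-gene log-rank strength, re-testing after each removal;
`exhaustive_k` enumerates subsets by increasing size up to 7 genes
(mirroring typical decisive-panel sizes). Both are provided because the
search procedure behind published decisive subsets is generally unstated;
greedy can miss jointly-decisive sets that exhaustive finds on small
panels. An HR screening band (e.g. keeping only HR < 0.5 or > 2) is a
reporting filter, not a computation, and is left to the caller.

## Expression patterns

A cell is called `up` when `log2FC ≥ 2` and `p < 0.05`, `down` when
`log2FC ≤ -2` and `p < 0.05`, `ns` otherwise and `missing` when inputs are
absent. The boundary |log2FC| = 2 — a four-fold change — counts as
differentially expressed (inclusive reading of the stated cut).

Cancer-specific genes have the stated call in exactly one cancer and
ns/missing everywhere else. Pan-cancer genes have ≥ 5 non-ns calls; they
are `preferentially_up`/`preferentially_down` when one direction carries
more than 2/3 of the calls (this majority rule is the package's own
definition of "preferential", stated in output metadata), otherwise
`mixed`.

**PCA with imputation.** The cancers × genes matrix is encoded ternary
(up = +1, down = −1, ns = 0, missing imputed) by default — cancer
clustering reflects shared DE *patterns*, not magnitudes — with a log2FC
encoding available as an option; neither encoding is claimed to replicate
any external analysis exactly. Missing cells start at their row mean, then
the algorithm alternates a rank-k SVD reconstruction of the column-centered
matrix with a refill of the missing cells until the largest imputed-cell
change is below `tol` (default 1e-6, up to 5000 iterations; the iteration
is a cheap small-matrix SVD and converges geometrically). Columns (genes)
are centered; rows are not scaled. Final scores and explained-variance
fractions come from the SVD of the completed centered matrix. The
implementation is exposed as a scikit-learn-style transformer
(`SVDImputePCA`, with `fit`/`transform` and `explained_variance_ratio_`)
wrapped by the `pca_svd_impute` function.

## Synthetic-data generators

The generators produce inputs with the statistical structure the analysis
assumes, each returning a ground-truth ledger for parameter-recovery tests.
All randomness flows from a master seed through named substreams
(CRC32-keyed `SeedSequence` spawn keys), so outputs are byte-identical
under a fixed seed and adding one generator call never perturbs another.

* **PPI network** — default conditions: a
  219-member roster with 177 connected members, the partner-count
  distribution (63, 30, 40, 27, 6, 11) matched *exactly* (sizes are drawn
  within each bin and realized as exact degrees), 8 planted roster–roster
  edges, 517 partners shared by exactly two targets and 768 partner edges
  through ≥ 3-target partners. Shared-partner assignments are drawn
  weighted by remaining degree budget so small subinteractomes are not
  exhausted; an infeasible demand raises an error.
* **Hallmark annotation** — flags only partners private to one target
  (non-roster, single roster neighbor) so each CH-score target `10k/n` is
  realized exactly; unachievable targets raise an error naming the target.
  Score targets are drawn lognormal around a median of 2.8.
* **Expression pairs** — Gaussian copula with log-normal marginals; the
  latent correlation solves the bivariate-normal relation
  `rho_s = (6/pi) asin(rho/2)`, so the target Spearman correlation is exact
  in expectation (recovered within ±0.05 at n = 2000).
* **Survival cohorts** — exponential event times with hazard
  `lambda_0` (default 1/24 per month, a median survival of ~16.6 months,
  typical of an aggressive-cancer cohort) for the low group and
  `lambda_0 × HR` (default HR 2) for the planted high group; 500 patients
  and 20% censoring by default. Censoring is administrative-uniform on
  `[0, T_max]` with `T_max` solved numerically (Brent) for the requested
  censoring fraction. Signature-gene expression is shifted +3 SD in the
  high group so the median split recovers the planted labels (99%+
  agreement for two-gene panels).
* **DE matrices** — planted gene blocks shared across cancer sets emulate
  the reference pattern: a two-cancer cluster sharing a 68-gene up block,
  several single-cancer blocks, a 100-gene exclusive down block in one
  cancer (plus a 24-gene block shared with a second cancer), and a small
  pan-cancer group. Background cells are guaranteed non-significant and
  missing cells (10%) are confined to background cells, so planted
  structure is never destroyed by missingness.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: realistic RNA-seq count noise, batch
effects and normalization artifacts; real marginal expression
distributions; correlated censoring or non-proportional hazards; gene-gene
correlation beyond the specified pairs; database-specific identifier noise
in interaction sources. Recovery results on synthetic data demonstrate
correctness of the computations, not robustness to those real-data
features.

## Problem sizes used in checks

The acceptance script and test suite use: the full 219-roster network for
the censuses; n = 2000 samples for copula recovery; a 500-patient cohort
for hazard-ratio recovery; 1000 replicates of 120-patient null cohorts for
log-rank type-I calibration (rejection rate at alpha = 0.05 expected
within ±0.02); 200 replicates for classification power; 15 × 10 rank-1
matrices with 10% deletions for imputation accuracy (max error < 1e-6).

## Known limitations

* The O/E hazard ratio understates strong effects (see above); use a Cox
  model when an unbiased point estimate at HR ≥ 3 matters.
* The exact-permutation Spearman p-value enumerates all `n!` permutations
  and is practical only for `n ≤ 9`, as enforced.
* ORA treats gene sets as unstructured; hierarchical redundancy between
  terms is reported, not collapsed.
* The pipeline consumes DE effect sizes and interaction lists as inputs; it
  neither quantifies RNA-seq data nor queries interaction databases.
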