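# Methods

## Model

A gene's *baseline tolerance* is the distribution of functional impact
scores (FIS) of germline nsSNVs retained in that gene in healthy
populations: purifying selection removes variants the organism cannot
tolerate, so what remains measures how much perturbation the gene's function
admits. A somatic mutation's score is standardized against this
distribution,

    transfic = (os − dm) / dstd,

where *os* is the mutation's oriented (and, for bounded tools,
logit-transformed) score and *dm*, *dstd* the mean and standard deviation of
the oriented germline scores pooled for the gene. The transformation is a
per-gene z-score: it re-expresses "how damaging" as "how damaging relative
to what this gene tolerates". Two consequences are worth noting. First, the
transformation applies the same shift/scale to every mutation in genes
sharing a pool, so it cannot reorder mutations within one gene — it reorders
genes' score scales relative to each other. Second, it assumes the oriented
scores are reasonably location-scale summarizable; the logit transform for
SIFT/PPH2 exists precisely to make those scales closer to normal.

## Pooling procedure

Per-gene germline coverage is far too sparse to estimate a distribution per
gene, so variants are pooled across functionally related genes:

1. collect the gene's terms from a flat gene-set collection (GO Molecular
   Function is the recommended system; any GMT works);
2. rank terms by member-gene count ascending (most specific first), ties
   broken lexicographically by term id for determinism;
3. walk the ranking, accumulating the **set union** of variants in member
   genes that are scored by **all** required tools, stopping at the first
   prefix with at least `min_pool` variants (default 20);
4. logit-transform SIFT and PPH2 raw scores (clamp ε = 1e-3, configurable;
   SIFT emits exact zeros frequently) and orient all scales
   damage-increasing: SIFT → logit(1 − s), PPH2 → logit(p), MA → identity;
5. record per-tool mean and **sample** standard deviation (n−1); at
   `min_pool` = 20 the difference from the population convention is < 3%.

Genes with no annotation, or whose full term list never reaches `min_pool`,
fall back to the statistics of the entire catalog (all jointly scored
variants). Genes present in the catalog but absent from the collection, and
vice versa, both receive (fallback) entries so transformation never misses a
gene silently.

Design choices made where the procedure was genuinely open:

* **Joint qualification.** A variant counts toward `min_pool` only if scored
  by every required tool, and each tool's *dm*/*dstd* are computed on that
  same jointly scored pool, so the three baselines describe one variant set.
* **SIFT orientation.** SIFT's "lower = damaging" scale is reconciled with
  the positive high-impact boundary by transforming logit(1 − s), making all
  transformed scales increase with damage.
* **Degenerate pools.** A pool with zero variance (or a single value) for
  some tool keeps its mean but borrows the global *dstd*, avoiding infinite
  transformed scores while preserving centering; the substitution is logged.
* **Flat annotation truth.** The pooling core does not walk an ontology DAG;
  GO ancestor propagation must be applied upstream if term hierarchies are
  wanted in the ranking.
* **Duplicate rows.** Duplicate variant ids collapse to the first
  occurrence (conflicts logged). When no sample-count column is configured,
  each collapsed row still counts as one observation toward recurrence.

## Classification

Transformed scores are binned with per-tool boundary pairs; defaults are
SIFT (−1, 2), PPH2 (−1, 1.5), MA (−1, 2). Edges attach upward (`t <
low_upper` is low, `t >= high_lower` is high): the equality case is not
pinned by the boundary definitions, and this rule is deterministic. Scores
are stored at full precision; two-decimal values are presentation only.

`calibrate_boundaries` rederives such pairs from data: the low/medium
boundary is the largest observed score of the highly recurrent sample whose
CCDF is still ≥ 95% (the low category holds at most ~5% of highly recurrent
mutations), and the medium/high boundary is the smallest observed score of
the non-recurrent sample whose CCDF is ≤ 25%. Thresholds come from the
observed score grid — no interpolation — which on n = 10⁴ normal samples
recovers the closed-form quantiles to within ~0.02.

## Evaluation harness

Because no gold-standard driver/passenger set exists, labels are proxies:
positives are mutations recurring in ≥ k samples or lying in a curated
driver-gene list; negatives are non-recurrent mutations (outside the list,
for the gene-list design). Intermediate recurrences belong to neither
subset. The recurrence identity is gene id + variant id, configurable.

Performance of a score column is the maximum MCC over a full-range cutoff
sweep (candidate cutoffs: every distinct score, plus one above the maximum;
`score >= cutoff` predicts positive; MCC ties break toward the smaller
cutoff), with accuracy reported at the same cutoff. MCC is preferred because
proxy sets are heavily negative-skewed. The sweep is vectorized with suffix
counts; tests verify exact agreement with an independent brute-force
enumeration, including tie cases. The zero-marginal MCC is defined as 0.

## Synthetic data

`simulate_universe` generates the one structural feature the method
exploits: functional groups whose germline score distributions differ in
location. Defaults: 10 groups × 5 genes, group MA means on a linear grid
over [0, 2] oriented units (matching the observed spread between the least
and most tolerant functional categories), σ = 0.3, Poisson(8) germline SNVs
per gene — about 40 jointly scored SNVs behind each gene's pool, so the
default `min_pool` = 20 is met within one term. SIFT/PPH2 raw scores are
drawn from per-group Beta distributions whose means track group tolerance
(tolerant groups harbor more damaging germline variants), so the logit path
is exercised end to end. 10% of genes are annotated to a second (adjacent)
term.

`simulate_somatic` plants drivers (20% of 2000 mutations by default) with
oriented scores shifted +2.0 units and genes drawn with weight
exp(−2·μ_g) — concentrated in the least tolerant groups, mirroring the
overrepresentation of cancer genes there. Driver sample counts are
1 + Poisson(2.5), so ~92% recur in ≥ 2 samples; passengers appear once and
follow their gene's germline-like distribution. All draws come from a single
`numpy.random.default_rng` stream: outputs are fully determined by the seed.

What passing tests on this generator do and do not show: they verify the
estimator recovers planted group distributions, that the transformation
standardizes its own pool exactly, and that when the generating process
matches the method's assumption (drivers concentrated in low-tolerance
groups) the transformed score separates drivers better than the raw score —
and that neither does under the null. They do **not** reproduce performance
on real COSMIC/ICGC data, real GO topology, allele-frequency structure, or
annotation-quality artifacts; absolute MCC values on synthetic benchmarks
carry no real-world meaning.

## Numerical notes and limitations

* Logit clamp ε = 1e-3 bounds oriented SIFT/PPH2 values to ±6.91; exact 0/1
  raw scores are clamped, not excluded.
* All writers serialize floats with `repr`, so write/read round-trips are
  exact; the baseline table format is versioned (`#transfic-baseline v1`).
* The per-gene walk is restricted to the terms actually annotating the gene;
  pool sizes reported (`n_pooled`) count distinct (gene, variant) pairs.
* Multi-transcript consequence collapsing is out of scope: input tables must
  already carry one score per variant per tool.
* The method cannot help when positives and negatives sit in genes of equal
  tolerance, and it inherits any bias of the annotation system used for
  pooling; disease (non-cancer) variant classification is explicitly not a
  target, as disease genes show no tolerance skew for it to exploit.
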