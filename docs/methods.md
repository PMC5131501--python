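# Methods

`coexmap` implements a target-gene co-expression analysis pipeline for
bulk expression matrices: Pearson correlation tables, cytoband-coordinate
mapping of top-correlated genes, a TSS-anchored chromosomal cis-effect
test with a permutation null, running-sum (GSEA-style) gene-set
enrichment, and binomial over-representation — together with a synthetic
paired normal/tumor study generator that plants the correlation structure
each statistic is designed to detect. This note records the models, the
defaults and why, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## Correlation tables

For a target gene *t* and every other gene *g*, the pipeline computes the
Pearson product-moment coefficient r over samples, with the two-sided
p-value from the Student-t transform t = r·√((n−2)/(1−r²)) on n−2 degrees
of freedom. Genes with zero expression in more than 5% of samples are
removed first (`filter_low_expression`; the boundary is strict — exactly
5% is retained — and "zero" is exact equality to 0.0, since normalized
RSEM-like input carries no epsilon ambiguity). The filter is applied per
analyzed matrix, not across pooled conditions; subgroup analyses
therefore re-filter after subsetting.

Conventions chosen where the field's tooling is ambiguous:

* sample standard deviation (and the sd inside cv = sd/mean) uses the
  n−1 denominator, matching `cor.test`/`sd` semantics;
* p-values are floored at the smallest positive normal double
  (~2.2e−308) so downstream ranking and FDR never see an exact zero;
  result writers additionally *print* anything below 1.11e−16 as
  "<1.11e-16", the customary double-precision complement floor;
* ties in r break lexicographically by gene symbol, everywhere, so every
  rank is reproducible;
* constant genes (zero variance), for which r is undefined, are dropped
  from a table with a warning; a constant *target* is an error.

## Cytoband coordinates

A band label `ApB.N` / `AqB.N` maps to the scalar A − B.N/100 (p arm) or
A + B.N/100 (q arm); X and Y map to 23 and share one axis column. Bands
without a sub-band decimal read B.N = B ("8q13" → 8.13). Multi-digit
sub-bands use the full decimal ("12p13.31" → 11.8669), which makes 13.31
sort past 13.9 within an arm — accepted as a plotting convention of the
conversion formula, not a genomic ordering, and flagged here so nobody
reads fine-scale order off the axis.

## Running-sum enrichment

Walking a ranked gene list, P_hit is the normalized cumulative weight of
set members (weight = |r|^w, default exponent w = 1; w = 0 gives equal
weights) and P_miss the cumulative fraction of non-members; ES is the
maximum of P_hit − P_miss and the deficit its minimum. The running sum
ends at exactly zero, ES = 1 iff all members precede all non-members, and
the deficit is −1 iff the reverse (unweighted). Weights use |r| so
negative-correlation tails cannot produce negative cumulative weight.
Ranking is by signed r descending by default (|r| available): for a
positive-co-expression question the interesting tail is the top of the
signed ranking.

Significance comes from a gene-set permutation null: ES of Nh genes drawn
uniformly without replacement (1000 draws by default), summarized by mean
and sd (n−1). Two tail estimators are exposed:

* `normal_approx` (default): the one-sided upper tail of
  Normal(mean, sd) at the observed ES — the classical shortcut;
* `empirical`: the add-one estimator (1 + #{null ≥ ES})/(n_perm + 1).

The normal approximation is **anti-conservative**: the ES null (a maximum
of a tied-down random walk) is right-skewed, so a normal fit
underestimates the upper tail. In our null simulations at the default
study scale the cis test's rejection rate at α = 0.05 was ≈ 0.075 under
`normal_approx` and 0.063 under `empirical` (see the calibration section
below for why even the empirical rate sits slightly above 0.05). For
calibrated inference use `mode="empirical"`; `normal_approx` remains the
default because it is what the upstream analysis convention prescribes,
and extreme tail p-values under it should be read as ordering scores, not
probabilities.

Permutation draws are vectorized by evaluating the running difference
only at hit positions (its maximum can occur only there or at the final
rank, where it is zero); tests verify bit-level agreement with the full
prefix walk. Null distributions in a multi-set scan are cached per Nh —
given the ranking, the null depends on the set only through its size.

## Chromosomal cis-effect test

For a target with an annotated TSS, the hit pool Gi collects
same-chromosome genes with |TSS − TSS_target| ≤ 1 Mbp (closed interval;
strand ignored; 1-based coordinates), restricted to the genes present in
the correlation table; Go is the same-chromosome remainder. The target's
own r = 1 row is excluded before ranking. ES of Gi along the target's
ranking is compared with the null ES of Nh = |Gi| genes drawn from Go
only, so chromosome-wide expression trends cancel. The genome-wide scan
repeats this with every annotated gene as target, applies
Benjamini–Hochberg across probes (step-up with monotonicity enforcement,
q_(i) = min_{j≥i} p_(j)·m/j, delegated to statsmodels and checked against
an independent oracle in the tests), and reports — never silently drops —
probes whose pools are degenerate (empty window, |Go| < Nh, constant
expression).

### Calibration of the cis test

Beyond the normal-approximation skew, the test carries a second, subtler
inflation: Gi is excluded from Go, so on a short chromosome the observed
ES and its null are negatively dependent (when Go happens to underfill
the top ranks, Gi tends to overfill them). An iid exchangeability
simulation (random scores, random pools, no expression model) reproduces
both effects separately: with ~180 same-chromosome null genes the
empirical-mode rejection rate at α = 0.05 is ≈ 0.065–0.07 and the
normal-mode rate ≈ 0.08, while an unrestricted null pool restores 0.05.
At the scale of a real transcriptome (≳600 genes per chromosome) the pool
effect largely vanishes. Consumers comparing few targets should prefer
the empirical mode and treat borderline p ≈ 0.05 results with one extra
grain of salt on short chromosomes.

## Binomial over-representation

The top k = 1000 genes by |r| form the pool. For each annotation set,
μ = |members ∩ universe|/|universe| over the analyzable universe (the
correlation table's gene list), and p = P(X > found) for
X ~ Binomial(k, μ) — deliberately the "one minus CDF at found"
convention, an off-by-one from P(X ≥ found), kept for fidelity to the
upstream definition. The "expected" column is the smallest count with
p < 0.05 at that μ, a yardstick for how far above background a found
count sits. Each gene counts once per set (set semantics); published
tables derived from multi-annotation sources can print slightly larger μ
than |members|/|universe| would give, so μ is always recomputed from the
supplied GMT rather than trusted from any external table. Rows are sorted
by raw binomial p (no correction, matching the upstream convention); a BH
q column is available behind a flag.

## Synthetic paired studies

The generator emulates the study design the pipeline targets — ~40–50
paired normal/tumor samples with TCGA-like barcodes whose first three
"-"-separated fields form the participant tag — with two planted
structures on log-normal expression:

* **normal condition**: the target plus a `module_size`-gene trans module
  (scattered across non-target chromosomes) share one latent factor with
  loading √rho_module each, so every planted pair correlates at
  rho_module (default 0.8) on the log scale;
* **tumor condition**: the module decouples and the target couples to a
  cis block of genes on its own chromosome. The target is the *hub*:
  loading rho_cis^(1/4) against rho_cis^(3/4) for block genes, giving
  target–block correlation exactly rho_cis (default 0.7) and block–block
  rho_cis^(3/2). A focal dosage event peaking on the target would
  produce exactly this asymmetry, and it makes the target the strongest
  cis signal of its own neighbourhood — the property the genome-wide
  scan's recovery tests exercise. A fully symmetric block (every pair at
  rho_cis) makes target and block genes statistically exchangeable, in
  which case *which* of them attains the scan minimum is essentially a
  draw.

The cis block is laid out as two flanks near the edges of the target's
window: every block gene within 1 Mbp of the target, but the flanks more
than a window apart from each other. The target's window therefore holds
the whole block while each block gene's window holds only its own flank
plus the target — again concentrating the detectable signal on the
target. Cytoband strings are synthesized consistently with TSS order
(p arm then q arm, band numbers increasing away from the centromere), so
the cytoband coordinate is strictly increasing in TSS along a chromosome
and monotonicity is testable.

Log expression y = base_log_mean + a·f + √(1−a²)·ε is mapped to linear
scale as exp(log_sigma·y), rescaled so the population grand mean is
exp(base_log_mean); dropout then zeroes each value independently with
probability `dropout_rate` (default 0 — dropout is switched on to
exercise the zero filter, not as a background assumption). Defaults:
2,000 genes over 10 chromosomes at 100 kbp TSS spacing (a test-scale
stand-in for a ~1.4×10⁴-gene transcriptome), 42 pairs, log_sigma = 0.4
(log-scale noise sd, giving cv ≈ 0.42 per gene, bracketing the ~0.26–0.7
range typical of stable transcripts in bulk tissue), base_log_mean = 7
(grand mean ≈ 1100 on the RSEM-like scale). With log_sigma = 0.4 the
linear-scale Pearson correlation of a pair planted at ρ = 0.8 is
(e^{0.8·0.16}−1)/(e^{0.16}−1) ≈ 0.79 — the mild lognormal attenuation is
deliberate and inside the Fisher-z bands the tests assert.

Every operation draws from `default_rng([seed, op_offset])`, so each
artifact (annotations, each condition, gene sets, metadata) is
individually reproducible and a study regenerates byte-identically.

**What passing tests do not show.** The generator has no library-size or
GC artifacts, no batch structure, no count noise (a negative-binomial
layer would matter for low-expression genes; correlations of
moderate-to-high expressors are the object here), no correlated dropout,
and one planted module rather than a full scale-free co-expression
network. Recovery results on these studies demonstrate that the
statistics detect the structure they define — not that real tumors
reorganize expression this way.

## Problem sizes used in the checked experiments

The statistical acceptance checks run at the generator's default scale:
2,000 genes, 42 pairs. Calibration uses 500 null replicates with 200
permutations per test (the empirical-mode add-one estimator needs only
the tail ordering, which 200 draws resolve at α = 0.05); recovery uses 20
seeded studies with 1,000 permutations in the pathway and genome-wide
scans, where the BH ranking of extreme tails benefits from the larger
null sample. A full genome-wide cis scan at this scale takes ~15 s on one
core.

## Known limitations

* The cis test measures positional enrichment only; it cannot attribute
  a cis-effect to copy number, methylation or any mechanism.
* The normal-approximation p is anti-conservative (above); genome-wide
  ranks are reliable, absolute tail probabilities are not.
* Cytoband coordinates are a 1-D plotting device; they do not encode
  physical distance and sub-band ordering is formula-driven.
* μ in over-representation assumes one count per gene per set; supplied
  GMTs with redundant sets simply yield redundant rows.
* The participant-tag pairing rule (prefix up to the third "-",
  first-tumor-in-file-order on ties) is a convention; data with other
  barcode semantics need a custom tag column.
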