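# coexmap

Target-gene co-expression analysis for bulk expression matrices.

Given a normalized gene-by-sample expression table (RSEM-like values, as
in TCGA level-3 RNA-seq) and one target gene, `coexmap` builds the
target's **correlation table** — Pearson r against every other gene,
ranked — and asks three questions of it:

1. **Where are the co-expressed genes?** The top-|r| genes are mapped to
   scalar cytoband coordinates (band `ApB.N`/`AqB.N` → A ∓ B.N/100) for a
   one-axis chromosome plot, and a **cis-effect test** measures whether
   the target's strongest partners cluster within 1 Mbp of its own TSS: a
   running-sum enrichment score (ES) of the TSS-window gene pool Gi along
   the target's ranking, against the ES null of |Gi| genes drawn from the
   same chromosome outside the window (Go), with permutation p-values and
   Benjamini–Hochberg FDR across a genome-wide scan. A dominant cis
   signal (e.g. co-amplification) is the signature by which tumor tissue
   departs from the function-driven co-expression seen in normal tissue.
2. **Which functional gene sets are they in?** GSEA-style running-sum
   enrichment of each annotation set (GMT) along the ranking:
   ES = max(P_hit − P_miss), random-gene-set permutation null, normal or
   empirical tail p, FDR over the scan.
3. **Are sets over-represented among the top genes?** Binomial upper
   tail p = P(X > found), X ~ Binomial(1000, μ), with μ the set's
   background rate in the analyzable universe, plus the minimum count
   that would reach p < 0.05.

A synthetic-study generator produces paired normal/tumor matrices with a
planted co-expression module (normal) and a planted cis block around the
target (tumor), plus annotations, gene sets and sample metadata — so the
whole pipeline runs and is tested without any external download. Sample
subsetting by metadata and participant-tag pairing of normal with tumor
samples are built in.

## Worked example

```python
import coexmap as cm

spec = cm.SyntheticSpec(seed=1)          # 2000 genes, 42 pairs
normal, tumor, meta = cm.generate_paired_study(spec)
ann  = cm.generate_annotations(spec)
sets = cm.generate_gene_sets(spec)

pairs, unmatched = cm.match_normal_tumor_pairs(meta)
print(len(pairs), len(unmatched))        # -> 42 0

table = cm.build_correlation_table(normal, spec.target_gene)
print(table.frame.head(3).to_string(index=False))
#   feature        r            p  n  rank
# GENE00006 0.879200 1.870274e-14 42     1
# GENE00007 0.869739 7.717320e-14 42     2
# GENE00009 0.848699 1.257946e-12 42     3
```

The top of the normal-tissue ranking is exactly the planted module
(r ≈ 0.85 at 42 samples for a pairwise log-scale correlation of 0.8),
each with the two-sided t-test p-value on 40 degrees of freedom. The
pathway scan finds the planted set first with the maximal running sum:

```python
scan = cm.pathway_scan(table, sets, n_perm=1000, seed=7)
print(scan.head(1)[["set_id", "nh", "es", "p", "q"]].to_string(index=False))
#         set_id  nh       es        p        q
# planted_module   9 1.000000 0.000033 0.001690
```

(ES = 1 means every member precedes every non-member in the ranking; the
p comes from 1000 random 9-gene draws.) The cis-effect contrast between
conditions:

```python
for cond, m in [("normal", normal), ("tumor", tumor)]:
    t = cm.build_correlation_table(m, spec.target_gene, sort="unsorted")
    pools = cm.build_cis_pools(ann, spec.target_gene, universe=t.features)
    r = cm.cis_es_test(t, pools, n_perm=1000, seed=7)
    print(cond, f"nh={r.nh} es={r.es:.3f} p={r.p:.3g}")
# normal nh=20 es=0.236 p=0.274
# tumor  nh=20 es=0.798 p=4.15e-08
```

In normal tissue the 20 genes within 1 Mbp of the target are nowhere
special in its ranking (ES 0.24, p 0.27); in the tumor condition the
planted cis block dominates it (ES 0.80). `genomewide_cis_scan` repeats
this for every gene and attaches BH q-values; on tumor data the target is
the scan minimum.

Everything is also reachable from the shell:

```sh
coexmap --seed 1 simulate --outdir study/
coexmap corrtable --matrix study/expression_normal.tsv \
        --target GENE00000 --out table.tsv
coexmap ora      --table table.tsv --gmt study/gene_sets.gmt --out ora.tsv
coexmap cytoband --table table.tsv --annotations study/annotations.tsv \
        --k 500 --out points.tsv --plot points.png
coexmap cis-scan --matrix study/expression_tumor.tsv \
        --annotations study/annotations.tsv --all --out cis.tsv
```

See `docs/methods.md` for the statistical conventions (weighting,
tie-breaks, p-value floors), the calibration analysis of the permutation
tests, and what the synthetic studies do and do not demonstrate.

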