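# lncatlas

Analysis toolkit for multi-tissue long non-coding RNA (lncRNA) expression
atlases, built around the desk-scale statistics used to characterise the
porcine lncRNA landscape: which lncRNAs are expressed where, which are
housekeeping versus tissue-specific, where they sit relative to coding
genes, which are positionally conserved across species, and how they wire
into cis-regulatory and ceRNA networks.

## Who this is for

Computational biologists who already have transcript annotations (GTF),
gene-level count matrices, LiftOver output (BED) and miRanda-style
interaction tables, and want the downstream classification and network
layer as tested, reusable functions rather than one-off scripts. A
synthetic-data generator with planted ground truth is included so every
stage can be validated end to end without any external download.

## The rules implemented

For a feature with per-tissue mean expression `x_1..x_T` (CPM by default):

- **Expression filter** — keep a feature iff some tissue has more than 10
  reads (strictly) in at least 3 of its samples.
- **Housekeeping** — mean(x) exceeds the median of all features' means
  (strict) and CV = sd(x)/mean(x) < 1 (strict; sd uses the n−1 denominator).
- **Tissue-specific in T** — (i) x_T ranks in the top 25 % of all features
  in T, (ii) x_T > 50 % of Σx (strict; at most one tissue can qualify, so
  the assignment is unique), (iii) x_T ≥ 3 · max of the other tissues
  (inclusive).
- **Genomic context** — exonic > intronic > upstream > downstream >
  intergenic precedence against coding transcripts, 10 kb TSS/TES windows,
  sense/antisense relative to the partner gene.
- **Cis target** — coding gene within ±100 kb (edge to edge) whose
  expression has Pearson r > 0.6 (strict) with the lncRNA.
- **Hub** — |MM| > 0.8 and |GS| > 0.2 (strict), with MM the correlation
  with the module eigengene (first PC of the standardised module) and GS
  the correlation with a one-vs-rest tissue indicator.
- **Differential expression** — Benjamini–Hochberg adjusted p < 0.05
  (strict) and |log2FC| ≥ 1 (inclusive).
- **ceRNA triple** — join of sponge–miRNA and miRNA–mRNA edges retained at
  score > 140 and energy < −20 kcal/mol (both strict).
- **Positional conservation** — a lifted foreign lncRNA interval that
  overlaps any pig lncRNA span by ≥ 1 bp.

## Worked example

```python
from lncatlas.simulate import SimConfig, simulate_truth
from lncatlas.quantify import expression_filter, cpm_normalize
from lncatlas.classify import classify_all
from lncatlas.conservation import call_conserved, conservation_report

ann, cm, truth, aux = simulate_truth(SimConfig(seed=42))
kept = sorted(expression_filter(cm))          # 1901 of 2000 lncRNAs pass
em = cpm_normalize(cm.subset(kept))
res = classify_all(em)
print(sum(r.label == "housekeeping" for r in res),
      sum(r.label == "tissue_specific" for r in res))
# 200 300   <- exactly the planted class sizes

recs = call_conserved(aux["lifted"], ann)
rep = conservation_report(recs, n_source=500)
print(rep.n_conserved, rep.rate_pct)
# 50 10.0   <- the generator planted a 10% conserved fraction

print(conservation_report(None, 13_380, n_conserved=1078).rate_pct)
# 8.1       <- report arithmetic on real human->pig LiftOver counts
```

The numbers mean: the classifier recovered all 200 planted housekeeping
and 300 planted tissue-specific lncRNAs from the noisy negative-binomial
counts; all 50 planted conserved foreign lncRNAs were called from interval
overlap alone; and 1078 conserved out of 13,380 human lncRNAs corresponds
to a conservation rate of 8.1 %.

A full pipeline run (simulate → filter → describe → classify → cis →
conserve → hubs → de-filter → cerna → stages) with a JSON report:

```bash
lncatlas run --out run1/          # or: lncatlas run --config run.yaml --out run1/
```

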