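# mamshift

Stage-resolved gene-program scoring and cardiomyocyte subtype conversion
inference for single-cell RNA-seq time courses.

`mamshift` is aimed at analysts studying pressure-overload cardiac
hypertrophy (TAC model) — or any staged single-cell time course — who want
to track a gene program across disease stages and ask which cell subtypes
convert into which as disease progresses. It implements the compute layer
of that analysis as a tested, reusable library plus CLI:

- **QC and normalization** — cells expressing fewer than 200 or more than
  10,000 genes are removed (strict inequalities; boundary cells kept);
  counts are scaled per cell to a fixed total and log1p-transformed.
- **MAM module scoring** — a per-cell score for the 13-gene MAM
  (mitochondria-associated ER membrane) program: Mfn1, Mfn2, Bcap31,
  Pacs2, Tespa1, Hspa9, Itpr3, Sigmar1, Vapb, Fis1, Vdac, Mcu, Ptpip51.
  For a cell *i* and gene set *S* with bin-matched control genes
  *C(g)*,

      score(i) = mean_{g∈S} x_ig − mean_{g∈S} mean_{c∈C(g)} x_ic

  where controls are drawn per set gene from the same dataset-average
  expression bin (24 equal-frequency bins, 100 controls per gene, seeded
  sampling). Any gene set can be substituted.
- **Ancestor-voting conversion inference** — every cardiomyocyte of stage
  *t* is Spearman-correlated with all cardiomyocytes of stage *t−1* over
  a highly-variable-gene universe; its top-5 correlated cells are its
  potential ancestors and their subtype labels vote (plurality; ties by
  summed correlation, then label). Edge support(A→B) counts the stage-*t*
  cells of subtype B whose voted ancestor subtype is A.
- **Subcluster selection rules** — before any trajectory analysis, a
  subtype must exceed 10% of CM cells at some stage (strict), an edge
  needs ≥ 10 supporting cells, and the conversion direction must not
  conflict with the subtype proportion change. Every exclusion is audited
  with the rule it failed.
- **Dynamics** — per-stage subtype fractions, the rank correlation of the
  stage-mean score with the CM2+CM3 fraction, and smoothed per-gene trends
  along a deterministic stage-based pseudo-order, classified as rising /
  falling / rise-then-fall / flat.
- **Synthetic cohorts** — a negative-binomial generator that plants all of
  the above (stage-peaked MAM program, CM2→CM9 and CM3→CM10 conversions,
  declining Mfn1/Hspa9) with a ground-truth ledger, so the whole pipeline
  is testable without external data.

## Worked example

```python
from mamshift import *
from mamshift.simulate import SimConfig

adata, truth = generate_cohort(SimConfig(seed=1))   # 16,000 cells x 1,000 genes
filtered, qc = qc_filter(adata)                     # <200 / >10,000 detected genes
norm = log_normalize(filtered)
score = module_score(norm, MAM_GENE_SET, seed=1)
print(stage_score_summary(score, norm.obs, restrict_type="CM").round(3))
```

```
          n   mean     sd  ci_low  ci_high
stage
0w     2000  0.068  0.229   0.058    0.078
2w     2000  0.674  0.218   0.665    0.684
5w     2000  0.423  0.241   0.412    0.433
8w     2000  0.153  0.245   0.142    0.164
11w    2000 -0.042  0.239  -0.052   -0.031
```

The per-stage mean MAM score peaks at 2 weeks (hypertrophy with preserved
ejection fraction) and declines through 5, 8 and 11 weeks — the
compensatory-then-exhausted program shape the generator plants.

```python
graph = infer_conversions(norm)                       # Spearman top-5 voting
props = stage_proportions(norm.obs)                   # CM subtype fractions
sel = select_trajectory_subclusters(graph, props.fractions)
conv = sel.retained_edges.query("ancestor != descendant")
print(conv[["ancestor", "descendant", "transition", "support"]].to_string(index=False))
```

```
ancestor descendant transition  support
     CM2        CM9     2w->5w      100
     CM3       CM10     2w->5w      100
     CM2        CM9     5w->8w      119
     CM3       CM10     5w->8w      118
     CM2        CM9    8w->11w       95
     CM3       CM10    8w->11w       90
```

The retained non-self edges are exactly the planted CM2→CM9 and CM3→CM10
conversions; supports approximate the planted converting-cell counts
(100/120/100 per transition). Coupling and trends:

```python
corr = score_proportion_correlation(
    stage_score_summary(score, norm.obs, restrict_type="CM")["mean"], props)
# rho(score, CM2+CM3 fraction) = 0.70 over 5 stages  (small-n caveat: 5 points)
ordered_gene_trend(norm, "Mfn1", scores=score.scores).direction   # 'falling'
ordered_gene_trend(norm, "Hspa9", scores=score.scores).direction  # 'falling'
stage_order_graph(conv)   # [['CM2', 'CM3'], ['CM10', 'CM9']]
```

The same pipeline runs from the shell:

```sh
mamshift simulate --out fixture/ --seed 1
mamshift run --in fixture/ --out results/ --seed 1   # report.json + audit TSVs
```

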