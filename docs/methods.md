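# Methods

## Scope and data model

`mamshift` analyses a staged single-cell RNA-seq cohort: a genes × cells
count matrix plus per-cell metadata (stage label, major cell type,
subtype). The in-memory container is an `AnnData` (cells × genes), with
stages as an ordered categorical. Cluster/subtype labels are treated as
pluggable inputs — the package does not re-derive them (a k-means-on-PCs
helper exists as plumbing only); in real use they come from a standard
clustering, in tests from the generator's ground truth.

The stage axis follows the TAC pressure-overload hypertrophy model: 0
weeks (normal), 2 weeks (hypertrophy with preserved ejection fraction),
5 weeks (reduced EF), 8 and 11 weeks (failure).

## QC and normalization

Cells expressing `< min_genes` (default 200) or `> max_genes` (default
10,000) genes are removed. The inequalities are strict: boundary cells
(exactly 200 or exactly 10,000 detected genes) are retained, and the
`QCReport` records how many cells each rule removed. The filter is
idempotent.

Normalization is `log1p(count / cell_total × scale_factor)` with
`scale_factor = 1e4` (the common single-cell convention). A zero-total
cell is an error naming the cell rather than a silent NaN.

Highly variable genes are ranked by clipped standardized variance: a
degree-2 polynomial is fit to log10(variance) against log10(mean) across
genes, each gene's values are standardized by the trend-predicted sd and
clipped to ±√n_cells, and genes are re-ranked by the variance of the
clipped values. The quadratic trend replaces the usual loess so the
ranking is deterministic and loop-checkable; ties break lexicographically
by gene id.

## Module score

The MAM score is a bin-matched control score. Genes are ordered by
dataset-average expression (ties broken by gene id) and cut into
`n_bins = 24` equal-frequency bins. For each set gene, `n_ctrl = 100`
control genes are sampled without replacement from its bin (excluding the
gene itself; a seeded RNG, sampling in canonical sorted-gene order so the
result is invariant to how the gene set is listed). The score of a cell
is the mean expression of the set genes minus the mean over set genes of
the per-gene control means, so each set gene contributes equally to the
control term. A bin smaller than `n_ctrl` contributes all its genes with
a logged warning; set genes absent from the matrix are dropped with a
warning (some MAM symbols are aliases that a given annotation may lack)
and reported in the result.

Consequences used as test invariants: a constant matrix scores exactly
zero; adding a constant to every gene of a cell leaves that cell's score
unchanged; with `n_ctrl` at least the bin size the score is a closed-form
deterministic quantity.

The packaged default set is the 13-gene MAM program (Mfn1, Mfn2, Bcap31,
Pacs2, Tespa1, Hspa9, Itpr3, Sigmar1, Vapb, Fis1, Vdac, Mcu, Ptpip51);
any GMT or one-gene-per-line file can be substituted.

Stage summaries report n, mean, sd and a normal-approximation 95% CI
(mean ± 1.96·sd/√n) per stage in stage order, optionally restricted to
one major type.

## Ancestor voting and conversion graph

For each adjacent stage pair (t−1, t), every stage-t cardiomyocyte is
Spearman-correlated with every stage-(t−1) cardiomyocyte. Correlations
use average ranks for ties and are computed over a gene universe that
defaults to the top 500 HVGs of the combined two-stage CM submatrix
(an `all`-genes mode exists). Because the statistic is rank-based, every
downstream result is invariant under strictly increasing transforms of
the expression values.

The query cell's top-k (k = 5) most correlated previous-stage cells are
its potential ancestors; ties at the cutoff break by previous-cell id. A
previous cell with zero expression variance yields an undefined
correlation and is excluded; a zero-variance query cell casts no vote and
is counted as invalid. The ancestors' subtype labels vote by plurality;
vote ties break by larger summed correlation, then lexicographically by
label. Edge support(A→B) over t−1→t is the number of valid-voting
stage-t cells of subtype B whose voted ancestor subtype is A, so supports
over a transition sum exactly to the number of valid votes (a conservation
law asserted in tests), and `vote_fraction` is support divided by the
descendant subtype's valid votes.

All tie-breaks are deterministic by construction; the same inputs always
give the same edge table.

### Selection rules

Three rules gate subclusters and edges before trajectory work, each with
an audited verdict:

1. a subtype is retained iff its CM fraction exceeds `min_frac = 0.10`
   at some stage (strict `>`, so exactly 10% is excluded);
2. an edge needs `support ≥ min_support = 10` (inclusive, so exactly 10
   is retained);
3. the conversion direction A→B must not conflict with the proportion
   change: the default predicate rejects an edge iff B's fraction
   strictly fell while A's strictly rose across that transition. A
   stricter variant (reject whenever B's fraction fell at all) is
   config-switchable. The predicate is isolated in one pure function.

Excluded edges carry the names of every rule they failed. The retained
non-self edges form a DAG layered topologically for downstream ordering;
self-edges (a subtype persisting into itself) are dropped from the
layering, and a cycle is reported as an error listing the cycle rather
than broken silently.

## Dynamics

Per-stage subtype fractions are exact counts over CM cells (absent
subtypes report 0; an empty stage yields a null row). The score/proportion
coupling is the Spearman rho between the stage-mean score and the summed
CM2+CM3 fraction across stages. With five stages this is descriptive: the
result always carries a small-n caveat flag and deliberately no p-value —
a rank correlation over five points has no meaningful sampling
distribution.

Gene trends are computed along a deterministic pseudo-order — stage order,
within a stage by MAM score descending — standing in for a model-based
pseudotime, which is out of scope. Values are smoothed with a centred
rolling mean (default window 51 cells) for display; the direction class
(rising / falling / rise-then-fall / flat / mixed) comes from the sign
pattern of first differences of the *stage-level* means with threshold
ε = 0.05 × (range of stage means). The ε fraction is a package choice,
exposed in the config.

## Synthetic cohort generator

The generator emulates the study conditions end-to-end so every stage of
the pipeline has a planted, recoverable truth:

- **Stages and composition.** Five stages (0/2/5/8/11 w), 3,200 cells per
  stage of which 62.5% are CM (≈ 2,000 CM cells/stage) and the rest EC /
  FB / MP / T / GN at fixed fractions. Eleven CM subtypes follow a
  per-stage schedule in which CM2+CM3 peak at 2 w (56% of CM cells) and
  decline to 11% by 11 w while CM9/CM10/CM11 expand reciprocally. Cells
  are allocated to subtypes by largest-remainder rounding (deterministic
  at small n; a multinomial mode exists behind a flag).
- **Counts.** Gamma-Poisson (negative binomial) with per-gene lognormal
  baseline means, a shared quadratic dispersion α = 0.35
  (Var = μ + αμ²), and per-cell library sizes uniform on [2,000, 6,000].
  Each of the 16 cell labels has a 25-gene marker block at log-fold 1.6.
  The marker strength was chosen so that per-cell rank correlations
  separate subtypes cleanly — weaker markers let abundant subtypes
  capture rare subtypes' top-5 lists by base rate alone, which would
  defeat the voting procedure the generator exists to exercise.
- **MAM program.** MAM genes in CM cells get a constant log elevation of
  0.4 (making the program CM-enriched at every stage) plus a stage offset
  of {0w: 0, 2w: 0.8, 5w: 0.5, 8w: 0.2, 11w: 0} — the rise-at-2w,
  decline-thereafter shape. No quantitative effect size exists to copy
  for this program, so the offsets are chosen for testability: large
  enough that the stage ranking of mean scores is stable at 2,000 cells
  per stage, small enough that per-cell noise dominates a single cell.
- **Declining genes.** Mfn1 and Hspa9 get per-gene stage offsets
  {0.9, 0.7, 0.45, 0.2, 0} that *replace* the MAM stage offset for those
  genes, planting a monotone decline while the other 11 set genes carry
  the 2 w peak.
- **Conversions.** CM2→CM9 and CM3→CM10 at 2w→5w, 5w→8w and 8w→11w
  (100/120/100 cells per edge). A converting descendant's expected
  profile is a convex combination in log1p space of its assigned
  ancestor's realized count profile and the descendant subtype's baseline
  (ancestor weight 0.7), rescaled to the cell's library size — so the
  descendant rank-correlates with one specific previous-stage cell more
  than with the field, which is exactly the signal the voting procedure
  presumes. Ancestor assignments, per-stage schedules, score offsets and
  planted edges are recorded in a `GroundTruth` ledger.
- **QC plants.** Optionally, per stage, low-complexity cells with 50–150
  total counts (hence < 200 detected genes) for QC-recovery tests.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene-gene correlation structure beyond the marker blocks,
zero-inflation beyond NB sampling, or read-level noise. Passing the
planted-recovery tests therefore shows the pipeline's algorithms are
correct and well-conditioned under NB noise at realistic depth — not that
the biological conclusions of any real dataset are reproduced.

## Evaluation conventions

Planted-lineage precision and recall are computed over the retained
*non-self* edges (ancestor ≠ descendant): self-edges are the expected
persistence of non-converting cells and are not conversions. Recovery is
averaged over five seeded cohorts; support conservation is exact per
transition.

## Determinism and numerical choices

Every stochastic step (generator, control-gene sampling) uses a seeded
`numpy` Generator; fixed seed ⇒ bit-identical counts, scores, edges and
reports (timestamps are excluded from reports for this reason). All
order-dependent operations (bins, top-k, votes, HVG ranking, largest
remainder) define explicit lexicographic tie-breaks. Degenerate inputs
fail loudly: zero-total cells, empty stages, all-NaN correlation rows,
empty retained sets and DAG cycles each raise or flag rather than
propagating silently.

## Problem sizes

Unit tests run on 400-cell-per-stage cohorts (conversion counts scaled
accordingly); the acceptance suite and `scripts/acceptance.py` use the
full default cohort (3,200 cells/stage, ≈ 2,000 CM) over five seeds —
about a minute end-to-end on one CPU, chosen so the whole suite stays
interactive.

## Known limitations

- The conversion inference assumes the previous stage contains the true
  ancestors; unsampled intermediate states fold into the nearest sampled
  stage.
- Plurality voting with k=5 is biased toward abundant previous-stage
  subtypes when per-cell signal is weak; the audit (vote fractions,
  supports) should be inspected before interpreting low-support edges.
- The rule-3 consistency predicate is one reading of "direction must not
  conflict with proportion change"; the stricter reading is provided but
  both are heuristics on 5-point fraction series.
- The 5-stage score/proportion correlation is descriptive only.
- HVG selection uses a global quadratic mean-variance trend; datasets
  with strongly non-quadratic trends may rank tails differently than
  loess-based implementations.
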