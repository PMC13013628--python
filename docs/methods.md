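# Methods

## The analysis

`hippomaturity` reimplements, as an open and testable pipeline, a
cross-dataset transcriptomic screen for hippocampal *hyper-maturity* and
*accelerated aging*: model datasets (mutant or treated animals vs
controls) whose differential-expression signatures are directionally
concordant with the expression changes of normal postnatal development
(young vs adult) or of aging (old vs adult). The original screen ran on a
proprietary platform ("Running Fisher" on a commercial omics database);
this package replaces that black box with a fully specified statistic and
a synthetic-data generator that plants the structure the analysis is
meant to detect, so every stage can be validated against ground truth.

## The signed overlap statistic

Two filtered DEG lists (|linear FC| > 1.2 and raw p < 0.05, both strict)
are each split into up- and down-regulated genes ranked by decreasing
|log2 FC| (ties: ascending p, then gene id). For each of the four
direction pairs (up/up, down/down, up/down, down/up) a grid of rank
cutoffs — deciles of each list by default — is scanned; at each grid cell
the exact hypergeometric upper tail P[X ≥ overlap] of the two prefix
sets is evaluated against a shared gene universe N (default 20 000, the
order of the mouse protein-coding gene count; the intersection of the
measured universes when both are known). The quadrant p-value is the
minimum over the grid, Bonferroni-multiplied by the number of grid cells
(valid under arbitrary dependence, hence conservative). The two
concordant quadrants are combined by Fisher's method (χ², 4 df), likewise
the two discordant quadrants; the overall overlap P is the smaller of the
two, with sign +1 when concordance dominates. With a single cutoff at
100% and no correction the statistic reduces exactly to a plain one-sided
Fisher/hypergeometric overlap test (`FULL_SCAN`).

The platform's true cutoff schedule, correction and aggregation are not
published; the decile scan is this package's concrete instantiation and
its published overlap P values are therefore not bit-reproducible
targets. What is reproduced is the documented character of the method —
rank-based, fold-change ordered, Fisher-based, signed — with exactness
and calibration guarantees the tests verify: quadrant tails match
exhaustive subset enumeration for all universes N ≤ 12, and on
independent random lists the empirical P(overall p < 0.01) stays below
0.01 (the Bonferroni scan plus the discreteness of small-overlap tails
makes the test conservative).

A monotonicity caveat found during validation: adding a gene shared at
the top of both lists never weakens the overlap for concordance-dominated
pairs (sign +1), but for discordance-dominated pairs the signed statistic
correctly moves toward 1, and under the decile scan a cutoff shift
(ceil(f·(n+1)) = ceil(f·n)) can displace a previously included gene. The
property test asserts the sign-positive form, which held without
exception in 200 randomized instances for both scan configurations.

## Numerical representation of p-values

All overlap tails are computed in natural-log space: a vectorized
segmented log-sum-exp over gammaln log-pmf terms (checked against scipy's
`hypergeom.logsf` to 1e-8 relative), and a closed form for the 4-df
Fisher combination, ln p₁p₂ + log1p(−ln p₁p₂). This matters because
under the default study conditions (800-gene signatures, N = 20 000) true
overlap P values routinely fall below 10⁻³⁰⁰, the double-precision
underflow limit. Stored probability floats are floored at 1e-300, but
signed indices use the exact log magnitude — otherwise roughly half the
default cohort would tie at index 300 and planted concordance would not
be recoverable in rank order. Indices are therefore always finite and
fully ordered.

## Indices

- **Maturity / aging index**: sign × (−log10 overlap P) against a
  reference panel. The published formula writes the discordant case as
  −log10(−1 × P), which is arithmetically unusable for a positive
  probability; it is read as signed-P notation, giving the bidirectional
  axis used in the scatter plots. One value per model is the family
  comparison of largest absolute index ("most significant"), matching a
  screening rule that requires concordance with *at least one* reference
  timepoint; mean or a fixed timepoint are selectable.
- **Anxiety index**: Cohen's d from group summary statistics with the
  unweighted pooled SD √((s²_model + s²_control)/2) — exactly the printed
  form, without n-weighting — multiplied by a per-measure polarity (+1
  when larger means more anxiety) and averaged unweighted across a
  model's 1–3 measures. SEM-reported groups are converted once at
  ingestion via SD = SEM·√n.
- **Correlation**: Pearson r with the exact two-sided p from
  t = r√(n−2)/√(1−r²) on n−2 df (cross-checked against
  `scipy.stats.pearsonr`), plus the least-squares line.

## PCA grouping

The model × reference matrix of signed indices is column-standardized
(zero-variance columns are an error) and projected onto its first two
principal components (full SVD, deterministic). Grouping is 2-means with
a fixed initialization at the two models with extreme PC1 scores — a
deterministic stand-in for the paper's unstated grouping rule — and the
cluster whose members have the higher mean signed index over the
development columns is labeled `development_like`. Labels are invariant
to row order, and flipping the sign of the aging columns (an isometry on
standardized rows) does not move development labels.

## Enrichment and cell-type contributions

Per-model "feature genes" are the concordant shared genes (up in both or
down in both) of the model vs reference comparison at full cutoffs.
Enrichment per gene-set term is the hypergeometric upper tail with BH
q-values within each query; the meta-analysis combines each term's
per-query p-values by Fisher's method (χ², 2K df) and ranks by combined
p (ties broken by term id).

A model's accelerated-aging signature is its concordant shared genes with
an aged reference, with the model's effect sizes retained for ranking.
Each cell type's old-vs-young DEG list is filtered with the standard
criteria and compared directionally with the signature; the contribution
score is −log10(overall P) when concordant and floored at 0 when
discordant (the axis is a contribution magnitude), with
percent_common = 100·|signature ∩ cell-type DEGs|/|signature| as the
companion size. Scores are independent across cell types.

## The synthetic-data generator

The generator is first-class, tested code and defines the study
conditions:

- **Universe**: 20 000 genes. **References**: 7 developmental timepoints
  (emulating postnatal days 8–29 vs adult) sharing a common core
  signature (85% of an 800-gene signature, half up / half down) whose
  per-gene |log2 FC| decays linearly (multiplier 1.0 → 0.4) toward
  adulthood, plus 15% timepoint-private genes; and 3 aging timepoints
  (emulating 16/24/29 months vs adult) with a partially disjoint
  signature (25% shared with the developmental core, directions
  preserved) whose magnitudes grow with age (0.5 → 1.0).
- **Noise model**: signature genes draw |log2 FC| ~ N(1, 0.3) truncated
  at 0.3 and a p-value from a one-sample z model, p = 2Φ(−|log2 FC|/0.25);
  null genes draw log2 FC ~ N(0, 0.1) and p ~ U(0,1). This makes the
  |FC| > 1.2, p < 0.05 filter meaningful without simulating read counts
  (null genes pass both filters at ≈5·10⁻⁴).
- **Models**: 19 by default — 17 concordance-planted on a grid
  f ∈ [0.30, 0.95] (emulating the 17 screened hyper-maturity datasets)
  and two discordant (f = −0.7, −0.4; planted immaturity). A fraction |f|
  of the reference signature is differentially expressed in the model,
  concordant when f > 0 and inverted when f < 0, plus 400 background DEGs
  from signature-free genes. Models can be planted against the
  developmental core or the aging signature per a family vector.
- **Behavior**: per model 1–3 measures drawn from a catalog with both
  polarities (e.g. time in open arms, polarity −1; latency to the light
  box, +1). The population polarity-adjusted d is slope·f + N(0, σ) with
  slope 1 and σ = 0.2; reported group means/SDs are sampled at 20 animals
  per group. The group size is the one free parameter neither stated nor
  derivable: it was set once so that the generator satisfies its stated
  recovery property (E[Pearson r between planted f and recovered d] ≥
  0.8 under slope 1, σ = 0.2; at n = 10 sampling noise of d caps E[r]
  near 0.72). Twenty per group is within the usual range for mouse
  behavioral batteries.
- **Cell-type atlas**: 11 cell types named after the dentate-gyrus
  single-cell populations (granule cells, microglia, astrocytes, stem
  and progenitor pools, vascular types, …). Designated contributors
  (default microglia at share 0.5) carry that fraction of the aging
  signature with concordant directions; every cell type carries 300
  background DEGs.
- **Gene sets**: 50 terms; one designated term contains the full
  developmental core plus 100 padding genes, the rest are random draws
  of 50–300 genes.

Everything is a pure function of the config (identical seed ⇒ identical
output, asserted byte-level on the pipeline report), and ground truth is
returned with the data and written as plain TSV sidecars.

What the generator does **not** emulate: read counts, library sizes or
any sequencing-level noise; platform or batch effects; cross-species
ortholog mapping (gene identity is by uppercased symbol, with an optional
two-column override map); correlation structure among genes; or the
composition of a real 260 000-dataset database (screening operates on
user-supplied region/life-stage metadata, reproducing the logic, not the
catalog). Passing tests therefore demonstrate that the statistics recover
the structure they assume — not that real datasets satisfy those
assumptions.

## Degenerate inputs and tie-breaking

Empty ranked lists yield overlap p = 1; zero-log2FC records carry no
direction and are dropped with a warning; an empty aging signature warns
and scores every cell type 0; duplicate gene ids in a table collapse to
the most significant record; enrichment ranking and screening order break
ties lexicographically so output is deterministic.

## Problem sizes in the test suite and acceptance script

Unit tests run on a scaled cohort (4 000 genes, 200-gene signatures, 6
models). The statistical validation suite uses the full default
conditions: 200 replicate 19-model cohorts for concordance and
correlation recovery, 100 seeds each for classification (12 + 5 planted
models), cell-type and enrichment recovery, 1000 replicates for null
calibration, and exhaustive enumeration up to N = 12 for the exact-tail
oracle. `scripts/acceptance.py` recomputes the same quantities at 25–400
replicates per check so a complete run stays in the minutes range.

## Known limitations

- The decile scan is a stand-in for an undisclosed procedure; absolute
  overlap P values are not comparable to the platform's, only their
  qualitative behavior (sign, ordering, calibration) is.
- The maturity-anxiety Pearson r is attenuated relative to the planted
  link because the index is a nonlinear (log-p) transform of concordance
  and behavioral effect sizes carry sampling noise; rank correlation is
  the faithful recovery metric.
- Cross-species comparison by symbol matching is a crude surrogate for
  homology mapping.
- The two-group PCA split assumes exactly two phenotype dimensions; with
  fewer than three models or a zero-variance column the classifier
  refuses rather than guesses.
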