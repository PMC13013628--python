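# hippomaturity

Cross-dataset transcriptomic maturity analysis for the hippocampus:
screening differential-expression (DEG) signatures for *hyper-maturity*
(concordance with postnatal developmental expression change) and
*accelerated aging* (concordance with old-vs-adult change), and relating
the result to anxiety-like behavior.

The package is aimed at computational neuroscientists who want the full
screening pipeline — directional signature overlap, signed indices,
behavioral effect sizes, phenotype grouping, enrichment meta-analysis and
cell-type contribution scoring — as open, deterministic, testable code,
exercisable end to end on synthetic cohorts with planted ground truth
instead of a proprietary omics database.

## The statistics at the core

**Signed rank-scan overlap.** Two filtered DEG lists (|FC| > 1.2,
p < 0.05) are split into up/down genes ranked by |log2 FC|. For each
direction pair (up/up, down/down, up/down, down/up) a decile grid of
rank cutoffs is scanned and the exact hypergeometric upper tail

P[X ≥ k],  X ~ Hypergeom(N, k_A, k_B)

is evaluated for every prefix pair, Bonferroni-corrected for the grid.
Concordant and discordant quadrant pairs are each combined by Fisher's
method (χ², 4 df); the overall overlap P is the smaller of the two, with
sign +1 when concordance dominates. All tails are computed in log space,
so indices stay exact far below double-precision underflow.

**Indices.** Maturity (or aging) index = sign × (−log10 overlap P)
against the reference panel, one value per model (most significant
timepoint). Anxiety index = polarity-adjusted Cohen's d from group
summaries, d = (M_model − M_control)/S_pooled with
S_pooled = √((S²_model + S²_control)/2), averaged over a model's
measures. The two axes are related by Pearson r with the exact two-sided
p from t = r√(n−2)/√(1−r²).

**Downstream.** PCA on the column-standardized signed index matrix with
deterministic 2-means splits models into development-like vs aging-like
groups; concordant feature genes feed a hypergeometric + Fisher
meta-enrichment over GMT collections; and per-cell-type old-vs-young DEG
lists score each cell type's contribution to a model's accelerated-aging
signature (−log10 P, floored at 0 when discordant).

## Worked example

```bash
python analysis/04_maturity_anxiety.py
```

generates the default synthetic cohort (19 models over a 20 000-gene
universe, 17 planted concordant with development, 2 planted immature),
compares every model with the seven developmental reference timepoints,
and correlates the maturity index with the behavioral anxiety index:

```
maturity vs anxiety over 19 models:
  Pearson r = 0.813, two-sided p = 2.3e-05
  regression line: anxiety = 0.0014 * maturity + -0.080
  Spearman(planted concordance, maturity) = 1.000
table -> results/indices.tsv
```

The Spearman of 1.0 says the planted concordance grid is recovered in
exact rank order by the signed overlap index; the Pearson r relates that
transcriptomic axis to the anxiety effect sizes the generator linked to
it (slope 1, noise SD 0.2). The same cohort can be pushed through the
other numbered drivers: `02` screens candidates (17/19 pass the
hippocampus + overlap P < 1e-10 rule, and only concordance-planted
models do), `05` groups a 12 + 5 cohort into development-like vs
aging-like with 17/17 agreement, `06` recovers the gene-set term that
seeded the signature as the top meta-enrichment hit, and `07` ranks the
designated contributor cell type (microglia) first.

Or run everything at once:

```bash
hippomaturity run-all --seed 1 --out results/run
```

## Library layout

| module | contents |
| --- | --- |
| `hippomaturity.deg_io` | DEG-table / GMT reading, validation, the FC/p filter, universe harmonization |
| `hippomaturity.running_fisher` | the signed rank-scan overlap statistic |
| `hippomaturity.indices` | maturity/aging indices, Cohen's d, correlation |
| `hippomaturity.enrichment` | hypergeometric enrichment + Fisher meta-analysis |
| `hippomaturity.classification` | PCA + deterministic 2-means phenotype grouping |
| `hippomaturity.celltype` | aging-signature extraction and contribution scores |
| `hippomaturity.synthetic` | the cohort generator with planted ground truth |
| `hippomaturity.pipeline` | screening rules and end-to-end orchestration |
| `hippomaturity.cli` | `hippomaturity` command with one subcommand per stage |

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and known limitations.

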