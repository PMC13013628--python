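#!/usr/bin/env python
"""Build the model x reference matrix of signed -log10 overlap P values.

Every model is compared directionally against every developmental and
aging reference timepoint; the signed index matrix is the input to both
the per-model maturity/aging summaries and the PCA grouping.
"""

from pathlib import Path

from hippomaturity.classification import build_index_matrix
from hippomaturity.deg_io import apply_filter
from hippomaturity.running_fisher import compare_datasets
from hippomaturity.synthetic import (
    SimulationConfig,
    make_model_cohort,
    make_reference_panel,
    reference_ids,
)

ROOT = Path(__file__).resolve().parent.parent

config = SimulationConfig(seed=1)
panel, _ = make_reference_panel(config)
dev_ids, aging_ids = reference_ids(config)
refs = [apply_filter(r) for r in panel]
models, _ = make_model_cohort(config)

overlaps = {
    (m.dataset_id, r.dataset_id): compare_datasets(
        apply_filter(m), r, config.n_genes_universe
    )
    for m in models
    for r in refs
}
matrix = build_index_matrix(
    overlaps, [m.dataset_id for m in models], dev_ids + aging_ids
)
out = ROOT / "results" / "index_matrix.tsv"
out.parent.mkdir(exist_ok=True)
matrix.rename_axis("model_id").to_csv(out, sep="\t", float_format="%.6g")

print(f"matrix: {matrix.shape[0]} models x {matrix.shape[1]} references")
strongest = matrix[dev_ids].max(axis=1).idxmax()
weakest = matrix[dev_ids].max(axis=1).idxmin()
print(f"strongest developmental concordance: {strongest} "
      f"(index {matrix.loc[strongest, dev_ids].max():.0f})")
print(f"weakest: {weakest} (index {matrix.loc[weakest, dev_ids].max():.0f})")
print(f"matrix -> {out.relative_to(ROOT)}")
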