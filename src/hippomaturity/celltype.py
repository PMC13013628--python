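"""Cell-type contribution scoring for an accelerated-aging signature.

A model's accelerated-aging signature is the set of genes it shares, with
matching direction, with an aged-vs-adult reference list. Each cell
type's own old-vs-young DEG list (from single-cell data, supplied as a
per-cell-type table) is then compared directionally against that
signature; the contribution score is -log10 of the signed overlap P when
the comparison is concordant and 0 when it is discordant, with the
percentage of signature genes shared as a companion magnitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .deg_io import DEGList, FilterCriteria, apply_filter
from .running_fisher import ScanConfig, compare_datasets, extract_concordant_genes


@dataclass
class CellTypeAtlas:
    """Per-cell-type old-vs-young DEG lists over a shared universe."""

    celltypes: dict  # name -> DEGList
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        if not self.celltypes:
            raise ValueError("atlas needs at least one cell type")
        if len(set(self.celltypes)) != len(self.celltypes):
            raise ValueError("cell type names must be unique")

    def __len__(self) -> int:
        return len(self.celltypes)


@dataclass(frozen=True)
class ContributionScore:
    model_id: str
    celltype_name: str
    neg_log_p: float  # >= 0; 0 when the comparison is discordant
    percent_common: float  # 100 * |signature ∩ celltype DEGs| / |signature|


def aging_signature(
    model: DEGList,
    aged_reference: DEGList,
    n_universe: int,
    scan: ScanConfig = ScanConfig(),
) -> DEGList:
    """Concordant shared genes of a model vs an aged reference.

    Returns the model's records restricted to genes up in both or down in
    both lists (directions and effect sizes retained for downstream
    ranking). Both inputs must already be filtered.
    """
    result = compare_datasets(model, aged_reference, n_universe, scan)
    up_shared, down_shared = extract_concordant_genes(result)
    keep = set(up_shared) | set(down_shared)
    if not keep:
        warnings.warn(
            f"{model.dataset_id} vs {aged_reference.dataset_id}: empty aging signature"
        )
    sig = model.with_records(model.records[model.records["gene_id"].isin(keep)])
    sig.dataset_id = f"{model.dataset_id}|aging_signature"
    return sig


def score_contributions(
    signature: DEGList,
    atlas: CellTypeAtlas,
    n_universe: int,
    scan: ScanConfig = ScanConfig(),
    criteria: FilterCriteria = FilterCriteria(),
) -> list:
    """Score every cell type's contribution to an aging signature.

    Each cell type's DEG list is filtered (|FC| > 1.2, p < 0.05 by
    default) and compared directionally with the signature; neg_log_p is
    floored at 0 for discordant comparisons since the score is a
    contribution magnitude. Scores are independent across cell types.
    """
    scores = []
    n_sig = len(signature)
    for name in sorted(atlas.celltypes):
        if n_sig == 0:
            scores.append(ContributionScore(signature.dataset_id, name, 0.0, 0.0))
            continue
        ct = apply_filter(atlas.celltypes[name], criteria)
        if len(ct) == 0:
            scores.append(ContributionScore(signature.dataset_id, name, 0.0, 0.0))
            continue
        result = compare_datasets(signature, ct, n_universe, scan)
        neg_log_p = -result.overall_log10p if result.sign > 0 else 0.0
        shared = signature.genes & ct.genes
        scores.append(
            ContributionScore(
                model_id=signature.dataset_id,
                celltype_name=name,
                neg_log_p=neg_log_p,
                percent_common=100.0 * len(shared) / n_sig,
            )
        )
    return scores
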