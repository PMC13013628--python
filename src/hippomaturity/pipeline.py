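"""End-to-end orchestration: simulate, filter, compare, index, classify,
enrich, score cell types, and screen — with every threshold logged and
every report numeric reproducible from the stage files it cites."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .celltype import aging_signature, score_contributions
from .classification import build_index_matrix, classify_models
from .deg_io import DEGList, FilterCriteria, apply_filter
from .enrichment import meta_enrich
from .indices import (
    IndexTable,
    correlate_indices,
    model_anxiety_index,
    model_maturity_summary,
)
from .running_fisher import ScanConfig, compare_datasets, extract_concordant_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningConfig:
    """Candidate screening rules: tissue keyword, life-stage exclusions,
    and the signed overlap-P threshold against the development panel."""

    region_keyword: str = "Hippocampus"
    overlap_p_threshold: float = 1e-10
    exclusion_labels: frozenset = frozenset({"embryo", "infant", "cultured"})

    def __post_init__(self) -> None:
        if not 0 < self.overlap_p_threshold < 1:
            raise ValueError("overlap_p_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    simulation: synthetic.SimulationConfig = synthetic.SimulationConfig()
    filter_criteria: FilterCriteria = FilterCriteria()
    scan: ScanConfig = ScanConfig()
    screening: ScreeningConfig = ScreeningConfig()
    outdir: str = "results/run"

    @property
    def n_universe(self) -> int:
        return self.simulation.n_genes_universe

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic.SimulationConfig(**raw.get("simulation", {}))
        filt = FilterCriteria(**raw.get("filter_criteria", {}))
        scan_raw = dict(raw.get("scan", {}))
        if "cutoff_fractions" in scan_raw:
            scan_raw["cutoff_fractions"] = tuple(scan_raw["cutoff_fractions"])
        scan = ScanConfig(**scan_raw)
        screen_raw = dict(raw.get("screening", {}))
        if "exclusion_labels" in screen_raw:
            screen_raw["exclusion_labels"] = frozenset(screen_raw["exclusion_labels"])
        screening = ScreeningConfig(**screen_raw)
        return cls(
            simulation=sim,
            filter_criteria=filt,
            scan=scan,
            screening=screening,
            outdir=raw.get("outdir", "results/run"),
        )


def screen_candidates(candidates, references, config: RunConfig, overlaps=None):
    """Screen candidate datasets against the development reference panel.

    A candidate passes when its region label contains the keyword
    (case-insensitive), its life stage is not excluded, and it reaches a
    concordant (sign +1) overlap P below the threshold against at least
    one development reference. Returns ``(dataset_id, best SignedOverlap)``
    pairs sorted by ascending best overlap P. ``candidates`` must be
    filtered DEG lists; ``overlaps`` may supply precomputed comparisons
    keyed by (dataset_id, reference_id).
    """
    references = list(references)
    if not references:
        raise ValueError("empty reference panel")
    scr = config.screening
    hits = []
    for cand in candidates:
        if scr.region_keyword.lower() not in cand.region.lower():
            logger.info("screen: %s excluded by region %r", cand.dataset_id, cand.region)
            continue
        if cand.life_stage.lower() in scr.exclusion_labels:
            logger.info(
                "screen: %s excluded by life stage %r", cand.dataset_id, cand.life_stage
            )
            continue
        best = None
        for ref in references:
            key = (cand.dataset_id, ref.dataset_id)
            ov = (
                overlaps[key]
                if overlaps is not None and key in overlaps
                else compare_datasets(cand, ref, config.n_universe, config.scan)
            )
            if ov.sign == 1 and (best is None or ov.overall_p < best.overall_p):
                best = ov
        if best is not None and best.overall_p < scr.overlap_p_threshold:
            hits.append((cand.dataset_id, best))
    hits.sort(key=lambda item: (item[1].overall_p, item[0]))
    return hits


@dataclass
class ReportBundle:
    index_table: IndexTable
    maturity: pd.Series
    aging: pd.Series
    anxiety: pd.Series
    correlation: object
    assignment: object
    enrichment: pd.DataFrame | None
    contributions: pd.DataFrame
    screening: list
    summary: dict


def run_all(config: RunConfig = RunConfig()) -> ReportBundle:
    """Execute the full synthetic analysis and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    logger.info(
        "run_all: seed=%d filter=|FC|>%g,p<%g scan=%s threshold=%g",
        sim.seed,
        config.filter_criteria.min_abs_fold_change,
        config.filter_criteria.max_pvalue,
        config.scan.correction,
        config.screening.overlap_p_threshold,
    )

    panel, _ = synthetic.make_reference_panel(sim)
    models, model_truths = synthetic.make_model_cohort(sim)
    measures, _ = synthetic.make_behavior_table(sim)
    atlas, _ = synthetic.make_celltype_atlas(sim)
    collection, _ = synthetic.make_geneset_collection(sim)

    refs_f = [apply_filter(r, config.filter_criteria) for r in panel]
    models_f = [apply_filter(m, config.filter_criteria) for m in models]
    dev_ids, aging_ids = synthetic.reference_ids(sim)
    families = {r: "development" for r in dev_ids}
    families.update({r: "aging" for r in aging_ids})

    overlaps = {
        (m.dataset_id, r.dataset_id): compare_datasets(
            m, r, config.n_universe, config.scan
        )
        for m in models_f
        for r in refs_f
    }

    table = IndexTable.from_overlaps(overlaps, families)
    maturity = model_maturity_summary(table, "development")
    aging = model_maturity_summary(table, "aging")
    by_model: dict = {}
    for m in measures:
        by_model.setdefault(m.model_id, []).append(m)
    anxiety = pd.Series(
        {mid: model_anxiety_index(ms) for mid, ms in by_model.items()}, name="anxiety"
    ).reindex(maturity.index)
    corr = correlate_indices(maturity.to_numpy(), anxiety.to_numpy())

    matrix = build_index_matrix(
        overlaps, [m.dataset_id for m in models_f], [r.dataset_id for r in refs_f]
    )
    assignment = classify_models(matrix, development_columns=dev_ids)

    screening = screen_candidates(models_f, refs_f[: len(dev_ids)], config, overlaps)
    screened_ids = [sid for sid, _ in screening]

    queries = {}
    for sid, best in screening:
        up, down = extract_concordant_genes(best)
        genes = set(up) | set(down)
        if genes:
            queries[sid] = genes
    enrichment = (
        meta_enrich(queries, collection, config.n_universe)
        if len(queries) >= 2
        else None
    )

    aged_ref = refs_f[len(dev_ids) + sim.n_aging_timepoints - 1]
    aging_like = sorted(
        mid for mid, g in assignment.groups.items() if g == "aging_like"
    )
    if not aging_like:
        aging_like = [aging.abs().idxmax()]
    model_by_id = {m.dataset_id: m for m in models_f}
    contrib_rows = []
    for mid in aging_like:
        sig = aging_signature(
            model_by_id[mid], aged_ref, config.n_universe, config.scan
        )
        for s in score_contributions(
            sig, atlas, config.n_universe, config.scan, config.filter_criteria
        ):
            contrib_rows.append(
                {
                    "model_id": mid,
                    "celltype": s.celltype_name,
                    "neg_log_p": s.neg_log_p,
                    "percent_common": s.percent_common,
                }
            )
    contributions = pd.DataFrame(contrib_rows)

    planted = pd.Series(
        {t.model_id: t.concordance for t in model_truths}, name="planted_concordance"
    ).reindex(maturity.index)
    spearman = float(maturity.corr(planted, method="spearman"))

    summary = {
        "seed": sim.seed,
        "n_models": sim.n_models,
        "n_references": len(refs_f),
        "filter": {
            "min_abs_fold_change": config.filter_criteria.min_abs_fold_change,
            "max_pvalue": config.filter_criteria.max_pvalue,
        },
        "screening_threshold": config.screening.overlap_p_threshold,
        "n_screened": len(screened_ids),
        "screened_ids": screened_ids,
        "maturity_anxiety": {
            "r": corr.r,
            "p_two_sided": corr.p_two_sided,
            "slope": corr.slope,
            "intercept": corr.intercept,
            "n": corr.n,
        },
        "spearman_planted_vs_maturity": spearman,
        "groups": {
            "development_like": sorted(
                m for m, g in assignment.groups.items() if g == "development_like"
            ),
            "aging_like": sorted(
                m for m, g in assignment.groups.items() if g == "aging_like"
            ),
        },
        "explained_variance_fractions": list(
            assignment.explained_variance_fractions
        ),
        "top_enriched_term": None
        if enrichment is None
        else str(enrichment.iloc[0]["term_id"]),
    }

    # stage outputs: every numeric in summary.json recomputable from these
    matrix.rename_axis("model_id").to_csv(
        outdir / "index_matrix.tsv", sep="\t", float_format="%.6g"
    )
    scatter = pd.DataFrame(
        {"maturity_index": maturity, "aging_index": aging, "anxiety_index": anxiety}
    )
    scatter.rename_axis("model_id").to_csv(
        outdir / "indices.tsv", sep="\t", float_format="%.6g"
    )
    pd.DataFrame(
        {
            "model_id": list(assignment.groups),
            "group": [assignment.groups[m] for m in assignment.groups],
            "PC1": assignment.pc_scores["PC1"].to_numpy(),
            "PC2": assignment.pc_scores["PC2"].to_numpy(),
        }
    ).to_csv(outdir / "assignment.tsv", sep="\t", index=False, float_format="%.6g")
    if enrichment is not None:
        enrichment.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
    contributions.to_csv(
        outdir / "contributions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        [
            {"dataset_id": sid, "best_overall_p": ov.overall_p, "sign": ov.sign}
            for sid, ov in screening
        ]
    ).to_csv(outdir / "screening.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ReportBundle(
        index_table=table,
        maturity=maturity,
        aging=aging,
        anxiety=anxiety,
        correlation=corr,
        assignment=assignment,
        enrichment=enrichment,
        contributions=contributions,
        screening=screening,
        summary=summary,
    )
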