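"""Synthetic cohort generator with planted, recoverable structure.

Emulates the inputs of the cross-dataset maturity analysis without any
downloads: a developmental reference panel (seven timepoints whose
per-gene effect magnitudes decay toward adulthood), an aging panel (three
timepoints, partially disjoint signature, magnitudes growing with age), a
cohort of model datasets with tunable direction-concordance against a
reference signature, behavioral summary tables whose true effect sizes
are linearly linked to the planted concordance, an 11-cell-type aging DEG
atlas with designated contributor cell types, and a gene-set collection
whose designated term seeds the developmental signature.

Noise model: signature genes draw |log2FC| ~ Normal(mu=1, sd=0.3)
truncated below at 0.3 (scaled by the timepoint multiplier) and get a
p-value from a one-sample z model (p = 2*Phi(-|log2fc|/0.25)); null genes
draw log2FC ~ Normal(0, 0.1) with p ~ Uniform(0, 1). This makes the
standard |FC| > 1.2, p < 0.05 filter meaningful without simulating read
counts. Every generator is a pure function of the config (identical seed,
identical output), and ground truth is returned alongside the data and
written as plain TSV sidecars by :func:`write_run`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .celltype import CellTypeAtlas
from .deg_io import DEGList, GeneSetCollection, write_deg_table, write_gmt
from .indices import BehavioralMeasure

DEV_AGES_DAYS = (8, 11, 14, 17, 21, 25, 29)
AGING_AGES_MONTHS = (16, 24, 29)
CELLTYPE_NAMES = (
    "astrocyte",
    "quiescent_nsc",
    "active_nsp",
    "neuroblast",
    "granule_cell",
    "cajal_retzius",
    "opc",
    "endothelial",
    "pericyte",
    "smooth_muscle",
    "microglia",
)

#: behavioral measure catalog: (name, polarity); +1 = larger means more anxiety
MEASURE_CATALOG = (
    ("time_in_open_arms", -1),
    ("latency_to_light_box", 1),
    ("time_in_light_box", -1),
    ("center_time_open_field", -1),
    ("marble_burying_count", 1),
)

EFFECT_SE = 0.25  # per-gene standard error of the one-sample z model
DEV_CORE_FRACTION = 0.85  # shared core across developmental timepoints
AGING_DEV_OVERLAP = 0.25  # fraction of the aging signature shared with the dev core


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def _default_grid(n_models: int):
    """17 hyper-maturity models on a positive grid plus immaturity models."""
    n_neg = max(0, min(2, n_models - 1)) if n_models >= 3 else 0
    n_pos = n_models - n_neg
    pos = tuple(np.round(np.linspace(0.30, 0.95, n_pos), 4))
    neg = (-0.7, -0.4)[:n_neg]
    return pos + neg


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the published design: a 20000-gene universe, seven
    developmental and three aging reference timepoints, 800-gene
    signatures (half up, half down), 19 models (17 concordant with
    development plus two planted-immature), and a unit-slope link from
    planted concordance to the behavioral effect size with residual SD
    0.2.
    """

    n_genes_universe: int = 20000
    n_dev_timepoints: int = 7
    n_aging_timepoints: int = 3
    signature_size: int = 800
    n_models: int = 19
    concordance_grid: tuple = None
    model_families: tuple = None  # "development" or "aging" per model
    link_slope: float = 1.0
    link_noise_sd: float = 0.2
    behavior_group_n: int = 20
    n_background_degs: int = 400
    n_celltypes: int = 11
    contributors: tuple = ("microglia",)
    contributor_shares: tuple = (0.5,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concordance_grid is None:
            object.__setattr__(self, "concordance_grid", _default_grid(self.n_models))
        object.__setattr__(
            self, "concordance_grid", tuple(float(f) for f in self.concordance_grid)
        )
        if self.model_families is None:
            object.__setattr__(
                self, "model_families", ("development",) * self.n_models
            )
        object.__setattr__(self, "model_families", tuple(self.model_families))
        object.__setattr__(self, "contributors", tuple(self.contributors))
        object.__setattr__(
            self, "contributor_shares", tuple(float(s) for s in self.contributor_shares)
        )
        if self.signature_size > self.n_genes_universe:
            raise InvalidConfigError("signature_size exceeds the gene universe")
        if self.signature_size < 4 or self.signature_size % 2:
            raise InvalidConfigError("signature_size must be an even integer >= 4")
        if len(self.concordance_grid) != self.n_models:
            raise InvalidConfigError("concordance_grid length must equal n_models")
        if any(not -1 <= f <= 1 for f in self.concordance_grid):
            raise InvalidConfigError("concordance fractions must lie in [-1, 1]")
        if len(self.model_families) != self.n_models:
            raise InvalidConfigError("model_families length must equal n_models")
        if any(f not in ("development", "aging") for f in self.model_families):
            raise InvalidConfigError("model families must be 'development' or 'aging'")
        if not 1 <= self.n_celltypes <= len(CELLTYPE_NAMES):
            raise InvalidConfigError(f"n_celltypes must be 1..{len(CELLTYPE_NAMES)}")
        if len(self.contributors) != len(self.contributor_shares):
            raise InvalidConfigError("one share per designated contributor required")
        if any(not 0 <= s <= 1 for s in self.contributor_shares):
            raise InvalidConfigError("contributor shares must lie in [0, 1]")
        needed = (
            self.signature_size  # dev core
            + self.signature_size  # aging-only reserve
            + self.n_dev_timepoints * self._n_private
            + self.n_background_degs
        )
        if needed > self.n_genes_universe:
            raise InvalidConfigError(
                f"universe of {self.n_genes_universe} too small for the planted "
                f"structure ({needed} genes needed)"
            )

    @property
    def _n_private(self) -> int:
        return int(round((1 - DEV_CORE_FRACTION) * self.signature_size))


@dataclass(frozen=True)
class ReferenceTruth:
    """Generator bookkeeping for the reference panel."""

    universe: tuple
    dev_core_genes: tuple
    dev_core_directions: dict  # gene -> +1 / -1
    dev_core_magnitudes: dict  # gene -> base |log2FC| at the earliest timepoint
    dev_timepoint_signatures: tuple  # per timepoint: dict gene -> (direction, |log2fc|)
    dev_multipliers: tuple
    aging_genes: tuple
    aging_directions: dict
    aging_magnitudes: dict
    aging_multipliers: tuple
    background_pool: tuple  # genes free of any planted signature


@dataclass(frozen=True)
class ModelTruth:
    model_id: str
    concordance: float
    family: str
    planted_genes: tuple
    planted_directions: dict


_TRUTH_CACHE: dict = {}
_INDEX_CACHE: dict = {}


def _gene_index(config) -> dict:
    if config not in _INDEX_CACHE:
        _INDEX_CACHE[config] = {
            g: i for i, g in enumerate(reference_truth(config).universe)
        }
    return _INDEX_CACHE[config]


def _truncnorm_mag(rng, size):
    return np.maximum(0.3, rng.normal(1.0, 0.3, size))


def _z_model_p(mag):
    """p-value consistent with |log2fc| = mag under the one-sample z model."""
    return np.clip(2.0 * stats.norm.sf(np.asarray(mag) / EFFECT_SE), 1e-300, 1.0)


def reference_truth(config: SimulationConfig) -> ReferenceTruth:
    """Deterministic planted structure shared by every generator."""
    if config in _TRUTH_CACHE:
        return _TRUTH_CACHE[config]
    rng = np.random.default_rng([config.seed, 0])
    n, s = config.n_genes_universe, config.signature_size
    universe = np.array([f"G{i:05d}" for i in range(n)])
    perm = rng.permutation(n)
    core_idx = perm[:s]
    core = universe[core_idx]
    directions = {}
    half = s // 2
    for i, g in enumerate(core):
        directions[g] = 1 if i < half else -1
    core_mag = dict(zip(core, _truncnorm_mag(rng, s)))

    n_common = int(round(DEV_CORE_FRACTION * s))
    common = core[:n_common]
    n_priv = config._n_private
    n_aging_shared = int(round(AGING_DEV_OVERLAP * s))
    aging_shared = rng.choice(core, n_aging_shared, replace=False)
    aging_only = universe[perm[s : s + (s - n_aging_shared)]]
    aging_genes = np.concatenate([aging_shared, aging_only])
    aging_dirs = {}
    aging_mags = {}
    mags_new = _truncnorm_mag(rng, len(aging_only))
    dirs_new = rng.choice([1, -1], len(aging_only))
    for g in aging_shared:
        aging_dirs[g] = directions[g]  # shared trajectory keeps its direction
        aging_mags[g] = core_mag[g]
    for g, d, m in zip(aging_only, dirs_new, mags_new):
        aging_dirs[g] = int(d)
        aging_mags[g] = float(m)

    priv_start = 2 * s - n_aging_shared
    dev_mult = tuple(np.linspace(1.0, 0.4, config.n_dev_timepoints))
    timepoint_sigs = []
    for t in range(config.n_dev_timepoints):
        sig = {}
        mult = dev_mult[t]
        for g in common:
            sig[g] = (directions[g], core_mag[g] * mult)
        priv = universe[perm[priv_start + t * n_priv : priv_start + (t + 1) * n_priv]]
        priv_mag = _truncnorm_mag(rng, n_priv)
        priv_dir = rng.choice([1, -1], n_priv)
        for g, d, m in zip(priv, priv_dir, priv_mag):
            sig[g] = (int(d), float(m * mult))
        timepoint_sigs.append(sig)

    bg_start = priv_start + config.n_dev_timepoints * n_priv
    background_pool = universe[perm[bg_start:]]
    truth = ReferenceTruth(
        universe=tuple(universe),
        dev_core_genes=tuple(core),
        dev_core_directions=directions,
        dev_core_magnitudes=core_mag,
        dev_timepoint_signatures=tuple(timepoint_sigs),
        dev_multipliers=dev_mult,
        aging_genes=tuple(aging_genes),
        aging_directions=aging_dirs,
        aging_magnitudes=aging_mags,
        aging_multipliers=tuple(np.linspace(0.5, 1.0, config.n_aging_timepoints)),
        background_pool=tuple(background_pool),
    )
    _TRUTH_CACHE[config] = truth
    return truth


def _assemble_deg_list(
    config, rng, dataset_id, signature, *, region="DG", life_stage="adult"
) -> DEGList:
    """Full-universe DEG table: planted signature plus null background."""
    truth = reference_truth(config)
    universe = np.asarray(truth.universe)
    n = len(universe)
    log2fc = rng.normal(0.0, 0.1, n)
    pvals = rng.uniform(0.0, 1.0, n)
    if signature:
        idx = _gene_index(config)
        sig_idx = np.fromiter((idx[g] for g in signature), dtype=int, count=len(signature))
        dirs = np.fromiter((signature[g][0] for g in signature), dtype=float)
        mags = np.fromiter((signature[g][1] for g in signature), dtype=float)
        log2fc[sig_idx] = dirs * mags
        pvals[sig_idx] = _z_model_p(mags)
    records = pd.DataFrame(
        {"gene_id": universe, "log2fc": log2fc, "pvalue": pvals}
    )
    return DEGList(
        dataset_id=dataset_id,
        records=records,
        species="mouse",
        region=region,
        life_stage=life_stage,
        universe=None,  # shared universe handled via harmonize fallback
    )


def reference_ids(config: SimulationConfig):
    """(development ids, aging ids) on the emulated age scales."""
    if config.n_dev_timepoints == len(DEV_AGES_DAYS):
        dev = [f"dev_{a:02d}d" for a in DEV_AGES_DAYS]
    else:
        dev = [f"dev_t{i}" for i in range(config.n_dev_timepoints)]
    if config.n_aging_timepoints == len(AGING_AGES_MONTHS):
        aging = [f"aged_{a}m" for a in AGING_AGES_MONTHS]
    else:
        aging = [f"aged_t{i}" for i in range(config.n_aging_timepoints)]
    return dev, aging


def make_reference_panel(config: SimulationConfig):
    """Developmental + aging reference DEG lists over the shared universe.

    Returns ``(panel, truth)``: n_dev + n_aging lists in reference-id
    order, and the :class:`ReferenceTruth` bookkeeping.
    """
    truth = reference_truth(config)
    dev_ids, aging_ids = reference_ids(config)
    panel = []
    for t, ref_id in enumerate(dev_ids):
        rng = np.random.default_rng([config.seed, 1, t])
        panel.append(
            _assemble_deg_list(
                config, rng, ref_id, truth.dev_timepoint_signatures[t]
            )
        )
    for t, ref_id in enumerate(aging_ids):
        mult = truth.aging_multipliers[t]
        sig = {
            g: (truth.aging_directions[g], truth.aging_magnitudes[g] * mult)
            for g in truth.aging_genes
        }
        rng = np.random.default_rng([config.seed, 1, 100 + t])
        panel.append(_assemble_deg_list(config, rng, ref_id, sig))
    return panel, truth


def make_model_dataset(config: SimulationConfig, model_index: int):
    """One model dataset with planted concordance f against its reference.

    A fraction |f| of the reference signature genes (developmental core or
    aging signature, per ``model_families``) is differentially expressed
    in the model — same direction as the reference when f > 0, opposite
    when f < 0 — plus ``n_background_degs`` significant genes drawn from
    signature-free background. Returns ``(deg_list, truth)``.
    """
    if not 0 <= model_index < config.n_models:
        raise InvalidConfigError(f"model_index {model_index} out of range")
    truth = reference_truth(config)
    f = config.concordance_grid[model_index]
    family = config.model_families[model_index]
    rng = np.random.default_rng([config.seed, 2, model_index])
    if family == "development":
        ref_genes = np.asarray(truth.dev_core_genes)
        ref_dirs = truth.dev_core_directions
    else:
        ref_genes = np.asarray(truth.aging_genes)
        ref_dirs = truth.aging_directions
    n_planted = int(round(abs(f) * config.signature_size))
    planted = rng.choice(ref_genes, n_planted, replace=False) if n_planted else []
    orientation = 1 if f >= 0 else -1
    signature = {}
    mags = _truncnorm_mag(rng, n_planted)
    for g, m in zip(planted, mags):
        signature[g] = (orientation * ref_dirs[g], float(m))
    background = rng.choice(
        np.asarray(truth.background_pool), config.n_background_degs, replace=False
    )
    bg_mags = _truncnorm_mag(rng, config.n_background_degs)
    bg_dirs = rng.choice([1, -1], config.n_background_degs)
    for g, d, m in zip(background, bg_dirs, bg_mags):
        signature[g] = (int(d), float(m))
    model_id = f"model_{model_index:02d}"
    deg = _assemble_deg_list(
        config, rng, model_id, signature, region="Hippocampus", life_stage="adult"
    )
    model_truth = ModelTruth(
        model_id=model_id,
        concordance=f,
        family=family,
        planted_genes=tuple(planted),
        planted_directions={g: signature[g][0] for g in planted},
    )
    return deg, model_truth


def make_model_cohort(config: SimulationConfig):
    """All model datasets plus their ground-truth sidecars."""
    models, truths = [], []
    for i in range(config.n_models):
        deg, t = make_model_dataset(config, i)
        models.append(deg)
        truths.append(t)
    return models, truths


def make_behavior_table(config: SimulationConfig):
    """Behavioral summary statistics linked to the planted concordance.

    Per model, 1-3 measures (mixed polarities) whose population
    polarity-adjusted d equals slope * f + Normal(0, noise SD); reported
    group means/SDs are sampled at the configured group size. Returns
    ``(measures, truth_table)``.
    """
    rng = np.random.default_rng([config.seed, 3])
    base_mean, base_sd = 20.0, 5.0
    n = config.behavior_group_n
    measures, rows = [], []
    for i in range(config.n_models):
        f = config.concordance_grid[i]
        d_true = config.link_slope * f + rng.normal(0.0, config.link_noise_sd)
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(MEASURE_CATALOG), k, replace=False)
        for j in chosen:
            name, pol = MEASURE_CATALOG[j]
            ctrl = rng.normal(base_mean, base_sd, n)
            model = rng.normal(base_mean + pol * d_true * base_sd, base_sd, n)
            measures.append(
                BehavioralMeasure(
                    model_id=f"model_{i:02d}",
                    measure=name,
                    polarity=pol,
                    mean_model=float(model.mean()),
                    sd_model=float(model.std(ddof=1)),
                    n_model=n,
                    mean_control=float(ctrl.mean()),
                    sd_control=float(ctrl.std(ddof=1)),
                    n_control=n,
                )
            )
            rows.append(
                {
                    "model_id": f"model_{i:02d}",
                    "measure": name,
                    "polarity": pol,
                    "concordance": f,
                    "d_population": d_true,
                }
            )
    return measures, pd.DataFrame(rows)


def make_celltype_atlas(config: SimulationConfig):
    """Per-cell-type old-vs-young DEG lists with designated contributors.

    Designated contributor cell types carry their configured share of the
    aging reference signature (concordant directions); all cell types
    carry signature-free background DEGs. Returns ``(atlas, truth)`` where
    truth maps cell type -> planted aging-signature genes.
    """
    truth = reference_truth(config)
    names = CELLTYPE_NAMES[: config.n_celltypes]
    share_of = dict(zip(config.contributors, config.contributor_shares))
    unknown = set(config.contributors) - set(names)
    if unknown:
        raise InvalidConfigError(f"unknown contributor cell types: {sorted(unknown)}")
    aging_genes = np.asarray(truth.aging_genes)
    celltypes, planted_truth = {}, {}
    for ct_index, name in enumerate(names):
        rng = np.random.default_rng([config.seed, 4, ct_index])
        signature = {}
        share = share_of.get(name, 0.0)
        n_planted = int(round(share * len(aging_genes)))
        planted = (
            rng.choice(aging_genes, n_planted, replace=False) if n_planted else []
        )
        mags = _truncnorm_mag(rng, n_planted)
        for g, m in zip(planted, mags):
            signature[g] = (truth.aging_directions[g], float(m))
        n_bg = 300
        background = rng.choice(np.asarray(truth.background_pool), n_bg, replace=False)
        bg_dirs = rng.choice([1, -1], n_bg)
        bg_mags = _truncnorm_mag(rng, n_bg)
        for g, d, m in zip(background, bg_dirs, bg_mags):
            signature[g] = (int(d), float(m))
        celltypes[name] = _assemble_deg_list(
            config, rng, f"celltype_{name}", signature, region="DG"
        )
        planted_truth[name] = tuple(planted)
    return CellTypeAtlas(celltypes=celltypes), planted_truth


def make_geneset_collection(config: SimulationConfig, n_terms: int = 50):
    """GMT-style collection whose designated term seeds the dev signature.

    Returns ``(collection, designated_term_id)``; the designated term
    contains the full developmental core plus padding genes, the other
    terms are random draws from the universe.
    """
    truth = reference_truth(config)
    rng = np.random.default_rng([config.seed, 5])
    universe = np.asarray(truth.universe)
    designated_index = int(rng.integers(0, n_terms))
    sets = {}
    for i in range(n_terms):
        term_id = f"GS{i:04d}"
        if i == designated_index:
            padding = rng.choice(universe, 100, replace=False)
            genes = frozenset(truth.dev_core_genes) | frozenset(padding)
            sets[term_id] = ("planted developmental program", genes)
        else:
            size = int(rng.integers(50, 301))
            genes = frozenset(rng.choice(universe, size, replace=False))
            sets[term_id] = (f"random gene set {i}", genes)
    return (
        GeneSetCollection(name="synthetic_collection", sets=sets),
        f"GS{designated_index:04d}",
    )


def behavior_to_frame(measures) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": m.model_id,
                "measure": m.measure,
                "polarity": m.polarity,
                "mean_model": m.mean_model,
                "sd_model": m.sd_model,
                "n_model": m.n_model,
                "mean_control": m.mean_control,
                "sd_control": m.sd_control,
                "n_control": m.n_control,
            }
            for m in measures
        ]
    )


def write_run(config: SimulationConfig, outdir, *, full_tables: bool = True) -> dict:
    """Generate a complete synthetic run and write it under ``outdir``.

    Writes reference and model DEG tables, the behavior table, the
    cell-type atlas, the gene-set collection (GMT), ground-truth sidecar
    TSVs, and a ``manifest.yaml`` describing every file and the seed.
    Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, truth = make_reference_panel(config)
    models, model_truths = make_model_cohort(config)
    measures, behavior_truth = make_behavior_table(config)
    atlas, atlas_truth = make_celltype_atlas(config)
    collection, designated = make_geneset_collection(config)

    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "files": {},
    }

    def _write(deg, rel):
        if full_tables:
            write_deg_table(deg, outdir / rel)
            manifest["files"][deg.dataset_id] = rel

    for deg in panel:
        _write(deg, f"references/{deg.dataset_id}.tsv")
    for deg in models:
        _write(deg, f"models/{deg.dataset_id}.tsv")
    for name, deg in atlas.celltypes.items():
        _write(deg, f"celltypes/{name}.tsv")

    behavior_to_frame(measures).to_csv(
        outdir / "behavior.tsv", sep="\t", index=False, float_format="%.6g"
    )
    manifest["files"]["behavior"] = "behavior.tsv"
    write_gmt(collection, outdir / "genesets.gmt")
    manifest["files"]["genesets"] = "genesets.gmt"
    manifest["designated_term"] = designated

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        {
            "model_id": [t.model_id for t in model_truths],
            "concordance": [t.concordance for t in model_truths],
            "family": [t.family for t in model_truths],
            "n_planted": [len(t.planted_genes) for t in model_truths],
            "planted_genes": [",".join(t.planted_genes) for t in model_truths],
        }
    ).to_csv(truth_dir / "models.tsv", sep="\t", index=False)
    behavior_truth.to_csv(
        truth_dir / "behavior.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        {
            "celltype": list(atlas_truth),
            "planted_genes": [",".join(g) for g in atlas_truth.values()],
        }
    ).to_csv(truth_dir / "celltypes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": list(truth.dev_core_genes),
            "direction": [truth.dev_core_directions[g] for g in truth.dev_core_genes],
        }
    ).to_csv(truth_dir / "dev_core_signature.tsv", sep="\t", index=False)
    manifest["files"]["truth"] = "truth/"
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
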