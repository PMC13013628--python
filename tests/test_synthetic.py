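import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hippomaturity.deg_io import apply_filter
from hippomaturity.synthetic import (
    InvalidConfigError,
    SimulationConfig,
    make_behavior_table,
    make_celltype_atlas,
    make_geneset_collection,
    make_model_dataset,
    make_reference_panel,
    reference_truth,
    write_run,
)


class TestConfig:
    def test_defaults_match_study_design(self):
        cfg = SimulationConfig()
        assert cfg.n_dev_timepoints == 7
        assert cfg.n_aging_timepoints == 3
        assert cfg.n_models == 19 == len(cfg.concordance_grid)
        assert sum(f > 0 for f in cfg.concordance_grid) == 17
        assert all(-1 <= f <= 1 for f in cfg.concordance_grid)

    def test_signature_larger_than_universe_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_genes_universe=100, signature_size=200)

    def test_grid_bounds_enforced(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_models=2, concordance_grid=(0.5, 1.5))


class TestReferencePanel:
    def test_determinism_under_fixed_seed(self, small_config):
        p1, _ = make_reference_panel(small_config)
        p2, _ = make_reference_panel(small_config)
        assert len(p1) == small_config.n_dev_timepoints + small_config.n_aging_timepoints
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a.records, b.records)

    def test_adjacent_timepoints_share_most_signature_genes(self, small_config):
        truth = reference_truth(small_config)
        sigs = [set(s) for s in truth.dev_timepoint_signatures]
        for a, b in zip(sigs, sigs[1:]):
            overlap = len(a & b) / len(a)
            assert overlap >= 0.8

    def test_per_gene_magnitude_decays_monotonically(self, small_config):
        truth = reference_truth(small_config)
        for g in truth.dev_core_genes[:20]:
            if all(g in s for s in truth.dev_timepoint_signatures):
                mags = [s[g][1] for s in truth.dev_timepoint_signatures]
                assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_null_gene_pvalues_uniform(self, small_config):
        """Null p-values pass a KS test against U(0,1) at n >= 5000."""
        panel, truth = make_reference_panel(small_config)
        pools = []
        for t, sig in enumerate(truth.dev_timepoint_signatures):
            rec = panel[t].records
            pools.append(
                rec.loc[~rec["gene_id"].isin(set(sig)), "pvalue"].to_numpy()
            )
        null_p = np.concatenate(pools)
        assert len(null_p) >= 5000
        assert stats.kstest(null_p, "uniform").pvalue > 0.01

    def test_aging_signature_partially_disjoint(self, small_config):
        truth = reference_truth(small_config)
        shared = set(truth.aging_genes) & set(truth.dev_core_genes)
        frac = len(shared) / len(truth.aging_genes)
        assert 0.1 < frac < 0.5


class TestModelDatasets:
    def test_full_concordance_plants_everything(self):
        cfg = SimulationConfig(
            n_genes_universe=4000,
            signature_size=200,
            n_models=1,
            concordance_grid=(1.0,),
            n_background_degs=100,
            seed=5,
        )
        truth = reference_truth(cfg)
        deg, model_truth = make_model_dataset(cfg, 0)
        assert set(model_truth.planted_genes) == set(truth.dev_core_genes)
        rec = deg.records.set_index("gene_id")
        for g in truth.dev_core_genes:
            assert np.sign(rec.loc[g, "log2fc"]) == truth.dev_core_directions[g]

    def test_negative_concordance_flips_directions(self, small_config):
        truth = reference_truth(small_config)
        deg, model_truth = make_model_dataset(small_config, 5)  # f = -0.9
        rec = deg.records.set_index("gene_id")
        for g in model_truth.planted_genes[:20]:
            assert np.sign(rec.loc[g, "log2fc"]) == -truth.dev_core_directions[g]

    def test_determinism(self, small_config):
        d1, _ = make_model_dataset(small_config, 2)
        d2, _ = make_model_dataset(small_config, 2)
        pd.testing.assert_frame_equal(d1.records, d2.records)

    def test_out_of_range_index(self, small_config):
        with pytest.raises(InvalidConfigError):
            make_model_dataset(small_config, small_config.n_models)


class TestBehaviorTable:
    def test_population_effect_equals_link_without_noise(self):
        cfg = SimulationConfig(
            n_genes_universe=4000,
            signature_size=200,
            n_models=2,
            concordance_grid=(0.5, -0.5),
            link_noise_sd=0.0,
            seed=3,
        )
        _, truth = make_behavior_table(cfg)
        by_model = truth.groupby("model_id")["d_population"].first()
        assert by_model["model_00"] == pytest.approx(0.5)
        assert by_model["model_01"] == pytest.approx(-0.5)

    def test_measures_cover_both_polarities(self, small_config):
        measures, _ = make_behavior_table(small_config)
        assert {m.polarity for m in measures} == {1, -1}
        assert all(1 <= len(m.measure) for m in measures)

    def test_one_to_three_measures_per_model(self, small_config):
        measures, _ = make_behavior_table(small_config)
        counts = pd.Series([m.model_id for m in measures]).value_counts()
        assert counts.between(1, 3).all()
        assert len(counts) == small_config.n_models

    def test_effect_sizes_track_planted_concordance(self):
        """Pearson r between planted f and recovered d is high (MC average)."""
        from hippomaturity.indices import model_anxiety_index

        rs = []
        for seed in range(30):
            cfg = SimulationConfig(
                n_genes_universe=4000,
                signature_size=200,
                n_models=19,
                seed=seed,
            )
            measures, truth = make_behavior_table(cfg)
            by_model = {}
            for m in measures:
                by_model.setdefault(m.model_id, []).append(m)
            d = pd.Series({k: model_anxiety_index(v) for k, v in by_model.items()})
            f = truth.groupby("model_id")["concordance"].first()
            rs.append(np.corrcoef(f[d.index], d)[0, 1])
        assert np.mean(rs) >= 0.8


class TestCellTypeAtlasGeneration:
    def test_determinism(self, small_config):
        a1, t1 = make_celltype_atlas(small_config)
        a2, t2 = make_celltype_atlas(small_config)
        assert t1 == t2
        for name in a1.celltypes:
            pd.testing.assert_frame_equal(
                a1.celltypes[name].records, a2.celltypes[name].records
            )

    def test_contributor_carries_planted_share(self, small_config):
        _, truth = make_celltype_atlas(small_config)
        ref = reference_truth(small_config)
        assert len(truth["microglia"]) == round(0.5 * len(ref.aging_genes))
        assert set(truth["microglia"]) <= set(ref.aging_genes)
        assert truth["astrocyte"] == ()


class TestGeneSetCollection:
    def test_designated_term_contains_core(self, small_config):
        coll, designated = make_geneset_collection(small_config)
        truth = reference_truth(small_config)
        assert set(truth.dev_core_genes) <= coll.genes_of(designated)


def test_write_run_is_complete_and_deterministic(small_config, tmp_path):
    m1 = write_run(small_config, tmp_path / "a", full_tables=False)
    m2 = write_run(small_config, tmp_path / "b", full_tables=False)
    assert m1["seed"] == m2["seed"] and m1["designated_term"] == m2["designated_term"]
    for rel in ["behavior.tsv", "genesets.gmt", "truth/models.tsv"]:
        assert (tmp_path / "a" / rel).read_text() == (tmp_path / "b" / rel).read_text()
    truth_models = pd.read_csv(tmp_path / "a" / "truth" / "models.tsv", sep="\t")
    assert list(truth_models["concordance"]) == list(small_config.concordance_grid)


def test_planted_concordance_recoverable_end_to_end(small_config):
    """Rank correlation between the planted grid and maturity indices ~ 1."""
    from hippomaturity.indices import IndexTable, model_maturity_summary
    from hippomaturity.running_fisher import compare_datasets
    from hippomaturity.synthetic import make_model_cohort, reference_ids

    panel, _ = make_reference_panel(small_config)
    dev_ids, _ = reference_ids(small_config)
    refs = [apply_filter(r) for r in panel[: len(dev_ids)]]
    models, truths = make_model_cohort(small_config)
    overlaps = {
        (m.dataset_id, r.dataset_id): compare_datasets(
            apply_filter(m), r, small_config.n_genes_universe
        )
        for m in models
        for r in refs
    }
    table = IndexTable.from_overlaps(overlaps, {r: "development" for r in dev_ids})
    maturity = model_maturity_summary(table, "development")
    planted = pd.Series(
        {t.model_id: t.concordance for t in truths}
    ).reindex(maturity.index)
    assert maturity.corr(planted, method="spearman") >= 0.9
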