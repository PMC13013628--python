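import math

import numpy as np
import pytest
from scipy import stats

from hippomaturity.deg_io import negate
from hippomaturity.running_fisher import (
    FULL_SCAN,
    QUADRANT_KEYS,
    ScanConfig,
    compare_datasets,
    extract_concordant_genes,
    fisher_combine,
    hypergeom_overlap_p,
    rank_by_effect,
    running_overlap_p,
)

from _oracles import closed_form_overlap_tail, enumerate_overlap_tail
from conftest import random_deg, toy_deg


class TestRankByEffect:
    def test_ordering_by_magnitude_and_direction(self):
        deg = toy_deg([("A", 1.0, 0.01), ("B", -0.5, 0.02), ("C", 0.6, 0.03)])
        up, down = rank_by_effect(deg)
        assert up == ["A", "C"] and down == ["B"]

    def test_magnitude_ties_broken_by_pvalue(self):
        deg = toy_deg([("X", 0.5, 0.02), ("Y", 0.5, 0.01)])
        up, _ = rank_by_effect(deg)
        assert up == ["Y", "X"]

    def test_all_up_gives_empty_down(self):
        deg = toy_deg([("A", 0.2, 0.1), ("B", 0.4, 0.1)])
        up, down = rank_by_effect(deg)
        assert down == [] and set(up) == {"A", "B"}

    def test_zero_log2fc_excluded_with_warning(self):
        deg = toy_deg([("A", 0.0, 0.1), ("B", 0.4, 0.1)])
        with pytest.warns(UserWarning, match="zero-log2fc"):
            up, down = rank_by_effect(deg)
        assert up == ["B"] and down == []


class TestHypergeomOverlapP:
    def test_full_overlap_closed_form(self):
        # C(3,3)C(7,0)/C(10,3) = 1/120
        assert hypergeom_overlap_p(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_overlap_p(5, 7, 0, 100) == 1.0

    def test_saturated_list_forces_overlap(self):
        assert hypergeom_overlap_p(10, 4, 4, 10) == pytest.approx(1.0)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_p(3, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_overlap_p(11, 3, 2, 10)

    @pytest.mark.parametrize("n_universe", [5, 8])
    def test_matches_subset_enumeration(self, n_universe):
        for k_a in range(1, n_universe + 1):
            for k_b in range(1, n_universe + 1):
                for m in range(0, min(k_a, k_b) + 1):
                    expected = enumerate_overlap_tail(n_universe, k_a, k_b, m)
                    assert hypergeom_overlap_p(k_a, k_b, m, n_universe) == pytest.approx(
                        expected, rel=1e-9, abs=1e-12
                    )

    def test_deep_tail_matches_integer_arithmetic(self):
        # far below double-precision sf territory for naive summation
        p = hypergeom_overlap_p(50, 50, 48, 20000)
        expected = closed_form_overlap_tail(20000, 50, 50, 48)
        assert math.log10(p) == pytest.approx(math.log10(expected), rel=1e-9)


class TestFisherCombine:
    def test_unit_pvalues_stay_unit(self):
        assert fisher_combine(1.0, 1.0) == 1.0

    def test_half_half_matches_chi2_oracle(self):
        # closed form exp(-x/2)(1+x/2) at x = -4 ln 0.5 -> 0.59657
        assert fisher_combine(0.5, 0.5) == pytest.approx(0.596574, abs=1e-6)
        assert fisher_combine(0.5, 0.5) == pytest.approx(
            float(stats.chi2.sf(-2 * (np.log(0.5) + np.log(0.5)), 4))
        )

    def test_symmetry(self):
        assert fisher_combine(0.01, 0.7) == pytest.approx(fisher_combine(0.7, 0.01))

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_combine(0.0, 0.5)


class TestRunningOverlap:
    def test_single_cutoff_reduces_to_plain_fisher(self):
        rng = np.random.default_rng(2)
        a = [f"G{i:05d}" for i in rng.choice(500, 40, replace=False)]
        b = [f"G{i:05d}" for i in rng.choice(500, 60, replace=False)]
        res = running_overlap_p(a, b, 500, FULL_SCAN)
        shared = len(set(a) & set(b))
        assert res.pvalue == pytest.approx(hypergeom_overlap_p(40, 60, shared, 500))
        assert res.best_cut_a == 40 and res.best_cut_b == 60

    def test_disjoint_lists_give_p_one(self):
        a = [f"A{i}" for i in range(30)]
        b = [f"B{i}" for i in range(30)]
        res = running_overlap_p(a, b, 20000)
        assert res.pvalue == 1.0 and res.shared_at_full == frozenset()

    def test_empty_list_gives_p_one(self):
        res = running_overlap_p([], ["A"], 100)
        assert res.pvalue == 1.0 and res.shared_at_full == frozenset()

    def test_identical_lists_are_overwhelming(self):
        genes = [f"G{i:05d}" for i in range(50)]
        res = running_overlap_p(genes, genes, 20000)
        assert res.pvalue < 1e-50

    def test_bonferroni_never_smaller_than_raw(self):
        rng = np.random.default_rng(3)
        a = [f"G{i:05d}" for i in rng.choice(2000, 100, replace=False)]
        b = [f"G{i:05d}" for i in rng.choice(2000, 100, replace=False)]
        raw = running_overlap_p(a, b, 2000, ScanConfig(correction="none"))
        corr = running_overlap_p(a, b, 2000, ScanConfig())
        assert corr.pvalue >= raw.pvalue


class TestCompareDatasets:
    def _random_pair(self, seed, n=80):
        rng = np.random.default_rng(seed)
        return random_deg(rng, n, 2000, "a"), random_deg(rng, n, 2000, "b")

    def test_self_comparison_is_concordant(self):
        a, _ = self._random_pair(1)
        res = compare_datasets(a, a, 20000)
        assert res.sign == 1
        assert res.quadrants["up_down"].overlap == 0
        assert res.quadrants["down_up"].overlap == 0
        up, down = extract_concordant_genes(res)
        ranked_up, ranked_down = rank_by_effect(a)
        assert set(up) == set(ranked_up) and set(down) == set(ranked_down)

    def test_negation_flips_sign_preserves_magnitude(self):
        a, _ = self._random_pair(2)
        res = compare_datasets(a, a, 20000)
        resn = compare_datasets(a, negate(a), 20000)
        assert resn.sign == -1
        assert resn.overall_log10p == pytest.approx(res.overall_log10p)
        # negating both arguments restores the sign
        resnn = compare_datasets(negate(a), negate(a), 20000)
        assert resnn.sign == 1

    def test_quadrant_invariants(self):
        a, b = self._random_pair(3)
        res = compare_datasets(a, b, 20000)
        sets = [res.quadrants[k].shared_genes for k in QUADRANT_KEYS]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (sets[i] & sets[j])
        for q in res.quadrants.values():
            assert 0 < q.pvalue <= 1
            assert q.overlap <= min(q.k_a, q.k_b)
        assert res.overall_p == min(res.concordant_p, res.discordant_p)
        assert (res.sign == 1) == (res.concordant_p <= res.discordant_p)

    def test_adding_shared_top_gene_never_weakens_concordant_overlap(self):
        """Monotonicity over randomized small instances.

        Holds for concordance-dominated pairs (sign +1): a shared
        top-ranked gene can only strengthen the concordant quadrants. For
        discordance-dominated pairs the signed statistic rightly moves
        toward 1 (less discordant), so those are out of scope.
        """
        checked = 0
        for seed in range(40):
            a, b = self._random_pair(seed + 10, n=40)
            before = compare_datasets(a, b, 20000)
            if before.sign != 1:
                continue
            checked += 1
            boosted_a = toy_deg(
                [("ZZTOP", 5.0, 1e-6)] + list(a.records.itertuples(index=False)),
                dataset_id="a+",
            )
            boosted_b = toy_deg(
                [("ZZTOP", 5.0, 1e-6)] + list(b.records.itertuples(index=False)),
                dataset_id="b+",
            )
            after = compare_datasets(boosted_a, boosted_b, 20000)
            assert after.overall_log10p <= before.overall_log10p + 1e-9
        assert checked >= 10

    def test_planted_concordance_detected(self, small_config):
        from hippomaturity.deg_io import apply_filter
        from hippomaturity.synthetic import make_model_dataset, make_reference_panel

        panel, _ = make_reference_panel(small_config)
        ref = apply_filter(panel[0])
        model, truth = make_model_dataset(small_config, 0)  # f = +0.9
        res = compare_datasets(apply_filter(model), ref, small_config.n_genes_universe)
        assert res.sign == 1 and res.overall_p < 1e-10
        model2, truth2 = make_model_dataset(small_config, 4)  # f = -0.5
        res2 = compare_datasets(apply_filter(model2), ref, small_config.n_genes_universe)
        assert res2.sign == -1
        # concordant shared genes contain planted signature genes surviving filters
        fmod = apply_filter(model)
        up, down = extract_concordant_genes(res)
        concordant = set(up) | set(down)
        planted_surviving = set(truth.planted_genes) & fmod.genes & ref.genes
        assert planted_surviving <= concordant
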