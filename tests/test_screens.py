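"""Driver classification, tissue specificity, third-order screens,
conditional frequencies and the pathway-sharing test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hitswitch.cohort_io import AlterationMatrix, DriverCatalog
from hitswitch.interaction import InteractionResults, Table2x2
from hitswitch.screens import (
    build_driver_class_report,
    classify_driver,
    conditional_frequencies,
    default_background_pairs,
    functional_sharing_test,
    log_or_difference,
    pathway_restricted_screen,
    sharing_score,
    three_way_screen,
    tissue_specificity_screen,
)
from hitswitch.simulate import GeneSpec, SimConfig, simulate_cohort


def _call(gene, mode, ct="X", p=0.001, coef=1.0):
    return InteractionResults(
        term="mut:CNA", coef=coef, se=0.2, zvalue=coef / 0.2, pvalue=p,
        estimable=True, pseudocount=0.0, gene=gene, cancer_type=ct, mode=mode,
    )


class TestClassifyDriver:
    def test_loss_only_is_class_two(self):
        calls = [_call("RB1", "loss", ct=f"C{i}") for i in range(3)]
        assert classify_driver("RB1", calls) == 2

    def test_no_calls_is_class_one(self):
        assert classify_driver("SF3B1", []) == 1

    def test_gain_only_is_class_three(self):
        assert classify_driver("KRAS", [_call("KRAS", "gain")]) == 3

    def test_loss_and_gain_across_types_is_class_four(self):
        calls = [_call("CUL3", "loss", ct="KIRP"), _call("CUL3", "gain", ct="HNSC")]
        assert classify_driver("CUL3", calls) == 4

    def test_order_invariance(self):
        calls = [_call("G", "gain", ct="A"), _call("G", "loss", ct="B"), _call("G", "loss", ct="C")]
        for perm in itertools.permutations(calls):
            assert classify_driver("G", perm) == 4

    def test_wrong_gene_rejected(self):
        with pytest.raises(ValueError):
            classify_driver("A", [_call("B", "loss")])

    def test_report_counts(self):
        calls = [_call("A", "loss", ct="X"), _call("A", "loss", ct="Y"), _call("B", "gain")]
        report = build_driver_class_report(
            ["A", "B", "C"], calls, [("A", "X"), ("A", "Y"), ("B", "X"), ("C", "X")]
        )
        assert report.class_of("A") == 2
        assert report.class_of("B") == 3
        assert report.class_of("C") == 1
        row = report.table.set_index("gene").loc["A"]
        assert row["n_sig_loss"] == 2 and row["n_eligible_types"] == 2


def _sim_matrix(psi, seed, ct, n=2000, gene="A", p_mut=0.2, p_loss=0.2):
    cfg = SimConfig(
        n_samples=n,
        genes=(GeneSpec(gene, p_mut, p_loss=p_loss, psi_loss=psi),),
        seed=seed,
        cancer_type=ct,
    )
    return simulate_cohort(cfg)[0]


class TestTissueSpecificity:
    def test_contrast_recovers_planted_difference(self):
        matrices = {
            "DET": _sim_matrix(2.0, seed=1, ct="DET"),
            "OTH": _sim_matrix(0.0, seed=2, ct="OTH"),
        }
        results = tissue_specificity_screen(matrices, [_call("A", "loss", ct="DET")])
        assert len(results) == 1
        assert results[0].coef == pytest.approx(2.0, abs=0.6)
        assert results[0].pvalue < 0.01

    def test_identical_interaction_centers_on_zero(self):
        matrices = {
            "DET": _sim_matrix(1.0, seed=3, ct="DET", n=4000),
            "OTH": _sim_matrix(1.0, seed=4, ct="OTH", n=4000),
        }
        results = tissue_specificity_screen(matrices, [_call("A", "loss", ct="DET")])
        assert abs(results[0].coef) < 0.5

    def test_single_cohort_gene_skipped(self):
        matrices = {"DET": _sim_matrix(2.0, seed=5, ct="DET")}
        assert tissue_specificity_screen(matrices, [_call("A", "loss", ct="DET")]) == []

    def test_low_frequency_other_cohort_excluded(self):
        matrices = {
            "DET": _sim_matrix(2.0, seed=6, ct="DET"),
            "OTH": _sim_matrix(0.0, seed=7, ct="OTH", p_mut=0.01),
        }
        assert tissue_specificity_screen(matrices, [_call("A", "loss", ct="DET")]) == []


class TestLogOrDifference:
    def test_identical_tables_zero(self):
        t = Table2x2(n00=50, n01=10, n10=5, n11=20, gene="A")
        assert log_or_difference(t, t) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        det = Table2x2(n00=50, n01=10, n10=5, n11=20, gene="A")
        oth = Table2x2(n00=90, n01=10, n10=9, n11=1, gene="A")
        c = 0.5
        expected = math.log((20.5 * 50.5) / (5.5 * 10.5)) - math.log((1.5 * 90.5) / (9.5 * 10.5))
        assert log_or_difference(det, oth) == pytest.approx(expected)
        assert log_or_difference(oth, det) == pytest.approx(-expected)


def _partner_cohort(seed=0, n=2000, tau=-2.0):
    genes = [
        GeneSpec("A", 0.2, p_loss=0.2, psi_loss=1.0, modifier="B", tau_loss=tau),
        GeneSpec("B", 0.2),
    ] + [GeneSpec(f"P{i}", 0.05 + 0.02 * i) for i in range(8)]
    cfg = SimConfig(n_samples=n, genes=tuple(genes), seed=seed, cancer_type="X")
    matrix, truth = simulate_cohort(cfg)
    catalog = DriverCatalog(
        pd.DataFrame(
            {"gene": [g.name for g in genes], "cancer_type": "X", "role": "unassigned"}
        )
    )
    return matrix, catalog, truth


class TestThreeWayScreen:
    def test_partner_set_matches_brute_force(self):
        matrix, catalog, _ = _partner_cohort(seed=1)
        results = three_way_screen(matrix, [("A", "loss")], catalog, min_partner_freq=0.02)
        tested = {r.partner for r in results}
        freqs = matrix.mut_freq()
        expected = {g for g in matrix.genes if g != "A" and freqs[g] >= 0.02}
        assert tested == expected
        assert "A" not in tested

    def test_low_frequency_partner_excluded(self):
        matrix, catalog, _ = _partner_cohort(seed=2)
        results = three_way_screen(matrix, [("A", "loss")], catalog, min_partner_freq=0.5)
        assert results == []

    def test_planted_modifier_ranks_first(self):
        matrix, catalog, _ = _partner_cohort(seed=3)
        results = three_way_screen(matrix, [("A", "loss")], catalog)
        best = max(results, key=lambda r: abs(r.coef))
        assert best.partner == "B"
        assert best.coef < 0  # tau = -2 weakens the interaction


class TestConditionalFrequencies:
    def test_direct_counting(self):
        # 4 A-gain samples with B mutated, 1 of them A-mutant
        mut = np.array([[1, 1], [0, 1], [0, 1], [0, 1], [0, 0], [1, 0]], dtype=np.uint8)
        cn = np.array([[1, 0], [1, 0], [1, 0], [1, 0], [0, 0], [0, 0]], dtype=np.int8)
        matrix = AlterationMatrix(
            cancer_type="X",
            samples=tuple(f"s{i}" for i in range(6)),
            genes=("A", "B"),
            mut=mut,
            cn=cn,
        )
        cf = conditional_frequencies(matrix, "A", "gain", "B")
        assert cf.mut_given_cna_b1 == pytest.approx(0.25)
        assert math.isnan(cf.mut_given_cna_b0)  # no A-gain sample without B
        assert cf.cna_given_mut_b1 == pytest.approx(1.0)

    def test_no_b_mutation_gives_nan_strata(self, toy_matrix):
        toy_matrix.mut[:, 1] = 0
        cf = conditional_frequencies(toy_matrix, "GA", "loss", "GB")
        assert math.isnan(cf.cna_given_mut_b1)
        assert math.isnan(cf.mut_given_cna_b1)
        assert not math.isnan(cf.cna_given_mut_b0)

    def test_independent_cohort_strata_agree(self):
        matrix, _, _ = _partner_cohort(seed=8, n=30_000, tau=0.0)
        cf = conditional_frequencies(matrix, "A", "loss", "P0")
        assert cf.cna_given_mut_b1 == pytest.approx(cf.cna_given_mut_b0, abs=0.08)

    def test_same_gene_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            conditional_frequencies(toy_matrix, "GA", "loss", "GA")


def brute_force_u(x, y):
    """Mann–Whitney U by direct pairwise counting, 0.5 per tie."""
    return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)


class TestFunctionalSharing:
    def test_example_u_statistic(self):
        ann = {"a": {"t1", "t2"}, "b": {"t1", "t2", "t3"}, "c": {"t1"}}
        # engineered scores [2,3,1] vs [0,0,1,0]
        inter = [("a", "b"), ("b", "a"), ("a", "c")]
        ann_full = dict(ann)
        ann_full.update({"x": set(), "y": {"t9"}, "z": {"t1"}, "w": set()})
        back = [("x", "y"), ("y", "w"), ("c", "z"), ("x", "w")]
        scores_i = [sharing_score(p, ann_full) for p in inter]
        scores_b = [sharing_score(p, ann_full) for p in back]
        assert scores_i == [2.0, 2.0, 1.0]  # (a,b) shares t1,t2
        u, p = functional_sharing_test(inter, back, ann_full)
        assert u == pytest.approx(brute_force_u(scores_i, scores_b))

    def test_spec_scores_u(self):
        assert brute_force_u([2, 3, 1], [0, 0, 1, 0]) == pytest.approx(11.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=8),
        st.lists(st.integers(0, 4), min_size=2, max_size=8),
    )
    def test_ranking_formula_matches_brute_force(self, x, y):
        ann = {f"g{i}": {f"t{j}" for j in range(s)} for i, s in enumerate(x + y)}
        ann["hub"] = {f"t{j}" for j in range(10)}
        pairs_x = [(f"g{i}", "hub") for i in range(len(x))]
        pairs_y = [(f"g{i + len(x)}", "hub") for i in range(len(y))]
        u, _ = functional_sharing_test(pairs_x, pairs_y, ann)
        assert u == pytest.approx(brute_force_u(x, y))

    def test_identical_multisets_p_near_one(self):
        ann = {f"g{i}": {"t"} for i in range(8)}
        pairs = [(f"g{i}", f"g{(i + 1) % 8}") for i in range(4)]
        _, p = functional_sharing_test(pairs, pairs, ann)
        assert p > 0.9

    def test_complete_separation_maximal_u(self):
        ann = {"a": {"t1", "t2"}, "b": {"t1", "t2"}, "c": {"t1"}, "x": set(), "y": set(), "z": set()}
        inter = [("a", "b"), ("a", "c")]
        back = [("x", "y"), ("y", "z"), ("x", "z")]
        u, p = functional_sharing_test(inter, back, ann)
        assert u == len(inter) * len(back)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            functional_sharing_test([], [("a", "b")], {})

    def test_background_pair_construction(self):
        catalog = DriverCatalog(
            pd.DataFrame(
                {"gene": ["A", "B", "C", "D"], "cancer_type": ["X"] * 4, "role": ["TSG"] * 4}
            )
        )
        pairs = default_background_pairs(catalog, "X", exclude=[("B", "A")])
        assert ("A", "B") not in pairs and ("B", "A") not in pairs
        assert len(pairs) == 5  # C(4,2) - 1


class TestPathwayRestricted:
    def test_restricted_set_is_subset_with_shared_terms(self):
        matrix, catalog, _ = _partner_cohort(seed=4)
        ann = {"A": {"ras"}, "B": {"ras"}, "P0": {"other"}}
        full = three_way_screen(matrix, [("A", "loss")], catalog)
        restricted = pathway_restricted_screen(matrix, [("A", "loss")], catalog, ann)
        tested_full = {r.partner for r in full}
        tested_restricted = {r.partner for r in restricted}
        assert tested_restricted == {"B"}
        assert tested_restricted <= tested_full
        assert len(restricted) < len(full)

    def test_empty_annotation_map_empty_screen(self):
        matrix, catalog, _ = _partner_cohort(seed=5)
        assert pathway_restricted_screen(matrix, [("A", "loss")], catalog, {}) == []
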