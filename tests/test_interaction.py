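"""Saturated log-linear fits: closed-form identities, the iterative-GLM
oracle, masking rules, and symmetry properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hitswitch.interaction import (
    Table2x2,
    Table2x2x2,
    TwoWayInteractionModel,
    batch_two_way,
    fit_three_way,
    fit_tissue_contrast,
    fit_two_way,
    odds_ratio,
    tabulate_three_way,
    tabulate_two_way,
)


def glm_interaction_fit(cells):
    """Independent oracle: iteratively fitted saturated Poisson log-linear
    model; returns (coefficient, SE) of the mut:CNA term."""
    import warnings

    import statsmodels.api as sm

    mut = np.array([0, 0, 1, 1])
    cna = np.array([0, 1, 0, 1])
    design = np.column_stack([np.ones(4), mut, cna, mut * cna])
    with warnings.catch_warnings():
        # the saturated fit reproduces the cells exactly; statsmodels calls
        # that perfect separation
        warnings.simplefilter("ignore")
        fit = sm.GLM(np.asarray(cells, float), design, family=sm.families.Poisson()).fit(
            tol=1e-12, maxiter=200
        )
    return fit.params[3], fit.bse[3]


class TestTabulateTwoWay:
    def test_loss_masking_rule(self, toy_matrix):
        # CN states [0,0,-1,-1,+1,-2], muts [0,1,0,1,1,1]: the +1 and -2
        # samples are excluded; each remaining cell holds one sample
        table = tabulate_two_way(toy_matrix, "GA", "loss")
        assert (table.n00, table.n10, table.n01, table.n11) == (1, 1, 1, 1)
        assert table.total == 4
        assert table.n_excluded == 2

    def test_gain_masking_rule(self, toy_matrix):
        # gain table keeps CN >= 0: samples s0, s1, s4; the single +1
        # sample is mutated
        table = tabulate_two_way(toy_matrix, "GA", "gain")
        assert table.n01 + table.n11 == 1
        assert table.n11 == 1
        assert table.total == 3
        assert table.n_excluded == 3

    def test_loss_and_gain_overlap_on_wild_type(self, toy_matrix):
        loss = tabulate_two_way(toy_matrix, "GA", "loss")
        gain = tabulate_two_way(toy_matrix, "GA", "gain")
        # CN=0 samples appear in both tables
        assert loss.n00 + loss.n10 == gain.n00 + gain.n10 == 2

    def test_deep_loss_variant_includes_minus_two(self, toy_matrix):
        table = tabulate_two_way(toy_matrix, "GA", "loss", loss_includes_deep=True)
        assert table.total == 5
        assert table.n11 == 2  # the -1 and -2 mutated samples

    def test_absent_gene_raises(self, toy_matrix):
        with pytest.raises(KeyError):
            tabulate_two_way(toy_matrix, "NOPE", "loss")


class TestFitTwoWay:
    def test_independent_table_coefficient_zero(self):
        res = fit_two_way(Table2x2(n00=90, n01=10, n10=9, n11=1))
        assert res.coef == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        res = fit_two_way(Table2x2(n00=50, n01=10, n10=5, n11=20))
        assert res.coef == pytest.approx(math.log(20), abs=1e-9)
        assert res.se == pytest.approx(math.sqrt(1 / 50 + 1 / 10 + 1 / 5 + 1 / 20), abs=1e-9)
        assert res.zvalue == pytest.approx(res.coef / res.se, abs=1e-9)
        assert res.zvalue == pytest.approx(4.925, abs=1e-3)

    def test_zero_cell_not_estimable(self):
        res = fit_two_way(Table2x2(n00=50, n01=10, n10=5, n11=0))
        assert not res.estimable
        assert res.coef is None and res.pvalue is None

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            fit_two_way(Table2x2(n00=1, n01=1, n10=1, n11=1), pseudocount=-0.5)

    def test_matches_iterative_glm(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            cells = rng.integers(1, 200, size=4)
            res = fit_two_way(Table2x2(*map(int, cells)))
            coef, se = glm_interaction_fit(cells)
            assert res.coef == pytest.approx(coef, abs=1e-6)
            assert res.se == pytest.approx(se, abs=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_transposition_symmetry(self, cells):
        n00, n01, n10, n11 = cells
        a = fit_two_way(Table2x2(n00=n00, n01=n01, n10=n10, n11=n11))
        b = fit_two_way(Table2x2(n00=n00, n01=n10, n10=n01, n11=n11))
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-12)
        assert a.coef == pytest.approx(b.coef, rel=1e-12)

    def test_model_results_surface(self):
        model = TwoWayInteractionModel(Table2x2(n00=50, n01=10, n10=5, n11=20, gene="TP53", cancer_type="LUAD"))
        res = model.fit()
        lo, hi = res.conf_int()
        assert lo < res.coef < hi
        text = res.summary()
        assert "TP53" in text and "coef" in text

    def test_signed_by_cn_orientation(self):
        res = fit_two_way(Table2x2(n00=50, n01=10, n10=5, n11=20, mode="loss"))
        assert res.coef_signed_by_cn == pytest.approx(-res.coef)
        res_g = fit_two_way(Table2x2(n00=50, n01=10, n10=5, n11=20, mode="gain"))
        assert res_g.coef_signed_by_cn == pytest.approx(res_g.coef)


class TestThreeWay:
    def _table(self, s0, s1):
        return Table2x2x2(
            stratum0=Table2x2(*s0, gene="A"), stratum1=Table2x2(*s1, gene="A"), gene_b="B"
        )

    def test_identical_strata_coefficient_zero(self):
        t = self._table((20, 5, 5, 20), (20, 5, 5, 20))
        assert fit_three_way(t).coef == pytest.approx(0.0, abs=1e-12)

    def test_pseudocounted_example(self):
        # stratum ORs (with +1): 441/36 and 63/441 -> ln(85.75)
        t = self._table((20, 20, 20, 2), (20, 5, 5, 20))
        res = fit_three_way(t, pseudocount=1)
        assert res.coef == pytest.approx(math.log(85.75), abs=1e-9)

    def test_swapping_strata_negates(self):
        t = self._table((20, 20, 20, 2), (20, 5, 5, 20))
        t_swapped = self._table((20, 5, 5, 20), (20, 20, 20, 2))
        assert fit_three_way(t).coef == pytest.approx(-fit_three_way(t_swapped).coef)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(0, 300)] * 8))
    def test_stratum_decomposition_identity(self, cells):
        s0, s1 = cells[:4], cells[4:]
        t = self._table(s0, s1)
        res = fit_three_way(t, pseudocount=1)
        from hitswitch.interaction import fit_two_way as f2

        d = f2(t.stratum1, pseudocount=1).coef - f2(t.stratum0, pseudocount=1).coef
        assert res.coef == pytest.approx(d, abs=1e-12)

    def test_tabulate_partitions_samples(self, toy_matrix):
        t = tabulate_three_way(toy_matrix, "GA", "loss", "GB")
        loss = tabulate_two_way(toy_matrix, "GA", "loss")
        assert t.stratum0.total + t.stratum1.total == loss.total

    def test_no_target_mutation_gives_empty_stratum(self, toy_matrix):
        m = toy_matrix
        m.mut[:, 1] = 0
        t = tabulate_three_way(m, "GA", "loss", "GB")
        assert t.stratum1.total == 0

    def test_same_gene_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            tabulate_three_way(toy_matrix, "GA", "loss", "GA")


class TestTissueContrast:
    def test_pseudocounted_example(self):
        det = Table2x2(n00=50, n01=10, n10=5, n11=20, gene="A")
        oth = Table2x2(n00=50, n01=10, n10=5, n11=5, gene="A")
        res = fit_tissue_contrast(det, oth, pseudocount=1)
        assert res.coef == pytest.approx(math.log(3.5), abs=1e-9)

    def test_identical_tables_zero(self):
        t = Table2x2(n00=50, n01=10, n10=5, n11=20, gene="A")
        assert fit_tissue_contrast(t, t).coef == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_labels_rejected(self):
        a = Table2x2(n00=1, n01=1, n10=1, n11=1, gene="A", mode="loss")
        b = Table2x2(n00=1, n01=1, n10=1, n11=1, gene="B", mode="loss")
        with pytest.raises(ValueError):
            fit_tissue_contrast(a, b)


class TestOddsRatio:
    def test_zero_cell_with_haldane_pseudocount(self):
        t = Table2x2(n00=10, n01=0, n10=5, n11=20)
        assert odds_ratio(t) == pytest.approx(78.2727, abs=1e-3)

    def test_independent_table_without_pseudocount(self):
        assert odds_ratio(Table2x2(n00=90, n01=10, n10=9, n11=1), pseudocount=0) == pytest.approx(1.0)

    def test_all_zero_table_is_one(self):
        assert odds_ratio(Table2x2(n00=0, n01=0, n10=0, n11=0)) == pytest.approx(1.0)


class TestBatchTwoWay:
    def test_agrees_with_scalar_path(self):
        rng = np.random.default_rng(4)
        mut = (rng.random((200, 10)) < 0.3).astype(np.uint8)
        cn = rng.choice([-2, -1, 0, 1, 2], size=(200, 10), p=[0.05, 0.2, 0.5, 0.2, 0.05]).astype(np.int8)
        from hitswitch.cohort_io import AlterationMatrix

        matrix = AlterationMatrix(
            cancer_type="X",
            samples=tuple(f"s{i}" for i in range(200)),
            genes=tuple(f"g{i}" for i in range(10)),
            mut=mut,
            cn=cn,
        )
        for mode in ("loss", "gain"):
            coef, se, p = batch_two_way(mut, cn, mode, pseudocount=0.5)
            for j, gene in enumerate(matrix.genes):
                res = fit_two_way(tabulate_two_way(matrix, gene, mode), pseudocount=0.5)
                assert coef[j] == pytest.approx(res.coef, abs=1e-12)
                assert p[j] == pytest.approx(res.pvalue, abs=1e-12)
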