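"""Saturated log-linear interaction models on 2×2 and 2×2×2 alteration tables.

For a 2×2 contingency table of cell counts ``N`` cross-classifying a gene's
mutation status against its copy-number state, the saturated Poisson
log-linear model

    N ~ mut + CNA + mut:CNA,   family = Poisson(log link)

has a closed-form maximum-likelihood solution: the ``mut:CNA`` coefficient
equals the log odds ratio ``ln(n11·n00 / (n10·n01))`` and its standard
error is ``sqrt(1/n00 + 1/n01 + 1/n10 + 1/n11)``. The 2×2×2 extension adds
a third binary factor (mutation of a second gene, or cohort membership in
the tissue contrast); its highest-order coefficient is the log ratio of
the two stratum odds ratios, with SE the square root of the summed
reciprocal cells over all eight cells. Two-sided p-values are asymptotic
Wald normal tails, matching the regression-summary convention.

Copy-number masking: the loss-model table compares CN wild-type (0) against
broad one-copy loss (−1), excluding gains and deep deletions; the gain-model
table compares wild-type against gain (+1 or +2), excluding all losses. A
``loss_includes_deep`` variant treats CN ≤ −1 as loss.

Sign convention: coefficients here are co-occurrence oriented — positive
means mutation and the altered CN state co-occur more than expected under
independence, in both the loss and the gain model. Output tables also carry
a CN-signed column (loss coefficients negated) mirroring the display
convention in which stronger mutation/loss co-occurrence is more negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .cohort_io import AlterationMatrix

__all__ = [
    "Mode",
    "Table2x2",
    "Table2x2x2",
    "InteractionResults",
    "TwoWayInteractionModel",
    "ThreeWayInteractionModel",
    "TissueContrastModel",
    "tabulate_two_way",
    "tabulate_three_way",
    "fit_two_way",
    "fit_three_way",
    "fit_tissue_contrast",
    "odds_ratio",
    "batch_two_way",
]

Mode = Literal["loss", "gain"]


def _check_mode(mode: str) -> None:
    if mode not in ("loss", "gain"):
        raise ValueError(f"mode must be 'loss' or 'gain', got {mode!r}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table2x2:
    """2×2 cell counts; first index = mutation (0/1), second = CNA altered.

    ``n01`` counts unmutated/altered samples, ``n10`` mutated/wild-type.
    """

    n00: int
    n01: int
    n10: int
    n11: int
    gene: str = ""
    cancer_type: str = ""
    mode: str = "loss"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("n00", "n01", "n10", "n11"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        _check_mode(self.mode)

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def counts(self) -> np.ndarray:
        return np.array([self.n00, self.n01, self.n10, self.n11], dtype=float)


@dataclass(frozen=True)
class Table2x2x2:
    """Two 2×2 strata indexed by the third binary factor (0 / 1)."""

    stratum0: Table2x2
    stratum1: Table2x2
    gene_b: str = ""

    def __post_init__(self) -> None:
        if (self.stratum0.gene, self.stratum0.mode) != (self.stratum1.gene, self.stratum1.mode):
            raise ValueError("strata must share gene A and CNA mode")

    @property
    def gene(self) -> str:
        return self.stratum0.gene

    @property
    def mode(self) -> str:
        return self.stratum0.mode

    def counts(self) -> np.ndarray:
        return np.concatenate([self.stratum0.counts(), self.stratum1.counts()])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionResults:
    """One fitted interaction term from a saturated log-linear model.

    When ``estimable`` is False (a zero cell with zero pseudocount), the
    coefficient, SE, z and p are all ``None``. Coefficients are
    co-occurrence oriented (see module docstring).
    """

    term: str
    coef: float | None
    se: float | None
    zvalue: float | None
    pvalue: float | None
    estimable: bool
    pseudocount: float
    gene: str = ""
    cancer_type: str = ""
    mode: str = "loss"
    partner: str | None = None
    orientation: str = "co-occurrence"
    table: Table2x2 | Table2x2x2 | None = field(default=None, repr=False, compare=False)

    @property
    def coef_signed_by_cn(self) -> float | None:
        """Coefficient in the CN-signed display convention (loss negated)."""
        if self.coef is None:
            return None
        return -self.coef if self.mode == "loss" else self.coef

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        if not self.estimable:
            raise ValueError("term not estimable; no confidence interval")
        zq = stats.norm.ppf(1 - alpha / 2)
        return (self.coef - zq * self.se, self.coef + zq * self.se)

    def summary(self) -> str:
        lines = [
            "Saturated log-linear interaction fit",
            "=" * 52,
            f"term:        {self.term}",
            f"gene:        {self.gene or '-'}   cancer type: {self.cancer_type or '-'}",
            f"CNA mode:    {self.mode}" + (f"   partner: {self.partner}" if self.partner else ""),
            f"pseudocount: {self.pseudocount:g}",
        ]
        if self.estimable:
            lo, hi = self.conf_int()
            lines += [
                f"coef (co-occurrence): {self.coef: .4f}   SE: {self.se:.4f}",
                f"z: {self.zvalue: .3f}   two-sided p: {self.pvalue:.3g}",
                f"95% CI: [{lo:.4f}, {hi:.4f}]",
            ]
        else:
            lines.append("not estimable (zero cell with zero pseudocount)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def _masks(cn: np.ndarray, mode: str, loss_includes_deep: bool) -> tuple[np.ndarray, np.ndarray]:
    """(included, altered) boolean masks for one CNA mode."""
    if mode == "loss":
        if loss_includes_deep:
            included = cn <= 0
            altered = cn <= -1
        else:
            included = (cn == 0) | (cn == -1)
            altered = cn == -1
    else:
        included = cn >= 0
        altered = cn >= 1
    return included, altered


def _tabulate(
    mut: np.ndarray,
    cn: np.ndarray,
    mode: str,
    *,
    gene: str = "",
    cancer_type: str = "",
    loss_includes_deep: bool = False,
) -> Table2x2:
    included, altered = _masks(cn, mode, loss_includes_deep)
    m = mut.astype(bool)
    n11 = int((m & altered).sum())
    n10 = int((m & included & ~altered).sum())
    n01 = int((~m & altered).sum())
    n00 = int((~m & included & ~altered).sum())
    return Table2x2(
        n00=n00, n01=n01, n10=n10, n11=n11,
        gene=gene, cancer_type=cancer_type, mode=mode,
        n_excluded=int((~included).sum()),
    )


def tabulate_two_way(
    matrix: AlterationMatrix,
    gene: str,
    mode: Mode,
    *,
    loss_includes_deep: bool = False,
) -> Table2x2:
    """Cross-classify one gene's mutation against its CN state.

    Loss mode keeps samples with CN ∈ {0, −1} (altered = −1); gain mode
    keeps CN ∈ {0, +1, +2} (altered ≥ +1). Other samples are excluded and
    counted in ``n_excluded``.
    """
    _check_mode(mode)
    return _tabulate(
        matrix.mut_col(gene),
        matrix.cn_col(gene),
        mode,
        gene=gene,
        cancer_type=matrix.cancer_type,
        loss_includes_deep=loss_includes_deep,
    )


def tabulate_three_way(
    matrix: AlterationMatrix,
    gene_a: str,
    mode: Mode,
    gene_b: str,
    *,
    loss_includes_deep: bool = False,
) -> Table2x2x2:
    """Stratify gene A's mutation × CNA table by gene B's mutation status.

    Only gene B's somatic mutation is used; its copy number is ignored.
    """
    if gene_a == gene_b:
        raise ValueError("gene A and gene B must differ")
    _check_mode(mode)
    mut_a = matrix.mut_col(gene_a)
    cn_a = matrix.cn_col(gene_a)
    b = matrix.mut_col(gene_b).astype(bool)
    strata = []
    for target in (False, True):
        sel = b == target
        strata.append(
            _tabulate(
                mut_a[sel], cn_a[sel], mode,
                gene=gene_a, cancer_type=matrix.cancer_type,
                loss_includes_deep=loss_includes_deep,
            )
        )
    return Table2x2x2(stratum0=strata[0], stratum1=strata[1], gene_b=gene_b)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _log_or(cells: np.ndarray) -> tuple[float, float]:
    """(log odds ratio, SE) of a pseudocounted 2×2 cell vector."""
    n00, n01, n10, n11 = cells
    coef = math.log(n11) + math.log(n00) - math.log(n10) - math.log(n01)
    se = math.sqrt((1.0 / cells).sum())
    return coef, se


def _wald(coef: float, se: float) -> tuple[float, float]:
    z = coef / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


class TwoWayInteractionModel:
    """Saturated Poisson log-linear model for one 2×2 table.

    ``fit()`` evaluates the closed-form MLE of the ``mut:CNA`` term; an
    iterative GLM would return the same numbers (this identity is the
    oracle check in the test suite). With any zero cell and zero
    pseudocount the term is not estimable and is flagged as such rather
    than silently regularized.
    """

    term = "mut:CNA"

    def __init__(self, table: Table2x2, pseudocount: float = 0.0):
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.table = table
        self.pseudocount = float(pseudocount)

    def fit(self) -> InteractionResults:
        cells = self.table.counts() + self.pseudocount
        common = dict(
            term=self.term,
            pseudocount=self.pseudocount,
            gene=self.table.gene,
            cancer_type=self.table.cancer_type,
            mode=self.table.mode,
            table=self.table,
        )
        if (cells == 0).any():
            return InteractionResults(
                coef=None, se=None, zvalue=None, pvalue=None, estimable=False, **common
            )
        coef, se = _log_or(cells)
        z, p = _wald(coef, se)
        return InteractionResults(
            coef=coef, se=se, zvalue=z, pvalue=p, estimable=True, **common
        )


class ThreeWayInteractionModel:
    """Saturated log-linear model for a 2×2×2 table; the three-way term is
    the log ratio of stratum odds ratios.

    The default pseudocount of 1 (added to every cell) follows the screen's
    convention for higher-order tables, where zero cells are common.
    """

    term = "mut:CNA:target"

    def __init__(self, table: Table2x2x2, pseudocount: float = 1.0):
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.table = table
        self.pseudocount = float(pseudocount)

    def fit(self) -> InteractionResults:
        c0 = self.table.stratum0.counts() + self.pseudocount
        c1 = self.table.stratum1.counts() + self.pseudocount
        common = dict(
            term=self.term,
            pseudocount=self.pseudocount,
            gene=self.table.gene,
            cancer_type=self.table.stratum0.cancer_type,
            mode=self.table.mode,
            partner=self.table.gene_b or None,
            table=self.table,
        )
        if (c0 == 0).any() or (c1 == 0).any():
            return InteractionResults(
                coef=None, se=None, zvalue=None, pvalue=None, estimable=False, **common
            )
        # Difference of stratum log-ORs == ln(OR1/OR0); computed this way the
        # stratum-decomposition identity holds exactly in floating point.
        lor1, _ = _log_or(c1)
        lor0, _ = _log_or(c0)
        coef = lor1 - lor0
        se = math.sqrt((1.0 / c0).sum() + (1.0 / c1).sum())
        z, p = _wald(coef, se)
        return InteractionResults(
            coef=coef, se=se, zvalue=z, pvalue=p, estimable=True, **common
        )


class TissueContrastModel(ThreeWayInteractionModel):
    """Contrast of one gene's mutation×CNA interaction between the cohort
    where it was detected (stratum 1) and the pooled other eligible cohorts
    (stratum 0). Mathematically identical to the three-way model with
    cohort membership as the third factor.
    """

    term = "mut:CNA:tissue"

    def __init__(self, table_detected: Table2x2, table_other: Table2x2, pseudocount: float = 1.0):
        if (table_detected.gene, table_detected.mode) != (table_other.gene, table_other.mode):
            raise ValueError("detected and other tables must share gene and mode")
        super().__init__(
            Table2x2x2(stratum0=table_other, stratum1=table_detected, gene_b=""),
            pseudocount=pseudocount,
        )

    def fit(self) -> InteractionResults:
        res = super().fit()
        # keep the detected cohort's label on the result
        object.__setattr__(res, "term", self.term)
        object.__setattr__(res, "cancer_type", self.table.stratum1.cancer_type)
        return res


# thin functional wrappers ---------------------------------------------------


def fit_two_way(table: Table2x2, pseudocount: float = 0.0) -> InteractionResults:
    return TwoWayInteractionModel(table, pseudocount).fit()


def fit_three_way(table: Table2x2x2, pseudocount: float = 1.0) -> InteractionResults:
    return ThreeWayInteractionModel(table, pseudocount).fit()


def fit_tissue_contrast(
    table_detected: Table2x2, table_other: Table2x2, pseudocount: float = 1.0
) -> InteractionResults:
    return TissueContrastModel(table_detected, table_other, pseudocount).fit()


def odds_ratio(table: Table2x2, pseudocount: float = 0.5) -> float:
    """Pseudocounted odds ratio (n11+c)(n00+c) / ((n10+c)(n01+c)).

    The default c = 0.5 (Haldane–Anscombe) avoids division by zero when a
    cell is empty.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    c = pseudocount
    return float(
        (table.n11 + c) * (table.n00 + c) / ((table.n10 + c) * (table.n01 + c))
    )


# ---------------------------------------------------------------------------
# vectorized batch fits (used by the permutation null)
# ---------------------------------------------------------------------------


def batch_two_way(
    mut: np.ndarray,
    cn: np.ndarray,
    mode: Mode,
    pseudocount: float = 0.0,
    *,
    loss_includes_deep: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-way coefficients, SEs and p-values for every gene column at once.

    ``mut`` is (samples × genes) binary, ``cn`` integer states. Returns
    float arrays with NaN where the term is not estimable. Numerically
    identical to per-gene :func:`fit_two_way`.
    """
    _check_mode(mode)
    included, altered = _masks(cn, mode, loss_includes_deep)
    m = mut.astype(bool)
    n11 = (m & altered).sum(axis=0).astype(float)
    n10 = (m & included & ~altered).sum(axis=0).astype(float)
    n01 = (~m & altered).sum(axis=0).astype(float)
    n00 = (~m & included & ~altered).sum(axis=0).astype(float)
    cells = np.stack([n00, n01, n10, n11]) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(cells)
        coef = logs[3] + logs[0] - logs[2] - logs[1]
        se = np.sqrt((1.0 / cells).sum(axis=0))
        bad = (cells == 0).any(axis=0)
        coef[bad] = np.nan
        se[bad] = np.nan
        z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[bad] = np.nan
    return coef, se, p
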