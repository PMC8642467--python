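"""Biological screens built on the interaction models: the four-class
driver taxonomy, tissue specificity, third-order (modifier) screens,
conditional co-occurrence frequencies, and the pathway-sharing test.

Driver classes summarize a gene's significant mutation×CNA interactions
across cancer types: class 1 ("one-hit") has none; class 2 ("two-hit
loss") has loss-mode interactions only; class 3 ("two-hit gain") gain only;
class 4 both modes, whether in the same or different cancer types.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import AlterationMatrix, DriverCatalog
from .interaction import (
    InteractionResults,
    Table2x2,
    fit_three_way,
    fit_tissue_contrast,
    odds_ratio,
    tabulate_three_way,
    tabulate_two_way,
)

logger = logging.getLogger(__name__)

__all__ = [
    "classify_driver",
    "DriverClassReport",
    "build_driver_class_report",
    "tissue_specificity_screen",
    "log_or_difference",
    "three_way_screen",
    "ConditionalFrequencies",
    "conditional_frequencies",
    "functional_sharing_test",
    "pathway_restricted_screen",
    "read_annotation_map",
    "sharing_score",
]


# ---------------------------------------------------------------------------
# driver classification
# ---------------------------------------------------------------------------


def classify_driver(gene: str, significant_calls: Iterable) -> int:
    """Four-class driver taxonomy from a gene's significant calls.

    1 = no significant interaction in any cancer type (one-hit);
    2 = loss-mode interactions only; 3 = gain only; 4 = both modes.
    Pure function of the call multiset; cancer-type order is irrelevant.
    """
    modes = set()
    for call in significant_calls:
        if call.gene != gene:
            raise ValueError(f"call for {call.gene!r} passed to classify_driver({gene!r})")
        modes.add(call.mode)
    if not modes:
        return 1
    if modes == {"loss"}:
        return 2
    if modes == {"gain"}:
        return 3
    return 4


@dataclass(frozen=True)
class DriverClassReport:
    """Per-gene driver class with supporting evidence counts."""

    table: pd.DataFrame  # gene, driver_class, n_eligible_types, n_sig_loss, n_sig_gain

    def class_of(self, gene: str) -> int:
        row = self.table.loc[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(gene)
        return int(row["driver_class"].iloc[0])


def build_driver_class_report(
    genes: Iterable[str],
    significant_calls: Sequence,
    eligible: Iterable[tuple[str, str]] = (),
) -> DriverClassReport:
    """Classify every gene from the significant-call list; ``eligible``
    (gene, cancer_type) pairs feed the eligible-type counts."""
    eligible_counts: dict[str, int] = {}
    for g, _ct in eligible:
        eligible_counts[g] = eligible_counts.get(g, 0) + 1
    by_gene: dict[str, list] = {g: [] for g in genes}
    for call in significant_calls:
        by_gene.setdefault(call.gene, []).append(call)
    rows = []
    for gene in sorted(by_gene):
        calls = by_gene[gene]
        rows.append(
            {
                "gene": gene,
                "driver_class": classify_driver(gene, calls),
                "n_eligible_types": eligible_counts.get(gene, 0),
                "n_sig_loss": sum(1 for c in calls if c.mode == "loss"),
                "n_sig_gain": sum(1 for c in calls if c.mode == "gain"),
            }
        )
    return DriverClassReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# tissue specificity
# ---------------------------------------------------------------------------


def _pool_tables(tables: Sequence[Table2x2]) -> Table2x2:
    first = tables[0]
    return Table2x2(
        n00=sum(t.n00 for t in tables),
        n01=sum(t.n01 for t in tables),
        n10=sum(t.n10 for t in tables),
        n11=sum(t.n11 for t in tables),
        gene=first.gene,
        cancer_type="pooled_other",
        mode=first.mode,
        n_excluded=sum(t.n_excluded for t in tables),
    )


def tissue_specificity_screen(
    matrices: Mapping[str, AlterationMatrix],
    detected_calls: Sequence,
    min_mut_freq: float = 0.02,
    pseudocount: float = 1.0,
    *,
    loss_includes_deep: bool = False,
) -> list[InteractionResults]:
    """Contrast each detected interaction against the pooled other cancer
    types in which the gene is mutated above ``min_mut_freq``.

    Calls whose gene has no other eligible cohort are skipped with a
    logged reason.
    """
    results = []
    for call in detected_calls:
        gene, mode, detected_ct = call.gene, call.mode, call.cancer_type
        others = []
        for ct, matrix in matrices.items():
            if ct == detected_ct or gene not in matrix.gene_index:
                continue
            if matrix.mut_freq()[gene] > min_mut_freq:
                others.append(
                    tabulate_two_way(matrix, gene, mode, loss_includes_deep=loss_includes_deep)
                )
        if not others:
            logger.info(
                "tissue_specificity_screen: %s/%s (%s) skipped — no other "
                "cancer type with the gene mutated above %.1f%%",
                gene, detected_ct, mode, 100 * min_mut_freq,
            )
            continue
        detected = tabulate_two_way(
            matrices[detected_ct], gene, mode, loss_includes_deep=loss_includes_deep
        )
        results.append(fit_tissue_contrast(detected, _pool_tables(others), pseudocount))
    return results


def log_or_difference(
    table_detected: Table2x2, table_other: Table2x2, pseudocount: float = 0.5
) -> float:
    """Difference of pseudocounted log odds ratios (detected − other);
    the volcano-plot effect size for the tissue contrast."""
    if (table_detected.gene, table_detected.mode) != (table_other.gene, table_other.mode):
        raise ValueError("tables must share gene and mode")
    return math.log(odds_ratio(table_detected, pseudocount)) - math.log(
        odds_ratio(table_other, pseudocount)
    )


# ---------------------------------------------------------------------------
# third-order screen
# ---------------------------------------------------------------------------


def _partners(
    matrix: AlterationMatrix,
    gene_a: str,
    catalog: DriverCatalog,
    min_partner_freq: float,
) -> list[str]:
    freqs = matrix.mut_freq()
    return [
        g
        for g in matrix.genes
        if g != gene_a and g in catalog.genes and freqs[g] >= min_partner_freq
    ]


def three_way_screen(
    matrix: AlterationMatrix,
    significant_pairs: Sequence[tuple[str, str]],
    catalog: DriverCatalog,
    min_partner_freq: float = 0.02,
    pseudocount: float = 1.0,
    *,
    allowed_partners: Mapping[str, Iterable[str]] | None = None,
    loss_includes_deep: bool = False,
) -> list[InteractionResults]:
    """Test every significant (gene A, mode) two-way pair against mutations
    in each cataloged partner gene B mutated in ≥ ``min_partner_freq`` of
    samples (gene B copy number is ignored).

    ``allowed_partners`` optionally restricts partners per gene A (used by
    the pathway-restricted screen). The partner threshold is inclusive
    (≥ 2%), unlike the strict > 2% gene-eligibility rule.
    """
    results = []
    for gene_a, mode in significant_pairs:
        partners = _partners(matrix, gene_a, catalog, min_partner_freq)
        if allowed_partners is not None:
            allow = set(allowed_partners.get(gene_a, ()))
            partners = [g for g in partners if g in allow]
        for gene_b in partners:
            table = tabulate_three_way(
                matrix, gene_a, mode, gene_b, loss_includes_deep=loss_includes_deep
            )
            results.append(fit_three_way(table, pseudocount))
    return results


@dataclass(frozen=True)
class ConditionalFrequencies:
    """Stratified co-occurrence frequencies for one (gene A, mode, gene B)
    triple; NaN marks an empty conditioning stratum."""

    cna_given_mut_b1: float
    cna_given_mut_b0: float
    mut_given_cna_b1: float
    mut_given_cna_b0: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.cna_given_mut_b1,
            self.cna_given_mut_b0,
            self.mut_given_cna_b1,
            self.mut_given_cna_b0,
        )


def conditional_frequencies(
    matrix: AlterationMatrix,
    gene_a: str,
    mode: str,
    gene_b: str,
    *,
    loss_includes_deep: bool = False,
) -> ConditionalFrequencies:
    """f(CNA_A | mut_A, ±mut_B) and f(mut_A | CNA_A, ±mut_B).

    The CNA indicator follows the mode's altered rule (−1 for loss, ≥+1
    for gain). Zero denominators yield NaN, never an error.
    """
    if gene_a == gene_b:
        raise ValueError("gene A and gene B must differ")
    mut_a = matrix.mut_col(gene_a).astype(bool)
    mut_b = matrix.mut_col(gene_b).astype(bool)
    cn = matrix.cn_col(gene_a)
    if mode == "loss":
        alt = cn <= -1 if loss_includes_deep else cn == -1
    elif mode == "gain":
        alt = cn >= 1
    else:
        raise ValueError(f"mode must be 'loss' or 'gain', got {mode!r}")

    def frac(num: np.ndarray, den: np.ndarray) -> float:
        d = int(den.sum())
        return float(num.sum() / d) if d else float("nan")

    return ConditionalFrequencies(
        cna_given_mut_b1=frac(alt & mut_a & mut_b, mut_a & mut_b),
        cna_given_mut_b0=frac(alt & mut_a & ~mut_b, mut_a & ~mut_b),
        mut_given_cna_b1=frac(mut_a & alt & mut_b, alt & mut_b),
        mut_given_cna_b0=frac(mut_a & alt & ~mut_b, alt & ~mut_b),
    )


# ---------------------------------------------------------------------------
# functional sharing
# ---------------------------------------------------------------------------


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) → gene → set of annotation terms."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["gene", "term"])
    out: dict[str, set[str]] = {}
    for gene, term in zip(table["gene"], table["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def sharing_score(
    pair: tuple[str, str],
    annotations: Mapping[str, Iterable[str]],
    method: str = "count",
) -> float:
    """Functional-similarity score of a gene pair: the number of shared
    annotation terms (default) or their Jaccard index."""
    a = set(annotations.get(pair[0], ()))
    b = set(annotations.get(pair[1], ()))
    if not a or not b:
        if pair[0] not in annotations or pair[1] not in annotations:
            logger.debug("sharing_score: unannotated gene in pair %s", pair)
        return 0.0
    shared = len(a & b)
    if method == "count":
        return float(shared)
    if method == "jaccard":
        return shared / len(a | b)
    raise ValueError(f"unknown sharing method {method!r}")


def functional_sharing_test(
    interacting_pairs: Sequence[tuple[str, str]],
    background_pairs: Sequence[tuple[str, str]],
    annotations: Mapping[str, Iterable[str]],
    method: str = "count",
) -> tuple[float, float]:
    """Mann–Whitney U test of annotation sharing: interacting vs background
    gene pairs. Returns (U for the interacting sample, two-sided p) with
    tie correction."""
    if not interacting_pairs or not background_pairs:
        raise ValueError("both pair lists must be non-empty")
    x = [sharing_score(p, annotations, method) for p in interacting_pairs]
    y = [sharing_score(p, annotations, method) for p in background_pairs]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def default_background_pairs(
    catalog: DriverCatalog,
    cancer_type: str,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[tuple[str, str]]:
    """All unordered pairs of cataloged driver genes for one cancer type,
    minus the interacting pairs."""
    genes = sorted(
        catalog.entries.loc[catalog.entries["cancer_type"] == cancer_type, "gene"].unique()
    )
    banned = {frozenset(p) for p in exclude}
    return [
        (a, b)
        for a, b in itertools.combinations(genes, 2)
        if frozenset((a, b)) not in banned
    ]


def pathway_restricted_screen(
    matrix: AlterationMatrix,
    significant_pairs: Sequence[tuple[str, str]],
    catalog: DriverCatalog,
    annotations: Mapping[str, Iterable[str]],
    min_partner_freq: float = 0.02,
    pseudocount: float = 1.0,
    *,
    loss_includes_deep: bool = False,
) -> list[InteractionResults]:
    """Third-order screen restricted to partners sharing ≥1 annotation term
    with gene A; the smaller test family sharpens the permutation FDR."""
    allowed: dict[str, set[str]] = {}
    for gene_a, _mode in significant_pairs:
        terms_a = set(annotations.get(gene_a, ()))
        allowed[gene_a] = {
            g
            for g, terms in annotations.items()
            if g != gene_a and terms_a & set(terms)
        }
    return three_way_screen(
        matrix,
        significant_pairs,
        catalog,
        min_partner_freq=min_partner_freq,
        pseudocount=pseudocount,
        allowed_partners=allowed,
        loss_includes_deep=loss_includes_deep,
    )
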