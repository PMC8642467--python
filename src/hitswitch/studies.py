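"""Simulation studies that characterize the screen's operating behaviour:
type-I error calibration on null cohorts, permutation-FDR false-call
control, planted-effect recovery, and modifier ranking.

These are the package's own validation experiments — each study generates
cohorts with the synthetic generator, runs the real screening code path,
and summarizes the outcome. They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import DriverCatalog
from .interaction import batch_two_way
from .permutation import calls_at_fdr, estimate_fdr
from .pipeline import _child_seeds, permute_alteration_matrix
from .screens import three_way_screen
from .simulate import GeneSpec, SimConfig, simulate_cohort

__all__ = [
    "NullCalibration",
    "null_calibration_study",
    "PsiRecovery",
    "psi_recovery_study",
    "tau_rank_study",
]


class _P:
    __slots__ = ("pvalue",)

    def __init__(self, pvalue: float):
        self.pvalue = pvalue


def _null_config(n_genes: int, n_samples: int, p_mut: float, p_cna: float, seed: int) -> SimConfig:
    genes = tuple(GeneSpec(f"G{i:03d}", p_mut, p_loss=p_cna) for i in range(n_genes))
    return SimConfig(n_samples=n_samples, genes=genes, seed=seed, cancer_type="NULL")


@dataclass(frozen=True)
class NullCalibration:
    """Aggregate outcome of the null-cohort calibration study."""

    n_tests: int
    type_i_error_rate: float  # fraction of two-sided p < 0.05
    n_nominal: int  # null tests with p <= 0.05
    n_fdr_calls: int  # tests admitted at the FDR target
    false_call_ratio: float  # n_fdr_calls / n_nominal

    @property
    def summary(self) -> str:
        return (
            f"{self.n_tests} null tests: {100 * self.type_i_error_rate:.2f}% at p<0.05; "
            f"{self.n_fdr_calls}/{self.n_nominal} nominal hits admitted at the FDR target "
            f"(ratio {self.false_call_ratio:.3f})"
        )


def null_calibration_study(
    *,
    n_genes: int = 200,
    n_samples: int = 1000,
    n_replicates: int = 20,
    n_permutations: int = 100,
    p_mut: float = 0.2,
    p_cna: float = 0.2,
    fdr_target: float = 0.10,
    seed: int = 0,
) -> NullCalibration:
    """Type-I error and FDR false-call control on fully null cohorts.

    Each replicate simulates an independent cohort with no planted
    interactions, fits the two-way loss model for every gene, and runs the
    full permutation-FDR procedure. Every call the procedure admits is by
    construction false; the false-call ratio relates those admissions to
    the nominally significant (p ≤ 0.05) null tests.
    """
    seeds = _child_seeds(seed, 2 * n_replicates)
    n_tests = 0
    n_p05 = 0
    n_calls = 0
    for rep in range(n_replicates):
        cfg = _null_config(n_genes, n_samples, p_mut, p_cna, seeds[2 * rep])
        matrix, _ = simulate_cohort(cfg)
        _, _, real_p = batch_two_way(matrix.mut, matrix.cn, "loss")
        real_p = real_p[~np.isnan(real_p)]
        n_tests += real_p.size
        n_p05 += int((real_p <= 0.05).sum())
        perm_seeds = _child_seeds(seeds[2 * rep + 1], n_permutations)
        permuted = []
        for k in range(n_permutations):
            pm = permute_alteration_matrix(matrix, perm_seeds[k])
            _, _, p = batch_two_way(pm.mut, pm.cn, "loss")
            permuted.append(p[~np.isnan(p)])
        curve = estimate_fdr(real_p, permuted, n_permutations=n_permutations)
        calls = calls_at_fdr([_P(p) for p in real_p], curve, fdr_target)
        n_calls += len(calls)
    return NullCalibration(
        n_tests=n_tests,
        type_i_error_rate=n_p05 / n_tests,
        n_nominal=n_p05,
        n_fdr_calls=n_calls,
        false_call_ratio=n_calls / n_p05 if n_p05 else 0.0,
    )


@dataclass(frozen=True)
class PsiRecovery:
    """Recovery of one planted two-way log-OR across replicate cohorts."""

    psi: float
    n_replicates: int
    mean_estimate: float
    bias: float
    coverage: float  # fraction of 95% Wald intervals covering psi
    n_estimable: int


def psi_recovery_study(
    psi_values: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    *,
    n_samples: int = 2000,
    n_replicates: int = 200,
    p_mut: float = 0.2,
    p_cna: float = 0.2,
    seed: int = 0,
) -> list[PsiRecovery]:
    """Fit the two-way model on cohorts with a planted psi and summarize
    estimator bias and 95% Wald-interval coverage.

    Replicates are simulated as independent genes of one cohort (each
    gene's draws are independent), which keeps the study inside the real
    batch code path.
    """
    out = []
    seeds = _child_seeds(seed, len(psi_values))
    for psi, s in zip(psi_values, seeds):
        genes = tuple(
            GeneSpec(f"G{i:03d}", p_mut, p_loss=p_cna, psi_loss=psi)
            for i in range(n_replicates)
        )
        cfg = SimConfig(n_samples=n_samples, genes=genes, seed=s, cancer_type="REC")
        matrix, _ = simulate_cohort(cfg)
        coef, se, _ = batch_two_way(matrix.mut, matrix.cn, "loss")
        ok = ~np.isnan(coef)
        covered = np.abs(coef[ok] - psi) <= 1.959963984540054 * se[ok]
        out.append(
            PsiRecovery(
                psi=psi,
                n_replicates=n_replicates,
                mean_estimate=float(coef[ok].mean()),
                bias=float(coef[ok].mean() - psi),
                coverage=float(covered.mean()),
                n_estimable=int(ok.sum()),
            )
        )
    return out


def tau_rank_study(
    *,
    n_replicates: int = 50,
    n_samples: int = 2000,
    tau: float = -2.0,
    psi: float = 1.0,
    n_partners: int = 10,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the planted modifier gene is the
    top-ranked partner (largest |three-way coefficient|) in the
    third-order screen."""
    seeds = _child_seeds(seed, n_replicates)
    hits = 0
    for rep in range(n_replicates):
        genes = [
            GeneSpec("A", 0.2, p_loss=0.2, psi_loss=psi, modifier="B", tau_loss=tau),
            GeneSpec("B", 0.2),
        ] + [GeneSpec(f"P{i:02d}", 0.05 + 0.015 * i) for i in range(n_partners)]
        cfg = SimConfig(n_samples=n_samples, genes=tuple(genes), seed=seeds[rep], cancer_type="X")
        matrix, _ = simulate_cohort(cfg)
        catalog = DriverCatalog(
            pd.DataFrame(
                {"gene": [g.name for g in genes], "cancer_type": "X", "role": "unassigned"}
            )
        )
        results = three_way_screen(matrix, [("A", "loss")], catalog)
        best = max(results, key=lambda r: abs(r.coef) if r.coef is not None else -1.0)
        hits += best.partner == "B"
    return hits / n_replicates
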