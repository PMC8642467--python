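"""Synthetic tumor cohorts with known marginal frequencies and planted
two-way / three-way log-odds interactions.

Each gene is simulated per sample from a joint distribution over
(mutation, CN state) whose margins match the configured mutation and CNA
frequencies and whose mutation×CNA log odds ratio equals the planted psi.
A gene with a modifier B uses psi when B is unmutated and psi + tau when B
is mutated, which plants a three-way (log ratio of stratum odds ratios)
interaction of exactly tau. CN states are emitted as −1 (loss) / +1 (gain)
integers, mutually exclusive per sample.

The generator emulates the statistical structure the screens assume — it
does not attempt mutation signatures, genomic positions, or segment-level
CNA correlation between genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_io import AlterationMatrix, OTHER_MISSENSE

__all__ = [
    "GeneSpec",
    "SimConfig",
    "TruthTable",
    "joint_cell_probs",
    "simulate_cohort",
    "write_cohort_inputs",
    "write_truth_table",
]


@dataclass(frozen=True)
class GeneSpec:
    """Simulation parameters for one gene.

    psi_* are planted two-way log odds ratios between mutation and the CNA
    mode; tau_* shift psi when the modifier gene is mutated.
    """

    name: str
    p_mut: float
    p_loss: float = 0.0
    p_gain: float = 0.0
    psi_loss: float = 0.0
    psi_gain: float = 0.0
    modifier: str | None = None
    tau_loss: float = 0.0
    tau_gain: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("p_mut", "p_loss", "p_gain"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.p_loss + self.p_gain > 1.0:
            raise ValueError(f"{self.name}: p_loss + p_gain > 1")
        for attr in ("psi_loss", "psi_gain", "tau_loss", "tau_gain"):
            if not math.isfinite(getattr(self, attr)):
                raise ValueError(f"{self.name}: {attr} must be finite")


@dataclass(frozen=True)
class SimConfig:
    """One synthetic cohort: sample size, per-gene specs, seed, label."""

    n_samples: int
    genes: tuple[GeneSpec, ...]
    seed: int = 0
    cancer_type: str = "SIM"
    n_hypermutators: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in SimConfig")
        by_name = {g.name: g for g in self.genes}
        for g in self.genes:
            if g.modifier is not None:
                if g.modifier not in by_name:
                    raise ValueError(f"{g.name}: modifier {g.modifier!r} has no spec")
                if g.modifier == g.name:
                    raise ValueError(f"{g.name}: gene cannot modify itself")
                if by_name[g.modifier].modifier is not None:
                    raise ValueError(
                        f"{g.name}: chained modifiers are not supported "
                        f"({g.modifier!r} has its own modifier)"
                    )

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SimConfig":
        genes = tuple(GeneSpec(**g) for g in doc["genes"])
        return cls(
            n_samples=int(doc["n_samples"]),
            genes=genes,
            seed=int(doc.get("seed", 0)),
            cancer_type=str(doc.get("cancer_type", "SIM")),
            n_hypermutators=int(doc.get("n_hypermutators", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for one simulated cohort: planted psi per (gene, mode),
    planted tau per (gene, modifier, mode), configured margins and seed."""

    psi: Mapping[tuple[str, str], float]
    tau: Mapping[tuple[str, str, str], float]
    margins: Mapping[str, tuple[float, float, float]]  # gene -> (p_mut, p_loss, p_gain)
    seed: int
    cancer_type: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, (pm, pl, pg) in self.margins.items():
            for mode, freq in (("loss", pl), ("gain", pg)):
                psi = self.psi.get((gene, mode), 0.0)
                taus = {b: t for (g, b, m), t in self.tau.items() if g == gene and m == mode}
                modifier = next(iter(taus), "")
                rows.append(
                    {
                        "gene": gene,
                        "mode": mode,
                        "p_mut": pm,
                        "p_cna": freq,
                        "psi": psi,
                        "modifier": modifier,
                        "tau": taus.get(modifier, 0.0),
                        "seed": self.seed,
                        "cancer_type": self.cancer_type,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# joint cell probabilities
# ---------------------------------------------------------------------------


def joint_cell_probs(p_mut: float, p_cna: float, psi: float) -> tuple[float, float, float, float]:
    """Cell probabilities (p00, p01, p10, p11) of a 2×2 joint with the given
    margins and log odds ratio psi.

    p11 is the root of the odds-ratio quadratic lying in the feasible
    interval [max(0, p_mut + p_cna − 1), min(p_mut, p_cna)]; the other
    cells follow from the margins. First index = mutation, second = CNA.
    """
    if not (0.0 < p_mut < 1.0 and 0.0 < p_cna < 1.0):
        raise ValueError("margins must lie strictly inside (0, 1)")
    if not math.isfinite(psi):
        raise ValueError("psi must be finite")
    if psi == 0.0:
        p11 = p_mut * p_cna
    else:
        t = math.exp(psi)
        a = t - 1.0
        s = 1.0 + (p_mut + p_cna) * a
        disc = s * s - 4.0 * a * t * p_mut * p_cna
        if disc < 0:
            raise ValueError("no feasible joint for the requested margins and psi")
        root = math.sqrt(disc)
        lo = max(0.0, p_mut + p_cna - 1.0)
        hi = min(p_mut, p_cna)
        candidates = [(s - root) / (2.0 * a), (s + root) / (2.0 * a)]
        feasible = [x for x in candidates if lo - 1e-12 <= x <= hi + 1e-12]
        if not feasible:
            raise ValueError("no feasible p11 root for the requested margins and psi")
        p11 = min(max(feasible[0], lo), hi)
    p10 = p_mut - p11
    p01 = p_cna - p11
    p00 = 1.0 - p_mut - p_cna + p11
    if min(p00, p01, p10, p11) < -1e-12:
        raise ValueError("margins and psi yield a negative cell probability")
    return (max(p00, 0.0), max(p01, 0.0), max(p10, 0.0), p11)


def _gene_cell_probs(spec: GeneSpec, psi_shift_loss: float = 0.0, psi_shift_gain: float = 0.0) -> np.ndarray:
    """Probabilities over the six (mut ∈ {0,1}) × (state ∈ {0,−1,+1}) cells.

    Each active CNA mode's joint with mutation is set marginally via
    :func:`joint_cell_probs`; loss and gain are mutually exclusive.
    Cell order: (m0,wt) (m0,loss) (m0,gain) (m1,wt) (m1,loss) (m1,gain).
    """
    pm = spec.p_mut
    if not 0.0 < pm < 1.0:
        raise ValueError(f"{spec.name}: p_mut must lie in (0, 1) to simulate")
    p11_loss = 0.0
    if spec.p_loss > 0:
        p11_loss = joint_cell_probs(pm, spec.p_loss, spec.psi_loss + psi_shift_loss)[3]
    p11_gain = 0.0
    if spec.p_gain > 0:
        p11_gain = joint_cell_probs(pm, spec.p_gain, spec.psi_gain + psi_shift_gain)[3]
    m1_wt = pm - p11_loss - p11_gain
    m0_loss = spec.p_loss - p11_loss
    m0_gain = spec.p_gain - p11_gain
    m0_wt = 1.0 - pm - m0_loss - m0_gain
    probs = np.array([m0_wt, m0_loss, m0_gain, m1_wt, p11_loss, p11_gain])
    if probs.min() < -1e-12:
        raise ValueError(
            f"{spec.name}: infeasible joint (loss+gain interactions exhaust p_mut)"
        )
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


_CELL_MUT = np.array([0, 0, 0, 1, 1, 1], dtype=np.uint8)
_CELL_CN = np.array([0, -1, 1, 0, -1, 1], dtype=np.int8)


def _draw_cells(rng: np.random.Generator, probs: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(6, size=n, p=probs)
    return _CELL_MUT[idx], _CELL_CN[idx]


def simulate_cohort(config: SimConfig) -> tuple[AlterationMatrix, TruthTable]:
    """Draw one cohort and its ground-truth table.

    Modifier-free genes are drawn first; a gene with modifier B then draws
    its (mut, CN) cells conditionally on B's realized mutation column, with
    log-OR psi (B unmutated) or psi + tau (B mutated). Identical seeds give
    identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    genes = list(config.genes)
    order = [g for g in genes if g.modifier is None] + [g for g in genes if g.modifier is not None]
    mut_cols: dict[str, np.ndarray] = {}
    cn_cols: dict[str, np.ndarray] = {}
    for spec in order:
        if spec.modifier is None:
            mut, cn = _draw_cells(rng, _gene_cell_probs(spec), n)
        else:
            b = mut_cols[spec.modifier].astype(bool)
            mut = np.zeros(n, dtype=np.uint8)
            cn = np.zeros(n, dtype=np.int8)
            probs_off = _gene_cell_probs(spec)
            probs_on = _gene_cell_probs(spec, spec.tau_loss, spec.tau_gain)
            n_on = int(b.sum())
            if n - n_on:
                mut[~b], cn[~b] = _draw_cells(rng, probs_off, n - n_on)
            if n_on:
                mut[b], cn[b] = _draw_cells(rng, probs_on, n_on)
        mut_cols[spec.name] = mut
        cn_cols[spec.name] = cn

    names = tuple(g.name for g in genes)
    mut_mat = np.column_stack([mut_cols[g] for g in names]).astype(np.uint8)
    cn_mat = np.column_stack([cn_cols[g] for g in names]).astype(np.int8)
    samples = [f"S{i:05d}" for i in range(n)]
    if config.n_hypermutators:
        # Samples mutated in every gene: exercise the Q3 + 1.5·IQR filter.
        extra_mut = np.ones((config.n_hypermutators, len(names)), dtype=np.uint8)
        extra_cn = np.zeros_like(extra_mut, dtype=np.int8)
        mut_mat = np.vstack([mut_mat, extra_mut])
        cn_mat = np.vstack([cn_mat, extra_cn])
        samples += [f"HYPER{i:03d}" for i in range(config.n_hypermutators)]

    matrix = AlterationMatrix(
        cancer_type=config.cancer_type,
        samples=tuple(samples),
        genes=names,
        mut=mut_mat,
        cn=cn_mat,
    )
    psi = {}
    tau = {}
    margins = {}
    for g in genes:
        margins[g.name] = (g.p_mut, g.p_loss, g.p_gain)
        for mode, p_cna, psival, tauval in (
            ("loss", g.p_loss, g.psi_loss, g.tau_loss),
            ("gain", g.p_gain, g.psi_gain, g.tau_gain),
        ):
            if p_cna > 0:
                psi[(g.name, mode)] = psival
                if g.modifier is not None and tauval != 0.0:
                    tau[(g.name, g.modifier, mode)] = tauval
    truth = TruthTable(psi=psi, tau=tau, margins=margins, seed=config.seed, cancer_type=config.cancer_type)
    return matrix, truth


# ---------------------------------------------------------------------------
# round-trip writers (synthetic cohorts flow through the real readers)
# ---------------------------------------------------------------------------


def write_cohort_inputs(
    matrix: AlterationMatrix,
    outdir: str | Path,
    roles: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write a cohort as the standard input files: a MAF-style mutation
    table, a gene × sample CN table, and a driver catalog covering the
    cohort's genes. Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(matrix.mut)
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": [matrix.genes[c] for c in cols],
            "Tumor_Sample_Barcode": [matrix.samples[r] for r in rows],
            "Variant_Classification": "Missense_Mutation",
            "Cancer_Type": matrix.cancer_type,
        }
    )
    mut_path = outdir / "mutations.tsv"
    maf.to_csv(mut_path, sep="\t", index=False)

    cn_path = outdir / "copy_number.tsv"
    cn_frame = pd.DataFrame(
        matrix.cn.T, index=list(matrix.genes), columns=list(matrix.samples)
    )
    cn_frame.index.name = "gene"
    cn_frame.to_csv(cn_path, sep="\t")

    cat_path = outdir / "driver_catalog.tsv"
    pd.DataFrame(
        {
            "gene": list(matrix.genes),
            "cancer_type": matrix.cancer_type,
            "role": [
                (roles or {}).get(g, "unassigned") for g in matrix.genes
            ],
        }
    ).to_csv(cat_path, sep="\t", index=False)
    return {"mutations": mut_path, "copy_number": cn_path, "catalog": cat_path}


def write_truth_table(truth: TruthTable, path: str | Path) -> Path:
    path = Path(path)
    truth.to_frame().to_csv(path, sep="\t", index=False)
    return path
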