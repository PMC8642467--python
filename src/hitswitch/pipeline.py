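"""End-to-end orchestration: two-way screen → permutation FDR → driver
classification → tissue specificity → third-order screens, with
tab-separated report tables and a YAML run manifest.

FDR is estimated jointly across all eligible gene–cancer pairs within one
model family (loss, gain, tissue, three-way); permutations are drawn per
cancer type, with the mutation, loss-event and gain-event tracks permuted
independently. Identical config + seed reproduces byte-identical tables
(the manifest carries timestamps and is excluded from that contract).
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    AlterationMatrix,
    DriverCatalog,
    MUTATION_CLASSES,
    build_alteration_matrix,
    eligible_pairs,
    read_copy_number,
    read_driver_catalog,
    read_mutations,
    read_qc_exclusions,
)
from .interaction import (
    InteractionResults,
    Table2x2,
    Table2x2x2,
    batch_two_way,
    fit_three_way,
    fit_tissue_contrast,
    fit_two_way,
    tabulate_three_way,
    tabulate_two_way,
)
from .permutation import FDRCurve, calls_at_fdr, estimate_fdr, permute_margins
from .screens import (
    build_driver_class_report,
    conditional_frequencies,
    pathway_restricted_screen,
    read_annotation_map,
    three_way_screen,
    tissue_specificity_screen,
)
from .simulate import SimConfig, simulate_cohort, write_cohort_inputs, write_truth_table

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "FamilyResult",
    "permute_alteration_matrix",
    "two_way_family",
    "tissue_family",
    "three_way_family",
    "run_pipeline",
    "results_to_frame",
    "load_matrices",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full run; either file inputs or simulation."""

    outdir: Path
    mutations: Path | None = None
    copy_number: Path | None = None
    catalog: Path | None = None
    qc_exclusions: Path | None = None
    annotations: Path | None = None
    simulation: tuple[SimConfig, ...] = ()
    fdr_target: float = 0.10
    n_permutations: int = 100
    seed: int = 0
    min_mut_freq: float = 0.02
    min_partner_freq: float = 0.02
    mutation_classes: frozenset[str] = frozenset(MUTATION_CLASSES)
    loss_includes_deep: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_target < 1.0:
            raise ValueError("fdr_target must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.simulation and (self.mutations is None or self.copy_number is None or self.catalog is None):
            raise ValueError("provide input paths or a simulation config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc, base=Path(path).parent)

    @classmethod
    def from_dict(cls, doc: Mapping, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")

        def p(key: str) -> Path | None:
            v = doc.get(key)
            return (base / v) if v else None

        sims: tuple[SimConfig, ...] = ()
        if "simulation" in doc:
            raw = doc["simulation"]
            sims = tuple(SimConfig.from_dict(d) for d in (raw if isinstance(raw, list) else [raw]))
        classes = doc.get("mutation_classes")
        return cls(
            outdir=base / doc["outdir"],
            mutations=p("mutations"),
            copy_number=p("copy_number"),
            catalog=p("catalog"),
            qc_exclusions=p("qc_exclusions"),
            annotations=p("annotations"),
            simulation=sims,
            fdr_target=float(doc.get("fdr_target", 0.10)),
            n_permutations=int(doc.get("n_permutations", 100)),
            seed=int(doc.get("seed", 0)),
            min_mut_freq=float(doc.get("min_mut_freq", 0.02)),
            min_partner_freq=float(doc.get("min_partner_freq", 0.02)),
            mutation_classes=frozenset(classes) if classes else frozenset(MUTATION_CLASSES),
            loss_includes_deep=bool(doc.get("loss_includes_deep", False)),
        )


# ---------------------------------------------------------------------------
# permuted matrices
# ---------------------------------------------------------------------------


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def permute_alteration_matrix(matrix: AlterationMatrix, seed: int) -> AlterationMatrix:
    """Margin-preserving permutation of one cohort's three event classes.

    Mutation, CNA-loss and CNA-gain binary tracks are permuted
    independently (each keeps its per-sample and per-gene totals). A
    (sample, gene) permuted to carry both loss and gain is encoded as
    CN −2, which the masking rule excludes from both model tables.
    """
    s_mut, s_loss, s_gain = _child_seeds(seed, 3)
    mut = permute_margins(matrix.mut, s_mut)
    loss = permute_margins((matrix.cn == -1).astype(np.uint8), s_loss)
    gain = permute_margins((matrix.cn >= 1).astype(np.uint8), s_gain)
    cn = np.zeros_like(matrix.cn)
    both = (loss == 1) & (gain == 1)
    cn[(loss == 1) & ~both] = -1
    cn[(gain == 1) & ~both] = 1
    cn[both] = -2
    return AlterationMatrix(
        cancer_type=matrix.cancer_type,
        samples=matrix.samples,
        genes=matrix.genes,
        mut=mut,
        cn=cn,
    )


# ---------------------------------------------------------------------------
# model families with permutation FDR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyResult:
    """One model family's results, its permutation FDR curve, and the
    significant calls at the configured target."""

    family: str
    results: tuple[InteractionResults, ...]
    curve: FDRCurve | None
    calls: tuple[InteractionResults, ...]
    fdr_target: float

    @property
    def n_tested(self) -> int:
        return len(self.results)


def two_way_family(
    matrices: Mapping[str, AlterationMatrix],
    catalog: DriverCatalog,
    mode: str,
    *,
    n_permutations: int = 100,
    seed: int = 0,
    fdr_target: float = 0.10,
    min_mut_freq: float = 0.02,
    pseudocount: float = 0.0,
    loss_includes_deep: bool = False,
) -> FamilyResult:
    """Two-way screen over all eligible gene–cancer pairs of one CNA mode,
    with permutation-count FDR pooled across cancer types."""
    results: list[InteractionResults] = []
    tested: dict[str, list[str]] = {}
    for ct, matrix in matrices.items():
        genes = [g for g, _ in eligible_pairs(matrix, catalog, min_mut_freq)]
        tested[ct] = genes
        for gene in genes:
            table = tabulate_two_way(matrix, gene, mode, loss_includes_deep=loss_includes_deep)
            results.append(fit_two_way(table, pseudocount))

    real_p = np.array(
        [r.pvalue for r in results if r.pvalue is not None], dtype=float
    )
    curve = None
    calls: list[InteractionResults] = []
    if real_p.size:
        perm_seeds = _child_seeds(seed, n_permutations)
        permuted = []
        for k in range(n_permutations):
            rep = []
            for ct, matrix in matrices.items():
                genes = tested[ct]
                if not genes:
                    continue
                pm = permute_alteration_matrix(matrix, perm_seeds[k] + zlib.crc32(ct.encode()) % 10007)
                idx = [matrix.gene_index[g] for g in genes]
                _, _, p = batch_two_way(
                    pm.mut[:, idx], pm.cn[:, idx], mode, pseudocount,
                    loss_includes_deep=loss_includes_deep,
                )
                rep.append(p)
            permuted.append(np.concatenate(rep) if rep else np.array([]))
        curve = estimate_fdr(real_p, permuted, n_permutations=n_permutations, seed=seed)
        calls = calls_at_fdr(results, curve, fdr_target)
    return FamilyResult(
        family=f"two_way_{mode}",
        results=tuple(results),
        curve=curve,
        calls=tuple(calls),
        fdr_target=fdr_target,
    )


def tissue_family(
    matrices: Mapping[str, AlterationMatrix],
    detected_calls: Sequence[InteractionResults],
    *,
    n_permutations: int = 100,
    seed: int = 0,
    fdr_target: float = 0.10,
    min_mut_freq: float = 0.02,
    pseudocount: float = 1.0,
    loss_includes_deep: bool = False,
) -> FamilyResult:
    """Tissue-specificity contrasts with their own permutation FDR; the
    test list (detected call × pooled other cohorts) is held fixed while
    the alteration matrices are permuted."""
    results = tissue_specificity_screen(
        matrices, detected_calls, min_mut_freq, pseudocount,
        loss_includes_deep=loss_includes_deep,
    )
    real_p = np.array([r.pvalue for r in results if r.pvalue is not None], dtype=float)
    curve = None
    calls: list[InteractionResults] = []
    if real_p.size:
        perm_seeds = _child_seeds(seed + 1, n_permutations)
        permuted = []
        for k in range(n_permutations):
            pmats = {
                ct: permute_alteration_matrix(m, perm_seeds[k] + zlib.crc32(ct.encode()) % 10007)
                for ct, m in matrices.items()
            }
            rep = tissue_specificity_screen(
                pmats, detected_calls, min_mut_freq, pseudocount,
                loss_includes_deep=loss_includes_deep,
            )
            permuted.append(
                np.array([r.pvalue for r in rep if r.pvalue is not None], dtype=float)
            )
        curve = estimate_fdr(real_p, permuted, n_permutations=n_permutations, seed=seed)
        calls = calls_at_fdr(results, curve, fdr_target)
    return FamilyResult(
        family="tissue_contrast",
        results=tuple(results),
        curve=curve,
        calls=tuple(calls),
        fdr_target=fdr_target,
    )


def three_way_family(
    matrices: Mapping[str, AlterationMatrix],
    catalog: DriverCatalog,
    significant_pairs: Mapping[str, Sequence[tuple[str, str]]],
    *,
    n_permutations: int = 100,
    seed: int = 0,
    fdr_target: float = 0.10,
    min_partner_freq: float = 0.02,
    pseudocount: float = 1.0,
    annotations: Mapping[str, Iterable[str]] | None = None,
    loss_includes_deep: bool = False,
) -> FamilyResult:
    """Third-order screen (optionally pathway-restricted via
    ``annotations``) over each cohort's significant two-way pairs, with
    permutation FDR pooled across cancer types."""

    def screen(mats: Mapping[str, AlterationMatrix]) -> list[InteractionResults]:
        out: list[InteractionResults] = []
        for ct, pairs in significant_pairs.items():
            if not pairs or ct not in mats:
                continue
            if annotations is None:
                out.extend(
                    three_way_screen(
                        mats[ct], pairs, catalog,
                        min_partner_freq=min_partner_freq,
                        pseudocount=pseudocount,
                        loss_includes_deep=loss_includes_deep,
                    )
                )
            else:
                out.extend(
                    pathway_restricted_screen(
                        mats[ct], pairs, catalog, annotations,
                        min_partner_freq=min_partner_freq,
                        pseudocount=pseudocount,
                        loss_includes_deep=loss_includes_deep,
                    )
                )
        return out

    results = screen(matrices)
    real_p = np.array([r.pvalue for r in results if r.pvalue is not None], dtype=float)
    curve = None
    calls: list[InteractionResults] = []
    if real_p.size:
        perm_seeds = _child_seeds(seed + 2, n_permutations)
        permuted = []
        for k in range(n_permutations):
            pmats = {
                ct: permute_alteration_matrix(m, perm_seeds[k] + zlib.crc32(ct.encode()) % 10007)
                for ct, m in matrices.items()
            }
            rep = screen(pmats)
            permuted.append(
                np.array([r.pvalue for r in rep if r.pvalue is not None], dtype=float)
            )
        curve = estimate_fdr(real_p, permuted, n_permutations=n_permutations, seed=seed)
        calls = calls_at_fdr(results, curve, fdr_target)
    family = "three_way" if annotations is None else "three_way_pathway"
    return FamilyResult(
        family=family,
        results=tuple(results),
        curve=curve,
        calls=tuple(calls),
        fdr_target=fdr_target,
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def results_to_frame(results: Sequence[InteractionResults]) -> pd.DataFrame:
    """Flatten interaction results into the tab-separated report layout."""
    rows = []
    for r in results:
        row = {
            "gene": r.gene,
            "cancer_type": r.cancer_type,
            "mode": r.mode,
            "partner": r.partner or "",
            "term": r.term,
            "coef": r.coef,
            "coef_signed_by_cn": r.coef_signed_by_cn,
            "se": r.se,
            "z": r.zvalue,
            "p": r.pvalue,
            "estimable": r.estimable,
            "pseudocount": r.pseudocount,
        }
        table = r.table
        if isinstance(table, Table2x2):
            row.update({k: getattr(table, k) for k in ("n00", "n01", "n10", "n11")})
        elif isinstance(table, Table2x2x2):
            for label, stratum in (("s0", table.stratum0), ("s1", table.stratum1)):
                row.update(
                    {f"{label}_{k}": getattr(stratum, k) for k in ("n00", "n01", "n10", "n11")}
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# input loading and the full run
# ---------------------------------------------------------------------------


def load_matrices(config: RunConfig) -> tuple[dict[str, AlterationMatrix], DriverCatalog]:
    """Build per-cancer-type alteration matrices from files or simulation."""
    if config.simulation:
        matrices: dict[str, AlterationMatrix] = {}
        cat_rows = []
        for sim in config.simulation:
            matrix, _truth = simulate_cohort(sim)
            matrices[matrix.cancer_type] = matrix
            cat_rows.extend(
                {"gene": g, "cancer_type": matrix.cancer_type, "role": "unassigned"}
                for g in matrix.genes
            )
        catalog = DriverCatalog(pd.DataFrame(cat_rows).drop_duplicates(["gene", "cancer_type"]))
        return matrices, catalog

    for path in (config.mutations, config.copy_number, config.catalog):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    calls = read_mutations(config.mutations)
    cn = read_copy_number(config.copy_number)
    catalog = read_driver_catalog(config.catalog)
    qc = read_qc_exclusions(config.qc_exclusions) if config.qc_exclusions else set()
    matrices = {}
    for ct in sorted(calls.cancer_types):
        try:
            matrices[ct] = build_alteration_matrix(
                calls, cn, catalog, ct, qc, config.mutation_classes
            )
        except ValueError as exc:
            logger.warning("cohort %s skipped: %s", ct, exc)
    if not matrices:
        raise ValueError("no cohort could be built from the inputs")
    return matrices, catalog


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full screen and write all report tables plus the run
    manifest under ``config.outdir``. Returns the in-memory results."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "fdr_target": config.fdr_target,
        "n_permutations": config.n_permutations,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    matrices, catalog = load_matrices(config)
    if config.simulation:
        for sim in config.simulation:
            matrix, truth = simulate_cohort(sim)
            simdir = outdir / "simulated" / matrix.cancer_type
            write_cohort_inputs(matrix, simdir)
            write_truth_table(truth, simdir / "truth.tsv")
    manifest["cohorts"] = {
        ct: {"n_samples": m.n_samples, "n_genes": len(m.genes)} for ct, m in matrices.items()
    }

    families: dict[str, FamilyResult] = {}
    for mode in ("loss", "gain"):
        fam = two_way_family(
            matrices, catalog, mode,
            n_permutations=config.n_permutations,
            seed=config.seed,
            fdr_target=config.fdr_target,
            min_mut_freq=config.min_mut_freq,
            loss_includes_deep=config.loss_includes_deep,
        )
        families[fam.family] = fam

    two_way_results = [r for m in ("loss", "gain") for r in families[f"two_way_{m}"].results]
    two_way_calls = [c for m in ("loss", "gain") for c in families[f"two_way_{m}"].calls]
    results_to_frame(two_way_results).to_csv(outdir / "two_way_results.tsv", sep="\t", index=False)
    results_to_frame(two_way_calls).to_csv(outdir / "two_way_calls.tsv", sep="\t", index=False)
    for mode in ("loss", "gain"):
        fam = families[f"two_way_{mode}"]
        if fam.curve is not None:
            fam.curve.to_frame().to_csv(outdir / f"fdr_two_way_{mode}.tsv", sep="\t", index=False)
    manifest["stages"]["two_way"] = {
        "n_tested": len(two_way_results),
        "n_significant": len(two_way_calls),
    }

    all_eligible = [
        pair for m in matrices.values() for pair in eligible_pairs(m, catalog, config.min_mut_freq)
    ]
    report = build_driver_class_report(
        {g for g, _ in all_eligible}, two_way_calls, all_eligible
    )
    report.table.to_csv(outdir / "driver_classes.tsv", sep="\t", index=False)
    manifest["stages"]["classify"] = {"n_genes": len(report.table)}

    tissue = tissue_family(
        matrices, two_way_calls,
        n_permutations=config.n_permutations,
        seed=config.seed,
        fdr_target=config.fdr_target,
        min_mut_freq=config.min_mut_freq,
        loss_includes_deep=config.loss_includes_deep,
    )
    results_to_frame(list(tissue.results)).to_csv(
        outdir / "tissue_contrast_results.tsv", sep="\t", index=False
    )
    if tissue.curve is not None:
        tissue.curve.to_frame().to_csv(outdir / "fdr_tissue.tsv", sep="\t", index=False)
    manifest["stages"]["tissue"] = {
        "n_tested": tissue.n_tested,
        "n_significant": len(tissue.calls),
    }

    pairs_by_ct: dict[str, list[tuple[str, str]]] = {}
    for call in two_way_calls:
        pairs_by_ct.setdefault(call.cancer_type, []).append((call.gene, call.mode))
    threeway = three_way_family(
        matrices, catalog, pairs_by_ct,
        n_permutations=config.n_permutations,
        seed=config.seed,
        fdr_target=config.fdr_target,
        min_partner_freq=config.min_partner_freq,
        loss_includes_deep=config.loss_includes_deep,
    )
    tw_frame = results_to_frame(list(threeway.results))
    if len(tw_frame):
        freqs = []
        for r in threeway.results:
            cf = conditional_frequencies(
                matrices[r.cancer_type], r.gene, r.mode, r.partner,
                loss_includes_deep=config.loss_includes_deep,
            )
            freqs.append(cf.as_tuple())
        tw_frame[
            ["f_cna_mut_b1", "f_cna_mut_b0", "f_mut_cna_b1", "f_mut_cna_b0"]
        ] = freqs
    tw_frame.to_csv(outdir / "three_way_results.tsv", sep="\t", index=False)
    results_to_frame(list(threeway.calls)).to_csv(
        outdir / "three_way_calls.tsv", sep="\t", index=False
    )
    if threeway.curve is not None:
        threeway.curve.to_frame().to_csv(outdir / "fdr_three_way.tsv", sep="\t", index=False)
    manifest["stages"]["three_way"] = {
        "n_tested": threeway.n_tested,
        "n_significant": len(threeway.calls),
    }

    pathway = None
    if config.annotations is not None:
        annotations = read_annotation_map(config.annotations)
        pathway = three_way_family(
            matrices, catalog, pairs_by_ct,
            n_permutations=config.n_permutations,
            seed=config.seed,
            fdr_target=config.fdr_target,
            min_partner_freq=config.min_partner_freq,
            annotations=annotations,
            loss_includes_deep=config.loss_includes_deep,
        )
        results_to_frame(list(pathway.results)).to_csv(
            outdir / "three_way_pathway_results.tsv", sep="\t", index=False
        )
        manifest["stages"]["three_way_pathway"] = {
            "n_tested": pathway.n_tested,
            "n_significant": len(pathway.calls),
        }

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return {
        "matrices": matrices,
        "catalog": catalog,
        "families": families,
        "tissue": tissue,
        "three_way": threeway,
        "pathway": pathway,
        "driver_classes": report,
        "manifest": manifest,
    }
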