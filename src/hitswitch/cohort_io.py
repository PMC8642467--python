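"""Cohort input handling: mutation and copy-number readers, sample QC, and
construction of per-cancer-type alteration matrices.

The analysis substrate is an :class:`AlterationMatrix` per cancer type: a
binary sample × gene somatic-mutation indicator alongside an integer
sample × gene copy-number state in GISTIC threshold coding (−2 deep
deletion, −1 broad loss, 0 neutral, +1 broad gain, +2 high amplification).
Samples enter a matrix only when present on both the mutation and the
copy-number platform, not flagged by QC, and not hypermutated
(variant count above Q3 + 1.5·IQR of the cohort).

Mutation tables are MAF-style TSVs. MC3-style MAFs carry no cancer-type
column, so :func:`read_mutations` accepts either an optional ``Cancer_Type``
column, an explicit sample→type mapping, or a single default label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PTV",
    "DELETERIOUS_MISSENSE",
    "OTHER_MISSENSE",
    "INFRAME_INDEL",
    "MUTATION_CLASSES",
    "DEFAULT_CLASS_MAP",
    "InputFormatError",
    "MutationCalls",
    "CopyNumberMatrix",
    "DriverCatalog",
    "AlterationMatrix",
    "read_mutations",
    "read_copy_number",
    "read_driver_catalog",
    "read_qc_exclusions",
    "hypermutator_cutoff",
    "flag_hypermutators",
    "build_alteration_matrix",
    "eligible_pairs",
]

# Non-synonymous mutation classes.
PTV = "PTV"
DELETERIOUS_MISSENSE = "deleterious_missense"
OTHER_MISSENSE = "other_missense"
INFRAME_INDEL = "inframe_indel"
MUTATION_CLASSES = frozenset({PTV, DELETERIOUS_MISSENSE, OTHER_MISSENSE, INFRAME_INDEL})

#: Sentinel used in class maps for missense rows, resolved per-row into
#: deleterious vs other missense from the SIFT / PolyPhen columns.
MISSENSE = "missense"

#: Default Variant_Classification → class mapping for MC3-style MAFs.
#: Premature truncation covers nonsense, frameshift indels and splice-site
#: variants; classifications absent from the map are skipped (with a count).
DEFAULT_CLASS_MAP: Mapping[str, str] = {
    "Nonsense_Mutation": PTV,
    "Frame_Shift_Del": PTV,
    "Frame_Shift_Ins": PTV,
    "Splice_Site": PTV,
    "Nonstop_Mutation": PTV,
    "Missense_Mutation": MISSENSE,
    "In_Frame_Del": INFRAME_INDEL,
    "In_Frame_Ins": INFRAME_INDEL,
}

DRIVER_ROLES = frozenset({"TSG", "OG", "DFG", "unassigned"})


class InputFormatError(ValueError):
    """Raised when an input table violates the expected format."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationCalls:
    """Per-sample non-synonymous mutation records.

    ``records`` has columns ``sample``, ``cancer_type``, ``gene``,
    ``mut_class`` (one of :data:`MUTATION_CLASSES`) and ``functional``
    (bool). A cohort may contain several records per (sample, gene).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "cancer_type", "gene", "mut_class", "functional"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"MutationCalls missing columns: {sorted(missing)}")
        if len(self.records):
            bad = set(self.records["mut_class"]) - MUTATION_CLASSES
            if bad:
                raise ValueError(f"unknown mutation classes: {sorted(bad)}")
            if (self.records["sample"].astype(str) == "").any():
                raise ValueError("empty sample id in mutation records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cancer_types(self) -> set[str]:
        return set(self.records["cancer_type"].unique())

    def for_cancer_type(self, cancer_type: str) -> pd.DataFrame:
        return self.records[self.records["cancer_type"] == cancer_type]


@dataclass(frozen=True)
class CopyNumberMatrix:
    """Gene × sample integer CN states in GISTIC threshold coding (−2..+2)."""

    values: pd.DataFrame  # index: gene, columns: sample, int dtype

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0:
            raise ValueError("copy-number matrix has no samples")
        arr = self.values.to_numpy()
        if arr.size and (arr.min() < -2 or arr.max() > 2):
            raise ValueError("copy-number states outside {-2..+2}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class DriverCatalog:
    """Driver-gene catalog: (gene, cancer_type, role) with role in
    {TSG, OG, DFG, unassigned}."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "cancer_type", "role"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"DriverCatalog missing columns: {sorted(missing)}")
        bad = set(self.entries["role"]) - DRIVER_ROLES
        if bad:
            raise ValueError(f"unknown driver roles: {sorted(bad)}")
        if self.entries.duplicated(["gene", "cancer_type"]).any():
            raise ValueError("duplicate (gene, cancer_type) catalog entries")

    @property
    def genes(self) -> set[str]:
        return set(self.entries["gene"].unique())

    def roles_for(self, gene: str) -> set[str]:
        return set(self.entries.loc[self.entries["gene"] == gene, "role"])


@dataclass(frozen=True)
class AlterationMatrix:
    """One cancer type's sample × gene mutation indicator and CN state.

    ``mut`` is binary (uint8), ``cn`` integer (−2..+2); the two share
    identical sample and gene axes.
    """

    cancer_type: str
    samples: tuple[str, ...]
    genes: tuple[str, ...]
    mut: np.ndarray
    cn: np.ndarray
    gene_index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        if self.mut.shape != (len(self.samples), len(self.genes)):
            raise ValueError("mutation matrix shape mismatch")
        if self.cn.shape != self.mut.shape:
            raise ValueError("mutation and CN matrices must share axes")
        if self.mut.size and not np.isin(np.unique(self.mut), [0, 1]).all():
            raise ValueError("mutation matrix is not binary")
        if self.cn.size and (self.cn.min() < -2 or self.cn.max() > 2):
            raise ValueError("CN states outside {-2..+2}")
        if self.gene_index is None:
            object.__setattr__(
                self, "gene_index", {g: i for i, g in enumerate(self.genes)}
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def mut_col(self, gene: str) -> np.ndarray:
        return self.mut[:, self._idx(gene)]

    def cn_col(self, gene: str) -> np.ndarray:
        return self.cn[:, self._idx(gene)]

    def mut_freq(self) -> pd.Series:
        """Per-gene mutation frequency over this matrix's samples."""
        return pd.Series(self.mut.mean(axis=0), index=list(self.genes))

    def _idx(self, gene: str) -> int:
        try:
            return self.gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix for {self.cancer_type}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def _is_deleterious(sift: object, polyphen: object) -> bool:
    """SIFT/PolyPhen call: deleterious when at least one tool flags it.

    MC3 encodes e.g. ``deleterious(0)`` / ``probably_damaging(0.98)``.
    """
    s = str(sift).lower()
    p = str(polyphen).lower()
    sift_del = s.startswith("deleterious")
    poly_del = "damaging" in p and not p.startswith("possibly_benign")
    return sift_del or poly_del


def read_mutations(
    path: str | Path,
    class_config: Mapping[str, str] | None = None,
    *,
    cancer_type_map: Mapping[str, str] | None = None,
    default_cancer_type: str | None = None,
) -> MutationCalls:
    """Read a MAF-style mutation table into :class:`MutationCalls`.

    Required columns: Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification. Optional: SIFT, PolyPhen (for the
    deleterious-missense call), Cancer_Type, Functional.

    Rows whose classification maps to no non-synonymous class are skipped
    and counted in the log. Missense rows are split into deleterious vs
    other missense when at least one of SIFT / PolyPhen2 predicts a
    deleterious/damaging variant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in _REQUIRED_MAF_COLUMNS:
        if col not in table.columns:
            raise InputFormatError(f"mutation table missing required column {col!r}")
    cmap = dict(DEFAULT_CLASS_MAP if class_config is None else class_config)

    mapped = table["Variant_Classification"].map(cmap)
    n_skipped = int(mapped.isna().sum())
    if n_skipped:
        logger.info("read_mutations: skipped %d rows with unmapped classifications", n_skipped)
    kept = table[mapped.notna()].copy()
    kept["mut_class"] = mapped[mapped.notna()]

    is_mis = kept["mut_class"] == MISSENSE
    if is_mis.any():
        sift = kept["SIFT"] if "SIFT" in kept.columns else pd.Series("", index=kept.index)
        poly = kept["PolyPhen"] if "PolyPhen" in kept.columns else pd.Series("", index=kept.index)
        delet = [
            _is_deleterious(s, p)
            for s, p in zip(sift[is_mis], poly[is_mis])
        ]
        kept.loc[is_mis, "mut_class"] = np.where(delet, DELETERIOUS_MISSENSE, OTHER_MISSENSE)

    if "Cancer_Type" in kept.columns:
        ctype = kept["Cancer_Type"].astype(str)
    elif cancer_type_map is not None:
        ctype = kept["Tumor_Sample_Barcode"].map(cancer_type_map)
        if ctype.isna().any():
            missing = kept.loc[ctype.isna(), "Tumor_Sample_Barcode"].iloc[0]
            raise InputFormatError(f"sample {missing!r} has no cancer-type assignment")
    elif default_cancer_type is not None:
        ctype = pd.Series(default_cancer_type, index=kept.index)
    else:
        raise InputFormatError(
            "no Cancer_Type column; pass cancer_type_map or default_cancer_type"
        )

    if "Functional" in kept.columns:
        functional = kept["Functional"].astype(str).str.lower().isin({"1", "true", "yes"})
    else:
        # Absent an external hotspot/functional list, every non-synonymous
        # call counts as functional.
        functional = pd.Series(True, index=kept.index)

    records = pd.DataFrame(
        {
            "sample": kept["Tumor_Sample_Barcode"].astype(str),
            "cancer_type": ctype.astype(str),
            "gene": kept["Hugo_Symbol"].astype(str),
            "mut_class": kept["mut_class"].astype(str),
            "functional": functional.to_numpy(),
        }
    ).reset_index(drop=True)
    return MutationCalls(records)


def read_copy_number(path: str | Path) -> CopyNumberMatrix:
    """Read a gene × sample table of GISTIC threshold CN states.

    First column holds gene symbols; remaining columns are samples with
    integer cells in {−2..+2}. Non-integer cells and out-of-range states
    raise :class:`InputFormatError` naming the offending gene and sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise InputFormatError(f"duplicate gene row {dup!r} in copy-number table")
    table = table.loc[:, ~table.columns.duplicated()]
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.all(values == np.floor(values)):
        rows, cols = np.where(values != np.floor(values.astype(float)))
        gene, sample = table.index[rows[0]], table.columns[cols[0]]
        raise InputFormatError(f"non-integer CN state at gene {gene!r}, sample {sample!r}")
    ivalues = values.astype(np.int64)
    bad = (ivalues < -2) | (ivalues > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InputFormatError(
            f"CN state {ivalues[r, c]} outside -2..+2 at gene "
            f"{table.index[r]!r}, sample {table.columns[c]!r}"
        )
    return CopyNumberMatrix(pd.DataFrame(ivalues.astype(np.int8), index=table.index.astype(str), columns=table.columns.astype(str)))


def read_driver_catalog(path: str | Path) -> DriverCatalog:
    """Read a (gene, cancer_type, role) driver catalog TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "cancer_type", "role"):
        if col not in table.columns:
            raise InputFormatError(f"driver catalog missing required column {col!r}")
    return DriverCatalog(table[["gene", "cancer_type", "role"]].copy())


def read_qc_exclusions(path: str | Path) -> set[str]:
    """Read a QC exclusion list: one sample id per line."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


# ---------------------------------------------------------------------------
# QC and matrix construction
# ---------------------------------------------------------------------------


def hypermutator_cutoff(variant_counts: Sequence[int] | np.ndarray) -> float:
    """Hypermutation threshold: Q3 + 1.5 × IQR of per-sample variant counts.

    Quantiles use linear interpolation. Samples strictly above the returned
    threshold are flagged hypermutated.
    """
    counts = np.asarray(variant_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("hypermutator_cutoff requires at least one sample")
    if (counts < 0).any():
        raise ValueError("variant counts must be non-negative")
    q1, q3 = np.quantile(counts, [0.25, 0.75])
    return float(q3 + 1.5 * (q3 - q1))


def flag_hypermutators(variant_counts: Mapping[str, int] | pd.Series) -> set[str]:
    """Samples whose variant count strictly exceeds the cohort cutoff."""
    series = pd.Series(variant_counts, dtype=float)
    cutoff = hypermutator_cutoff(series.to_numpy())
    return set(series.index[series > cutoff])


def build_alteration_matrix(
    calls: MutationCalls,
    cn: CopyNumberMatrix,
    catalog: DriverCatalog,
    cancer_type: str,
    qc_excluded: Iterable[str] = (),
    mutation_class_filter: Iterable[str] | None = None,
    *,
    exclude_hypermutators: bool = True,
    functional_only: bool = False,
) -> AlterationMatrix:
    """Assemble the QC-passing alteration matrix for one cancer type.

    Samples are the intersection of the mutation and CN platforms minus the
    QC exclusion list and (by default) hypermutated samples; the
    hypermutator cutoff is computed from per-sample variant counts over all
    non-synonymous records, before any class filter. The mutation indicator
    is 1 iff the sample has ≥1 record of an included class; genes are
    restricted to the driver catalog (∩ CN platform).
    """
    if mutation_class_filter is None:
        classes = set(MUTATION_CLASSES)
    else:
        classes = set(mutation_class_filter)
        if not classes:
            raise ValueError("mutation_class_filter must be non-empty")
        bad = classes - MUTATION_CLASSES
        if bad:
            raise ValueError(f"unknown mutation classes in filter: {sorted(bad)}")

    cohort = calls.for_cancer_type(cancer_type)
    if cohort.empty:
        raise ValueError(f"no mutation records for cancer type {cancer_type!r}")

    mut_platform = set(cohort["sample"])
    cn_platform = set(map(str, cn.samples))
    samples = (mut_platform & cn_platform) - set(qc_excluded)
    dropped_platform = len(mut_platform) - len(mut_platform & cn_platform)
    if dropped_platform:
        logger.info(
            "%s: %d samples lack CN data and were dropped", cancer_type, dropped_platform
        )

    if exclude_hypermutators and samples:
        counts = cohort[cohort["sample"].isin(samples)]["sample"].value_counts()
        counts = counts.reindex(sorted(samples), fill_value=0)
        hyper = flag_hypermutators(counts)
        if hyper:
            logger.info("%s: excluded %d hypermutated samples", cancer_type, len(hyper))
        samples -= hyper
    if not samples:
        raise ValueError(f"no samples remain after QC for cancer type {cancer_type!r}")

    sample_list = tuple(sorted(samples))
    cn_genes = set(map(str, cn.genes))
    genes = tuple(sorted(catalog.genes & cn_genes))
    dropped_genes = sorted((set(cohort["gene"]) & catalog.genes) - cn_genes)
    if dropped_genes:
        logger.info(
            "%s: %d cataloged genes absent from CN table were dropped: %s",
            cancer_type,
            len(dropped_genes),
            ", ".join(dropped_genes[:10]),
        )
    if not genes:
        raise ValueError(f"no cataloged genes with CN data for {cancer_type!r}")

    sub = cohort[
        cohort["sample"].isin(samples)
        & cohort["gene"].isin(genes)
        & cohort["mut_class"].isin(classes)
    ]
    if functional_only:
        # Keep PTVs plus functional-flagged non-synonymous calls.
        sub = sub[(sub["mut_class"] == PTV) | sub["functional"]]

    sidx = {s: i for i, s in enumerate(sample_list)}
    gidx = {g: i for i, g in enumerate(genes)}
    mut = np.zeros((len(sample_list), len(genes)), dtype=np.uint8)
    if len(sub):
        rows = sub["sample"].map(sidx).to_numpy()
        cols = sub["gene"].map(gidx).to_numpy()
        mut[rows, cols] = 1

    cn_block = cn.values.loc[list(genes), list(sample_list)].to_numpy().T.astype(np.int8)
    return AlterationMatrix(
        cancer_type=cancer_type,
        samples=sample_list,
        genes=genes,
        mut=mut,
        cn=cn_block,
    )


def eligible_pairs(
    matrix: AlterationMatrix,
    catalog: DriverCatalog,
    min_mut_freq: float = 0.02,
) -> list[tuple[str, str]]:
    """(gene, cancer_type) pairs eligible for the two-way screen.

    A gene qualifies when its mutation frequency in this cohort is strictly
    greater than ``min_mut_freq`` and it appears in the driver catalog for
    any cancer type.
    """
    freqs = matrix.mut_freq()
    cat_genes = catalog.genes
    return [
        (gene, matrix.cancer_type)
        for gene, f in freqs.items()
        if f > min_mut_freq and gene in cat_genes
    ]
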