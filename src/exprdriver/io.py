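"""Readers, writers and cohort-construction rules.

Three plain-text dialects are supported: tab-separated expression matrices
(rows = genes/probes, columns = patients), tab-separated binary mutation
matrices (rows = genes, columns = patients) and MAF-like mutation tables
(one somatic event per row, minimally Hugo_Symbol / Variant_Classification /
Tumor_Sample_Barcode).  Gene sets come in as standard GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "DEFAULT_KEEP_CLASSES",
    "ExpressionMatrix",
    "MutationMatrix",
    "MutationRecord",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_table",
    "write_expression_table",
    "read_mutation_table",
    "write_mutation_table",
    "read_maf",
    "mutation_matrix_from_records",
    "read_gmt",
    "write_gmt",
    "align_cohort",
]


class VariantClass(str, Enum):
    """Closed vocabulary of somatic variant classes."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    SILENT = "silent"
    OTHER = "other"


#: Classes that qualify a gene as somatically mutated for calling purposes.
#: Silent events are parsed and retained in the record list (they matter for
#: mutation-type contrasts) but never enter the binary matrix.
DEFAULT_KEEP_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT_INSERTION,
        VariantClass.FRAMESHIFT_DELETION,
    }
)

# MAF Variant_Classification spellings -> closed enum (matched lower-case).
_MAF_CLASS_MAP = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INSERTION,
    "frameshift_insertion": VariantClass.FRAMESHIFT_INSERTION,
    "frame_shift_del": VariantClass.FRAMESHIFT_DELETION,
    "frameshift_deletion": VariantClass.FRAMESHIFT_DELETION,
    "silent": VariantClass.SILENT,
}

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation event at gene level."""

    patient_id: str
    gene: str
    variant_class: VariantClass

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("MutationRecord.patient_id must be nonempty")
        if not self.gene:
            raise ValueError("MutationRecord.gene must be nonempty")


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifier(s): {dup}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued features x patients matrix (normalized upstream)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "patient")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=2 features and >=2 patients, "
                f"got {self.data.shape}"
            )
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MutationMatrix:
    """Binary genes x patients matrix; 1 = >=1 qualifying somatic mutation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "patient")
        values = self.data.to_numpy()
        if values.size == 0:
            raise ValueError("mutation matrix is empty")
        if not np.isin(values, (0, 1)).all():
            bad = values[~np.isin(values, (0, 1))][0]
            raise ValueError(f"mutation matrix cell not in {{0,1}}: {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.columns)

    def carriers(self, gene: str) -> frozenset[str]:
        row = self.data.loc[gene]
        return frozenset(row.index[row == 1])


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Flat term -> member-genes mapping (GMT semantics, no ontology DAG)."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs.genes
        return frozenset(out)


def _check_header_duplicates(path: str | Path) -> None:
    # pandas silently mangles duplicate column labels, so inspect the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise ValueError(f"duplicate patient identifier: {label!r}")
        seen.add(label)


def read_expression_table(
    path: str | Path, missing_policy: str | None = "drop-feature"
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row holds patient IDs, first column holds feature IDs.
    ``missing_policy`` is one of ``"drop-feature"`` (default: remove any
    feature row with a missing cell), ``"impute-feature-mean"`` or ``None``
    (missing cells are a hard error).  Non-numeric garbage is always a hard
    error naming the offending cell.
    """
    _check_header_duplicates(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "feature")
    _check_unique(raw.columns, "patient")

    stripped = raw.apply(lambda col: col.str.strip())
    na_mask = stripped.apply(lambda col: col.str.lower().isin(_NA_TOKENS))
    numeric = stripped.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    garbage = numeric.isna() & ~na_mask
    if garbage.to_numpy().any():
        r, c = np.argwhere(garbage.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {stripped.iat[r, c]!r} at "
            f"feature {raw.index[r]!r}, patient {raw.columns[c]!r}"
        )

    if na_mask.to_numpy().any():
        if missing_policy == "drop-feature":
            keep = ~na_mask.any(axis=1)
            dropped = int((~keep).sum())
            logger.warning("dropping %d feature(s) with missing values", dropped)
            numeric = numeric.loc[keep]
        elif missing_policy == "impute-feature-mean":
            means = numeric.mean(axis=1)
            numeric = numeric.apply(lambda col: col.fillna(means))
        elif missing_policy is None:
            r, c = np.argwhere(na_mask.to_numpy())[0]
            raise ValueError(
                f"missing expression value at feature {raw.index[r]!r}, "
                f"patient {raw.columns[c]!r} and no missing policy given"
            )
        else:
            raise ValueError(f"unknown missing policy {missing_policy!r}")

    return ExpressionMatrix(numeric.astype(float))


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="feature")


def read_mutation_table(path: str | Path) -> MutationMatrix:
    """Read a tab-separated binary genes x patients matrix."""
    _check_header_duplicates(path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.size == 0:
        raise ValueError(f"mutation table {path} is empty")
    raw.index = raw.index.astype(str)
    values = raw.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))][0]
        raise ValueError(f"mutation table cell not in {{0,1}}: {bad!r}")
    return MutationMatrix(raw.astype(np.int8))


def write_mutation_table(mut: MutationMatrix, path: str | Path) -> None:
    mut.data.to_csv(path, sep="\t", index_label="gene")


def _find_column(columns: Sequence[str], wanted: str) -> str:
    lowered = {c.lower(): c for c in columns}
    if wanted.lower() not in lowered:
        raise ValueError(f"MAF table lacks required column {wanted!r}")
    return lowered[wanted.lower()]


def parse_variant_class(label: str) -> VariantClass:
    """Map a MAF Variant_Classification string onto the closed enum.

    Unknown labels become OTHER (with a logged warning), never a crash.
    """
    key = label.strip().lower()
    if key in _MAF_CLASS_MAP:
        return _MAF_CLASS_MAP[key]
    try:
        return VariantClass(key)
    except ValueError:
        logger.warning("unknown variant classification %r mapped to 'other'", label)
        return VariantClass.OTHER


def read_maf(
    path: str | Path,
    keep_classes: frozenset[VariantClass] = DEFAULT_KEEP_CLASSES,
    barcode_prefix: int | None = 12,
) -> tuple[list[MutationRecord], MutationMatrix]:
    """Read a MAF-like table into records plus a binary matrix.

    The record list retains every event (silent included); the matrix is
    built from ``keep_classes`` only.  Sample barcodes are truncated to
    ``barcode_prefix`` characters (TCGA patient level, default 12); pass
    ``None`` to keep barcodes verbatim.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    gene_col = _find_column(table.columns, "Hugo_Symbol")
    class_col = _find_column(table.columns, "Variant_Classification")
    sample_col = _find_column(table.columns, "Tumor_Sample_Barcode")

    records: list[MutationRecord] = []
    for gene, vclass, barcode in zip(
        table[gene_col], table[class_col], table[sample_col]
    ):
        patient = str(barcode).strip()
        if barcode_prefix is not None:
            patient = patient[:barcode_prefix]
        records.append(
            MutationRecord(patient, str(gene).strip(), parse_variant_class(str(vclass)))
        )
    matrix = mutation_matrix_from_records(records, keep_classes)
    return records, matrix


def mutation_matrix_from_records(
    records: Iterable[MutationRecord],
    keep_classes: frozenset[VariantClass] = DEFAULT_KEEP_CLASSES,
) -> MutationMatrix:
    """Collapse per-event records into a binary gene x patient matrix."""
    records = list(records)
    if not records:
        raise ValueError("no mutation records")
    genes = sorted({r.gene for r in records})
    patients = sorted({r.patient_id for r in records})
    data = pd.DataFrame(
        np.zeros((len(genes), len(patients)), dtype=np.int8),
        index=genes,
        columns=patients,
    )
    for r in records:
        if r.variant_class in keep_classes:
            data.at[r.gene, r.patient_id] = 1
    return MutationMatrix(data)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (term, description, genes...)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning(
                    "skipping malformed GMT line %d (%d field(s))", lineno, len(fields)
                )
                continue
            term_id, name = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("skipping GMT line %d: no genes", lineno)
                continue
            if term_id in collection:
                logger.warning("duplicate GMT term %r: keeping first", term_id)
                continue
            collection.terms[term_id] = GeneSet(term_id, name, genes)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.genes)]) + "\n")


def align_cohort(
    expr: ExpressionMatrix, mut: MutationMatrix
) -> tuple[ExpressionMatrix, MutationMatrix]:
    """Restrict both matrices to patients present in both, expression order.

    Patients with only one of the two data types carry no information for
    neighbor-based calling and are removed.
    """
    mut_patients = set(mut.patient_ids)
    shared = [p for p in expr.patient_ids if p in mut_patients]
    if not shared:
        raise ValueError("no patients shared between expression and mutation data")
    return (
        ExpressionMatrix(expr.data.loc[:, shared]),
        MutationMatrix(mut.data.loc[:, shared]),
    )
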