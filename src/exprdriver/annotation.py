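"""Per-patient functional-term annotation and group/type contrasts.

A patient's "mutated-gene pool" is the union of genes mutated anywhere in
the patient's expression neighborhood.  Each gene-set term is tested for
over-representation of the pool against a background universe (by default
the genes mutated anywhere in the cohort, intersected with the gene-set
universe) with a one-sided Fisher test; terms passing alpha_term are
assigned to the patient.  Two kinds of downstream contrasts are provided:
annotated-patient counts between two patient groups (e.g. functional vs
non-functional carriers of a gene), and variant-class composition between
functional and non-functional mutations of one gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_ALPHA, FunctionalCall, fisher_exact_2x2
from .io import GeneSetCollection, MutationMatrix, MutationRecord, VariantClass
from .similarity import NeighborSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCall",
    "TypeContrast",
    "neighborhood_gene_pool",
    "annotate_patient",
    "annotate_cohort",
    "annotation_table",
    "term_coverage",
    "compare_groups_for_term",
    "compare_mutation_types",
]


@dataclass(frozen=True)
class AnnotationCall:
    patient_id: str
    term_id: str
    pool_hits: int
    pool_size: int
    background_hits: int
    background_size: int
    p_value: float
    is_annotated: bool


@dataclass(frozen=True)
class TypeContrast:
    """Variant-class composition of functional vs non-functional mutations."""

    gene: str
    table: pd.DataFrame  # class, n_functional, n_nonfunctional, fractions, p
    defined: bool  # False when either carrier group is empty


def neighborhood_gene_pool(
    patient: str, neighbor_set: NeighborSet, mut: MutationMatrix
) -> frozenset[str]:
    """Union of genes mutated in any member of the patient's neighborhood."""
    members = list(neighbor_set.member_ids)
    sub = mut.data[members]
    return frozenset(sub.index[sub.sum(axis=1) > 0])


def annotate_patient(
    patient: str,
    pool: frozenset[str],
    gene_sets: GeneSetCollection,
    background: frozenset[str],
    alpha_term: float = DEFAULT_ALPHA,
) -> list[AnnotationCall]:
    """Term over-representation of one patient's mutated-gene pool.

    The 2x2 table per term is gene-level: pool genes in/out of the term vs
    remaining background genes in/out of the term, tested one-sided
    (greater).  Terms with no background overlap are skipped; pool genes
    outside the background are ignored (the pool is a background subset by
    construction).
    """
    pool = frozenset(pool) & background
    if not pool:
        logger.warning("patient %s: empty mutated-gene pool, skipping annotation", patient)
        return []
    rest = background - pool
    out: list[AnnotationCall] = []
    for gs in gene_sets:
        term_bg = gs.genes & background
        if not term_bg:
            continue
        a = len(pool & term_bg)
        b = len(pool) - a
        c = len(rest & term_bg)
        d = len(rest) - c
        p = fisher_exact_2x2(a, b, c, d, sided="greater")
        out.append(
            AnnotationCall(
                patient_id=patient,
                term_id=gs.term_id,
                pool_hits=a,
                pool_size=len(pool),
                background_hits=len(term_bg),
                background_size=len(background),
                p_value=p,
                is_annotated=bool(p < alpha_term),
            )
        )
    return out


def cohort_background(
    mut: MutationMatrix, gene_sets: GeneSetCollection, universe: str = "cohort"
) -> frozenset[str]:
    """Background gene universe for term enrichment.

    ``"cohort"`` (default): genes mutated anywhere in the cohort intersected
    with the gene-set universe; ``"genesets"``: every gene mentioned by any
    term regardless of mutation status.
    """
    annotated = gene_sets.all_genes()
    if universe == "genesets":
        return annotated
    if universe == "cohort":
        mutated = frozenset(mut.data.index[mut.data.sum(axis=1) > 0])
        return mutated & annotated
    raise ValueError(f"unknown background universe {universe!r}")


def annotate_cohort(
    neighbor_sets: Mapping[str, NeighborSet],
    mut: MutationMatrix,
    gene_sets: GeneSetCollection,
    alpha_term: float = DEFAULT_ALPHA,
    universe: str = "cohort",
) -> tuple[list[AnnotationCall], list[str]]:
    """Annotate every callable patient; returns (calls, skipped patients)."""
    background = cohort_background(mut, gene_sets, universe)
    calls: list[AnnotationCall] = []
    skipped: list[str] = []
    for patient, ns in neighbor_sets.items():
        if not ns.callable:
            skipped.append(patient)
            continue
        pool = neighborhood_gene_pool(patient, ns, mut)
        calls.extend(
            annotate_patient(patient, pool, gene_sets, background, alpha_term)
        )
    return calls, skipped


def annotation_table(calls: Iterable[AnnotationCall]) -> pd.DataFrame:
    rows = [
        (
            c.patient_id,
            c.term_id,
            c.pool_hits,
            c.pool_size,
            c.background_hits,
            c.background_size,
            c.p_value,
            c.is_annotated,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient",
            "term",
            "pool_hits",
            "pool_size",
            "background_hits",
            "background_size",
            "p",
            "annotated",
        ],
    )


def term_coverage(calls: Iterable[AnnotationCall], n_patients: int) -> pd.DataFrame:
    """Fraction of the cohort annotated with each term, sorted descending."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    annotated: dict[str, set[str]] = {}
    for c in calls:
        if c.is_annotated:
            annotated.setdefault(c.term_id, set()).add(c.patient_id)
    rows = [
        (term, len(patients), len(patients) / n_patients)
        for term, patients in annotated.items()
    ]
    df = pd.DataFrame(rows, columns=["term", "n_annotated", "fraction"])
    return df.sort_values(
        ["fraction", "term"], ascending=[False, True], ignore_index=True
    )


def compare_groups_for_term(
    group_a: Iterable[str],
    group_b: Iterable[str],
    term_id: str,
    calls: Iterable[AnnotationCall],
    sided: str = "two_sided",
) -> tuple[tuple[tuple[int, int], tuple[int, int]], float]:
    """Fisher contrast of term-annotation counts between two patient groups.

    Returns the 2x2 table ((annotated_a, not_a), (annotated_b, not_b)) and
    its Fisher p (two-sided by default: the published contrasts describe
    "differences", not a direction).
    """
    a_set, b_set = set(group_a), set(group_b)
    if not a_set or not b_set:
        raise ValueError("both groups must be nonempty")
    if a_set & b_set:
        raise ValueError(f"groups overlap: {sorted(a_set & b_set)}")
    annotated = {
        c.patient_id for c in calls if c.term_id == term_id and c.is_annotated
    }
    a = len(a_set & annotated)
    b = len(a_set) - a
    c = len(b_set & annotated)
    d = len(b_set) - c
    return ((a, b), (c, d)), fisher_exact_2x2(a, b, c, d, sided=sided)


def compare_mutation_types(
    records: Iterable[MutationRecord],
    calls: Iterable[FunctionalCall],
    gene: str,
    sided: str = "two_sided",
) -> TypeContrast:
    """Variant-class composition contrast for one gene.

    Carriers are split into functional vs non-functional by their call for
    ``gene``; every record of the gene contributes once to its class in the
    carrier's group (per-record counting: one patient can carry several
    classes).  Each class gets a Fisher p of class-vs-rest between groups.
    """
    gene_records = [r for r in records if r.gene == gene]
    if not gene_records:
        raise ValueError(f"no mutation records for gene {gene!r}")
    functional_patients = {
        c.patient_id for c in calls if c.gene == gene and c.is_functional
    }
    rows = []
    counts: dict[VariantClass, list[int]] = {
        vc: [0, 0] for vc in VariantClass
    }
    for r in gene_records:
        group = 0 if r.patient_id in functional_patients else 1
        counts[r.variant_class][group] += 1
    total_f = sum(v[0] for v in counts.values())
    total_nf = sum(v[1] for v in counts.values())
    defined = total_f > 0 and total_nf > 0
    if not defined:
        logger.warning(
            "gene %s: one carrier group is empty; type contrast undefined", gene
        )
    for vc in VariantClass:
        nf_, nnf = counts[vc]
        frac_f = nf_ / total_f if total_f else float("nan")
        frac_nf = nnf / total_nf if total_nf else float("nan")
        if defined:
            p = fisher_exact_2x2(
                nf_, total_f - nf_, nnf, total_nf - nnf, sided=sided
            )
        else:
            p = float("nan")
        rows.append((vc.value, nf_, nnf, frac_f, frac_nf, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "variant_class",
            "n_functional",
            "n_nonfunctional",
            "frac_functional",
            "frac_nonfunctional",
            "p",
        ],
    )
    return TypeContrast(gene=gene, table=table, defined=defined)
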