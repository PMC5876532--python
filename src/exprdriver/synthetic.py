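"""Synthetic cohorts with planted drivers, passengers and ground truth.

The generator realises the two assumptions the caller relies on: a
functional ("driver") mutation imprints an expression signature, and
patients sharing a driver therefore share similar expression profiles.
Each driver gene owns a disjoint block of signature features; carriers of
the driver receive an additive shift of ``effect`` on that block on top of
i.i.d. Gaussian noise.  Passenger mutations hit genes at a small uniform
Bernoulli rate with no expression consequence, and one designated
"large gene" (a TTN-like stand-in for a huge coding sequence) uses an
inflated passenger rate while still never touching expression — the
canonical recurrence-without-function confounder.

Default parameters describe a cohort of 300 patients with strong subtype
structure: the effect-to-noise ratio is set so that two carriers of the
same driver correlate at roughly r = 0.9 over the biomarker features,
patients sharing one of two drivers at roughly r = 0.6, and unrelated
patients near 0 — i.e. the r > 0.6 neighborhood rule recovers driver
cliques the way subtype cliques appear in real tumor expression data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MutationMatrix,
    MutationRecord,
    VariantClass,
    write_expression_table,
    write_gmt,
    write_mutation_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "RecoveryReport",
    "simulate_cohort",
    "make_gene_sets",
    "evaluate_recovery",
    "write_cohort",
    "read_truth",
]

#: Variant-class distribution for qualifying (matrix-building) events,
#: dominated by missense as in typical somatic spectra.
DEFAULT_CLASS_PROBS: Mapping[VariantClass, float] = {
    VariantClass.MISSENSE: 0.70,
    VariantClass.NONSENSE: 0.12,
    VariantClass.FRAMESHIFT_INSERTION: 0.10,
    VariantClass.FRAMESHIFT_DELETION: 0.08,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator (defaults are the reference scenario)."""

    n_patients: int = 300
    n_features: int = 3000
    n_genes: int = 100
    n_drivers: int = 5
    signature_size: int = 100  # features per driver signature (disjoint blocks)
    effect: float = 3.0  # additive expression shift on signature features
    noise_sd: float = 0.2  # per-feature Gaussian noise
    driver_prevalence: float = 0.15  # per-driver carrier fraction
    passenger_rate: float = 0.01  # per-gene, per-patient Bernoulli rate
    large_gene_factor: float = 17.0  # passenger-rate multiplier for the large gene
    silent_rate: float = 0.003  # records-only silent events, per gene-patient
    coupled_pair: tuple[int, int] | None = None  # driver indices to correlate
    coupling: float = 0.0  # correlation of the coupled pair's indicators
    class_probs: Mapping[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_drivers > self.n_genes:
            raise ValueError("n_drivers must be <= n_genes")
        if self.n_drivers * self.signature_size > self.n_features:
            raise ValueError("driver signatures do not fit into n_features")
        for name in ("driver_prevalence", "passenger_rate", "silent_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.passenger_rate * self.large_gene_factor <= 1.0:
            raise ValueError("passenger_rate * large_gene_factor must be in [0,1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.coupled_pair is not None:
            i, j = self.coupled_pair
            if not (0 <= i < self.n_drivers and 0 <= j < self.n_drivers and i != j):
                raise ValueError(f"invalid coupled_pair {self.coupled_pair}")
            if not 0.0 <= self.coupling <= 1.0:
                raise ValueError("coupling must be in [0,1]")
        probs = np.array(list(self.class_probs.values()), dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be a probability distribution")
        if VariantClass.SILENT in self.class_probs:
            raise ValueError(
                "class_probs covers qualifying events only; silent events are "
                "controlled by silent_rate"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted driver structure of a simulated cohort."""

    driver_genes: tuple[str, ...]
    large_gene: str
    functional_pairs: frozenset[tuple[str, str]]  # (patient, gene)

    def drivers_of(self, patient: str) -> frozenset[str]:
        return frozenset(g for p, g in self.functional_pairs if p == patient)


@dataclass(frozen=True)
class SimulatedCohort:
    expression: ExpressionMatrix
    mutations: MutationMatrix
    records: tuple[MutationRecord, ...]
    truth: GroundTruth
    config: SimulationConfig


@dataclass(frozen=True)
class RecoveryReport:
    precision: float  # NaN when there are no functional calls
    recall: float
    n_true_pairs: int
    n_functional_calls: int
    per_gene: pd.DataFrame


def _draw_assignments(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Driver x patient Bernoulli indicator matrix, optionally coupled."""
    p = config.driver_prevalence
    assign = (rng.random((config.n_drivers, config.n_patients)) < p).astype(np.int8)
    if config.coupled_pair is not None and config.coupling > 0:
        i, j = config.coupled_pair
        # Bivariate Bernoulli with matching marginals and correlation rho:
        # P(both) = p^2 + rho p (1-p).
        p11 = p * p + config.coupling * p * (1 - p)
        u = rng.random(config.n_patients)
        x_i = assign[i].astype(bool)
        cond1 = p11 / p if p > 0 else 0.0
        cond0 = (p - p11) / (1 - p) if p < 1 else 0.0
        assign[j] = np.where(x_i, u < cond1, u < cond0).astype(np.int8)
    return assign


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SimulatedCohort:
    """Generate one cohort (expression, mutations, event records, truth).

    All randomness flows from ``config.seed``; identical configs give
    bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pat, n_feat, n_gene = config.n_patients, config.n_features, config.n_genes

    patients = [f"P{i + 1:04d}" for i in range(n_pat)]
    features = [f"F{i + 1:05d}" for i in range(n_feat)]
    genes = [f"G{i + 1:03d}" for i in range(n_gene)]
    driver_genes = tuple(genes[: config.n_drivers])
    large_gene = genes[-1]
    if large_gene in driver_genes:
        raise ValueError("need at least one non-driver gene for the large gene")

    assign = _draw_assignments(config, rng)

    # Expression: noise + disjoint signature shift per carried driver.
    expr = rng.normal(0.0, config.noise_sd, size=(n_feat, n_pat))
    for d in range(config.n_drivers):
        lo = d * config.signature_size
        block = slice(lo, lo + config.signature_size)
        carriers = assign[d] == 1
        expr[block, carriers] += config.effect

    # Mutations: passengers everywhere, inflated rate for the large gene,
    # certainty for planted drivers.
    rates = np.full(n_gene, config.passenger_rate)
    rates[genes.index(large_gene)] = config.passenger_rate * config.large_gene_factor
    mut = (rng.random((n_gene, n_pat)) < rates[:, None]).astype(np.int8)
    for d, gene in enumerate(driver_genes):
        mut[genes.index(gene)] = np.maximum(mut[genes.index(gene)], assign[d])

    # Event records: one qualifying event per mutated cell plus independent
    # records-only silent events.
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    records: list[MutationRecord] = []
    for gi, gene in enumerate(genes):
        for pi in np.flatnonzero(mut[gi]):
            vclass = classes[rng.choice(len(classes), p=probs)]
            records.append(MutationRecord(patients[pi], gene, vclass))
    silent_hits = rng.random((n_gene, n_pat)) < config.silent_rate
    for gi, pi in np.argwhere(silent_hits):
        records.append(
            MutationRecord(patients[pi], genes[gi], VariantClass.SILENT)
        )

    pairs = frozenset(
        (patients[pi], driver_genes[d])
        for d in range(config.n_drivers)
        for pi in np.flatnonzero(assign[d])
    )
    return SimulatedCohort(
        expression=ExpressionMatrix(
            pd.DataFrame(expr, index=features, columns=patients)
        ),
        mutations=MutationMatrix(
            pd.DataFrame(mut, index=genes, columns=patients)
        ),
        records=tuple(records),
        truth=GroundTruth(driver_genes, large_gene, pairs),
        config=config,
    )


def make_gene_sets(
    genes: Iterable[str],
    driver_genes: Iterable[str] = (),
    n_terms: int = 8,
    term_size: int = 20,
    seed: int = 0,
) -> GeneSetCollection:
    """Random flat gene sets over the simulated gene universe.

    Each planted driver gets one term containing it (plus random members);
    the remaining terms are uniform draws.  Useful to exercise the
    annotation stage of a simulated pipeline run.
    """
    genes = sorted(set(genes))
    drivers = [g for g in driver_genes if g in genes]
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    idx = 0
    for gene in drivers:
        members = set(rng.choice(genes, size=min(term_size - 1, len(genes)), replace=False))
        members.add(gene)
        idx += 1
        tid = f"TERM{idx:03d}"
        collection.terms[tid] = GeneSet(tid, f"module containing {gene}", frozenset(members))
    while idx < n_terms:
        members = rng.choice(genes, size=min(term_size, len(genes)), replace=False)
        idx += 1
        tid = f"TERM{idx:03d}"
        collection.terms[tid] = GeneSet(tid, "random module", frozenset(members))
    return collection


def evaluate_recovery(
    calls: Iterable,  # FunctionalCall
    truth: GroundTruth,
) -> RecoveryReport:
    """Precision/recall of functional calls against planted driver pairs."""
    called = {
        (c.patient_id, c.gene) for c in calls if c.is_functional
    }
    true_pairs = set(truth.functional_pairs)
    tp = called & true_pairs
    precision = len(tp) / len(called) if called else float("nan")
    recall = len(tp) / len(true_pairs) if true_pairs else float("nan")
    rows = []
    genes = sorted({g for _, g in true_pairs} | {g for _, g in called})
    for gene in genes:
        truth_g = {p for p, g in true_pairs if g == gene}
        called_g = {p for p, g in called if g == gene}
        rows.append(
            (
                gene,
                gene in truth.driver_genes,
                len(truth_g),
                len(called_g & truth_g),
                len(called_g - truth_g),
            )
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene", "is_driver", "true_pairs", "recovered", "false_calls"]
    )
    return RecoveryReport(
        precision=precision,
        recall=recall,
        n_true_pairs=len(true_pairs),
        n_functional_calls=len(called),
        per_gene=per_gene,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path,
                 gene_sets: GeneSetCollection | None = None) -> dict[str, Path]:
    """Write a cohort in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.tsv",
        "maf": outdir / "mutations.maf",
        "truth": outdir / "truth.tsv",
    }
    write_expression_table(cohort.expression, paths["expression"])
    write_mutation_table(cohort.mutations, paths["mutations"])
    maf = pd.DataFrame(
        [
            (r.gene, r.variant_class.value, r.patient_id)
            for r in cohort.records
        ],
        columns=["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"],
    )
    maf.to_csv(paths["maf"], sep="\t", index=False)
    truth = pd.DataFrame(
        sorted(cohort.truth.functional_pairs), columns=["patient", "gene"]
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if gene_sets is not None:
        paths["gene_sets"] = outdir / "gene_sets.gmt"
        write_gmt(gene_sets, paths["gene_sets"])
    return paths


def read_truth(path: str | Path) -> frozenset[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return frozenset(zip(df["patient"], df["gene"]))
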