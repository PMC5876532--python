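"""Per-(patient, gene) mutation-enrichment statistics and functional calls.

The core idea: a somatic mutation of patient P in gene g is "functional"
when g is mutated unusually often among P's expression neighbors.  With k
mutated members in a neighborhood of size n, K cohort-wide carriers and N
patients overall, the null of randomly chosen neighbors makes the mutated
count hypergeometric, so the enrichment p-value is the upper hypergeometric
tail P[X >= k] — identically the one-sided Fisher exact p of the 2x2 table

        [[k, n-k], [K-k, N-n-K+k]]  (neighbors vs rest, mutated vs not).

A seeded permutation sampler of random neighborhoods is kept as an
empirical cross-check of that analytic null.

A note on focal inclusion: following the published design the focal patient
counts in both k and n (so k >= 1 for every tested gene).  Because only
mutated (patient, gene) pairs are ever tested, this conditions the observed
count on k >= 1 while the null tail does not, which makes the default test
anti-conservative for rare genes.  ``include_focal=False`` removes the focal
patient from k, n, K and N consistently, giving an exactly calibrated
(conservative, by discreteness) variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, MutationMatrix
from .similarity import (
    DEFAULT_K_BIOMARKERS,
    DEFAULT_N_MIN,
    DEFAULT_N_NEIGHBORS,
    DEFAULT_R_MIN,
    NeighborSet,
    neighborhoods,
    pairwise_correlation,
    select_biomarkers,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalCall",
    "RecurrenceSummary",
    "CallerParams",
    "CallResult",
    "hypergeometric_tail",
    "fisher_exact_2x2",
    "chi2_2x2",
    "mutation_enrichment_p",
    "permutation_null_p",
    "call_functional_mutations",
    "scan_neighbor_sizes",
    "calls_table",
    "summarize_recurrence",
    "recurrence_table",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class FunctionalCall:
    """Enrichment result for one (patient, mutated gene) pair."""

    patient_id: str
    gene: str
    k: int  # mutated members of the neighborhood (focal included by default)
    n: int  # neighborhood size actually used
    K: int  # cohort-wide carrier count for the gene
    N: int  # cohort size
    p_value: float
    is_functional: bool


@dataclass(frozen=True)
class RecurrenceSummary:
    """Per-gene somatic vs functional recurrence (Table-style summary)."""

    gene: str
    somatic_count: int
    functional_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.functional_count <= self.somatic_count):
            raise ValueError(
                f"{self.gene}: functional_count {self.functional_count} must be "
                f"in [0, somatic_count={self.somatic_count}]"
            )

    @property
    def percentage(self) -> float:
        """functional / somatic x 100, rounded to one decimal."""
        if self.somatic_count == 0:
            return 0.0
        return round(100.0 * self.functional_count / self.somatic_count, 1)


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the functional-mutation caller."""

    k_biomarkers: int = DEFAULT_K_BIOMARKERS
    n: int = DEFAULT_N_NEIGHBORS
    r_min: float = DEFAULT_R_MIN
    n_min: int = DEFAULT_N_MIN
    alpha: float = DEFAULT_ALPHA
    include_focal: bool = True
    correction: str | None = None  # None or "bh" (Benjamini-Hochberg)


@dataclass
class CallResult:
    calls: list[FunctionalCall]
    skipped_patients: list[str]
    params: CallerParams


def _validate_margins(k: int, n: int, K: int, N: int) -> None:
    if min(k, n, K, N) < 0:
        raise ValueError(f"negative count in (k={k}, n={n}, K={K}, N={N})")
    if k > min(n, K) or n > N or K > N:
        raise ValueError(
            f"inconsistent hypergeometric arguments (k={k}, n={n}, K={K}, N={N})"
        )


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws).

    Exact tail summation (scipy's survival function works in log space), so
    it stays accurate for large cohorts and deep tails.
    """
    _validate_margins(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


_SIDED = {"greater": "greater", "less": "less", "two_sided": "two-sided"}


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "greater") -> float:
    """Fisher's exact test on [[a, b], [c, d]].

    One-sided tails coincide with the hypergeometric tail of the
    corresponding margins; the two-sided p sums all tables whose
    conditional probability does not exceed the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in ({a}, {b}, {c}, {d})")
    if sided not in _SIDED:
        raise ValueError(f"sided must be one of {sorted(_SIDED)}, got {sided!r}")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table %s: p = 1", table.tolist())
        return 1.0
    return float(stats.fisher_exact(table, alternative=_SIDED[sided])[1])


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = True) -> float:
    """Chi-square association test on [[a, b], [c, d]] (Yates by default).

    Provided alongside Fisher because published contingency statistics are
    frequently chi-square approximations even when labelled otherwise.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in ({a}, {b}, {c}, {d})")
    return float(
        stats.chi2_contingency([[a, b], [c, d]], correction=correction)[1]
    )


def mutation_enrichment_p(
    patient: str,
    gene: str,
    neighbor_set: NeighborSet,
    mut: MutationMatrix,
    alpha: float = DEFAULT_ALPHA,
    include_focal: bool = True,
) -> FunctionalCall:
    """Score one (patient, gene) pair against its expression neighborhood.

    k counts mutated neighborhood members and K cohort carriers; the
    p-value is the upper hypergeometric tail.  An uncallable neighborhood
    yields a call with p marked NaN and no functional flag.
    """
    row = mut.data.loc[gene]
    if row[patient] != 1:
        raise ValueError(f"patient {patient!r} does not carry a mutation in {gene!r}")
    members = list(neighbor_set.member_ids)
    k = int(row[members].sum())
    n = len(members)
    K = int(row.sum())
    N = mut.data.shape[1]
    if not include_focal:
        k, n, K, N = k - 1, n - 1, K - 1, N - 1
    if not neighbor_set.callable:
        return FunctionalCall(patient, gene, k, n, K, N, float("nan"), False)
    p = hypergeometric_tail(k, n, K, N) if n > 0 else 1.0
    return FunctionalCall(patient, gene, k, n, K, N, p, bool(p < alpha))


def permutation_null_p(
    patient: str,
    gene: str,
    mut: MutationMatrix,
    n: int,
    observed_k: int,
    n_perm: int = 1000,
    seed: int | None = None,
    condition_on_focal: bool = False,
) -> float:
    """Empirical enrichment p from randomly drawn size-n neighborhoods.

    Each permutation draws a uniform random size-n patient subset and counts
    its carriers of ``gene``; the empirical p is
    (1 + #{draws with count >= observed k}) / (n_perm + 1).  The default
    unconditional draws realise exactly the analytic hypergeometric null;
    ``condition_on_focal=True`` forces the focal patient into every draw
    (the stricter reading of "random neighbors of P1").
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    patients = mut.patient_ids
    N = len(patients)
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N={N}, got n={n}")
    row = mut.data.loc[gene].to_numpy()
    focal_idx = patients.index(patient)
    rng = np.random.default_rng(seed)

    # Vectorised sampling without replacement: rank random keys per draw.
    keys = rng.random((n_perm, N))
    if condition_on_focal:
        keys[:, focal_idx] = -1.0  # focal always among the n smallest keys
    subset_idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
    counts = row[subset_idx].sum(axis=1)
    return float((1 + int((counts >= observed_k).sum())) / (n_perm + 1))


def call_functional_mutations(
    expr: ExpressionMatrix,
    mut: MutationMatrix,
    params: CallerParams = CallerParams(),
    corr: pd.DataFrame | None = None,
) -> CallResult:
    """Run the full caller: biomarkers -> neighborhoods -> enrichment calls.

    Expression and mutation matrices must already be patient-aligned.  One
    call is produced per (callable patient, mutated gene) pair; patients
    whose neighborhood stays below n_min members are listed in
    ``skipped_patients`` and contribute no calls.
    """
    if expr.patient_ids != mut.patient_ids:
        raise ValueError("expression and mutation patients differ; run align_cohort")
    if corr is None:
        biomarkers = select_biomarkers(expr, params.k_biomarkers)
        corr = pairwise_correlation(expr, biomarkers)
    sets = neighborhoods(corr, n=params.n, r_min=params.r_min, n_min=params.n_min)

    patients = mut.patient_ids
    genes = mut.gene_ids
    values = mut.data.to_numpy()
    K_all = values.sum(axis=1)
    N = len(patients)
    pos = {p: i for i, p in enumerate(patients)}

    calls: list[FunctionalCall] = []
    skipped: list[str] = []
    for patient in patients:
        ns = sets[patient]
        if not ns.callable:
            skipped.append(patient)
            continue
        member_idx = [pos[pid] for pid in ns.member_ids]
        mutated = np.flatnonzero(values[:, pos[patient]] == 1)
        if mutated.size == 0:
            continue
        k_vec = values[np.ix_(mutated, member_idx)].sum(axis=1)
        n_size = len(member_idx)
        for gi, k in zip(mutated, k_vec):
            k, n_, K_, N_ = int(k), n_size, int(K_all[gi]), N
            if not params.include_focal:
                k, n_, K_, N_ = k - 1, n_ - 1, K_ - 1, N_ - 1
            p = hypergeometric_tail(k, n_, K_, N_) if n_ > 0 else 1.0
            calls.append(
                FunctionalCall(patient, genes[gi], k, n_, K_, N_, p, False)
            )

    calls = _apply_significance(calls, params)
    return CallResult(calls=calls, skipped_patients=skipped, params=params)


def _apply_significance(
    calls: list[FunctionalCall], params: CallerParams
) -> list[FunctionalCall]:
    if not calls:
        return calls
    pvals = np.array([c.p_value for c in calls])
    if params.correction is None:
        flags = pvals < params.alpha
    elif params.correction == "bh":
        from statsmodels.stats.multitest import multipletests

        flags = multipletests(pvals, alpha=params.alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown correction {params.correction!r}")
    return [replace(c, is_functional=bool(f)) for c, f in zip(calls, flags)]


def scan_neighbor_sizes(
    expr: ExpressionMatrix,
    mut: MutationMatrix,
    params: CallerParams = CallerParams(),
    n_values: Sequence[int] = tuple(range(5, 31)),
) -> dict[int, CallResult]:
    """Re-run the caller for each neighborhood size n (default 5..30).

    The published analysis explored this whole range without pooling; the
    scan reports each n side by side and shares one correlation matrix.
    """
    biomarkers = select_biomarkers(expr, params.k_biomarkers)
    corr = pairwise_correlation(expr, biomarkers)
    out: dict[int, CallResult] = {}
    for n in n_values:
        p = replace(params, n=n, n_min=min(params.n_min, n))
        out[n] = call_functional_mutations(expr, mut, p, corr=corr)
    return out


def calls_table(calls: Iterable[FunctionalCall]) -> pd.DataFrame:
    """Calls as a stable tab-friendly table (patient, gene, k, n, K, N, p, functional)."""
    rows = [
        (c.patient_id, c.gene, c.k, c.n, c.K, c.N, c.p_value, c.is_functional)
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["patient", "gene", "k", "n", "K", "N", "p", "functional"]
    )


def summarize_recurrence(
    calls: Iterable[FunctionalCall], mut: MutationMatrix
) -> list[RecurrenceSummary]:
    """Per-gene somatic count, functional count and percentage.

    Sorted by functional count descending (gene ID breaks ties), covering
    every gene with at least one somatic carrier.
    """
    functional: dict[str, int] = {}
    for c in calls:
        if c.is_functional:
            functional[c.gene] = functional.get(c.gene, 0) + 1
    somatic = mut.data.sum(axis=1)
    out = [
        RecurrenceSummary(gene, int(count), functional.get(gene, 0))
        for gene, count in somatic.items()
        if count > 0
    ]
    out.sort(key=lambda s: (-s.functional_count, -s.somatic_count, s.gene))
    return out


def recurrence_table(summaries: Iterable[RecurrenceSummary]) -> pd.DataFrame:
    rows = [
        (s.gene, s.somatic_count, s.functional_count, s.percentage)
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["gene", "somatic", "functional", "percentage"]
    )
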