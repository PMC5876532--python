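"""Biomarker selection and expression-similarity patient neighborhoods.

The similarity structure of the cohort is summarised in two steps: the top-k
highest-variance features ("biomarkers", default k=2000) define each
patient's expression vector, and per-patient neighborhoods are the n
patients (the focal patient included) with the largest Pearson correlation
to that vector, subject to a minimum correlation r_min.  Distance, where
needed, is 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerSet",
    "NeighborSet",
    "select_biomarkers",
    "pairwise_correlation",
    "find_neighbors",
    "neighborhoods",
    "neighbor_table",
    "write_correlation",
]

DEFAULT_K_BIOMARKERS = 2000
DEFAULT_N_NEIGHBORS = 10
DEFAULT_R_MIN = 0.6
DEFAULT_N_MIN = 5


@dataclass(frozen=True)
class BiomarkerSet:
    """Top-variance features, ordered by descending sample variance."""

    feature_ids: tuple[str, ...]
    variances: tuple[float, ...]
    k: int

    def __post_init__(self) -> None:
        if list(self.variances) != sorted(self.variances, reverse=True):
            raise ValueError("biomarker variances must be non-increasing")


@dataclass(frozen=True)
class NeighborSet:
    """Ordered expression neighbors of one patient.

    The focal patient is always the first entry with r = 1; subsequent
    entries are ordered by decreasing correlation, all >= r_min.  A
    neighborhood is ``callable`` when it reached at least ``n_min`` members
    (self included); patients below that get no enrichment calls.
    """

    patient_id: str
    neighbors: tuple[tuple[str, float], ...]
    n: int
    r_min: float
    callable: bool

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.neighbors)

    def __len__(self) -> int:
        return len(self.neighbors)


def select_biomarkers(expr: ExpressionMatrix, k: int = DEFAULT_K_BIOMARKERS) -> BiomarkerSet:
    """Pick the k features with the largest expression variance.

    Variance is the unbiased sample variance across patients.  Ties are
    broken by lexicographic feature ID so the selection is reproducible; a
    fully constant matrix triggers a warning but still returns k features.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    variances = expr.data.var(axis=1, ddof=1)
    if (variances == 0).all():
        logger.warning("all feature variances are zero; selecting by ID order")
    ranked = variances.to_frame("var")
    ranked["fid"] = ranked.index.astype(str)
    ranked = ranked.sort_values(["var", "fid"], ascending=[False, True])
    k_eff = min(k, len(ranked))
    chosen = ranked.iloc[:k_eff]
    return BiomarkerSet(
        feature_ids=tuple(chosen["fid"]),
        variances=tuple(float(v) for v in chosen["var"]),
        k=k_eff,
    )


def pairwise_correlation(
    expr: ExpressionMatrix, biomarkers: BiomarkerSet | None = None
) -> pd.DataFrame:
    """Patient x patient Pearson correlation over the biomarker features.

    Returns a symmetric DataFrame with unit diagonal.  A patient whose
    biomarker vector has zero variance has undefined correlations; its
    off-diagonal entries are NaN (and it is later excluded from neighbor
    candidacy) with a logged warning.
    """
    if biomarkers is None:
        biomarkers = select_biomarkers(expr)
    if len(biomarkers.feature_ids) < 2:
        raise ValueError("need at least 2 biomarker features for correlation")
    sub = expr.data.loc[list(biomarkers.feature_ids)].to_numpy(dtype=float)
    patients = expr.patient_ids
    sd = sub.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [p for p, d in zip(patients, degenerate) if d]
        logger.warning("zero-variance biomarker vector for patient(s): %s", bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=patients, columns=patients)


def find_neighbors(
    corr: pd.DataFrame,
    patient: str,
    n: int = DEFAULT_N_NEIGHBORS,
    r_min: float = DEFAULT_R_MIN,
    n_min: int = DEFAULT_N_MIN,
) -> NeighborSet:
    """Neighborhood of ``patient``: self plus up to n-1 best correlates.

    Candidates are the other patients with r >= r_min (NaN excluded),
    ranked by decreasing r with lexicographic patient-ID tie-break.
    Running out of candidates is not an error: the neighborhood is simply
    short, and flagged not-callable when below n_min members.
    """
    if patient not in corr.index:
        raise KeyError(f"patient {patient!r} not in correlation matrix")
    if not (1 <= n_min <= n):
        raise ValueError(f"need 1 <= n_min <= n, got n_min={n_min}, n={n}")
    row = corr.loc[patient].drop(labels=[patient])
    ok = row[(row >= r_min) & row.notna()]
    order = sorted(ok.items(), key=lambda item: (-item[1], item[0]))[: n - 1]
    entries = [(patient, 1.0)] + [(pid, float(r)) for pid, r in order]
    return NeighborSet(
        patient_id=patient,
        neighbors=tuple(entries),
        n=n,
        r_min=r_min,
        callable=len(entries) >= n_min,
    )


def neighborhoods(
    corr: pd.DataFrame,
    n: int = DEFAULT_N_NEIGHBORS,
    r_min: float = DEFAULT_R_MIN,
    n_min: int = DEFAULT_N_MIN,
) -> dict[str, NeighborSet]:
    """find_neighbors for every patient of the correlation matrix."""
    return {
        patient: find_neighbors(corr, patient, n=n, r_min=r_min, n_min=n_min)
        for patient in corr.index
    }


def neighbor_table(sets: Mapping[str, NeighborSet]) -> pd.DataFrame:
    """Flatten neighborhoods to (patient, neighbor, rank, r, callable)."""
    rows = []
    for patient in sets:
        ns = sets[patient]
        for rank, (pid, r) in enumerate(ns.neighbors):
            rows.append((patient, pid, rank, r, ns.callable))
    return pd.DataFrame(
        rows, columns=["patient", "neighbor", "rank", "r", "callable"]
    )


def write_correlation(corr: pd.DataFrame, path: str | Path) -> None:
    corr.to_csv(path, sep="\t", index_label="patient")
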