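"""End-to-end orchestration: files in, call/annotation/network tables out.

All interchange is plain tab-separated text so stages compose via files and
every intermediate is inspectable.  A run manifest records the full
parameter set and library versions; because every source of randomness is
seeded, the manifest suffices to reproduce a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_cohort, annotation_table, term_coverage
from .enrichment import (
    CallerParams,
    CallResult,
    call_functional_mutations,
    calls_table,
    recurrence_table,
    summarize_recurrence,
)
from .io import (
    align_cohort,
    read_expression_table,
    read_gmt,
    read_maf,
    read_mutation_table,
)
from .network import build_synergy_network, write_network
from .similarity import (
    neighbor_table,
    neighborhoods,
    pairwise_correlation,
    select_biomarkers,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths plus parameters for a full pipeline run."""

    expression: str
    mutations: str | None = None  # binary matrix
    maf: str | None = None  # alternative mutation input
    gmt: str | None = None  # optional gene sets; annotation skipped if absent
    outdir: str = "exprdriver_out"
    k_biomarkers: int = 2000
    n: int = 10
    r_min: float = 0.6
    n_min: int = 5
    alpha: float = 0.01
    alpha_term: float = 0.01
    min_shared: int = 2
    min_score: float = 0.0
    include_focal: bool = True
    correction: str | None = None
    group_sided: str = "two_sided"
    background_universe: str = "cohort"
    missing_policy: str = "drop-feature"
    barcode_prefix: int | None = 12
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def caller_params(self) -> CallerParams:
        return CallerParams(
            k_biomarkers=self.k_biomarkers,
            n=self.n,
            r_min=self.r_min,
            n_min=self.n_min,
            alpha=self.alpha,
            include_focal=self.include_focal,
            correction=self.correction,
        )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run call + annotation + network stages and write the output bundle.

    Returns the mapping of output names to written paths.  The annotation
    stage is skipped (with a logged notice) when no GMT is configured.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    logger.info("stage io: reading inputs")
    expr = read_expression_table(config.expression, config.missing_policy)
    if config.mutations:
        mut = read_mutation_table(config.mutations)
        records = None
    elif config.maf:
        records, mut = read_maf(config.maf, barcode_prefix=config.barcode_prefix)
    else:
        raise ValueError("config needs either 'mutations' or 'maf'")
    expr, mut = align_cohort(expr, mut)

    logger.info("stage similarity: %d patients", expr.n_patients)
    biomarkers = select_biomarkers(expr, config.k_biomarkers)
    corr = pairwise_correlation(expr, biomarkers)
    sets = neighborhoods(corr, n=config.n, r_min=config.r_min, n_min=config.n_min)
    outputs["neighbors"] = outdir / "neighbors.tsv"
    neighbor_table(sets).to_csv(outputs["neighbors"], sep="\t", index=False)

    logger.info("stage enrichment: calling functional mutations")
    result = call_functional_mutations(expr, mut, config.caller_params(), corr=corr)
    outputs["calls"] = outdir / "calls.tsv"
    calls_table(result.calls).to_csv(outputs["calls"], sep="\t", index=False)
    outputs["recurrence"] = outdir / "recurrence.tsv"
    recurrence_table(summarize_recurrence(result.calls, mut)).to_csv(
        outputs["recurrence"], sep="\t", index=False
    )
    outputs["skipped_patients"] = outdir / "skipped_patients.txt"
    outputs["skipped_patients"].write_text(
        "".join(f"{p}\n" for p in result.skipped_patients)
    )

    if config.gmt:
        logger.info("stage annotation")
        gene_sets = read_gmt(config.gmt)
        ann_calls, _ = annotate_cohort(
            sets, mut, gene_sets,
            alpha_term=config.alpha_term,
            universe=config.background_universe,
        )
        outputs["annotations"] = outdir / "annotations.tsv"
        annotation_table(ann_calls).to_csv(outputs["annotations"], sep="\t", index=False)
        outputs["coverage"] = outdir / "coverage.tsv"
        term_coverage(ann_calls, expr.n_patients).to_csv(
            outputs["coverage"], sep="\t", index=False
        )
    else:
        logger.info("no gene sets configured: skipping annotation stage")

    logger.info("stage network")
    graph = build_synergy_network(
        result.calls,
        n_patients=expr.n_patients,
        min_shared=config.min_shared,
        min_score=config.min_score,
    )
    outputs["network_graphml"] = outdir / "network.graphml"
    write_network(graph, outputs["network_graphml"], format="graphml")
    outputs["network_edges"] = outdir / "network_edges.tsv"
    write_network(graph, outputs["network_edges"], format="edge_tsv")

    manifest = {
        "exprdriver_version": __version__,
        "config": dataclasses.asdict(config),
        "n_patients": expr.n_patients,
        "n_genes": len(mut.gene_ids),
        "n_biomarkers": biomarkers.k,
        "n_calls": len(result.calls),
        "n_skipped_patients": len(result.skipped_patients),
        "outputs": {name: str(path) for name, path in outputs.items()},
        "versions": _library_versions(),
    }
    outputs["manifest"] = outdir / "manifest.yaml"
    with open(outputs["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outputs


def _library_versions() -> dict[str, str]:
    import networkx
    import numpy
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }
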