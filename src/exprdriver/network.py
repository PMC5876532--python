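"""Synergy network of co-occurring functional mutations.

Two genes are "synergistic" when their functional-mutation carriers
overlap.  The synergy score of genes a and b with functional carrier sets
A and B is |A intersect B| / max(|A|, |B|), a bounded [0, 1] co-occurrence
weight (0 for disjoint carriers, 1 when the larger set swallows the
smaller one and they coincide in the overlap).  Co-occurrence significance
is a one-sided Fisher test of the overlap against independent carrier
sets.  The network connects genes with at least ``min_shared`` shared
functional carriers; node weights are functional-carrier counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .enrichment import FunctionalCall, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "synergy_score",
    "cooccurrence_significance",
    "functional_carriers",
    "build_synergy_network",
    "write_network",
    "read_network",
    "edge_table_rows",
]

DEFAULT_MIN_SHARED = 2


def synergy_score(
    carriers_a: Iterable[str],
    carriers_b: Iterable[str],
    literal_union: bool = False,
) -> float:
    """Synergy of two functional-carrier sets: |A & B| / max(|A|, |B|).

    ``literal_union=True`` replaces the numerator by |A | B| (an audit mode
    reproducing the unbounded union variant of the score, which is >= 1 by
    construction and not useful as an edge weight).
    """
    A, B = set(carriers_a), set(carriers_b)
    if not A or not B:
        raise ValueError("carrier sets must be nonempty")
    numerator = len(A | B) if literal_union else len(A & B)
    return numerator / max(len(A), len(B))


def cooccurrence_significance(
    carriers_a: Iterable[str], carriers_b: Iterable[str], N: int
) -> float:
    """One-sided Fisher p for carrier-set overlap beyond independence.

    Table: [[shared, |A|-shared], [|B|-shared, N-|A|-|B|+shared]] over the
    cohort of N patients.
    """
    A, B = set(carriers_a), set(carriers_b)
    if not A or not B:
        raise ValueError("carrier sets must be nonempty")
    if N < len(A | B):
        raise ValueError(f"N={N} smaller than the union of carrier sets")
    s = len(A & B)
    return fisher_exact_2x2(s, len(A) - s, len(B) - s, N - len(A) - len(B) + s,
                            sided="greater")


def functional_carriers(calls: Iterable[FunctionalCall]) -> dict[str, frozenset[str]]:
    """gene -> set of patients with a functional call for that gene."""
    acc: dict[str, set[str]] = {}
    for c in calls:
        if c.is_functional:
            acc.setdefault(c.gene, set()).add(c.patient_id)
    return {g: frozenset(p) for g, p in acc.items()}


def build_synergy_network(
    calls: Iterable[FunctionalCall],
    n_patients: int,
    min_shared: int = DEFAULT_MIN_SHARED,
    min_score: float = 0.0,
) -> nx.Graph:
    """Build the weighted synergy network from functional calls.

    Nodes: genes with >= 1 functional call, weighted by functional-carrier
    count.  Edges: unordered gene pairs with ``shared >= min_shared`` and
    ``score >= min_score``, annotated with shared count, synergy score and
    co-occurrence Fisher p.  Node/edge insertion is sorted, so the output
    is deterministic.
    """
    carriers = functional_carriers(calls)
    graph = nx.Graph()
    if not carriers:
        logger.warning("no functional calls: returning an empty synergy network")
        return graph
    genes = sorted(carriers)
    for gene in genes:
        graph.add_node(gene, weight=len(carriers[gene]))
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            shared = len(carriers[a] & carriers[b])
            if shared < min_shared:
                continue
            score = synergy_score(carriers[a], carriers[b])
            if score < min_score:
                continue
            p = cooccurrence_significance(carriers[a], carriers[b], n_patients)
            graph.add_edge(a, b, shared=shared, score=score, p=p)
    return graph


def edge_table_rows(graph: nx.Graph) -> list[tuple[str, str, int, float, float]]:
    rows = []
    for a, b, attrs in sorted(graph.edges(data=True)):
        rows.append((a, b, attrs["shared"], attrs["score"], attrs["p"]))
    return rows


def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML or a tab-separated edge list."""
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tshared\tscore\tp\n")
            for a, b, shared, score, p in edge_table_rows(graph):
                fh.write(f"{a}\t{b}\t{shared}\t{score}\t{p}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    graph = nx.read_graphml(path)
    out = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        out.add_node(str(node), weight=int(attrs.get("weight", 0)))
    for a, b, attrs in graph.edges(data=True):
        out.add_edge(
            str(a),
            str(b),
            shared=int(attrs["shared"]),
            score=float(attrs["score"]),
            p=float(attrs["p"]),
        )
    return out
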