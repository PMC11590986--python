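"""Topology-based link prediction over the knowledge graph.

Unconnected node pairs are scored by the common-neighbor family of
similarity measures (as popularized by graph-database data-science
toolkits), treating all edges as undirected:

* ``common_neighbors``  — ``|N(a) ∩ N(b)|``
* ``adamic_adar``       — ``Σ_{w ∈ N(a)∩N(b), deg(w) ≥ 2} 1 / ln deg(w)``
* ``resource_allocation`` — ``Σ_{w ∈ N(a)∩N(b)} 1 / deg(w)``
* ``preferential_attachment`` — ``|N(a)| · |N(b)|``

A higher score suggests a higher likelihood of an undiscovered relationship
between the pair.  In this schema protein and MeSH nodes are never directly
adjacent (their common neighbors are documents), so the candidate universe
for protein × MeSH prediction is the full cartesian product of the two node
sets.  Degree-1 common neighbors are skipped by Adamic–Adar (1/ln 1 is
undefined); such neighbors cannot occur for protein × MeSH pairs, whose
common neighbors carry at least the two edges connecting them to the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .kg import KnowledgeGraph

MEASURES = (
    "common_neighbors",
    "adamic_adar",
    "resource_allocation",
    "preferential_attachment",
)

DEFAULT_MEASURE = "adamic_adar"


def neighbors(kg: KnowledgeGraph, node_id: str) -> set[str]:
    """All nodes adjacent via any edge type (undirected)."""
    if node_id not in kg.graph:
        raise KeyError(f"unknown node {node_id!r}")
    return set(kg.graph.neighbors(node_id))


def pair_score(kg: KnowledgeGraph, a: str, b: str, measure: str = DEFAULT_MEASURE) -> float:
    """Similarity score of an (a, b) pair under one measure; symmetric in (a, b)."""
    if a == b:
        raise ValueError("pair_score requires two distinct nodes")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    na, nb = neighbors(kg, a), neighbors(kg, b)
    if measure == "preferential_attachment":
        return float(len(na) * len(nb))
    common = na & nb
    if measure == "common_neighbors":
        return float(len(common))
    deg = kg.graph.degree
    if measure == "adamic_adar":
        return float(sum(1.0 / math.log(deg(w)) for w in common if deg(w) >= 2))
    return float(sum(1.0 / deg(w) for w in common))


@dataclass
class PairScoreTable:
    """Scored candidate pairs of two node types, sorted by score descending."""

    table: pd.DataFrame  # node_a, node_b, measure, score
    type_a: str
    type_b: str
    measure: str

    def to_matrix(self) -> pd.DataFrame:
        """Wide matrix (rows = type-a nodes, columns = type-b nodes) for heatmaps."""
        return self.table.pivot(index="node_a", columns="node_b", values="score")


def rank_candidate_pairs(
    kg: KnowledgeGraph, type_a: str, type_b: str, measure: str = DEFAULT_MEASURE
) -> PairScoreTable:
    """Score every (type_a, type_b) node pair without a direct edge.

    The full product is reported (zeros included), sorted by score descending
    with lexicographic (node_a, node_b) tie-breaks; pairs already joined by an
    edge are excluded.
    """
    a_nodes = kg.nodes_of_type(type_a)
    b_nodes = kg.nodes_of_type(type_b)
    rows = []
    for a in a_nodes:
        na = neighbors(kg, a)
        for b in b_nodes:
            if b in na:  # existing direct edge: not a prediction candidate
                continue
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "measure": measure,
                    "score": pair_score(kg, a, b, measure),
                }
            )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "measure", "score"])
    df = df.sort_values(
        by=["score", "node_a", "node_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return PairScoreTable(table=df, type_a=type_a, type_b=type_b, measure=measure)
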