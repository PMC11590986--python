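"""Heterogeneous knowledge graph over proteins, documents, MeSH, and pathways.

Schema: four node types (``protein``, ``document``, ``mesh``, ``pathway``)
and three edge types — ``assigns`` (document→mesh), ``mentions``
(document→protein, with the occurrence count as an attribute), and
``contains`` (pathway→protein).  The CaseOLAP score matrix lives beside the
graph as an attribute table, not as an edge type.

On top of the graph this module implements the co-occurrence analyses: a
protein co-occurs with an OS molecule when some document both mentions the
protein and is assigned the molecule's MeSH descriptor.  OS molecules are
scored as the mean CaseOLAP score of their co-occurring proteins per CVD
category; pathways as the mean of member-protein scores damped by the
pathway's enrichment p-value, ``mean(S(p, C) · (1 − p))``, over the members
inside the curated entity set (reverse mapping).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .caseolap import ScoreMatrix
from .corpus_cube import TextCube
from .vocab import (
    MeshDescriptor,
    OsDescriptor,
    OS_PHASES,
    PathwayRecord,
    ProteinEntity,
)

logger = logging.getLogger(__name__)

NODE_TYPES = ("protein", "document", "mesh", "pathway")
EDGE_TYPES = ("assigns", "mentions", "contains")

# edge type -> (source node type, target node type)
EDGE_SCHEMA = {
    "assigns": ("document", "mesh"),
    "mentions": ("document", "protein"),
    "contains": ("pathway", "protein"),
}


class KnowledgeGraphError(ValueError):
    pass


@dataclass
class KnowledgeGraph:
    """Typed-node/typed-edge graph backed by an undirected networkx graph."""

    graph: nx.Graph

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, t in self.graph.nodes(data="node_type") if t == node_type
        )

    def edges_of_type(self, edge_type: str) -> list[tuple[str, str, dict]]:
        src_t, _ = EDGE_SCHEMA[edge_type]
        out = []
        for u, v, data in self.graph.edges(data=True):
            if data["edge_type"] == edge_type:
                if self.graph.nodes[v]["node_type"] == src_t:
                    u, v = v, u
                out.append((u, v, data))
        return out

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_type"]

    def node_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in NODE_TYPES}
        for _, t in self.graph.nodes(data="node_type"):
            counts[t] += 1
        return counts

    def edge_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TYPES}
        for _, _, t in self.graph.edges(data="edge_type"):
            counts[t] += 1
        return counts


def build_knowledge_graph(
    cube: TextCube,
    mention_index: Mapping[str, Mapping[str, int]],
    proteins: Mapping[str, ProteinEntity],
    cvd_vocab: Mapping[str, MeshDescriptor],
    os_vocab: Mapping[str, OsDescriptor],
    pathways: Mapping[str, PathwayRecord] | None = None,
    doc_mesh: Mapping[str, Iterable[str]] | None = None,
) -> KnowledgeGraph:
    """Assemble the heterogeneous graph from the pipeline's artifacts.

    Nodes: every document in the cube universe, every CVD and OS MeSH
    descriptor, every curated protein, every pathway record.  Edges:
    ``assigns`` for each (document, in-vocabulary descriptor) pair from
    ``doc_mesh`` (doc_id → assigned MeSH IDs); ``mentions`` for each
    (document, protein) with positive count; ``contains`` from pathway
    membership lists.  Document MeSH IDs outside both vocabularies are
    dropped (count logged); a mention of a protein outside the entity list
    is an error.
    """
    g = nx.Graph()
    for d in sorted(cube.universe):
        g.add_node(d, node_type="document")
    mesh_ids: set[str] = set(cvd_vocab) | set(os_vocab)
    for m in sorted(mesh_ids):
        name = cvd_vocab[m].name if m in cvd_vocab else os_vocab[m].name
        g.add_node(m, node_type="mesh", name=name, is_os=m in os_vocab)
    for p in sorted(proteins):
        g.add_node(p, node_type="protein", name=proteins[p].primary_name)
    pathways = pathways or {}
    for pw in sorted(pathways):
        rec = pathways[pw]
        g.add_node(pw, node_type="pathway", name=rec.name, p_value=rec.p_value)

    n_dropped = 0
    if doc_mesh:
        for d, ms in doc_mesh.items():
            if d not in cube.universe:
                continue
            for m in ms:
                if m in mesh_ids:
                    g.add_edge(d, m, edge_type="assigns")
                else:
                    n_dropped += 1
    if n_dropped:
        logger.info("dropped %d document MeSH assignments outside the vocabularies", n_dropped)

    for d, counts in mention_index.items():
        if d not in cube.universe:
            continue
        for p, n in counts.items():
            if p not in proteins:
                raise KnowledgeGraphError(f"mention of unknown protein_id {p!r}")
            g.add_edge(d, p, edge_type="mentions", count=int(n))

    for pw, rec in pathways.items():
        for p in rec.member_protein_ids:
            if p in proteins:
                g.add_edge(pw, p, edge_type="contains")

    return KnowledgeGraph(graph=g)


def export_graph(kg: KnowledgeGraph, directory, format: str = "bulk_csv") -> list[Path]:
    """Write the graph as graph-database bulk-import CSVs or as GraphML.

    ``bulk_csv`` produces one ``nodes_<type>.csv`` per node type with
    ``id:ID,:LABEL,...`` headers and one ``edges_<type>.csv`` per edge type
    with ``:START_ID,:END_ID,:TYPE,...`` headers.  ``graphml`` writes a single
    typed-attribute file readable by :func:`load_graphml`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "bulk_csv":
        for nt in NODE_TYPES:
            path = d / f"nodes_{nt}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["id:ID", ":LABEL", "name"])
                for n in kg.nodes_of_type(nt):
                    w.writerow([n, nt, kg.graph.nodes[n].get("name", "")])
            written.append(path)
        for et in EDGE_TYPES:
            path = d / f"edges_{et}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow([":START_ID", ":END_ID", ":TYPE", "count"])
                for u, v, data in sorted(kg.edges_of_type(et)[:], key=lambda e: (e[0], e[1])):
                    w.writerow([u, v, et, data.get("count", "")])
            written.append(path)
    elif format == "graphml":
        path = d / "kg.graphml"
        nx.write_graphml(kg.graph, path)
        written.append(path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return written


def load_bulk_csv(directory) -> KnowledgeGraph:
    """Re-import a bulk_csv export (inverse of :func:`export_graph`)."""
    d = Path(directory)
    g = nx.Graph()
    for nt in NODE_TYPES:
        with open(d / f"nodes_{nt}.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                attrs = {"node_type": row[":LABEL"]}
                if row.get("name"):
                    attrs["name"] = row["name"]
                g.add_node(row["id:ID"], **attrs)
    for et in EDGE_TYPES:
        with open(d / f"edges_{et}.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                attrs = {"edge_type": row[":TYPE"]}
                if row.get("count"):
                    attrs["count"] = int(row["count"])
                g.add_edge(row[":START_ID"], row[":END_ID"], **attrs)
    return KnowledgeGraph(graph=g)


def load_graphml(path) -> KnowledgeGraph:
    return KnowledgeGraph(graph=nx.read_graphml(path))


def protein_os_cooccurrence(kg: KnowledgeGraph) -> pd.DataFrame:
    """Document-level co-occurrence of proteins with OS MeSH descriptors.

    Rows ``(protein_id, os_descriptor_id, n_docs)`` for every pair supported
    by at least one document that mentions the protein and is assigned the
    descriptor.
    """
    g = kg.graph
    pair_docs: dict[tuple[str, str], int] = {}
    for d in kg.nodes_of_type("document"):
        ms = []
        ps = []
        for nb in g.neighbors(d):
            data = g.edges[d, nb]
            if data["edge_type"] == "assigns" and g.nodes[nb].get("is_os"):
                ms.append(nb)
            elif data["edge_type"] == "mentions":
                ps.append(nb)
        for p in ps:
            for m in ms:
                pair_docs[(p, m)] = pair_docs.get((p, m), 0) + 1
    rows = [
        {"protein_id": p, "os_descriptor_id": m, "n_docs": n}
        for (p, m), n in sorted(pair_docs.items())
    ]
    return pd.DataFrame(rows, columns=["protein_id", "os_descriptor_id", "n_docs"])


def count_os_cvd_proteins(cooccurrence: pd.DataFrame, scores: ScoreMatrix) -> int:
    """Proteins co-occurring with ≥1 OS molecule that also score in ≥1 CVD category."""
    if cooccurrence.empty:
        return 0
    scoring = set(scores.scoring_proteins())
    return len(set(cooccurrence["protein_id"]) & scoring)


def os_molecule_score(
    cooccurrence: pd.DataFrame,
    scores: ScoreMatrix,
    molecule: str,
    category: str,
) -> float | None:
    """Mean CaseOLAP score, in one category, of the proteins co-occurring with
    an OS molecule; ``None`` (no row) when nothing co-occurs with it."""
    partners = cooccurrence.loc[
        cooccurrence["os_descriptor_id"] == molecule, "protein_id"
    ].unique()
    partners = [p for p in partners if p in scores.score.index]
    if not partners:
        return None
    return float(scores.score.loc[partners, category].mean())


def os_molecule_scores(
    cooccurrence: pd.DataFrame,
    scores: ScoreMatrix,
    categories: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Eq.-style association table for every supported OS molecule × category."""
    categories = list(categories) if categories is not None else scores.categories
    rows = []
    for m in sorted(cooccurrence["os_descriptor_id"].unique()) if not cooccurrence.empty else []:
        support = int(
            cooccurrence.loc[cooccurrence["os_descriptor_id"] == m, "n_docs"].sum()
        )
        for c in categories:
            s = os_molecule_score(cooccurrence, scores, m, c)
            if s is not None:
                rows.append(
                    {"entity_id": m, "category": c, "score": s, "n_support_docs": support}
                )
    return pd.DataFrame(rows, columns=["entity_id", "category", "score", "n_support_docs"])


def pathway_score(
    kg: KnowledgeGraph,
    scores: ScoreMatrix,
    pathway: PathwayRecord,
    category: str,
) -> float | None:
    """Mean of member-protein CaseOLAP scores damped by (1 − p-value).

    Reverse mapping: the mean runs over the pathway's member proteins that are
    inside the curated entity set (i.e. have a row in the score matrix).
    ``None`` when no member is in the entity set.
    """
    members = [p for p in pathway.member_protein_ids if p in scores.score.index]
    if not members:
        return None
    return float(
        (scores.score.loc[members, category] * (1.0 - pathway.p_value)).mean()
    )


def pathway_scores(
    kg: KnowledgeGraph,
    scores: ScoreMatrix,
    pathways: Mapping[str, PathwayRecord],
    categories: Iterable[str] | None = None,
) -> pd.DataFrame:
    categories = list(categories) if categories is not None else scores.categories
    rows = []
    for pw_id in sorted(pathways):
        rec = pathways[pw_id]
        members = [p for p in rec.member_protein_ids if p in scores.score.index]
        if not members:
            continue
        for c in categories:
            s = pathway_score(kg, scores, rec, c)
            rows.append(
                {"entity_id": pw_id, "category": c, "score": s, "n_support_docs": len(members)}
            )
    return pd.DataFrame(rows, columns=["entity_id", "category", "score", "n_support_docs"])


def overlap_tables(
    cube: TextCube,
    mention_index: Mapping[str, Mapping[str, int]],
    scores: ScoreMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OS-phase × CVD-category overlap matrices at document and protein level.

    The document matrix counts documents in both the category cell and the
    phase flag; the protein matrix counts proteins with a positive score in
    the category that are mentioned by at least one such shared document.
    """
    categories = list(cube.cells)
    doc_m = pd.DataFrame(0, index=list(OS_PHASES), columns=categories, dtype=int)
    prot_m = pd.DataFrame(0, index=list(OS_PHASES), columns=categories, dtype=int)
    for phase in OS_PHASES:
        phase_docs = cube.os_docs.get(phase, set())
        for cat in categories:
            shared = cube.cells[cat] & phase_docs
            doc_m.loc[phase, cat] = len(shared)
            prots = set()
            for d in shared:
                prots |= set(mention_index.get(d, {}))
            prots = {
                p
                for p in prots
                if p in scores.score.index and scores.score.loc[p, cat] > 0
            }
            prot_m.loc[phase, cat] = len(prots)
    return doc_m, prot_m


def sunburst_export(
    scored_items: pd.DataFrame,
    hierarchy: Mapping[str, str | None],
    categories_of_interest: Iterable[str],
    *,
    root_name: str = "root",
) -> dict:
    """Aggregate an association table into sunburst-ready hierarchical JSON.

    ``scored_items`` has columns entity_id/category/score; each entity is a
    leaf whose value is its summed score over ``categories_of_interest``.
    ``hierarchy`` maps node → parent (``None`` for top level); every internal
    node's value is the sum of its children, so the root value equals the sum
    over all leaves.  Returns a dict ``{name, value, children}``.
    """
    cats = set(categories_of_interest)
    sub = scored_items[scored_items["category"].isin(cats)]
    leaf_values = sub.groupby("entity_id")["score"].sum().to_dict()
    for leaf in leaf_values:
        if leaf not in hierarchy:
            raise KeyError(f"scored item {leaf!r} not present in the hierarchy")

    children: dict[str | None, list[str]] = {}
    for node, parent in hierarchy.items():
        children.setdefault(parent, []).append(node)

    def build(node: str) -> dict:
        kids = [build(k) for k in sorted(children.get(node, []))]
        if kids:
            value = sum(k["value"] for k in kids)
            return {"name": node, "value": value, "children": kids}
        return {"name": node, "value": leaf_values.get(node, 0.0), "children": []}

    top = [build(n) for n in sorted(children.get(None, []))]
    return {"name": root_name, "value": sum(t["value"] for t in top), "children": top}


def write_sunburst(tree: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree, fh, indent=2)
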