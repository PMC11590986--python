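"""End-to-end convenience driver: corpus → cube → mentions → scores → graph."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .caseolap import ScoreMatrix, compute_score_matrix
from .corpus_cube import DocumentRecord, TextCube, build_text_cube
from .kg import KnowledgeGraph, build_knowledge_graph
from .mentions import MentionCountMatrix, aggregate_counts, build_mention_index, compile_matcher
from .vocab import (
    CategoryDefinition,
    MeshDescriptor,
    OsDescriptor,
    PathwayRecord,
    ProteinEntity,
    expand_categories,
)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    cube: TextCube
    mention_index: dict[str, dict[str, int]]
    counts: MentionCountMatrix
    scores: ScoreMatrix
    doc_mesh: dict[str, tuple[str, ...]]
    kg: KnowledgeGraph | None = None


def run_pipeline(
    corpus: Iterable[DocumentRecord],
    categories: Iterable[CategoryDefinition],
    mesh_vocab: Mapping[str, MeshDescriptor],
    os_vocab: Mapping[str, OsDescriptor],
    proteins: Mapping[str, ProteinEntity],
    pathways: Mapping[str, PathwayRecord] | None = None,
    *,
    build_graph: bool = False,
    binary_counts: bool = False,
) -> PipelineResult:
    """Run text-cube construction, mention counting, CaseOLAP scoring, and
    (optionally) knowledge-graph assembly over an in-memory corpus."""
    corpus = list(corpus)
    expanded = expand_categories(categories, mesh_vocab)
    cube = build_text_cube(corpus, expanded, os_vocab)
    matcher = compile_matcher(proteins)
    mention_index = build_mention_index(corpus, matcher)
    counts = aggregate_counts(cube, mention_index, proteins, binary=binary_counts)
    scores = compute_score_matrix(counts)
    doc_mesh = {d.doc_id: d.mesh_ids for d in corpus}
    kg = None
    if build_graph:
        kg = build_knowledge_graph(
            cube, mention_index, proteins, mesh_vocab, os_vocab, pathways, doc_mesh
        )
    return PipelineResult(
        cube=cube, mention_index=mention_index, counts=counts,
        scores=scores, doc_mesh=doc_mesh, kg=kg,
    )
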