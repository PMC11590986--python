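"""Shared fixtures: a hand-enumerable four-document micro-corpus."""

from dataclasses import dataclass

import pytest

from cardiomine.corpus_cube import DocumentRecord, build_text_cube
from cardiomine.mentions import aggregate_counts, build_mention_index, compile_matcher
from cardiomine.vocab import (
    CategoryDefinition,
    MeshDescriptor,
    OsDescriptor,
    ProteinEntity,
    expand_categories,
)


@dataclass
class MicroFixture:
    """Two categories (ARR, CM), two proteins, four documents.

    d1, d2 carry the ARR descriptor; d3, d4 the CM descriptor; d2 also
    carries an OS descriptor of the MOS phase.  Mentions realized in text:
    d1 mentions P1 twice; d2 mentions P1 once and P2 once; d3 mentions P2
    twice; d4 mentions nothing.  Hence tf(P1, ARR) = 3, tf(P2, ARR) = 1,
    tf(P2, CM) = 2, and the category totals are 4 (ARR) and 2 (CM).
    """

    mesh: dict
    categories: tuple
    os_vocab: dict
    proteins: dict
    docs: list
    expanded: dict
    cube: object
    index: dict
    counts: object


@pytest.fixture
def micro() -> MicroFixture:
    mesh = {
        "D000001": MeshDescriptor("D000001", "Arrhythmias, Cardiac", ("C14.280.067",)),
        "D000002": MeshDescriptor("D000002", "Cardiomyopathies", ("C14.280.238",)),
    }
    categories = (
        CategoryDefinition("ARR", "Arrhythmias, cardiac", ("C14.280.067",)),
        CategoryDefinition("CM", "Cardiomyopathies and heart failure", ("C14.280.238",)),
    )
    os_vocab = {
        "D000010": OsDescriptor("D000010", "Glutathione", "MOS", "antioxidants")
    }
    proteins = {
        "P1": ProteinEntity("P1", "ProtOne", ("alpha regulator",)),
        "P2": ProteinEntity("P2", "ProtTwo", ()),
    }
    docs = [
        DocumentRecord("d1", "t", "ProtOne binds ProtOne", ("D000001",)),
        DocumentRecord("d2", "t", "alpha regulator inhibits ProtTwo", ("D000001", "D000010")),
        DocumentRecord("d3", "t", "ProtTwo and ProtTwo", ("D000002",)),
        DocumentRecord("d4", "t", "nothing relevant here", ("D000002",)),
    ]
    expanded = expand_categories(categories, mesh)
    cube = build_text_cube(docs, expanded, os_vocab)
    matcher = compile_matcher(proteins)
    index = build_mention_index(docs, matcher)
    counts = aggregate_counts(cube, index, proteins)
    return MicroFixture(
        mesh=mesh, categories=categories, os_vocab=os_vocab, proteins=proteins,
        docs=docs, expanded=expanded, cube=cube, index=index, counts=counts,
    )
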