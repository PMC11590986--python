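"""Document corpus I/O and text-cube construction.

A *text cube* partitions a document corpus into (possibly overlapping)
category cells using document metadata — here, the MeSH descriptors assigned
to each abstract.  Documents are assigned to a CVD category when they carry at
least one descriptor from that category's expansion (root or descendant);
an OS sub-cube flags, per OS phase, the documents that additionally carry an
oxidative-stress descriptor of that phase.  Documents with no CVD category
fall outside the cube universe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .vocab import OsDescriptor, OS_PHASES

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Raised for malformed corpus files."""


@dataclass(frozen=True)
class DocumentRecord:
    """One abstract: PMID-like ID, title, abstract text, assigned MeSH IDs."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    mesh_ids: tuple[str, ...] = ()

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract


@dataclass
class TextCube:
    """Category → document-set map with an OS-phase sub-cube.

    ``cells`` may overlap (multi-membership); ``universe`` is the set of all
    documents in at least one CVD cell; ``n_excluded`` counts corpus documents
    that matched no CVD category and were left out.
    """

    cells: dict[str, set[str]]
    os_docs: dict[str, set[str]]
    universe: set[str]
    n_excluded: int = 0

    def os_any(self) -> set[str]:
        """Documents flagged for at least one OS phase."""
        out: set[str] = set()
        for docs in self.os_docs.values():
            out |= docs
        return out


def read_corpus(path: str | PathLike) -> Iterator[DocumentRecord]:
    """Stream DocumentRecords from a JSON Lines file, in file order.

    Duplicate doc_ids keep the first occurrence (warning logged).  A line that
    is not valid JSON or lacks ``doc_id`` raises CorpusError naming the line.
    """
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: unparseable JSON ({exc})") from exc
            if "doc_id" not in rec or not str(rec["doc_id"]):
                raise CorpusError(f"line {lineno}: missing doc_id")
            doc_id = str(rec["doc_id"])
            if doc_id in seen:
                logger.warning("duplicate doc_id %s at line %d; keeping first", doc_id, lineno)
                continue
            seen.add(doc_id)
            yield DocumentRecord(
                doc_id=doc_id,
                title=str(rec.get("title", "")),
                abstract=str(rec.get("abstract", "")),
                mesh_ids=tuple(dict.fromkeys(str(m) for m in rec.get("mesh_ids", []))),
            )


def write_corpus(docs: Iterable[DocumentRecord], path: str | PathLike) -> None:
    """Write documents as JSON Lines (inverse of read_corpus)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "title": d.title,
                        "abstract": d.abstract,
                        "mesh_ids": list(d.mesh_ids),
                    }
                )
                + "\n"
            )


def assign_to_categories(
    doc: DocumentRecord, expanded: Mapping[str, set[str]]
) -> set[str]:
    """Categories whose expansion intersects the document's MeSH IDs."""
    mesh = set(doc.mesh_ids)
    return {cat for cat, ids in expanded.items() if mesh & ids}


def build_text_cube(
    corpus: Iterable[DocumentRecord],
    expanded: Mapping[str, set[str]],
    os_vocab: Mapping[str, OsDescriptor] | None = None,
) -> TextCube:
    """Assign each document to CVD cells and OS phase flags.

    ``expanded`` maps category abbreviation → descriptor-ID expansion
    (from :func:`cardiomine.vocab.expand_categories`).  Only documents in at
    least one CVD cell enter the universe; OS flags are recorded for those.
    """
    os_vocab = os_vocab or {}
    phase_of = {d.descriptor_id: d.phase for d in os_vocab.values()}
    cells: dict[str, set[str]] = {cat: set() for cat in expanded}
    os_docs: dict[str, set[str]] = {p: set() for p in OS_PHASES}
    universe: set[str] = set()
    n_excluded = 0
    for doc in corpus:
        cats = assign_to_categories(doc, expanded)
        if not cats:
            n_excluded += 1
            continue
        universe.add(doc.doc_id)
        for cat in cats:
            cells[cat].add(doc.doc_id)
        for m in doc.mesh_ids:
            phase = phase_of.get(m)
            if phase is not None:
                os_docs[phase].add(doc.doc_id)
    return TextCube(cells=cells, os_docs=os_docs, universe=universe, n_excluded=n_excluded)


def cube_statistics(cube: TextCube) -> pd.DataFrame:
    """Per-category document counts: total and OS-flagged, plus a TOTAL row.

    Mirrors a per-category publication-statistics table; the TOTAL row counts
    unique documents (a document in several categories counts once).
    """
    os_any = cube.os_any()
    rows = []
    for cat, docs in cube.cells.items():
        rows.append({"category": cat, "n_docs": len(docs), "n_os_docs": len(docs & os_any)})
    rows.append(
        {
            "category": "TOTAL",
            "n_docs": len(cube.universe),
            "n_os_docs": len(cube.universe & os_any),
        }
    )
    return pd.DataFrame(rows, columns=["category", "n_docs", "n_os_docs"])
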