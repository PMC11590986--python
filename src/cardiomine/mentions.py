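"""Dictionary-based protein mention detection and per-category aggregation.

Matching is case-insensitive and anchored at word boundaries, where a
boundary is a transition between ``[A-Za-z0-9]`` and anything else (or the
string edge).  Protein symbols such as "RyR2" end in digits, so the usual
``\\b`` word boundary is exactly this alphanumeric transition; hyphens inside
a synonym must appear literally in the text.  When surface forms overlap at a
position ("troponin" vs "troponin I"), the longest match wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .corpus_cube import DocumentRecord, TextCube
from .vocab import ProteinEntity


@dataclass(frozen=True)
class Matcher:
    """Compiled surface-form matcher over a curated protein lexicon."""

    pattern: re.Pattern
    lexicon: dict[str, str]  # lowercased surface form -> protein_id

    def find(self, text: str) -> list[tuple[int, int, str]]:
        """Non-overlapping matches as (start, end, protein_id), left to right."""
        return [
            (m.start(), m.end(), self.lexicon[m.group(0).lower()])
            for m in self.pattern.finditer(text)
        ]


def compile_matcher(entities: Mapping[str, ProteinEntity] | Iterable[ProteinEntity]) -> Matcher:
    """Compile a matcher recognizing every primary name and synonym.

    Alternatives are ordered longest-first so the regex engine realizes
    longest-match-wins at each position.
    """
    if isinstance(entities, Mapping):
        entities = entities.values()
    lexicon: dict[str, str] = {}
    for ent in entities:
        for form in ent.surface_forms:
            lexicon[form.lower()] = ent.protein_id
    if not lexicon:
        raise ValueError("cannot compile a matcher from an empty entity set")
    forms = sorted(lexicon, key=len, reverse=True)
    body = "|".join(re.escape(f) for f in forms)
    pattern = re.compile(
        rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", re.IGNORECASE
    )
    return Matcher(pattern=pattern, lexicon=lexicon)


def count_mentions(doc: DocumentRecord, matcher: Matcher) -> dict[str, int]:
    """Occurrence count per protein in title + " " + abstract.

    Synonym and primary-name hits sum into one protein_id; proteins with zero
    occurrences are absent from the result.
    """
    counts: dict[str, int] = {}
    for _, _, pid in matcher.find(doc.text):
        counts[pid] = counts.get(pid, 0) + 1
    return counts


def build_mention_index(
    corpus: Iterable[DocumentRecord], matcher: Matcher
) -> dict[str, dict[str, int]]:
    """Per-document mention counts for a whole corpus (docs with hits only)."""
    index: dict[str, dict[str, int]] = {}
    for doc in corpus:
        counts = count_mentions(doc, matcher)
        if counts:
            index[doc.doc_id] = counts
    return index


@dataclass
class MentionCountMatrix:
    """tf(protein, category) table plus per-category totals.

    ``tf.loc[p, C]`` is the summed occurrence count of protein ``p`` over the
    documents of cell ``C``; a document in two cells contributes to both.
    """

    tf: pd.DataFrame  # proteins x categories, int
    category_totals: pd.Series  # per-category sum over proteins

    @property
    def proteins(self) -> list[str]:
        return list(self.tf.index)

    @property
    def categories(self) -> list[str]:
        return list(self.tf.columns)


def aggregate_counts(
    cube: TextCube,
    index: Mapping[str, Mapping[str, int]],
    proteins: Iterable[str],
    *,
    binary: bool = False,
) -> MentionCountMatrix:
    """Aggregate per-document counts into tf(protein, category).

    With ``binary=True`` each document contributes at most 1 per protein
    (document-hit counting) instead of its occurrence count.  Documents in the
    cube but absent from the index count as zero mentions.
    """
    proteins = sorted(proteins)
    categories = list(cube.cells)
    tf = pd.DataFrame(0, index=proteins, columns=categories, dtype=int)
    for cat, docs in cube.cells.items():
        for d in docs:
            for pid, n in index.get(d, {}).items():
                tf.loc[pid, cat] += 1 if binary else n
    return MentionCountMatrix(tf=tf, category_totals=tf.sum(axis=0))


def export_mentions(index: Mapping[str, Mapping[str, int]], path) -> None:
    """Write one CSV row per (doc, protein) mention edge."""
    rows = [
        {"doc_id": d, "protein_id": p, "count": n}
        for d, counts in index.items()
        for p, n in counts.items()
    ]
    pd.DataFrame(rows, columns=["doc_id", "protein_id", "count"]).to_csv(path, index=False)
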