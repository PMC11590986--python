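"""Controlled vocabularies: MeSH descriptors, CVD categories, OS descriptors,
protein entities, and pathway records.

MeSH (Medical Subject Headings) descriptors carry one or more dot-delimited
*tree numbers* encoding their position in the NLM hierarchy; a descriptor is a
descendant of a root exactly when one of its tree numbers extends the root's
tree number at a dot boundary.  The eight cardiovascular-disease (CVD)
categories used throughout the pipeline are defined by their root tree numbers
under the heart-disease subtree (C14.280); oxidative-stress (OS) descriptors
are grouped into three phases — initiation (IOS), modulation (MOS), and
outcome (OOS).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")

#: Valid oxidative-stress phases: initiation, modulation, outcome.
OS_PHASES = ("IOS", "MOS", "OOS")


class VocabularyError(ValueError):
    """Raised when a vocabulary table violates its contract."""


@dataclass(frozen=True)
class MeshDescriptor:
    """A MeSH descriptor with its unique ID, display name, and tree numbers."""

    descriptor_id: str
    name: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.descriptor_id:
            raise VocabularyError("descriptor_id must be non-empty")
        if not self.tree_numbers:
            raise VocabularyError(
                f"descriptor {self.descriptor_id!r} has no tree numbers"
            )
        for t in self.tree_numbers:
            if not TREE_NUMBER_RE.match(t):
                raise VocabularyError(
                    f"descriptor {self.descriptor_id!r}: malformed tree number {t!r}"
                )


@dataclass(frozen=True)
class CategoryDefinition:
    """A disease category defined by one or more MeSH root tree numbers."""

    abbreviation: str
    name: str
    root_tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.root_tree_numbers:
            raise VocabularyError(
                f"category {self.abbreviation!r} has no root tree numbers"
            )


@dataclass(frozen=True)
class OsDescriptor:
    """An oxidative-stress MeSH descriptor with its phase and subcategory."""

    descriptor_id: str
    name: str
    phase: str
    subcategory: str

    def __post_init__(self) -> None:
        if self.phase not in OS_PHASES:
            raise VocabularyError(
                f"descriptor {self.descriptor_id!r}: unknown OS phase "
                f"{self.phase!r} (expected one of {OS_PHASES})"
            )


@dataclass(frozen=True)
class ProteinEntity:
    """A curated protein with a UniProt-style accession and its surface forms."""

    protein_id: str
    primary_name: str
    synonyms: tuple[str, ...] = ()

    @property
    def surface_forms(self) -> tuple[str, ...]:
        """All names this entity may appear under in text."""
        return (self.primary_name, *self.synonyms)


@dataclass(frozen=True)
class PathwayRecord:
    """A pathway with member proteins, optional parent, and enrichment p-value."""

    pathway_id: str
    name: str
    parent_id: str | None
    member_protein_ids: tuple[str, ...]
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise VocabularyError(
                f"pathway {self.pathway_id!r}: p_value {self.p_value} outside [0, 1]"
            )


# Table 1 category roots under the heart-diseases MeSH subtree.
DEFAULT_CVD_CATEGORIES: tuple[CategoryDefinition, ...] = (
    CategoryDefinition(
        "CM", "Cardiomyopathies and heart failure", ("C14.280.238", "C14.280.434")
    ),
    CategoryDefinition("ARR", "Arrhythmias, cardiac", ("C14.280.067",)),
    CategoryDefinition("CHD", "Heart defects, congenital", ("C14.280.400",)),
    CategoryDefinition("VD", "Heart valve diseases", ("C14.280.484",)),
    CategoryDefinition("IHD", "Myocardial ischemia", ("C14.280.647",)),
    CategoryDefinition("CCS", "Cardiac conduction system disease", ("C14.280.123",)),
    CategoryDefinition("VOO", "Ventricular outflow obstruction", ("C14.280.955",)),
    CategoryDefinition(
        "OHD",
        "Other heart diseases",
        (
            "C14.280.195",
            "C14.280.282",
            "C14.280.383",
            "C14.280.470",
            "C14.280.945",
            "C14.280.459",
            "C14.280.720",
        ),
    ),
)

CATEGORY_ORDER: tuple[str, ...] = tuple(c.abbreviation for c in DEFAULT_CVD_CATEGORIES)


def _as_frame(source, required: Sequence[str], sep: str = ",") -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VocabularyError(f"missing required columns: {missing}")
    return df


def load_mesh_vocabulary(source: str | PathLike | pd.DataFrame) -> dict[str, MeshDescriptor]:
    """Load a MeSH descriptor table into a vocabulary keyed by descriptor ID.

    The table needs columns ``descriptor_id``, ``name``, ``tree_numbers``
    (pipe-delimited).  Multiple rows with the same ID merge their tree numbers;
    rows with the same ID but conflicting names are rejected.
    """
    df = _as_frame(source, ("descriptor_id", "name", "tree_numbers"))
    vocab: dict[str, MeshDescriptor] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        did, name = row.descriptor_id.strip(), row.name.strip()
        trees = [t.strip() for t in row.tree_numbers.split("|") if t.strip()]
        for t in trees:
            if not TREE_NUMBER_RE.match(t):
                raise VocabularyError(f"row {i}: malformed tree number {t!r}")
        if did in vocab:
            prev = vocab[did]
            if prev.name != name:
                raise VocabularyError(
                    f"row {i}: descriptor {did!r} redefined with conflicting name "
                    f"{name!r} (was {prev.name!r})"
                )
            merged = tuple(dict.fromkeys((*prev.tree_numbers, *trees)))
            vocab[did] = MeshDescriptor(did, name, merged)
        else:
            vocab[did] = MeshDescriptor(did, name, tuple(dict.fromkeys(trees)))
    return vocab


def is_descendant_tree(tree: str, root: str) -> bool:
    """Dot-boundary prefix test: ``tree`` equals ``root`` or extends it below a dot."""
    return tree == root or tree.startswith(root + ".")


def expand_category(
    category: CategoryDefinition, vocab: Mapping[str, MeshDescriptor]
) -> set[str]:
    """Descriptor IDs of the category's roots and all their descendants.

    A descriptor belongs to the expansion when any of its tree numbers matches
    any root at a dot boundary; the result is the union over roots.
    """
    if not category.root_tree_numbers:
        raise VocabularyError(f"category {category.abbreviation!r} has no roots")
    return {
        d.descriptor_id
        for d in vocab.values()
        if any(
            is_descendant_tree(t, r)
            for t in d.tree_numbers
            for r in category.root_tree_numbers
        )
    }


def expand_categories(
    categories: Iterable[CategoryDefinition], vocab: Mapping[str, MeshDescriptor]
) -> dict[str, set[str]]:
    """Expansion of every category, keyed by abbreviation."""
    return {c.abbreviation: expand_category(c, vocab) for c in categories}


def load_os_vocabulary(source: str | PathLike | pd.DataFrame) -> dict[str, OsDescriptor]:
    """Load OS descriptors, validating phases and deduplicating by ID.

    A descriptor listed under two subcategories is kept once with its
    first-seen phase/subcategory; the duplicate is logged as a warning.
    """
    df = _as_frame(source, ("descriptor_id", "name", "phase", "subcategory"))
    vocab: dict[str, OsDescriptor] = {}
    for row in df.itertuples(index=False):
        d = OsDescriptor(
            row.descriptor_id.strip(), row.name.strip(), row.phase.strip(),
            row.subcategory.strip(),
        )
        if d.descriptor_id in vocab:
            logger.warning(
                "OS descriptor %s (%s) listed again under subcategory %r; "
                "keeping first-seen entry",
                d.descriptor_id, d.name, d.subcategory,
            )
        else:
            vocab[d.descriptor_id] = d
    return vocab


def os_phase_counts(vocab: Mapping[str, OsDescriptor]) -> dict[str, int]:
    """Number of unique descriptors per OS phase."""
    counts = {p: 0 for p in OS_PHASES}
    for d in vocab.values():
        counts[d.phase] += 1
    return counts


def load_protein_entities(source: str | PathLike | pd.DataFrame) -> dict[str, ProteinEntity]:
    """Load the curated protein list, building a collision-free match lexicon.

    Surface forms (primary name plus pipe-delimited synonyms) are compared
    case-insensitively across entities; the same form claimed by two proteins
    is an ambiguity error.
    """
    df = _as_frame(source, ("protein_id", "primary_name", "synonyms"))
    entities: dict[str, ProteinEntity] = {}
    claimed: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id.strip()
        if pid in entities:
            raise VocabularyError(f"duplicate protein_id {pid!r}")
        syns = tuple(
            dict.fromkeys(s.strip() for s in row.synonyms.split("|") if s.strip())
        )
        ent = ProteinEntity(pid, row.primary_name.strip(), syns)
        for form in ent.surface_forms:
            key = form.lower()
            if key in claimed and claimed[key] != pid:
                raise VocabularyError(
                    f"surface form {form!r} claimed by both {claimed[key]!r} and {pid!r}"
                )
            claimed[key] = pid
        entities[pid] = ent
    return entities


def build_lexicon(entities: Mapping[str, ProteinEntity]) -> dict[str, str]:
    """Map every lowercased surface form to its protein_id."""
    lex: dict[str, str] = {}
    for ent in entities.values():
        for form in ent.surface_forms:
            lex[form.lower()] = ent.protein_id
    return lex


def load_pathways(source: str | PathLike | pd.DataFrame) -> dict[str, PathwayRecord]:
    """Load a Reactome-style pathway table (TSV) with per-pathway p-values."""
    df = _as_frame(
        source,
        ("pathway_id", "name", "parent_id", "member_protein_ids", "p_value"),
        sep="\t",
    )
    records: dict[str, PathwayRecord] = {}
    for row in df.itertuples(index=False):
        pid = row.pathway_id.strip()
        if pid in records:
            raise VocabularyError(f"duplicate pathway_id {pid!r}")
        members = tuple(
            dict.fromkeys(m.strip() for m in row.member_protein_ids.split("|") if m.strip())
        )
        parent = row.parent_id.strip() or None
        records[pid] = PathwayRecord(pid, row.name.strip(), parent, members, float(row.p_value))
    _check_parent_acyclic(records)
    return records


def _check_parent_acyclic(records: Mapping[str, PathwayRecord]) -> None:
    for start in records:
        seen = set()
        node: str | None = start
        while node is not None:
            if node in seen:
                raise VocabularyError(f"pathway parent cycle through {node!r}")
            seen.add(node)
            rec = records.get(node)
            node = rec.parent_id if rec else None


def save_mesh_vocabulary(vocab: Mapping[str, MeshDescriptor], path) -> None:
    pd.DataFrame(
        {
            "descriptor_id": [d.descriptor_id for d in vocab.values()],
            "name": [d.name for d in vocab.values()],
            "tree_numbers": ["|".join(d.tree_numbers) for d in vocab.values()],
        }
    ).to_csv(path, index=False)


def save_os_vocabulary(vocab: Mapping[str, OsDescriptor], path) -> None:
    pd.DataFrame(
        {
            "descriptor_id": [d.descriptor_id for d in vocab.values()],
            "name": [d.name for d in vocab.values()],
            "phase": [d.phase for d in vocab.values()],
            "subcategory": [d.subcategory for d in vocab.values()],
        }
    ).to_csv(path, index=False)


def save_protein_entities(entities: Mapping[str, ProteinEntity], path) -> None:
    pd.DataFrame(
        {
            "protein_id": [e.protein_id for e in entities.values()],
            "primary_name": [e.primary_name for e in entities.values()],
            "synonyms": ["|".join(e.synonyms) for e in entities.values()],
        }
    ).to_csv(path, index=False)
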