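"""Packaged reference vocabularies.

The bundled CSVs are *synthetic stand-ins* (``*_synthetic.csv``) that
reproduce the recoverable structure of the curated study vocabularies: 176
unique CVD MeSH descriptors under the exact eight-category root tree numbers,
75 unique oxidative-stress descriptors (77 subcategory rows; two descriptors
sit in two subcategories) split 12 IOS / 59 MOS / 6 OOS, and 128
Ca²⁺-regulating protein entries with UniProt-style accessions.  Well-known
real descriptors and proteins (e.g. hydrogen peroxide, glutathione, RyR2,
cardiac troponin I, SERCA2) anchor the lists; the remainder are plausible
synthetic entries, since the full curated tables are not redistributable
here.
"""

from __future__ import annotations

from importlib import resources

from .vocab import (
    MeshDescriptor,
    OsDescriptor,
    ProteinEntity,
    load_mesh_vocabulary,
    load_os_vocabulary,
    load_protein_entities,
)


def _data_path(name: str):
    return resources.files("cardiomine.data").joinpath(name)


def load_cvd_mesh_fixture() -> dict[str, MeshDescriptor]:
    """176 CVD MeSH descriptors under the eight Table-style category roots."""
    with resources.as_file(_data_path("cvd_mesh_synthetic.csv")) as p:
        return load_mesh_vocabulary(p)


def load_os_fixture() -> dict[str, OsDescriptor]:
    """75 unique OS descriptors across the IOS/MOS/OOS phase subcategories."""
    with resources.as_file(_data_path("os_vocab_synthetic.csv")) as p:
        return load_os_vocabulary(p)


def load_protein_fixture() -> dict[str, ProteinEntity]:
    """128 Ca²⁺-regulating protein entities with synonym lexicon."""
    with resources.as_file(_data_path("proteins_synthetic.csv")) as p:
        return load_protein_entities(p)
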