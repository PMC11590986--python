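"""Vocabulary loading, category expansion, and round-trips."""

import numpy as np
import pandas as pd
import pytest

from cardiomine import datasets
from cardiomine.vocab import (
    CategoryDefinition,
    DEFAULT_CVD_CATEGORIES,
    MeshDescriptor,
    VocabularyError,
    expand_categories,
    expand_category,
    is_descendant_tree,
    load_mesh_vocabulary,
    load_os_vocabulary,
    load_pathways,
    load_protein_entities,
    os_phase_counts,
    save_mesh_vocabulary,
)


def mesh_df(rows):
    return pd.DataFrame(rows, columns=["descriptor_id", "name", "tree_numbers"])


class TestMeshLoading:
    def test_direct_load(self):
        vocab = load_mesh_vocabulary(
            mesh_df([("D_A", "a", "C14.280.067"), ("D_B", "b", "C14.280.067.198")])
        )
        assert len(vocab) == 2

    def test_empty_table(self):
        assert load_mesh_vocabulary(mesh_df([])) == {}

    def test_same_id_merges_tree_numbers(self):
        vocab = load_mesh_vocabulary(
            mesh_df([("D_A", "a", "C14.280.067"), ("D_A", "a", "C23.550.073")])
        )
        assert vocab["D_A"].tree_numbers == ("C14.280.067", "C23.550.073")

    def test_conflicting_names_rejected(self):
        with pytest.raises(VocabularyError, match="conflicting name"):
            load_mesh_vocabulary(mesh_df([("D_A", "a", "C14.1"), ("D_A", "b", "C14.2")]))

    def test_malformed_tree_number_names_row(self):
        with pytest.raises(VocabularyError, match="row 1"):
            load_mesh_vocabulary(mesh_df([("D_A", "a", "C14.1"), ("D_B", "b", "bogus")]))

    def test_round_trip(self, tmp_path):
        vocab = load_mesh_vocabulary(
            mesh_df([("D_A", "a", "C14.280.067|C23.550"), ("D_B", "b", "C14.280.123")])
        )
        p = tmp_path / "mesh.csv"
        save_mesh_vocabulary(vocab, p)
        assert load_mesh_vocabulary(p) == vocab


class TestExpandCategory:
    def test_prefix_closure(self):
        vocab = load_mesh_vocabulary(
            mesh_df(
                [
                    ("D1", "root", "C14.280.067"),
                    ("D2", "child", "C14.280.067.198"),
                    ("D3", "cousin", "C14.280.123"),
                ]
            )
        )
        cat = CategoryDefinition("ARR", "arr", ("C14.280.067",))
        assert expand_category(cat, vocab) == {"D1", "D2"}

    def test_dot_boundary_rule(self):
        # "C14.280.06" is not an ancestor of "C14.280.067"
        vocab = load_mesh_vocabulary(mesh_df([("D1", "x", "C14.280.067")]))
        cat = CategoryDefinition("X", "x", ("C14.280.06",))
        assert expand_category(cat, vocab) == set()

    def test_multi_root_union_matches_brute_force(self):
        rng = np.random.default_rng(5)
        ohd = DEFAULT_CVD_CATEGORIES[-1]
        assert ohd.abbreviation == "OHD" and len(ohd.root_tree_numbers) == 7
        trees = [
            f"C14.280.{rng.integers(100, 999)}" for _ in range(10)
        ] + [f"{r}.{rng.integers(100, 999)}" for r in ohd.root_tree_numbers[:5]] + [
            r for r in ohd.root_tree_numbers[:5]
        ]
        vocab = load_mesh_vocabulary(
            mesh_df([(f"D{i}", f"n{i}", t) for i, t in enumerate(trees)])
        )
        brute = {
            d.descriptor_id
            for d in vocab.values()
            for t in d.tree_numbers
            for r in ohd.root_tree_numbers
            if t == r or t.startswith(r + ".")
        }
        assert expand_category(ohd, vocab) == brute

    def test_idempotent_and_monotone(self):
        rows = [("D1", "a", "C14.280.067"), ("D2", "b", "C14.280.067.100")]
        vocab = load_mesh_vocabulary(mesh_df(rows))
        cat = CategoryDefinition("ARR", "arr", ("C14.280.067",))
        first = expand_category(cat, vocab)
        assert expand_category(cat, vocab) == first
        bigger = load_mesh_vocabulary(mesh_df(rows + [("D3", "c", "C14.280.067.200")]))
        assert first <= expand_category(cat, bigger)

    def test_random_vocabularies_match_brute_force(self):
        rng = np.random.default_rng(42)
        roots = [r for c in DEFAULT_CVD_CATEGORIES for r in c.root_tree_numbers]
        for _ in range(100):
            n = int(rng.integers(1, 25))
            trees = []
            for _ in range(n):
                base = roots[rng.integers(len(roots))]
                depth = int(rng.integers(0, 3))
                t = base + "".join(f".{rng.integers(100, 999)}" for _ in range(depth))
                if rng.random() < 0.3:  # off-tree sibling
                    t = f"C14.{rng.integers(100, 999)}"
                trees.append(t)
            vocab = load_mesh_vocabulary(
                mesh_df([(f"D{i}", f"n{i}", t) for i, t in enumerate(trees)])
            )
            expanded = expand_categories(DEFAULT_CVD_CATEGORIES, vocab)
            union = set().union(*expanded.values())
            brute = {
                d.descriptor_id
                for d in vocab.values()
                if any(
                    is_descendant_tree(t, r)
                    for t in d.tree_numbers
                    for r in roots
                )
            }
            assert union == brute


class TestOsVocabulary:
    def test_phase_counts(self):
        df = pd.DataFrame(
            [
                ("D1", "a", "IOS", "ros"),
                ("D2", "b", "MOS", "antioxidants"),
                ("D3", "c", "OOS", "damage"),
            ],
            columns=["descriptor_id", "name", "phase", "subcategory"],
        )
        assert os_phase_counts(load_os_vocabulary(df)) == {"IOS": 1, "MOS": 1, "OOS": 1}

    def test_duplicate_id_deduplicated_first_seen(self, caplog):
        df = pd.DataFrame(
            [("D1", "a", "MOS", "metabolites"), ("D1", "a", "MOS", "antioxidants")],
            columns=["descriptor_id", "name", "phase", "subcategory"],
        )
        with caplog.at_level("WARNING"):
            vocab = load_os_vocabulary(df)
        assert len(vocab) == 1
        assert vocab["D1"].subcategory == "metabolites"
        assert "listed again" in caplog.text

    def test_unknown_phase_rejected(self):
        df = pd.DataFrame(
            [("D1", "a", "XXX", "s")],
            columns=["descriptor_id", "name", "phase", "subcategory"],
        )
        with pytest.raises(VocabularyError, match="unknown OS phase"):
            load_os_vocabulary(df)


class TestProteinEntities:
    def test_lexicon_from_primary_and_synonyms(self):
        df = pd.DataFrame(
            [("P1", "RyR2", "ryanodine receptor 2")],
            columns=["protein_id", "primary_name", "synonyms"],
        )
        ents = load_protein_entities(df)
        assert len(ents) == 1
        assert ents["P1"].surface_forms == ("RyR2", "ryanodine receptor 2")

    def test_cross_entity_collision_rejected(self):
        df = pd.DataFrame(
            [("P1", "TnI", "troponin"), ("P2", "TnT", "troponin")],
            columns=["protein_id", "primary_name", "synonyms"],
        )
        with pytest.raises(VocabularyError, match="P1.*P2|troponin"):
            load_protein_entities(df)


class TestPathways:
    def test_load_and_parent_links(self, tmp_path):
        p = tmp_path / "pathways.tsv"
        p.write_text(
            "pathway_id\tname\tparent_id\tmember_protein_ids\tp_value\n"
            "R1\ttop\t\tP1|P2\t0.01\n"
            "R2\tchild\tR1\tP2\t0.2\n"
        )
        recs = load_pathways(p)
        assert recs["R2"].parent_id == "R1"
        assert recs["R1"].member_protein_ids == ("P1", "P2")

    def test_parent_cycle_rejected(self, tmp_path):
        p = tmp_path / "pathways.tsv"
        p.write_text(
            "pathway_id\tname\tparent_id\tmember_protein_ids\tp_value\n"
            "R1\ta\tR2\t\t0.5\nR2\tb\tR1\t\t0.5\n"
        )
        with pytest.raises(VocabularyError, match="cycle"):
            load_pathways(p)

    def test_p_value_outside_unit_interval_rejected(self, tmp_path):
        p = tmp_path / "pathways.tsv"
        p.write_text(
            "pathway_id\tname\tparent_id\tmember_protein_ids\tp_value\nR1\ta\t\tP1\t1.5\n"
        )
        with pytest.raises(VocabularyError, match="p_value"):
            load_pathways(p)


def test_default_categories_reproduce_published_roots():
    by_abbrev = {c.abbreviation: c for c in DEFAULT_CVD_CATEGORIES}
    assert list(by_abbrev) == ["CM", "ARR", "CHD", "VD", "IHD", "CCS", "VOO", "OHD"]
    assert by_abbrev["ARR"].root_tree_numbers == ("C14.280.067",)
    assert by_abbrev["CM"].root_tree_numbers == ("C14.280.238", "C14.280.434")
    assert len(by_abbrev["OHD"].root_tree_numbers) == 7


def test_packaged_fixture_loads_are_consistent():
    prot = datasets.load_protein_fixture()
    assert "Q92736" in prot  # ryanodine receptor 2 anchor
    counts = os_phase_counts(datasets.load_os_fixture())
    assert counts["IOS"] == 12 and counts["OOS"] == 6
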