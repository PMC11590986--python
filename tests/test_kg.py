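"""Knowledge-graph assembly, exports, co-occurrence queries, and scores."""

import numpy as np
import pandas as pd
import pytest

from cardiomine.caseolap import compute_score_matrix
from cardiomine.kg import (
    KnowledgeGraphError,
    build_knowledge_graph,
    count_os_cvd_proteins,
    export_graph,
    load_bulk_csv,
    load_graphml,
    os_molecule_score,
    os_molecule_scores,
    overlap_tables,
    pathway_score,
    protein_os_cooccurrence,
    sunburst_export,
)
from cardiomine.vocab import PathwayRecord


@pytest.fixture
def micro_kg(micro):
    doc_mesh = {d.doc_id: d.mesh_ids for d in micro.docs}
    return build_knowledge_graph(
        micro.cube, micro.index, micro.proteins, micro.mesh, micro.os_vocab,
        pathways=None, doc_mesh=doc_mesh,
    )


@pytest.fixture
def micro_scores(micro):
    return compute_score_matrix(micro.counts)


class TestBuild:
    def test_micro_fixture_node_and_edge_counts(self, micro_kg):
        assert micro_kg.node_counts() == {
            "document": 4, "protein": 2, "mesh": 3, "pathway": 0,
        }
        assert micro_kg.edge_counts() == {"mentions": 4, "assigns": 5, "contains": 0}

    def test_mentions_edges_equal_positive_count_pairs(self, micro, micro_kg):
        n_pairs = sum(len(v) for v in micro.index.values())
        assert micro_kg.edge_counts()["mentions"] == n_pairs

    def test_assigns_edges_drop_out_of_vocab_mesh(self, micro):
        doc_mesh = {d.doc_id: d.mesh_ids + ("D_UNKNOWN",) for d in micro.docs}
        kg = build_knowledge_graph(
            micro.cube, micro.index, micro.proteins, micro.mesh, micro.os_vocab,
            doc_mesh=doc_mesh,
        )
        assert kg.edge_counts()["assigns"] == 5

    def test_unknown_protein_mention_is_error(self, micro):
        bad_index = {"d1": {"P_UNKNOWN": 1}}
        with pytest.raises(KnowledgeGraphError):
            build_knowledge_graph(
                micro.cube, bad_index, micro.proteins, micro.mesh, micro.os_vocab,
                doc_mesh={},
            )

    def test_no_pathways_means_no_contains_edges(self, micro_kg):
        assert micro_kg.edge_counts()["contains"] == 0

    def test_pathway_membership_edges(self, micro):
        pw = {
            "R1": PathwayRecord("R1", "p", None, ("P1", "P2", "P_NOT_CURATED"), 0.1)
        }
        kg = build_knowledge_graph(
            micro.cube, micro.index, micro.proteins, micro.mesh, micro.os_vocab,
            pathways=pw, doc_mesh={},
        )
        assert kg.edge_counts()["contains"] == 2


class TestExport:
    def test_bulk_csv_round_trip(self, micro_kg, tmp_path):
        export_graph(micro_kg, tmp_path, format="bulk_csv")
        back = load_bulk_csv(tmp_path)
        assert back.node_counts() == micro_kg.node_counts()
        assert back.edge_counts() == micro_kg.edge_counts()
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in micro_kg.graph.edges
        }

    def test_bulk_csv_edge_rows(self, micro_kg, tmp_path):
        files = export_graph(micro_kg, tmp_path, format="bulk_csv")
        n_rows = 0
        for f in files:
            if f.name.startswith("edges_"):
                n_rows += sum(1 for _ in open(f)) - 1  # minus header
        assert n_rows == 9  # 4 mentions + 5 assigns

    def test_graphml_round_trip(self, micro_kg, tmp_path):
        export_graph(micro_kg, tmp_path, format="graphml")
        back = load_graphml(tmp_path / "kg.graphml")
        assert back.node_counts() == micro_kg.node_counts()
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in micro_kg.graph.edges
        }

    def test_empty_graph_exports_header_only(self, micro, tmp_path):
        from cardiomine.corpus_cube import TextCube

        empty = TextCube(cells={}, os_docs={}, universe=set())
        kg = build_knowledge_graph(empty, {}, {}, {}, {}, doc_mesh={})
        files = export_graph(kg, tmp_path, format="bulk_csv")
        for f in files:
            assert sum(1 for _ in open(f)) == 1


class TestCooccurrence:
    def test_micro_fixture_pairs(self, micro_kg):
        table = protein_os_cooccurrence(micro_kg)
        got = set(map(tuple, table.to_numpy()))
        # d2 mentions P1 and P2 and is assigned the MOS descriptor D000010
        assert got == {("P1", "D000010", 1), ("P2", "D000010", 1)}

    def test_protein_without_os_colocation_has_no_row(self, micro_kg):
        table = protein_os_cooccurrence(micro_kg)
        assert (table["n_docs"] >= 1).all()

    def test_count_os_cvd_proteins(self, micro_kg, micro_scores):
        table = protein_os_cooccurrence(micro_kg)
        assert count_os_cvd_proteins(table, micro_scores) == 2

    def test_count_zero_for_empty_inputs(self, micro_kg, micro_scores):
        empty = pd.DataFrame(columns=["protein_id", "os_descriptor_id", "n_docs"])
        assert count_os_cvd_proteins(empty, micro_scores) == 0
        zeroed = micro_scores
        zeroed.score.loc[:, :] = 0.0
        table = protein_os_cooccurrence(micro_kg)
        assert count_os_cvd_proteins(table, zeroed) == 0


class TestAssociationScores:
    def test_os_molecule_score_is_mean_over_partners(self, micro_kg, micro_scores):
        table = protein_os_cooccurrence(micro_kg)
        expected = micro_scores.score.loc[["P1", "P2"], "ARR"].mean()
        got = os_molecule_score(table, micro_scores, "D000010", "ARR")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_molecule_without_partners_emits_no_score(self, micro_scores):
        empty = pd.DataFrame(columns=["protein_id", "os_descriptor_id", "n_docs"])
        assert os_molecule_score(empty, micro_scores, "D000010", "ARR") is None
        assert os_molecule_scores(empty, micro_scores).empty

    def test_single_partner_mean_is_that_score(self, micro_scores):
        table = pd.DataFrame(
            [{"protein_id": "P1", "os_descriptor_id": "D000010", "n_docs": 2}]
        )
        got = os_molecule_score(table, micro_scores, "D000010", "ARR")
        assert got == pytest.approx(micro_scores.score.loc["P1", "ARR"], abs=1e-15)

    def test_pathway_score_limits(self, micro_kg, micro_scores):
        members = ("P1", "P2")
        mean_s = micro_scores.score.loc[list(members), "ARR"].mean()
        p0 = PathwayRecord("R1", "r", None, members, 0.0)
        p1 = PathwayRecord("R2", "r", None, members, 1.0)
        assert pathway_score(micro_kg, micro_scores, p0, "ARR") == pytest.approx(mean_s)
        assert pathway_score(micro_kg, micro_scores, p1, "ARR") == pytest.approx(0.0)

    def test_pathway_hand_value(self, micro_kg, micro_scores):
        # members scoring 0.4 and 0.2, p = 0.05 -> 0.3 * 0.95 = 0.285
        micro_scores.score.loc["P1", "ARR"] = 0.4
        micro_scores.score.loc["P2", "ARR"] = 0.2
        pw = PathwayRecord("R1", "r", None, ("P1", "P2"), 0.05)
        got = pathway_score(micro_kg, micro_scores, pw, "ARR")
        assert got == pytest.approx(0.285, abs=1e-12)

    def test_pathway_outside_entity_set_emits_no_score(self, micro_kg, micro_scores):
        pw = PathwayRecord("R1", "r", None, ("P_FOREIGN",), 0.1)
        assert pathway_score(micro_kg, micro_scores, pw, "ARR") is None


class TestOverlapTables:
    def test_micro_fixture_document_matrix(self, micro, micro_scores):
        doc_m, prot_m = overlap_tables(micro.cube, micro.index, micro_scores)
        assert doc_m.loc["MOS", "ARR"] == 1
        assert doc_m.loc["MOS", "CM"] == 0
        assert (doc_m.loc["IOS"] == 0).all()
        # d2 (the MOS doc in ARR) mentions P1 and P2, both scoring in ARR
        assert prot_m.loc["MOS", "ARR"] == 2

    def test_no_os_flags_gives_zero_matrices(self, micro, micro_scores):
        from cardiomine.corpus_cube import build_text_cube

        cube = build_text_cube(micro.docs, micro.expanded, {})
        doc_m, prot_m = overlap_tables(cube, micro.index, micro_scores)
        assert (doc_m.to_numpy() == 0).all() and (prot_m.to_numpy() == 0).all()

    def test_protein_matrix_bounded_by_scoring_count(self, micro, micro_scores):
        _, prot_m = overlap_tables(micro.cube, micro.index, micro_scores)
        assert (prot_m.to_numpy() <= micro_scores.n_scoring()).all()


class TestSunburst:
    def test_single_leaf_under_root(self):
        items = pd.DataFrame(
            [{"entity_id": "m1", "category": "ARR", "score": 0.4, "n_support_docs": 1}]
        )
        tree = sunburst_export(items, {"m1": None}, ["ARR"])
        assert tree["value"] == pytest.approx(0.4)

    def test_parent_sums_children(self):
        items = pd.DataFrame(
            [
                {"entity_id": "m1", "category": "ARR", "score": 0.3, "n_support_docs": 1},
                {"entity_id": "m2", "category": "CCS", "score": 0.2, "n_support_docs": 1},
            ]
        )
        hierarchy = {"parent": None, "m1": "parent", "m2": "parent"}
        tree = sunburst_export(items, hierarchy, ["ARR", "CCS"])
        assert tree["children"][0]["value"] == pytest.approx(0.5)

    def test_unknown_hierarchy_node_rejected(self):
        items = pd.DataFrame(
            [{"entity_id": "mX", "category": "ARR", "score": 0.1, "n_support_docs": 1}]
        )
        with pytest.raises(KeyError):
            sunburst_export(items, {"m1": None}, ["ARR"])

    def test_three_level_root_equals_brute_force_leaf_sum(self):
        rng = np.random.default_rng(7)
        hierarchy = {"top": None, "subA": "top", "subB": "top"}
        rows = []
        for i in range(10):
            leaf = f"leaf{i}"
            hierarchy[leaf] = "subA" if i % 2 else "subB"
            for cat in ("ARR", "CCS", "CM"):
                rows.append(
                    {"entity_id": leaf, "category": cat,
                     "score": float(rng.uniform()), "n_support_docs": 1}
                )
        items = pd.DataFrame(rows)
        tree = sunburst_export(items, hierarchy, ["ARR", "CCS"])
        brute = items[items["category"].isin(["ARR", "CCS"])]["score"].sum()
        assert tree["value"] == pytest.approx(brute, abs=1e-12)
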