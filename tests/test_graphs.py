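import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pertstream import (
    PerturbDataset,
    build_attention_mask,
    build_coexpression_graph,
    build_perturbation_graph,
    genes_of_pathway,
    jaccard_index,
    parse_pathway_hierarchy,
    pathways_of_gene,
    pearson_corr,
)
from pertstream.graphs import MASK_NEG, FormatError
from pertstream.io import write_hierarchy


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
    ])
    def test_known_values(self, x, y, expected):
        assert pearson_corr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_returns_zero(self):
        assert pearson_corr((1, 1, 1), (1, 2, 3)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr((1, 2), (1, 2, 3))


class TestCoexpressionGraph:
    def _dataset(self, expr, names):
        labels = [frozenset()] * expr.shape[0]
        return PerturbDataset(expression=expr, labels=labels, gene_names=names)

    def test_perfect_pair_has_edge_with_unit_weight(self):
        expr = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        g = build_coexpression_graph(self._dataset(expr, ["A", "B"]), threshold=0.9)
        assert g.has_edge("A", "B")
        assert g["A"]["B"]["weight"] == pytest.approx(1.0)

    def test_threshold_above_one_rejected(self, two_gene_dataset):
        with pytest.raises(ValueError):
            build_coexpression_graph(two_gene_dataset, threshold=1.01)

    def test_matches_brute_force_enumeration(self, rng):
        # 5 genes: one strongly correlated pair, the rest independent noise
        n = 40
        base = rng.normal(size=n)
        expr = np.abs(np.column_stack([
            base, base + rng.normal(scale=0.1, size=n),
            rng.normal(size=n), rng.normal(size=n), rng.normal(size=n),
        ])) + 1.0
        names = list("ABCDE")
        ds = self._dataset(expr, names)
        g = build_coexpression_graph(ds, threshold=0.8)
        expected = {
            frozenset({u, v})
            for u, v in itertools.combinations(names, 2)
            if abs(pearson_corr(expr[:, names.index(u)], expr[:, names.index(v)])) >= 0.8
        }
        assert {frozenset(e) for e in g.edges} == expected
        assert len(expected) == 1


class TestJaccard:
    def test_known_values(self):
        assert jaccard_index({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
        assert jaccard_index({"A"}, {"A"}) == 1.0
        assert jaccard_index({"A"}, {"B"}) == 0.0
        assert jaccard_index(set(), set()) == 0.0

    @given(
        u=st.sets(st.integers(0, 8), max_size=6),
        v=st.sets(st.integers(0, 8), max_size=6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, u, v):
        j = jaccard_index(u, v)
        assert j == jaccard_index(v, u)
        assert 0.0 <= j <= 1.0
        if u == v and u:
            assert j == 1.0


class TestPerturbationGraph:
    def test_clique_of_shared_term(self):
        go = {g: {"T"} for g in "ABC"}
        g = build_perturbation_graph(go, list("ABC"), h_pert=2)
        for u in "ABC":
            assert g.out_degree(u) == 2
            for _, v, d in g.out_edges(u, data=True):
                assert d["weight"] == 1.0

    def test_empty_term_set_is_isolated(self):
        go = {"A": {"T"}, "B": {"T"}, "C": set()}
        g = build_perturbation_graph(go, list("ABC"), h_pert=2)
        assert g.degree("C") == 0

    def test_top_neighbor_matches_brute_force(self):
        go = {
            "A": {"1", "2", "3"}, "B": {"1", "2"}, "C": {"2", "3", "4"},
            "D": {"4", "5"}, "E": {"5"}, "F": {"9"},
        }
        genes = sorted(go)
        g = build_perturbation_graph(go, genes, h_pert=1)
        for u in genes:
            best = max(
                ((jaccard_index(go[u], go[v]), v) for v in genes if v != u),
                key=lambda t: (t[0], [-ord(c) for c in t[1]]),
            )
            succ = list(g.successors(u))
            if best[0] == 0:
                assert succ == []
            else:
                assert succ == [best[1]]

    def test_degree_bounded_by_h_pert(self, tiny_annotations, tiny_grn):
        g = build_perturbation_graph(tiny_annotations.go_sets, tiny_grn.gene_names, h_pert=3)
        assert max(g.out_degree(n) for n in g.nodes) <= 3


class TestHierarchy:
    @pytest.fixture
    def fixture_files(self, tmp_path):
        relations = tmp_path / "rel.tsv"
        relations.write_text(
            "parent_id\tchild_id\tparent_level\tchild_level\n"
            "ROOT\tP1\t2\t1\nROOT\tP2\t2\t1\n"
        )
        members = tmp_path / "mem.gmt"
        members.write_text("P1\tna\tg1\tg2\tg3\nP2\tna\tg4\tg5\tg6\n")
        return relations, members

    def test_counts_from_fixture(self, fixture_files):
        h = parse_pathway_hierarchy(*fixture_files)
        assert len(h.pathways) == 3
        assert h.graph.number_of_edges() == 2
        assert sum(len(v) for v in h.memberships.values()) == 6

    def test_self_parent_rejected(self, tmp_path, fixture_files):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "parent_id\tchild_id\tparent_level\tchild_level\nP1\tP1\t2\t1\n"
        )
        with pytest.raises(FormatError, match="own parent"):
            parse_pathway_hierarchy(bad, fixture_files[1])

    def test_membership_of_undeclared_pathway_rejected(self, tmp_path, fixture_files):
        members = tmp_path / "bad.gmt"
        members.write_text("GHOST\tna\tg1\n")
        with pytest.raises(FormatError, match="undeclared"):
            parse_pathway_hierarchy(fixture_files[0], members)

    def test_parent_level_must_exceed_child(self, tmp_path, fixture_files):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "parent_id\tchild_id\tparent_level\tchild_level\nP1\tP2\t1\t1\n"
        )
        with pytest.raises(FormatError, match="must exceed"):
            parse_pathway_hierarchy(bad, fixture_files[1])

    def test_pathways_of_gene_includes_ancestors(self, fixture_files):
        h = parse_pathway_hierarchy(*fixture_files)
        assert pathways_of_gene(h, "g1") == {"P1", "ROOT"}
        assert pathways_of_gene(h, "unknown") == set()

    def test_gene_in_two_leaves_gets_union_of_chains(self, tmp_path):
        relations = tmp_path / "rel.tsv"
        relations.write_text(
            "parent_id\tchild_id\tparent_level\tchild_level\n"
            "ROOT\tMID\t3\t2\nMID\tL1\t2\t1\nROOT\tL2\t3\t1\n"
        )
        members = tmp_path / "mem.gmt"
        members.write_text("L1\tna\tgX\nL2\tna\tgX\n")
        h = parse_pathway_hierarchy(relations, members)
        assert pathways_of_gene(h, "gX") == {"L1", "L2", "MID", "ROOT"}

    def test_genes_of_pathway_descends_subtree(self, fixture_files):
        h = parse_pathway_hierarchy(*fixture_files)
        assert genes_of_pathway(h, "P1") == {"g1", "g2", "g3"}
        assert genes_of_pathway(h, "ROOT") == {f"g{i}" for i in range(1, 7)}
        with pytest.raises(KeyError):
            genes_of_pathway(h, "GHOST")

    def test_synthetic_hierarchy_round_trips(self, tiny_annotations, tmp_path):
        h = tiny_annotations.hierarchy
        write_hierarchy(h, tmp_path / "rel.tsv", tmp_path / "mem.gmt")
        back = parse_pathway_hierarchy(tmp_path / "rel.tsv", tmp_path / "mem.gmt")
        assert set(back.graph.nodes) == set(h.graph.nodes)
        assert set(back.graph.edges) == set(h.graph.edges)
        assert back.memberships == h.memberships


class TestAttentionMask:
    def test_matches_brute_force_pathway_overlap(self, tiny_annotations, tiny_dataset):
        h = tiny_annotations.hierarchy
        names = tiny_dataset.gene_names
        mask = build_attention_mask(names, h, tiny_dataset, fallback_threshold=0.4)
        corr = np.corrcoef(tiny_dataset.expression, rowvar=False)
        for i, u in enumerate(names):
            for j, v in enumerate(names):
                pu, pv = pathways_of_gene(h, u), pathways_of_gene(h, v)
                if i == j:
                    expected = 0.0
                elif pu and pv:
                    expected = 0.0 if pu & pv else MASK_NEG
                else:
                    expected = 0.0 if abs(corr[i, j]) >= 0.4 else MASK_NEG
                assert mask.matrix[i, j] == expected, (u, v)

    def test_symmetric_with_zero_diagonal(self, tiny_annotations, tiny_dataset):
        mask = build_attention_mask(
            tiny_dataset.gene_names, tiny_annotations.hierarchy, tiny_dataset
        )
        assert np.array_equal(mask.matrix, mask.matrix.T)
        assert np.all(np.diag(mask.matrix) == 0.0)

    def test_raising_fallback_threshold_never_permits_more(
        self, tiny_annotations, tiny_dataset
    ):
        h = tiny_annotations.hierarchy
        names = tiny_dataset.gene_names
        low = build_attention_mask(names, h, tiny_dataset, fallback_threshold=0.2)
        high = build_attention_mask(names, h, tiny_dataset, fallback_threshold=0.8)
        assert np.all(high.permitted() <= low.permitted())

    def test_unannotated_but_perfectly_correlated_pair_is_permitted(self):
        expr = np.array([[1.0, 2.0, 5.0], [2.0, 4.0, 4.8], [3.0, 6.0, 5.2],
                         [1.5, 3.0, 5.1]])
        ds = PerturbDataset(expr, [frozenset()] * 4, ["A", "B", "C"])
        import networkx as nx

        from pertstream.graphs import PathwayHierarchy
        g = nx.DiGraph()
        g.add_node("P", level=1)
        h = PathwayHierarchy(graph=g, memberships={"P": {"C"}})
        mask = build_attention_mask(["A", "B", "C"], h, ds, fallback_threshold=0.9)
        assert mask.matrix[0, 1] == 0.0  # r(A,B) = 1.0 >= 0.9
        assert mask.matrix[0, 2] == MASK_NEG

    def test_gene_names_must_match_dataset(self, tiny_annotations, tiny_dataset):
        with pytest.raises(ValueError):
            build_attention_mask(
                list(reversed(tiny_dataset.gene_names)),
                tiny_annotations.hierarchy,
                tiny_dataset,
            )
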