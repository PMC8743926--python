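"""Term co-annotation pairs, phenotype trees and network exports."""

from itertools import combinations

import networkx as nx
import pytest

from uhegpipe.annotation import GeneTermAnnotation
from uhegpipe.network import (
    PairCount,
    build_phenotype_tree,
    export_network,
    pair_counts,
)
from uhegpipe.ontology import parse_obo
from uhegpipe.summarize import term_gene_count_table


def make_annotation(genes, max_level=4):
    return GeneTermAnnotation(genes={g: set(ts) for g, ts in genes.items()}, max_level=max_level)


class TestPairCounts:
    def test_single_term_gene_yields_no_pairs(self):
        ann = make_annotation({"g": {("T:1", 4)}})
        assert pair_counts(ann) == []

    def test_triangle_from_three_terms(self):
        ann = make_annotation({"g": {("T:x", 4), ("T:y", 4), ("T:z", 4)}})
        got = pair_counts(ann)
        assert got == [
            PairCount("T:x", "T:y", 1),
            PairCount("T:x", "T:z", 1),
            PairCount("T:y", "T:z", 1),
        ]

    def test_level_filter_restricts_pairs(self):
        ann = make_annotation({"g": {("T:a", 1), ("T:b", 4), ("T:c", 4)}})
        assert pair_counts(ann, level_filter=[4]) == [PairCount("T:b", "T:c", 1)]
        assert len(pair_counts(ann, level_filter=[1, 4])) == 3

    def test_matches_double_loop_oracle(self, rng):
        genes = {}
        for i in range(50):
            n = int(rng.integers(1, 6))
            genes[f"g{i}"] = {(f"T:{t}", 4) for t in rng.choice(12, size=n, replace=False)}
        ann = make_annotation(genes)
        got = {(p.term_a, p.term_b): p.shared_genes for p in pair_counts(ann)}
        oracle = {}
        for ts in genes.values():
            for a, b in combinations(sorted(t for t, _ in ts), 2):
                oracle[(a, b)] = oracle.get((a, b), 0) + 1
        assert got == oracle

    def test_total_weight_equals_sum_of_choose2(self, rng):
        genes = {
            f"g{i}": {(f"T:{t}", 4) for t in rng.choice(9, size=int(rng.integers(1, 6)), replace=False)}
            for i in range(30)
        }
        ann = make_annotation(genes)
        total = sum(p.shared_genes for p in pair_counts(ann))
        expected = sum(len(ts) * (len(ts) - 1) // 2 for ts in genes.values())
        assert total == expected


TREE_OBO = (
    "[Term]\nid: T:0\nname: root\n\n"
    "[Term]\nid: T:1\nname: top\nis_a: T:0\n\n"
    "[Term]\nid: T:2\nname: mid\nis_a: T:1\n\n"
    "[Term]\nid: T:3\nname: deep\nis_a: T:2\n\n"
    "[Term]\nid: T:4\nname: side\nis_a: T:1\n"
)


class TestPhenotypeTree:
    def test_unannotated_subtree_prunes_to_nothing(self):
        ont = parse_obo(TREE_OBO)
        tree = build_phenotype_tree(ont, "T:1", make_annotation({}))
        assert tree.nodes == {} and tree.edges == []

    def test_path_preserved_to_deep_annotation(self):
        ont = parse_obo(TREE_OBO)
        ann = make_annotation({"g": {("T:3", 3)}})
        tree = build_phenotype_tree(ont, "T:1", ann)
        assert set(tree.nodes) == {"T:1", "T:2", "T:3"}
        assert [tree.nodes[t][2] for t in ("T:1", "T:2", "T:3")] == [0, 0, 1]
        assert tree.edges == [("T:1", "T:2"), ("T:2", "T:3")]

    def test_non_top_term_rejected(self):
        ont = parse_obo(TREE_OBO)
        with pytest.raises(ValueError, match="level"):
            build_phenotype_tree(ont, "T:2", make_annotation({}))

    def test_counts_bounded_by_term_table(self, diamond_ontology, rng):
        ont = diamond_ontology
        active = [t for t in ont.terms if t in ont and t != ont.root_id
                  and ont.name(t) not in ("normal phenotype", "no phenotypic analysis",
                                          "normal child")]
        genes = {}
        for i in range(25):
            picks = rng.choice(active, size=2, replace=False)
            genes[f"g{i}"] = {(t, ont.term_level(t)) for t in picks}
        ann = make_annotation(genes)
        tables = {
            lv: {r.term_id: r.gene_count for r in term_gene_count_table(ann, ont, lv, 25)}
            for lv in (1, 2, 3, 4)
        }
        for top in ont.top_level_terms():
            tree = build_phenotype_tree(ont, top, ann)
            for tid, (_, lv, count) in tree.nodes.items():
                if count:
                    assert count == tables[lv][tid]


class TestExports:
    def tree(self):
        ont = parse_obo(TREE_OBO)
        ann = make_annotation({"g": {("T:3", 3)}})
        return build_phenotype_tree(ont, "T:1", ann)

    def test_empty_tree_exports_reparse_empty(self, tmp_path):
        ont = parse_obo(TREE_OBO)
        tree = build_phenotype_tree(ont, "T:1", make_annotation({}))
        paths = export_network(tree, "graphml", tmp_path / "t.graphml")
        g = nx.read_graphml(paths[0])
        assert len(g) == 0

    def test_chain_sif_has_two_edges(self, tmp_path):
        paths = export_network(self.tree(), "sif", tmp_path / "t.sif")
        lines = paths[0].read_text().splitlines()
        assert lines == ["T:1\tis_a\tT:2", "T:2\tis_a\tT:3"]
        sidecar = paths[1].read_text().splitlines()
        assert sidecar[0] == "term_id\tname\tlevel\tgene_count"
        assert len(sidecar) == 4

    def test_graphml_round_trips_isomorphic(self, tmp_path):
        tree = self.tree()
        p = export_network(tree, "graphml", tmp_path / "t.graphml")[0]
        g = nx.read_graphml(p)
        assert set(g.nodes) == set(tree.nodes)
        assert {(u, v) for u, v in g.edges} == set(tree.edges)
        assert g.nodes["T:3"]["gene_count"] == 1

    def test_pair_edgelist_carries_weight(self, tmp_path):
        pairs = [PairCount("T:a", "T:b", 2)]
        p = export_network(pairs, "edgelist", tmp_path / "pairs.tsv")[0]
        assert p.read_text().splitlines()[1] == "T:a\tT:b\tcoannotated\t2"

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            export_network(self.tree(), "gexf", tmp_path / "x")

    def test_export_bytes_deterministic(self, tmp_path):
        a = export_network(self.tree(), "graphml", tmp_path / "a.graphml")[0]
        b = export_network(self.tree(), "graphml", tmp_path / "b.graphml")[0]
        assert a.read_bytes() == b.read_bytes()
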