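"""UHEG selection cascade: top-K, intersection, coding filter, collapse, variance."""

import numpy as np
import pytest

from uhegpipe.expression import ConsistencyError
from uhegpipe.selection import (
    ProbeAnnotation,
    collapse_to_unique_genes,
    filter_protein_coding,
    intersect_required,
    per_gene_variance,
    top_k_probes,
)

from conftest import make_matrix


def coding(sym, mgi):
    return ProbeAnnotation(sym, mgi, "protein coding gene")


class TestTopK:
    def test_saturates_at_probe_count(self):
        m = make_matrix(np.arange(10.0).reshape(5, 2))
        assert top_k_probes(m, "s0", k=99) == set(m.probe_ids)

    def test_matches_full_sort_oracle(self, rng):
        vals = rng.permutation(np.arange(10.0)).reshape(10, 1)
        m = make_matrix(vals, days=[10])
        got = top_k_probes(m, "s0", k=3)
        order = sorted(m.probe_ids, key=lambda p: -m.values.loc[p, "s0"])
        assert got == set(order[:3])

    def test_tie_break_is_probe_id_ascending(self):
        m = make_matrix(np.array([[5.0], [5.0], [5.0], [1.0]]))
        assert top_k_probes(m, "s0", k=2) == {"p000", "p001"}

    def test_unknown_sample_raises(self):
        m = make_matrix(np.ones((2, 2)))
        with pytest.raises(KeyError):
            top_k_probes(m, "nope", k=1)


class TestIntersection:
    def test_single_sample_identity(self):
        sets = {"a": {"x", "y"}}
        assert intersect_required(sets, ["a"]) == {"x", "y"}

    def test_two_set_overlap(self):
        sets = {"a": {"A", "B"}, "b": {"B", "C"}}
        assert intersect_required(sets, ["a", "b"]) == {"B"}

    def test_non_required_samples_ignored(self):
        sets = {"a": {"A", "B"}, "pd1": {"C"}}
        assert intersect_required(sets, ["a"]) == {"A", "B"}

    def test_matches_fold_left_oracle(self, rng):
        sets = {
            f"s{i}": set(rng.choice(50, size=30, replace=False).tolist())
            for i in range(12)
        }
        expected = set(range(50))
        for s in sets.values():
            expected &= s
        assert intersect_required(sets, list(sets)) == expected

    def test_adding_required_sample_never_enlarges(self, rng):
        sets = {f"s{i}": set(rng.choice(30, size=20, replace=False).tolist()) for i in range(5)}
        prev = intersect_required(sets, ["s0"])
        for i in range(1, 5):
            cur = intersect_required(sets, [f"s{j}" for j in range(i + 1)])
            assert cur <= prev
            prev = cur

    def test_empty_required_rejected(self):
        with pytest.raises(ValueError):
            intersect_required({"a": set()}, [])


class TestCodingFilterAndCollapse:
    MAP = {
        "p1": coding("Aa", "MGI:1"),
        "p2": coding("Aa", "MGI:1"),
        "p3": coding("Bb", "MGI:2"),
        "p4": ProbeAnnotation("Nc1", "MGI:3", "lncRNA gene"),
        "p5": ProbeAnnotation("Nc2", "MGI:4", "lncRNA gene"),
    }

    def test_all_coding_unchanged(self):
        probes = {"p1", "p2", "p3"}
        assert filter_protein_coding(probes, self.MAP) == probes

    def test_mixed_fixture_keeps_only_coding(self):
        # 3 coding, 2 noncoding, 1 unmapped
        got = filter_protein_coding({"p1", "p2", "p3", "p4", "p5", "p9"}, self.MAP)
        assert got == {"p1", "p2", "p3"}

    def test_collapse_picks_highest_mean_probe(self):
        m = make_matrix(np.array([[10.0, 10.0], [11.0, 11.0]]), probe_ids=["p1", "p2"])
        recs = collapse_to_unique_genes({"p1", "p2"}, self.MAP, m)
        assert len(recs) == 1
        assert recs[0].representative_probe == "p2"
        assert recs[0].mean_expression == 11.0

    def test_one_record_per_distinct_gene(self, rng):
        n, genes = 12, 5
        mapping = {
            f"q{i}": coding(f"G{i % genes}", f"MGI:{i % genes}") for i in range(n)
        }
        m = make_matrix(rng.normal(8, 1, size=(n, 3)), probe_ids=list(mapping))
        recs = collapse_to_unique_genes(set(mapping), mapping, m)
        assert len(recs) == genes
        assert sorted({r.mgi_id for r in recs}) == sorted({a.mgi_id for a in mapping.values()})

    def test_conflicting_symbols_rejected(self):
        bad = {"p1": coding("Aa", "MGI:1"), "p2": coding("Zz", "MGI:1")}
        m = make_matrix(np.ones((2, 2)), probe_ids=["p1", "p2"])
        with pytest.raises(ConsistencyError, match="conflicting symbols"):
            collapse_to_unique_genes({"p1", "p2"}, bad, m)


class TestVariance:
    def test_constant_vector_zero(self):
        m = make_matrix(np.full((1, 4), 8.0))
        recs = collapse_to_unique_genes({"p000"}, {"p000": coding("Aa", "MGI:1")}, m)
        table, frac = per_gene_variance(recs, m, threshold=1.0)
        assert table["variance"].iloc[0] == 0.0
        assert frac == 1.0

    def test_unit_variance_closed_form(self):
        m = make_matrix(np.array([[1.0, 2.0, 3.0]]))
        recs = collapse_to_unique_genes({"p000"}, {"p000": coding("Aa", "MGI:1")}, m)
        table, _ = per_gene_variance(recs, m)
        assert table["variance"].iloc[0] == pytest.approx(1.0)

    def test_matches_two_pass_definition(self, rng):
        vals = rng.normal(8, 2, size=(30, 6))
        m = make_matrix(vals)
        mapping = {p: coding(f"G{i}", f"MGI:{i}") for i, p in enumerate(m.probe_ids)}
        recs = collapse_to_unique_genes(set(m.probe_ids), mapping, m)
        table, _ = per_gene_variance(recs, m)
        for r in table.itertuples(index=False):
            x = m.values.loc[r.representative_probe].to_numpy()
            mean = x.sum() / len(x)
            expected = ((x - mean) ** 2).sum() / (len(x) - 1)
            assert r.variance == pytest.approx(expected, rel=1e-12)

    def test_requires_two_samples(self):
        m = make_matrix(np.ones((1, 1)))
        recs = collapse_to_unique_genes({"p000"}, {"p000": coding("Aa", "MGI:1")}, m)
        with pytest.raises(ValueError):
            per_gene_variance(recs, m)
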