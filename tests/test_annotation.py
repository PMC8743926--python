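"""Allele-report parsing, zygosity filtering, propagation and status logic."""

import io

import pytest

from uhegpipe.annotation import (
    AlleleAnnotationRecord,
    annotation_status,
    filter_by_zygosity,
    parse_allele_report,
    propagate_and_truncate,
    study_counts,
)
from uhegpipe.ontology import parse_obo

from conftest import oracle_ancestors, oracle_descendants, oracle_levels, scan_obo

HEADER = "allele_id\tmgi_id\tgene_symbol\tzygosity_category\tstudy_id\tterm_ids\n"


def rec(mgi, zyg="hm", study="PMID:1", terms=(), allele="AL:1"):
    return AlleleAnnotationRecord(allele, mgi, mgi, zyg, study, frozenset(terms))


CHAIN_OBO = (
    "[Term]\nid: T:0\nname: root\n\n"
    + "\n".join(
        f"[Term]\nid: T:{i}\nname: t{i}\nis_a: T:{i - 1}\n" for i in range(1, 7)
    )
    + "\n[Term]\nid: T:90\nname: normal phenotype\nis_a: T:0\n"
    + "\n[Term]\nid: T:91\nname: no phenotypic analysis\nis_a: T:0\n"
)


class TestParsing:
    def test_header_only_gives_empty_list(self):
        assert parse_allele_report(io.StringIO(HEADER)) == []

    def test_term_set_sizes_from_fixture(self):
        body = (
            "A:1\tMGI:1\tAa\thm\tPMID:1\tMP:1,MP:2\n"
            "A:2\tMGI:2\tBb\tht\tPMID:2\tMP:3\n"
            "A:3\tMGI:3\tCc\thm\t\t\n"
        )
        recs = parse_allele_report(io.StringIO(HEADER + body))
        assert sorted(len(r.term_ids) for r in recs) == [0, 1, 2]
        # row with empty study cell is kept
        assert recs[2].study_id == "" and recs[2].term_ids == frozenset()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            parse_allele_report(io.StringIO("allele_id\tmgi_id\nA:1\tMGI:1\n"))


class TestZygosity:
    def test_allowed_superset_is_identity(self):
        recs = [rec("MGI:1", z) for z in ("hm", "ht")]
        assert filter_by_zygosity(recs, ["hm", "ht"]) == recs

    def test_token_fixture_partition(self):
        recs = [rec(f"MGI:{i}", z) for i, z in enumerate(["hm", "ht", "cn", "cx"])]
        kept = filter_by_zygosity(recs, ["hm", "ht"])
        assert [r.zygosity_category for r in kept] == ["hm", "ht"]

    def test_case_insensitive_match(self):
        assert len(filter_by_zygosity([rec("MGI:1", "HM")], ["hm"])) == 1

    def test_empty_record_list(self):
        assert filter_by_zygosity([], ["hm"]) == []


class TestPropagation:
    def test_chain_truncation_to_four_levels(self):
        ont = parse_obo(CHAIN_OBO)
        ann = propagate_and_truncate([rec("MGI:1", terms=["T:6"])], ont, max_level=4)
        assert ann.terms_of("MGI:1") == {("T:1", 1), ("T:2", 2), ("T:3", 3), ("T:4", 4)}

    def test_excluded_subtree_annotation_vanishes(self):
        ont = parse_obo(CHAIN_OBO)
        ann = propagate_and_truncate([rec("MGI:1", terms=["T:90"])], ont)
        assert ann.terms_of("MGI:1") == set()

    def test_missing_excluded_name_is_configuration_error(self):
        ont = parse_obo("[Term]\nid: X:1\nname: r\n")
        with pytest.raises(ValueError, match="excluded term name"):
            propagate_and_truncate([], ont, excluded_term_names=["normal phenotype"])

    def test_unresolvable_terms_dropped_and_counted(self):
        ont = parse_obo(CHAIN_OBO)
        ann = propagate_and_truncate(
            [rec("MGI:1", terms=["T:2", "MP:9999999"])], ont
        )
        assert ann.dropped_terms == 1
        assert ann.terms_of("MGI:1") == {("T:1", 1), ("T:2", 2)}

    def test_matches_primitive_composition_oracle(self, diamond_ontology):
        ont = diamond_ontology
        from uhegpipe.ontology import write_obo
        terms = scan_obo(write_obo(ont))
        levels = oracle_levels(terms)
        excluded = oracle_descendants(terms, {"MP:0000008", "MP:0000010"})
        direct = {
            "MGI:1": ["MP:0000007", "MP:0000009"],
            "MGI:2": ["MP:0000006"],
            "MGI:3": ["MP:0000002"],
        }
        recs = [rec(g, terms=ts) for g, ts in direct.items()]
        ann = propagate_and_truncate(recs, ont, max_level=4)
        for g, ts in direct.items():
            expected = set()
            for t in ts:
                for a in {t} | oracle_ancestors(terms, t):
                    if a in excluded or a == ont.root_id:
                        continue
                    if 1 <= levels[a] <= 4:
                        expected.add((a, levels[a]))
            assert ann.terms_of(g) == expected

    def test_propagation_closure_invariant(self, diamond_ontology):
        ont = diamond_ontology
        ann = propagate_and_truncate([rec("MGI:1", terms=["MP:0000007"])], ont)
        held = {t for t, _ in ann.terms_of("MGI:1")}
        for t in held:
            for a in ont.ancestors(t):
                if a != ont.root_id and 1 <= ont.term_level(a) <= ann.max_level:
                    assert a in held

    def test_raising_max_level_only_adds_terms(self, diamond_ontology):
        recs = [rec("MGI:1", terms=["MP:0000007"])]
        prev = set()
        for lvl in (1, 2, 3, 4):
            cur = propagate_and_truncate(recs, diamond_ontology, max_level=lvl).terms_of("MGI:1")
            assert prev <= cur
            prev = cur


class TestStatusAndStudies:
    def test_tri_state_assignment(self):
        ont = parse_obo(CHAIN_OBO)
        recs = [rec("MGI:1", terms=["T:3"]), rec("MGI:2", terms=["T:90"])]
        ann = propagate_and_truncate(recs, ont)
        status = annotation_status(["MGI:1", "MGI:2", "MGI:3"], recs, ann)
        assert status == {
            "MGI:1": "abnormal",
            "MGI:2": "mutant_no_abnormal",
            "MGI:3": "no_mutant",
        }

    def test_distinct_study_counting(self):
        recs = [
            rec("MGI:1", study="s1", allele="A:1"),
            rec("MGI:1", study="s1", allele="A:2"),
            rec("MGI:1", study="s2", allele="A:3"),
            rec("MGI:1", study="", allele="A:4"),
            rec("MGI:2", study="s1", allele="A:5"),
        ]
        assert study_counts(recs) == {"MGI:1": 2, "MGI:2": 1}
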