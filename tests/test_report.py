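"""Assemblage summaries: comparison codes, per-site tallies, earliest
associated dates, totals arithmetic."""

import pytest

import zoomsid as z
from zoomsid.classify import ClassificationResult
from zoomsid.errors import TaxonomyError, ZoomsError
from zoomsid.example_assemblage import reference_records_and_calls
from zoomsid.report import (compare_to_morphology, earliest_association,
                            overall_summary, summarize_site)

GOAT = "Capra hircus"


def call(sid, name, failed=False, tentative=False, rank="species"):
    return ClassificationResult(
        specimen_id=sid, call=name, rank="none" if failed else rank,
        tentative=tentative, gate_passed=not failed,
    )


def record(sid, site="S", morph="caprine", start=700, end=800,
           basis="ceramic"):
    return z.SpecimenRecord(specimen_id=sid, site_id=site, context_id="C1",
                            morph_id=morph, date_start_ce=start,
                            date_end_ce=end, date_basis=basis)


class TestCompareToMorphology:
    def test_species_call_improves_caprine_morph(self, tree):
        assert compare_to_morphology(call("a", GOAT), "caprine", tree) == "I"

    def test_same_species_confirms(self, tree):
        assert compare_to_morphology(call("a", GOAT), GOAT, tree) == "C"

    def test_failed_extraction_is_f(self, tree):
        assert compare_to_morphology(call("a", "failed", failed=True),
                                     "caprine", tree) == "F"

    def test_disjoint_taxa_contradict(self, tree):
        assert compare_to_morphology(call("a", "Neotragus moschatus"),
                                     "caprine", tree) == "X"

    def test_size_class_membership_counts_as_improvement(self, tree):
        assert compare_to_morphology(call("a", GOAT), "Bovid Size 2",
                                     tree) == "I"
        assert compare_to_morphology(
            call("a", "caprine", rank="subfamily"), "Bovid Size 2", tree) == "I"

    def test_coarser_consistent_call_confirms(self, tree):
        got = compare_to_morphology(call("a", "caprine", rank="subfamily"),
                                    GOAT, tree)
        assert got == "C"

    def test_unknown_morph_vocabulary_errors(self, tree):
        with pytest.raises(TaxonomyError):
            compare_to_morphology(call("a", GOAT), "Bovid Size 9", tree)


class TestSummarizeSite:
    def test_printed_percentages(self, tree):
        # 242 of 244 -> 99%; 4 of 65 -> 6%
        for n, ns, pct in [(244, 242, 99), (65, 4, 6), (8, 1, 12)]:
            recs = [record(f"s{i}") for i in range(n)]
            calls = [call(f"s{i}", GOAT) for i in range(ns)] + \
                [call(f"s{i}", "failed", failed=True) for i in range(ns, n)]
            s = summarize_site(recs, calls, tree)
            assert (s.n_sampled, s.n_success, s.pct_success) == (n, ns, pct)
            assert s.cif_counts["F"] == n - ns

    def test_empty_site_errors(self, tree):
        with pytest.raises(ZoomsError):
            summarize_site([], [], tree)

    def test_call_without_record_errors(self, tree):
        with pytest.raises(ZoomsError):
            summarize_site([record("a")], [call("b", GOAT)], tree)

    def test_call_counts_sum_to_successes(self, tree):
        recs = [record(f"s{i}") for i in range(5)]
        calls = [call("s0", GOAT), call("s1", GOAT),
                 call("s2", "Ovis aries"),
                 call("s3", "unknown", rank="none"),
                 call("s4", "failed", failed=True)]
        s = summarize_site(recs, calls, tree)
        assert sum(s.call_counts.values()) == s.n_success == 4


class TestEarliestAssociation:
    def test_earliest_start_wins(self, tree):
        recs = [record("a", start=655, end=710, basis="radiocarbon"),
                record("b", start=670, end=770, basis="radiocarbon")]
        calls = [call("a", GOAT), call("b", GOAT)]
        assert earliest_association(recs, calls, GOAT, tree) == \
            (655, 710, "radiocarbon")

    def test_absent_taxon_returns_none(self, tree):
        recs = [record("a")]
        assert earliest_association(recs, [call("a", GOAT)], "Ovis aries",
                                    tree) is None

    def test_tie_broken_by_smaller_end(self, tree):
        recs = [record("a", start=700, end=900),
                record("b", start=700, end=800)]
        calls = [call("a", GOAT), call("b", GOAT)]
        assert earliest_association(recs, calls, GOAT, tree)[:2] == (700, 800)

    def test_radiocarbon_preferred_at_equal_range(self, tree):
        recs = [record("a", basis="ceramic"),
                record("b", basis="radiocarbon")]
        calls = [call("a", GOAT), call("b", GOAT)]
        assert earliest_association(recs, calls, GOAT, tree)[2] == \
            "radiocarbon"

    def test_descendants_count_toward_group(self, tree):
        recs = [record("a", start=655, end=710)]
        got = earliest_association(recs, [call("a", GOAT)], "caprine", tree)
        assert got == (655, 710, "ceramic")


class TestOverallSummary:
    def test_reference_assemblage_arithmetic(self, tree):
        records, calls = reference_records_and_calls(tree)
        by_site = {}
        for r in records:
            by_site.setdefault(r.site_id, []).append(r)
        res = {c.specimen_id: c for c in calls}
        summaries = [
            summarize_site(recs, [res[r.specimen_id] for r in recs], tree)
            for recs in by_site.values()
        ]
        totals = overall_summary(summaries)
        assert (totals.n_sampled, totals.n_success) == (394, 318)
        assert totals.pct_success == 81
        assert totals.call_counts[GOAT] == 259
        assert totals.call_share_pct(GOAT) == 81
        assert totals.call_counts["Ovis aries"] == 11
        assert totals.call_share_pct("Ovis aries") == 3

    def test_invariant_to_partitioning(self, tree):
        recs = [record(f"s{i}", site=("A" if i < 3 else "B"))
                for i in range(6)]
        calls = [call(f"s{i}", GOAT) for i in range(6)]
        merged = [record(f"s{i}", site="A") for i in range(6)]
        one = overall_summary([summarize_site(merged, calls, tree)])
        split_a = summarize_site(recs[:3], calls[:3], tree)
        split_b = summarize_site(recs[3:], calls[3:], tree)
        two = overall_summary([split_a, split_b])
        assert one.n_sampled == two.n_sampled
        assert one.call_counts == two.call_counts

    def test_single_site_totals_equal_site(self, tree):
        recs = [record("a"), record("b")]
        calls = [call("a", GOAT), call("b", "failed", failed=True)]
        s = summarize_site(recs, calls, tree)
        t = overall_summary([s])
        assert (t.n_sampled, t.n_success) == (s.n_sampled, s.n_success)

    def test_no_sites_errors(self):
        with pytest.raises(ZoomsError):
            overall_summary([])


class TestEarliestSecureOccurrence:
    def test_radiocarbon_terminus_beats_wide_bracket(self, tree):
        from zoomsid.report import earliest_secure_occurrence
        records, calls = reference_records_and_calls(tree)
        by_site = {}
        for r in records:
            by_site.setdefault(r.site_id, []).append(r)
        res = {c.specimen_id: c for c in calls}
        summaries = [
            summarize_site(recs, [res[r.specimen_id] for r in recs], tree)
            for recs in by_site.values()
        ]
        # the wide 530-1475 bracket starts earlier but is less secure than
        # the narrow radiocarbon range ending 710
        assert earliest_secure_occurrence(summaries, GOAT) == \
            ("UU", 655, 710, "radiocarbon")
        assert earliest_secure_occurrence(summaries, "Ovis aries") == \
            ("UU", 685, 855, "radiocarbon")
        assert earliest_secure_occurrence(summaries, "Canidae") is None
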