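import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_union_coverage

from introskim.calling import IntrogressionEvent, SegmentCall
from introskim.genome import Chromosome, GenomeSpec, Pedigree, PedigreeEntry
from introskim.summarise import (
    chromosome_summary,
    dedup_unique,
    genome_share,
    interval_union,
    line_code_stats,
    load_line_codes,
    size_stats,
    transfer_fraction,
    UniqueIntrogression,
)

MB = 1_000_000


@pytest.fixture(scope="module")
def long_spec():
    """One group with a long alien chromosome for size-structured dedup cases."""
    return GenomeSpec(
        [
            Chromosome("5A", 600 * MB, "A", 5),
            Chromosome("5B", 600 * MB, "B", 5),
            Chromosome("5D", 600 * MB, "D", 5),
            Chromosome("5T", 600 * MB, "T", 5),
        ]
    )


def _ped(entries):
    return Pedigree(
        {lid: PedigreeEntry(lid, bc1, acc) for lid, bc1, acc in entries}
    )


def _sub_event(line, alien_chrom, start_mb, end_mb, wheat_chrom, zygosity="hom"):
    gain = SegmentCall(line, alien_chrom, start_mb * MB, end_mb * MB,
                       "alien_gain", 0.9, end_mb - start_mb)
    loss = SegmentCall(line, wheat_chrom, start_mb * MB, end_mb * MB,
                       "wheat_loss", 0.02, end_mb - start_mb, zygosity=zygosity)
    return IntrogressionEvent(
        sample_id=line,
        event_class="homoeologous_substitution",
        alien_segment=gain,
        wheat_partner=loss,
        zygosity=zygosity,
    )


class TestDedup:
    def test_identical_segments_same_bc1_merge_to_one(self, long_spec):
        ped = _ped([("L1", "BC1", "ACC1"), ("L2", "BC1", "ACC1")])
        events = [
            _sub_event("L1", "5T", 100, 550, "5D"),
            _sub_event("L2", "5T", 100, 550, "5D"),
        ]
        uniques = dedup_unique(events, ped, long_spec)
        assert len(uniques) == 1
        assert uniques[0].member_lines == ["L1", "L2"]

    def test_identical_segments_different_bc1_stay_distinct(self, long_spec):
        ped = _ped([("L1", "BC1", "ACC1"), ("L2", "BC2", "ACC2")])
        events = [
            _sub_event("L1", "5T", 100, 550, "5D"),
            _sub_event("L2", "5T", 100, 550, "5D"),
        ]
        assert len(dedup_unique(events, ped, long_spec)) == 2

    def test_nested_trimmed_segments_same_bc1_stay_distinct(self, long_spec):
        """Later-generation recombination trims 450 -> 116 -> 30 Mb; reciprocal
        overlap below 0.8 keeps the three as separate unique introgressions."""
        ped = _ped([(f"L{i}", "BC1", "ACC1") for i in (1, 2, 3)])
        events = [
            _sub_event("L1", "5T", 150, 600, "5D"),   # 450 Mb
            _sub_event("L2", "5T", 484, 600, "5D"),   # 116 Mb
            _sub_event("L3", "5T", 570, 600, "5D"),   # 30 Mb
        ]
        assert len(dedup_unique(events, ped, long_spec)) == 3

    def test_output_invariant_to_event_order(self, long_spec):
        ped = _ped([("L1", "BC1", "A1"), ("L2", "BC1", "A1"), ("L3", "BC2", "A2")])
        events = [
            _sub_event("L1", "5T", 100, 550, "5D"),
            _sub_event("L2", "5T", 110, 560, "5D"),
            _sub_event("L3", "5T", 0, 80, "5A"),
        ]
        a = dedup_unique(events, ped, long_spec)
        b = dedup_unique(list(reversed(events)), ped, long_spec)
        assert [(u.code, u.start, u.end, tuple(u.member_lines)) for u in a] == [
            (u.code, u.start, u.end, tuple(u.member_lines)) for u in b
        ]

    def test_codes_follow_alien_target_serial_pattern(self, long_spec):
        ped = _ped([("L1", "BC1", "A1"), ("L2", "BC2", "A1"), ("L3", "BC3", "A1")])
        events = [
            _sub_event("L1", "5T", 0, 500, "5D"),
            _sub_event("L2", "5T", 300, 600, "5D"),
            _sub_event("L3", "5T", 0, 100, "5A"),
        ]
        uniques = dedup_unique(events, ped, long_spec)
        codes = {u.code for u in uniques}
        # serials in descending size order within 5T.D
        assert codes == {"5T.D1", "5T.D2", "5T.A1"}
        d1 = next(u for u in uniques if u.code == "5T.D1")
        assert d1.length == 500 * MB

    def test_line_missing_from_pedigree_is_an_error(self, long_spec):
        ped = _ped([("L1", "BC1", "A1")])
        with pytest.raises(KeyError, match="absent from pedigree"):
            dedup_unique([_sub_event("L2", "5T", 0, 100, "5D")], ped, long_spec)

    def test_additions_excluded_from_uniqueness(self, long_spec):
        ped = _ped([("L1", "BC1", "A1")])
        gain = SegmentCall("L1", "5T", 0, 600 * MB, "alien_gain", 0.9, 600)
        addition = IntrogressionEvent("L1", "whole_chromosome_addition", alien_segment=gain)
        assert dedup_unique([addition], ped, long_spec) == []


def _uniq(chrom, start_mb, end_mb, target="D", acc="A1", bc1="BC1", uid=1):
    return UniqueIntrogression(
        uid=uid, code="", alien_chrom=chrom, start=start_mb * MB, end=end_mb * MB,
        wheat_target=f"5{target}" if target else "addition",
        target_genome=target, bc1_id=bc1, accession=acc, member_lines=["L"],
    )


class TestTransferFraction:
    def test_overlapping_intervals_counted_once(self):
        spec = GenomeSpec([Chromosome("1T", 1000, "T", 1)])
        uniques = [
            UniqueIntrogression(1, "", "1T", 0, 100, "1D", "D", "B", "A", ["L"]),
            UniqueIntrogression(2, "", "1T", 50, 150, "1D", "D", "B", "A", ["L"]),
        ]
        rep = transfer_fraction(uniques, spec, "all")
        assert rep.fraction == pytest.approx(15.0)
        assert rep.covered_bp == 150
        assert rep.covered_bp == rep.total_bp - sum(g[3] for g in rep.gaps)

    def test_full_coverage_has_no_gaps(self, long_spec):
        uniques = [_uniq("5T", 0, 600)]
        rep = transfer_fraction(uniques, long_spec, "chromosome:5T")
        assert rep.fraction == 100.0
        assert rep.gaps == []

    def test_duplicating_an_interval_is_idempotent(self, long_spec):
        uniques = [_uniq("5T", 10, 200), _uniq("5T", 150, 300)]
        rep1 = transfer_fraction(uniques, long_spec, "all")
        rep2 = transfer_fraction(uniques + [uniques[0]], long_spec, "all")
        assert rep1.fraction == rep2.fraction

    def test_adding_an_interval_never_decreases_coverage(self, long_spec):
        uniques = [_uniq("5T", 10, 200)]
        base = transfer_fraction(uniques, long_spec, "all").fraction
        more = transfer_fraction(uniques + [_uniq("5T", 500, 550)], long_spec, "all").fraction
        assert more >= base

    def test_empty_scope_is_an_error(self, long_spec):
        with pytest.raises(KeyError):
            transfer_fraction([], long_spec, "chromosome:9Z")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 200)), min_size=0, max_size=20
        )
    )
    def test_union_fraction_matches_per_bp_marking(self, intervals):
        length = 1000
        ivs = [(s, min(s + l, length)) for s, l in intervals]
        merged = interval_union(ivs)
        covered = sum(e - s for s, e in merged)
        assert covered == brute_force_union_coverage(ivs, length)


class TestStats:
    def test_size_stats_basic(self):
        uniques = [_uniq("5T", 0, 10), _uniq("5T", 0, 20), _uniq("5T", 0, 90)]
        mean, median, lo, hi = size_stats(uniques)
        assert (mean, median, lo, hi) == (40 * MB, 20 * MB, 10 * MB, 90 * MB)

    def test_single_segment_collapses_all_four(self):
        (mean, median, lo, hi) = size_stats([_uniq("5T", 0, 42)])
        assert mean == median == lo == hi == 42 * MB

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            size_stats([])

    def test_genome_share_tally(self):
        uniques = [
            _uniq("5T", 0, 10, "D"),
            _uniq("5T", 0, 20, "D"),
            _uniq("5T", 0, 30, "D"),
            _uniq("5T", 0, 40, "A"),
        ]
        share = genome_share(uniques)
        assert share == {"A": 25.0, "B": 0.0, "D": 75.0}
        assert sum(share.values()) == pytest.approx(100.0)

    def test_genome_share_all_d(self):
        share = genome_share([_uniq("5T", 0, 10, "D")])
        assert share == {"A": 0.0, "B": 0.0, "D": 100.0}


class TestChromosomeSummary:
    def test_counts_partitioned_by_accession_with_totals(self, full_spec):
        uniques = [
            _uniq("3T", 0, 10, acc="A1", uid=1),
            _uniq("3T", 20, 40, acc="A1", uid=2),
            _uniq("3T", 50, 60, acc="A2", uid=3),
        ]
        df = chromosome_summary(uniques, None, full_spec)
        row = df[df["chrom"] == "3T"].iloc[0]
        assert (row["A1"], row["A2"], row["total"]) == (2, 1, 3)
        totals = df[df["chrom"] == "total"].iloc[0]
        assert totals["total"] == len(uniques)
        assert totals["total"] == df[df["chrom"] != "total"]["total"].sum()

    def test_empty_inputs_give_all_zero_table(self, full_spec):
        df = chromosome_summary([], None, full_spec)
        assert (df[df["chrom"] != "total"]["total"] == 0).all()


class TestPublishedLineTable:
    def test_counts_match_in_text_statements(self):
        stats = line_code_stats(load_line_codes())
        assert stats["n_lines"] == 68
        assert stats["max_per_line"] == 4
        assert stats["n_skim_only"] == 5
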