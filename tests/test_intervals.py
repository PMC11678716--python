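"""Interval arithmetic against brute-force oracles and its invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from loopblock import (
    ConfigurationError,
    GenomicInterval,
    IntervalSet,
    ValidationError,
    coverage_fraction,
    intersect,
    stratify_by_distance,
    window_join,
)
from loopblock.intervals import gap_between, read_bed, write_bed

from _oracles import brute_coverage, brute_intersect, brute_stratify, brute_window
from conftest import random_intervals


def iv(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, name=name)


class TestValidation:
    def test_rejects_inverted_and_empty_intervals(self):
        with pytest.raises(ValidationError, match="start < end"):
            GenomicInterval("chr1", 200, 100, name="bad")
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValidationError, match="chromosome"):
            GenomicInterval("", 0, 10)

    def test_error_names_the_record(self):
        with pytest.raises(ValidationError, match="offender"):
            GenomicInterval("chr1", 9, 3, name="offender")


class TestIntersect:
    def test_simple_overlap(self):
        pairs = intersect(
            IntervalSet([iv("chr1", 100, 200, "a")]),
            IntervalSet([iv("chr1", 150, 250, "b")]),
        )
        assert len(pairs) == 1
        a, b = pairs[0]
        assert (a.name, b.name) == ("a", "b")

    def test_half_open_abutment_is_not_overlap(self):
        pairs = intersect(
            IntervalSet([iv("chr1", 100, 200)]),
            IntervalSet([iv("chr1", 200, 300)]),
        )
        assert pairs == []

    def test_min_overlap_threshold(self):
        a = IntervalSet([iv("chr1", 100, 200, "a")])
        b = IntervalSet([iv("chr1", 190, 300, "b")])
        assert len(intersect(a, b, min_overlap=10)) == 1
        assert intersect(a, b, min_overlap=11) == []
        with pytest.raises(ConfigurationError):
            intersect(a, b, min_overlap=0)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            a = random_intervals(rng, 50, prefix="a")
            b = random_intervals(rng, 50, prefix="b")
            got = {
                (x.name, y.name)
                for x, y in intersect(IntervalSet(a), IntervalSet(b))
            }
            assert got == brute_intersect(a, b)

    def test_transpose_symmetry(self, rng):
        a = random_intervals(rng, 40, prefix="a")
        b = random_intervals(rng, 40, prefix="b")
        fwd = {(x.name, y.name) for x, y in intersect(IntervalSet(a), IntervalSet(b))}
        rev = {(y.name, x.name) for x, y in intersect(IntervalSet(b), IntervalSet(a))}
        assert fwd == rev


class TestWindowJoin:
    def test_gap_computation(self):
        triples = window_join(
            IntervalSet([iv("chr1", 1000, 1100, "a")]),
            IntervalSet([iv("chr1", 5000, 5100, "b")]),
            distance=10_000,
        )
        assert [(a.name, b.name, g) for a, b, g in triples] == [("a", "b", 3900)]

    def test_gap_beyond_window_excluded(self):
        triples = window_join(
            IntervalSet([iv("chr1", 1000, 1100)]),
            IntervalSet([iv("chr1", 5000, 5100)]),
            distance=3000,
        )
        assert triples == []

    def test_boundary_gap_exactly_at_distance_included(self):
        triples = window_join(
            IntervalSet([iv("chr1", 0, 100, "a")]),
            IntervalSet([iv("chr1", 600, 700, "b")]),
            distance=500,
        )
        assert [g for _, _, g in triples] == [500]

    def test_overlapping_pair_has_zero_gap(self):
        triples = window_join(
            IntervalSet([iv("chr1", 0, 100)]),
            IntervalSet([iv("chr1", 50, 150)]),
            distance=0,
        )
        assert [g for _, _, g in triples] == [0]

    def test_matches_brute_force_oracle(self, rng):
        for dist in (0, 137, 5_000, 60_000):
            a = random_intervals(rng, 60, prefix="a")
            b = random_intervals(rng, 60, prefix="b")
            got = {
                (x.name, y.name, g)
                for x, y, g in window_join(IntervalSet(a), IntervalSet(b), dist)
            }
            assert got == brute_window(a, b, dist)

    def test_negative_distance_rejected(self):
        with pytest.raises(ConfigurationError):
            window_join(IntervalSet(), IntervalSet(), -1)


class TestCoverage:
    def test_half_covered(self):
        fr = coverage_fraction(
            IntervalSet([iv("chr1", 0, 100)]), IntervalSet([iv("chr1", 50, 150)])
        )
        assert fr == [0.5]

    def test_empty_cover(self):
        assert coverage_fraction(IntervalSet([iv("chr1", 0, 100)]), IntervalSet()) == [0.0]

    def test_overlapping_cover_not_double_counted(self):
        fr = coverage_fraction(
            IntervalSet([iv("chr1", 0, 100)]),
            IntervalSet([iv("chr1", 10, 60), iv("chr1", 40, 90)]),
        )
        assert fr == [0.8]

    def test_matches_base_counting_oracle(self, rng):
        a = random_intervals(rng, 60, prefix="a")
        b = random_intervals(rng, 60, prefix="b")
        got = coverage_fraction(IntervalSet(a), IntervalSet(b))
        want = brute_coverage(sorted(a, key=lambda x: x.sort_key()), b)
        assert np.allclose(got, want)

    def test_monotone_under_added_cover_and_split_invariant(self, rng):
        a = IntervalSet(random_intervals(rng, 30, prefix="a"))
        b1 = random_intervals(rng, 20, prefix="b")
        b2 = b1 + random_intervals(rng, 20, prefix="c")
        f1 = coverage_fraction(a, IntervalSet(b1))
        f2 = coverage_fraction(a, IntervalSet(b2))
        assert all(y >= x - 1e-12 for x, y in zip(f1, f2))
        # splitting every b-interval at an interior point changes nothing
        split = []
        for x in b1:
            if x.length > 1:
                mid = x.start + x.length // 2
                split += [iv(x.chrom, x.start, mid), iv(x.chrom, mid, x.end)]
            else:
                split.append(x)
        assert np.allclose(f1, coverage_fraction(a, IntervalSet(split)))


class TestStratify:
    BOUNDS = (0, 10_000, 20_000, 30_000)

    def test_pairs_assigned_to_smallest_qualifying_bound(self):
        baits = IntervalSet([iv("chr1", 1000, 1100, "bait")])
        targets = IntervalSet(
            [iv("chr1", 5000, 5100, "near"), iv("chr1", 26000, 26100, "far")]
        )
        sp = stratify_by_distance(baits, targets, self.BOUNDS)
        by_stratum = {
            bound: [t.name for _, t, _ in triples]
            for bound, triples in sp.strata.items()
            if triples
        }
        assert by_stratum == {10_000: ["near"], 30_000: ["far"]}

    def test_overlapping_pair_goes_to_zero_stratum_only(self):
        baits = IntervalSet([iv("chr1", 1000, 1100, "bait")])
        targets = IntervalSet([iv("chr1", 1050, 1200, "t")])
        sp = stratify_by_distance(baits, targets, self.BOUNDS)
        assert len(sp.strata[0]) == 1
        assert sp.total() == 1

    def test_partition_and_union_match_oracle(self, rng):
        baits = random_intervals(rng, 40, prefix="b")
        targets = random_intervals(rng, 80, prefix="t")
        sp = stratify_by_distance(
            IntervalSet(baits), IntervalSet(targets), self.BOUNDS
        )
        want = brute_stratify(baits, targets, self.BOUNDS)
        got = {}
        for bound, triples in sp.strata.items():
            for a, b, g in triples:
                key = (a.name, b.name)
                assert key not in got, "pair appears in two strata"
                got[key] = (g, bound)
        assert got == want
        # union equals a single window at the max bound
        single = brute_window(baits, targets, self.BOUNDS[-1])
        assert {(a, b) for (a, b) in got} == {(a, b) for a, b, _ in single}

    def test_non_increasing_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            stratify_by_distance(IntervalSet(), IntervalSet(), (0, 10, 10))
        with pytest.raises(ConfigurationError):
            stratify_by_distance(IntervalSet(), IntervalSet(), ())


@given(
    starts=st.lists(st.integers(0, 5000), min_size=1, max_size=30),
    lengths=st.lists(st.integers(1, 500), min_size=1, max_size=30),
    dist=st.integers(0, 2000),
)
def test_window_join_property_matches_oracle(starts, lengths, dist):
    n = min(len(starts), len(lengths))
    a = [iv("chr1", s, s + l, f"a{i}") for i, (s, l) in enumerate(zip(starts[:n], lengths[:n]))]
    b = [iv("chr1", s + 123, s + 123 + l, f"b{i}") for i, (s, l) in enumerate(zip(starts[:n], lengths[:n]))]
    got = {(x.name, y.name, g) for x, y, g in window_join(IntervalSet(a), IntervalSet(b), dist)}
    assert got == brute_window(a, b, dist)


def test_bed_round_trip(tmp_path, rng):
    ivs = random_intervals(rng, 25)
    path = tmp_path / "x.bed"
    write_bed(ivs, path)
    back = read_bed(path)
    assert list(back) == sorted(ivs, key=GenomicInterval.sort_key)


def test_gap_between_cross_chromosome_is_none():
    assert gap_between(iv("chr1", 0, 10), iv("chr2", 0, 10)) is None
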