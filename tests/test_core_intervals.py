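"""Interval arithmetic, BED/bedGraph I/O, 5' coverage and CTSS calling."""

import numpy as np
import pandas as pd
import pytest

from pioneerkit.core_intervals import (
    BedParseError,
    GenomicInterval,
    IntervalIndex,
    SignalTrack,
    call_ctss,
    extend_interval,
    five_prime_coverage,
    merge_within,
    overlaps_any,
    read_bed,
    write_bed,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)

    def test_rejects_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, strand="*")


class TestBedIO:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\ts1\t0\t+\n")
        (iv,) = read_bed(p)
        assert iv == GenomicInterval("chr1", 100, 200, "+", "s1", 0.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\tfoo\t300\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)
        p.write_text("chr1\t300\t200\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p)

    def test_sorted_bed6_roundtrip_is_byte_identical(self, tmp_path, rng):
        records = []
        for i in range(50):
            start = int(rng.integers(0, 10_000))
            records.append(
                GenomicInterval(
                    f"chr{rng.integers(1, 4)}",
                    start,
                    start + int(rng.integers(1, 500)),
                    rng.choice(["+", "-", "."]),
                    f"r{i}",
                    float(rng.integers(0, 100)),
                )
            )
        ivs = sorted(records, key=lambda iv: (iv.chrom, iv.start, iv.end))
        p1, p2 = tmp_path / "x1.bed", tmp_path / "x2.bed"
        write_bed(ivs, p1)
        write_bed(read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestOverlapsAny:
    def test_one_base_overlap(self):
        assert overlaps_any(
            GenomicInterval("chr1", 100, 200), [GenomicInterval("chr1", 199, 300)]
        )

    def test_half_open_adjacency_is_not_overlap(self):
        assert not overlaps_any(
            GenomicInterval("chr1", 100, 200), [GenomicInterval("chr1", 200, 300)]
        )

    def test_empty_subjects(self):
        assert not overlaps_any(GenomicInterval("chr1", 0, 10), [])

    def test_matches_per_base_membership_oracle(self, rng):
        subjects = [
            GenomicInterval("chr1", s, s + int(rng.integers(1, 60)))
            for s in rng.integers(0, 10_000, 200)
        ]
        covered = set()
        for iv in subjects:
            covered.update(range(iv.start, iv.end))
        index = IntervalIndex(subjects)
        for _ in range(1000):
            s = int(rng.integers(0, 10_000))
            q = GenomicInterval("chr1", s, s + int(rng.integers(1, 80)))
            expected = any(b in covered for b in range(q.start, q.end))
            assert overlaps_any(q, index) == expected


class TestMergeWithin:
    def test_gap_at_most_max_gap_merges(self):
        merged = merge_within(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 55, 60)], 50
        )
        assert [(m.start, m.end) for m in merged] == [(0, 60)]

    def test_gap_above_max_gap_does_not_merge(self):
        merged = merge_within(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 61, 70)], 50
        )
        assert len(merged) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_within([GenomicInterval("chr1", 0, 10)], -1)

    def test_idempotent_and_matches_per_base_oracle(self, rng):
        ivs = [
            GenomicInterval("chr1", s, s + int(rng.integers(1, 40)))
            for s in rng.integers(0, 5000, 150)
        ]
        for gap in (0, 10, 50):
            merged = merge_within(ivs, gap)
            again = merge_within(merged, gap)
            assert [(m.start, m.end) for m in merged] == [
                (m.start, m.end) for m in again
            ]
            # oracle: paint bases, close gaps <= gap, read off runs
            hi = max(iv.end for iv in ivs) + gap + 2
            painted = np.zeros(hi, dtype=bool)
            for iv in ivs:
                painted[iv.start : iv.end] = True
            runs = []
            i = 0
            while i < hi:
                if painted[i]:
                    j = i
                    while j < hi:
                        nxt = np.flatnonzero(painted[j + 1 : j + 2 + gap])
                        if len(nxt) == 0:
                            break
                        j = j + 1 + int(nxt[-1])
                    runs.append((i, j + 1))
                    i = j + 1
                else:
                    i += 1
            assert [(m.start, m.end) for m in merged] == runs
            # output disjoint and sorted
            for a, b in zip(merged, merged[1:]):
                assert a.end + gap < b.start


class TestExtendInterval:
    @pytest.mark.parametrize(
        "iv,up,down,expected",
        [
            (GenomicInterval("chr1", 500, 510, "+"), 200, 0, (300, 510)),
            (GenomicInterval("chr1", 500, 510, "-"), 200, 0, (500, 710)),
            (GenomicInterval("chr1", 50, 60, "+"), 200, 0, (0, 60)),
            (GenomicInterval("chr1", 100, 110, "."), 20, 30, (80, 140)),
        ],
    )
    def test_strand_aware_extension(self, iv, up, down, expected):
        ext = extend_interval(iv, upstream=up, downstream=down)
        assert (ext.start, ext.end) == expected

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            extend_interval(GenomicInterval("chr1", 0, 10), upstream=-1)


class TestFivePrimeCoverage:
    def test_plus_read_counts_at_start(self):
        track = five_prime_coverage([GenomicInterval("chr1", 100, 150, "+")])
        assert track.window_array("chr1", 100, 101, "+")[0] == 1

    def test_minus_read_counts_at_last_base(self):
        track = five_prime_coverage([GenomicInterval("chr1", 100, 150, "-")])
        assert track.window_array("chr1", 149, 150, "-")[0] == 1
        assert track.window_array("chr1", 150, 151, "-")[0] == 0

    def test_unstranded_read_rejected(self):
        with pytest.raises(ValueError):
            five_prime_coverage([GenomicInterval("chr1", 100, 150, ".")])

    def test_mass_conservation_per_strand(self, rng):
        n = 10_000
        starts = rng.integers(0, 100_000, n)
        strands = rng.choice(["+", "-"], n)
        frame = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 50, "strand": strands}
        )
        track = five_prime_coverage(frame)
        assert track.total_mass("+") == (strands == "+").sum()
        assert track.total_mass("-") == (strands == "-").sum()
        assert track.total_mass() == n


class TestCallCtss:
    def _track(self, cov: dict, strand="+"):
        t = SignalTrack()
        pos = np.array(sorted(cov))
        t.add_events("chr1", pos, np.array([cov[p] for p in sorted(cov)], float),
                     strand=strand)
        return t

    def test_summit_is_argmax(self):
        t = self._track({100: 5, 101: 9, 102: 3})
        (peak,) = call_ctss(t, [GenomicInterval("chr1", 95, 110, "+")])
        assert peak.summit == 101
        assert peak.total_count == 17

    def test_tie_breaks_leftmost(self):
        t = self._track({100: 5, 102: 5})
        (peak,) = call_ctss(t, [GenomicInterval("chr1", 95, 110, "+")])
        assert peak.summit == 100

    def test_zero_coverage_peak_dropped(self):
        t = self._track({100: 5})
        assert call_ctss(t, [GenomicInterval("chr1", 500, 600, "+")]) == []

    def test_matches_brute_force_argmax(self, rng):
        pos = np.sort(rng.choice(50_000, 3000, replace=False))
        vals = rng.integers(1, 20, 3000).astype(float)
        t = SignalTrack()
        t.add_events("chr1", pos, vals, strand="+")
        lookup = dict(zip(pos.tolist(), vals.tolist()))
        for _ in range(100):
            s = int(rng.integers(0, 49_000))
            peak_iv = GenomicInterval("chr1", s, s + int(rng.integers(10, 400)), "+")
            got = call_ctss(t, [peak_iv])
            window = [lookup.get(p, 0.0) for p in range(peak_iv.start, peak_iv.end)]
            if sum(window) == 0:
                assert got == []
                continue
            best = max(window)
            expect_summit = peak_iv.start + window.index(best)  # leftmost max
            assert got[0].summit == expect_summit
            assert got[0].total_count == pytest.approx(sum(window))

    def test_result_invariant_under_peak_order(self, rng):
        t = SignalTrack()
        t.add_events("chr1", np.arange(0, 1000, 7), 2.0, strand="+")
        peaks = [
            GenomicInterval("chr1", s, s + 50, "+") for s in range(0, 900, 100)
        ]
        a = call_ctss(t, peaks)
        b = call_ctss(t, list(reversed(peaks)))
        assert sorted(p.summit for p in a) == sorted(p.summit for p in b)


class TestSignalTrackBedgraph:
    def test_roundtrip(self, tmp_path, rng):
        t = SignalTrack()
        pos = np.sort(rng.choice(5000, 300, replace=False))
        t.add_events("chr1", pos, rng.integers(1, 9, 300).astype(float))
        p = tmp_path / "t.bedgraph"
        t.to_bedgraph(p)
        back = SignalTrack.from_bedgraph(p)
        assert np.array_equal(
            t.window_array("chr1", 0, 5000), back.window_array("chr1", 0, 5000)
        )
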