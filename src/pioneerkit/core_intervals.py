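"""Genomic-interval data model, BED/bedGraph I/O, and the overlap/merge/coverage engine.

Conventions used throughout the package:

* Coordinates are 0-based, half-open ``[start, end)`` (BED convention).
  Adjacent intervals never overlap.
* Strand is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
* 5' ends: a ``+`` read's 5' position is ``start``; a ``-`` read's is
  ``end - 1`` (the last base of the half-open interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."``; ``name`` and ``score`` are
    optional BED6 payload.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CTSSPeak:
    """A stranded transcription-initiation peak with a single-base summit.

    The summit is the position of maximum 5'-end (CTSS) coverage within the
    peak; ties break to the genomic-leftmost position.
    """

    interval: GenomicInterval
    summit: int
    total_count: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a list of :class:`GenomicInterval`.

    Tab-separated, no header. Malformed lines raise :class:`BedParseError`
    naming the offending 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise BedParseError(f"{path}: line {lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def _format_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path, bed6: bool = True) -> None:
    """Write intervals as sorted BED (BED6 by default), tab-separated."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if bed6:
                cols += [iv.name or ".", _format_score(iv.score), iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Reads as DataFrames (vectorized representation used by the simulator and
# counting code; GenomicInterval stays the scalar boundary type)
# ---------------------------------------------------------------------------

READS_COLUMNS = ["chrom", "start", "end", "strand"]


def reads_to_frame(reads: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "start": np.asarray([r.start for r in reads], dtype=np.int64),
            "end": np.asarray([r.end for r in reads], dtype=np.int64),
            "strand": [r.strand for r in reads],
        }
    )


def frame_to_reads(frame: pd.DataFrame) -> list[GenomicInterval]:
    strands = frame["strand"] if "strand" in frame.columns else ["."] * len(frame)
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(frame["chrom"], frame["start"], frame["end"], strands)
    ]


def as_reads_frame(reads) -> pd.DataFrame:
    """Coerce a read set (DataFrame or sequence of intervals) to a DataFrame."""
    if isinstance(reads, pd.DataFrame):
        if "strand" not in reads.columns:
            reads = reads.assign(strand=".")
        return reads
    return reads_to_frame(list(reads))


# ---------------------------------------------------------------------------
# Overlap index
# ---------------------------------------------------------------------------

class IntervalIndex:
    """Per-chromosome sorted index supporting O(log n) any-overlap queries.

    Intervals are sorted by start; a running maximum of ends makes
    "does anything overlap [s, e)?" a single binary search.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for iv in intervals:
            buckets.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        for key, pairs in buckets.items():
            pairs.sort()
            starts = np.asarray([p[0] for p in pairs], dtype=np.int64)
            ends = np.asarray([p[1] for p in pairs], dtype=np.int64)
            self._by_chrom[key] = (starts, np.maximum.accumulate(ends))

    def _any_overlap_key(self, key: tuple[str, str], start: int, end: int) -> bool:
        entry = self._by_chrom.get(key)
        if entry is None:
            return False
        starts, maxends = entry
        k = int(np.searchsorted(starts, end, side="left"))
        return k > 0 and maxends[k - 1] > start

    def any_overlap(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> bool:
        """True iff some indexed interval shares >=1 base with ``[start, end)``.

        ``strand=None`` ignores strand; a concrete strand restricts to
        intervals on that strand.
        """
        if strand is None:
            return any(
                self._any_overlap_key((chrom, s), start, end) for s in STRANDS
            )
        return self._any_overlap_key((chrom, strand), start, end)


def overlaps_any(
    query: GenomicInterval,
    subjects: "IntervalIndex | Iterable[GenomicInterval]",
    match_strand: bool = False,
) -> bool:
    """True iff ``query`` shares at least one base with any subject interval.

    Half-open semantics: ``[100,200)`` and ``[200,300)`` do not overlap.
    Strand is ignored unless ``match_strand`` is set and the query is
    stranded, in which case only same-strand subjects count.
    """
    index = subjects if isinstance(subjects, IntervalIndex) else IntervalIndex(subjects)
    strand = query.strand if (match_strand and query.strand != ".") else None
    return index.any_overlap(query.chrom, query.start, query.end, strand)


def merge_within(
    intervals: Sequence[GenomicInterval], max_gap: int, stranded: bool = False
) -> list[GenomicInterval]:
    """Merge intervals whose gap (``next.start - prev.end``) is <= ``max_gap``.

    Merging is per chromosome (and per strand when ``stranded``). The output
    is sorted by (chrom, start) and pairwise disjoint; ``max_gap=0`` merges
    overlapping or book-ended intervals only.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    buckets: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand if stranded else ".")
        buckets.setdefault(key, []).append(iv)
    merged: list[GenomicInterval] = []
    for (chrom, strand), ivs in buckets.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    merged.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return merged


def extend_interval(
    interval: GenomicInterval,
    upstream: int = 0,
    downstream: int = 0,
    strand_aware: bool = True,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Extend an interval upstream/downstream of its transcription direction.

    With ``strand_aware``, "upstream" means against the direction of
    transcription, so a ``-`` strand interval extends to the right.
    Unstranded intervals (or ``strand_aware=False``) treat upstream as
    leftward. Results are clipped at 0 (and ``chrom_length`` if given).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("extensions must be >= 0")
    if strand_aware and interval.strand == "-":
        left, right = downstream, upstream
    else:
        left, right = upstream, downstream
    start = max(0, interval.start - left)
    end = interval.end + right
    if chrom_length is not None:
        end = min(end, chrom_length)
    return replace(interval, start=start, end=end)


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

class SignalTrack:
    """Sparse per-base coverage over a genome, optionally partitioned by strand.

    Internally each (chrom, strand) holds sorted position and value arrays;
    absent positions are zero and stored values are strictly positive.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._pending: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}

    # -- construction -------------------------------------------------------
    def add_events(
        self,
        chrom: str,
        positions: np.ndarray,
        weights: np.ndarray | float = 1.0,
        strand: str = ".",
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        if np.isscalar(weights):
            weights = np.full(positions.shape, float(weights))
        else:
            weights = np.asarray(weights, dtype=float)
        self._pending.setdefault((chrom, strand), []).append((positions, weights))

    def _finalize(self, key: tuple[str, str]) -> None:
        chunks = self._pending.pop(key, None)
        if not chunks:
            return
        pos = np.concatenate([c[0] for c in chunks])
        wts = np.concatenate([c[1] for c in chunks])
        if key in self._data:
            pos = np.concatenate([self._data[key][0], pos])
            wts = np.concatenate([self._data[key][1], wts])
        upos, inv = np.unique(pos, return_inverse=True)
        vals = np.zeros(len(upos))
        np.add.at(vals, inv, wts)
        keep = vals > 0
        self._data[key] = (upos[keep], vals[keep])

    def _entry(self, key: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
        if key in self._pending:
            self._finalize(key)
        return self._data.get(key, (np.empty(0, dtype=np.int64), np.empty(0)))

    # -- queries -------------------------------------------------------------
    def keys(self) -> list[tuple[str, str]]:
        ks = set(self._data) | set(self._pending)
        return sorted(ks)

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self.keys()})

    def strands(self) -> list[str]:
        return sorted({s for _, s in self.keys()})

    def total_mass(self, strand: str | None = None) -> float:
        total = 0.0
        for (c, s) in self.keys():
            if strand is not None and s != strand:
                continue
            total += float(self._entry((c, s))[1].sum())
        return total

    def window_array(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> np.ndarray:
        """Dense coverage over ``[start, end)``; strands summed when ``None``.

        ``start`` may be negative and ``end`` past the data; out-of-range
        offsets are zero-filled.
        """
        out = np.zeros(end - start)
        for s in ([strand] if strand is not None else STRANDS):
            pos, vals = self._entry((chrom, s))
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            out[pos[lo:hi] - start] += vals[lo:hi]
        return out

    def positions(self, chrom: str, strand: str = ".") -> tuple[np.ndarray, np.ndarray]:
        return self._entry((chrom, strand))

    def scale(self, factor: float) -> "SignalTrack":
        out = SignalTrack()
        for key in self.keys():
            pos, vals = self._entry(key)
            out.add_events(key[0], pos, vals * factor, strand=key[1])
        return out

    # -- bedGraph ------------------------------------------------------------
    def to_bedgraph(self, path, strand: str | None = None) -> None:
        """Write as 4-column bedGraph (0-based half-open), merging equal runs."""
        with open(path, "w") as fh:
            for (chrom, s) in self.keys():
                if strand is not None and s != strand:
                    continue
                pos, vals = self._entry((chrom, s))
                i = 0
                while i < len(pos):
                    j = i
                    while (
                        j + 1 < len(pos)
                        and pos[j + 1] == pos[j] + 1
                        and vals[j + 1] == vals[i]
                    ):
                        j += 1
                    v = vals[i]
                    vstr = str(int(v)) if float(v).is_integer() else repr(float(v))
                    fh.write(f"{chrom}\t{pos[i]}\t{pos[j] + 1}\t{vstr}\n")
                    i = j + 1

    @classmethod
    def from_bedgraph(cls, path, strand: str = ".") -> "SignalTrack":
        track = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise BedParseError(f"{path}: line {lineno}: expected 4 columns")
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
                track.add_events(
                    chrom, np.arange(start, end), value, strand=strand
                )
        return track


def five_prime_coverage(reads) -> SignalTrack:
    """Per-strand 5'-end coverage from stranded reads.

    A ``+`` read contributes at ``start``; a ``-`` read at ``end - 1``.
    Unstranded reads are rejected — CTSS quantification requires strand.
    Total mass per strand equals the read count on that strand.
    """
    frame = as_reads_frame(reads)
    if len(frame) and (frame["strand"] == ".").any():
        raise ValueError("five_prime_coverage requires stranded reads")
    track = SignalTrack()
    for (chrom, strand), grp in frame.groupby(["chrom", "strand"], sort=False):
        if strand == "+":
            pos = grp["start"].to_numpy(dtype=np.int64)
        else:
            pos = grp["end"].to_numpy(dtype=np.int64) - 1
        track.add_events(chrom, pos, 1.0, strand=strand)
    return track


def call_ctss(track: SignalTrack, peaks: Sequence[GenomicInterval]) -> list[CTSSPeak]:
    """Summit-call CTSS peaks: summit = argmax 5' coverage within the peak.

    Ties break to the genomic-leftmost position. Peaks with zero in-peak
    coverage are dropped (logged). Stranded peaks are quantified on their
    own strand; unstranded peaks pool both strands.
    """
    out: list[CTSSPeak] = []
    for peak in peaks:
        strand = None if peak.strand == "." else peak.strand
        window = track.window_array(peak.chrom, peak.start, peak.end, strand=strand)
        total = float(window.sum())
        if total <= 0:
            logger.info(
                "dropping zero-coverage peak %s:%d-%d(%s)",
                peak.chrom, peak.start, peak.end, peak.strand,
            )
            continue
        summit = peak.start + int(np.argmax(window))  # argmax -> leftmost max
        out.append(CTSSPeak(interval=peak, summit=summit, total_count=total))
    return out
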