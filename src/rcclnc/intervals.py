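"""Minimal genomic-interval engine.

All coordinates are 0-based, half-open ([start, end)), the BED convention.
Tables printed 1-based inclusive must be converted on ingestion
(:func:`from_one_based`). Only three primitives are needed downstream:
TSS derivation, nearest-feature distance from a point, and half-open
overlap counting — all implemented on sorted numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """One interval: chrom, [start, end), strand, optional score and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start: `start` on +, `end - 1` on -.

        Unstranded intervals have no TSS.
        """
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise ValueError(
            f"TSS undefined for unstranded interval {self.chrom}:{self.start}-{self.end}"
        )


def tss_of(interval: GenomicInterval) -> int:
    """Strand-aware transcription start position of ``interval``."""
    return interval.tss


def from_one_based(chrom: str, start1: int, end1: int, strand: str = ".") -> GenomicInterval:
    """Convert a 1-based inclusive coordinate pair (as printed in tables)."""
    return GenomicInterval(chrom, start1 - 1, end1, strand)


def shift(interval: GenomicInterval, offset: int) -> GenomicInterval:
    return GenomicInterval(
        interval.chrom, interval.start + offset, interval.end + offset,
        interval.strand, interval.score, interval.name,
    )


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True if ``inner`` lies wholly inside ``outer`` (same chrom)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def intersection_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlapping bp between two intervals (0 if disjoint or cross-chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalIndex:
    """Per-chromosome sorted-array index over a set of intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            s_sorted = starts[order]
            e_aligned = ends[order]
            self._by_chrom[chrom] = {
                "starts": s_sorted,
                "ends_by_start": e_aligned,
                # running max of ends lets nearest/overlap queries handle
                # intervals that overlap each other
                "cummax_end": np.maximum.accumulate(e_aligned),
                "ends_sorted": np.sort(ends),
            }

    def __len__(self) -> int:
        return len(self.intervals)

    def nearest_distance(self, chrom: str, pos: int) -> int | None:
        """Unsigned bp distance from point ``pos`` to the nearest interval.

        0 when the point falls inside an interval; None when the chromosome
        carries no interval. Distance to an interval [s, e) is ``s - pos``
        upstream and ``pos - (e - 1)`` downstream (last covered base).
        """
        data = self._by_chrom.get(chrom)
        if data is None:
            return None
        starts, cummax = data["starts"], data["cummax_end"]
        idx = int(np.searchsorted(starts, pos, side="right"))
        best: int | None = None
        if idx > 0:
            reach = int(cummax[idx - 1])
            if reach > pos:
                return 0
            best = pos - (reach - 1)
        if idx < len(starts):
            d = int(starts[idx]) - pos
            best = d if best is None else min(best, d)
        return best

    def count_overlaps(self, query: GenomicInterval) -> int:
        """Number of indexed intervals intersecting ``query`` by >= 1 bp."""
        data = self._by_chrom.get(query.chrom)
        if data is None:
            return 0
        n_start_before_qend = int(
            np.searchsorted(data["starts"], query.end, side="left")
        )
        n_end_at_or_before_qstart = int(
            np.searchsorted(data["ends_sorted"], query.start, side="right")
        )
        return n_start_before_qend - n_end_at_or_before_qstart

    def overlap_bp(self, query: GenomicInterval) -> int:
        """Total bp of ``query`` covered by any indexed interval (clipped union)."""
        data = self._by_chrom.get(query.chrom)
        if data is None:
            return 0
        starts = data["starts"]
        ends = data["ends_by_start"]
        lo = int(np.searchsorted(data["cummax_end"], query.start, side="right"))
        hi = int(np.searchsorted(starts, query.end, side="left"))
        covered = 0
        cursor = query.start
        for i in range(lo, hi):
            s = max(int(starts[i]), cursor)
            e = min(int(ends[i]), query.end)
            if e > s:
                covered += e - s
                cursor = e
        return covered


def overlap_count(
    queries: Sequence[GenomicInterval], track: Iterable[GenomicInterval]
) -> tuple[np.ndarray, dict]:
    """Per-query count of track intervals intersecting it, plus totals."""
    index = IntervalIndex(track)
    counts = np.array([index.count_overlaps(q) for q in queries], dtype=np.int64)
    totals = {
        "n_queries": len(counts),
        "n_with_overlap": int((counts > 0).sum()),
        "total_overlaps": int(counts.sum()),
    }
    return counts, totals


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file (name col 4, score col 5, strand col 6)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, score, name))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )
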