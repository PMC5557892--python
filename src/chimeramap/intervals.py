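"""Genomic interval primitives and single-linkage interval clustering.

Coordinates are 0-based, half-open throughout the package; GTF input
(1-based inclusive) is converted at parse time and BED output is written
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class IntervalCluster:
    """Union span of single-linkage-merged intervals sharing a key."""

    key: Hashable
    span: GenomicInterval
    members: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


def cluster_intervals(
    records: Iterable,
    same_key: Callable[[object], Hashable],
    interval_of: Callable[[object], GenomicInterval] = lambda r: r,
    max_gap: int = 0,
) -> list[IntervalCluster]:
    """Single-linkage merge of intervals sharing a key and strand.

    Records whose intervals overlap, or whose gap is at most ``max_gap``
    (half-open adjacency, gap 0, does not merge with ``max_gap=0``), are
    placed in one cluster.  The cluster span is the union of member
    intervals.  Output is a partition of the input.
    """
    buckets: dict[tuple, list] = {}
    for rec in records:
        iv = interval_of(rec)
        buckets.setdefault((same_key(rec), iv.chrom, iv.strand), []).append(rec)

    clusters: list[IntervalCluster] = []
    for (key, chrom, strand), recs in sorted(
        buckets.items(), key=lambda kv: (str(kv[0][0]), kv[0][1], kv[0][2])
    ):
        recs = sorted(recs, key=lambda r: (interval_of(r).start, interval_of(r).end))
        cur_members: list = []
        cur_start = cur_end = None
        for rec in recs:
            iv = interval_of(rec)
            # merge on strict overlap, or when the uncovered gap is < max_gap
            # (half-open adjacency therefore does not merge at max_gap=0)
            if cur_end is not None and iv.start < cur_end + max_gap + (max_gap > 0):
                cur_members.append(rec)
                cur_end = max(cur_end, iv.end)
            else:
                if cur_members:
                    clusters.append(
                        IntervalCluster(
                            key,
                            GenomicInterval(chrom, cur_start, cur_end, strand),
                            cur_members,
                        )
                    )
                cur_members = [rec]
                cur_start, cur_end = iv.start, iv.end
        if cur_members:
            clusters.append(
                IntervalCluster(
                    key, GenomicInterval(chrom, cur_start, cur_end, strand), cur_members
                )
            )
    return clusters


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Union of plain intervals (per chrom/strand)."""
    clusters = cluster_intervals(intervals, same_key=lambda _: None, max_gap=max_gap)
    return sorted(c.span for c in clusters)
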