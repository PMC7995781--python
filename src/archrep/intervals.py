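"""Stranded genomic intervals and disjoint interval-set arithmetic.

All coordinates are 0-based half-open throughout the package; file readers
convert from whatever convention the on-disk format uses.  Interval sets
(:class:`RegionSet`) are kept fully merged — sorted, pairwise disjoint and
non-adjacent — so that total length is simply the sum of interval lengths
and coverage fractions are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "merge_intervals",
    "subtract_intervals",
    "overlap_bp",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome (or sequence) name.
    start, end : int
        0-based half-open coordinates; ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} (expected '+' or '-')")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _as_array(intervals: Iterable[tuple[int, int]] | np.ndarray) -> np.ndarray:
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals)
    if arr.size == 0:
        return arr.reshape(0, 2).astype(np.int64)
    return arr.astype(np.int64).reshape(-1, 2)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Merge (start, end) pairs into a sorted, disjoint, non-adjacent array.

    Adjacent intervals (``a.end == b.start``) are coalesced, so the result
    is the minimal representation of the covered base set.
    """
    arr = _as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out: list[list[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(
    span: tuple[int, int], covered: np.ndarray | Iterable[tuple[int, int]]
) -> np.ndarray:
    """Bases of ``span`` not covered by ``covered`` (which must be merged)."""
    s0, e0 = int(span[0]), int(span[1])
    out: list[tuple[int, int]] = []
    cursor = s0
    for s, e in _as_array(covered):
        s, e = max(int(s), s0), min(int(e), e0)
        if e <= s:
            continue
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < e0:
        out.append((cursor, e0))
    return _as_array(out)


def overlap_bp(
    a: np.ndarray | Iterable[tuple[int, int]],
    b: np.ndarray | Iterable[tuple[int, int]],
) -> int:
    """Total bases covered by both ``a`` and ``b`` (each merged internally)."""
    a = merge_intervals(_as_array(a))
    b = merge_intervals(_as_array(b))
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            total += int(e - s)
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class RegionSet:
    """A merged, ordered set of intervals on one chromosome and strand.

    Invariants: intervals sorted by start, pairwise disjoint and
    non-adjacent.  Constructed via :meth:`from_intervals`, which merges.
    """

    chrom: str
    strand: str
    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    @classmethod
    def from_intervals(
        cls, chrom: str, strand: str, intervals: Iterable[tuple[int, int]]
    ) -> "RegionSet":
        return cls(chrom=chrom, strand=strand, intervals=merge_intervals(intervals))

    @property
    def total_length(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals[:, 1] - self.intervals[:, 0]).sum())

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return len(self.intervals) > 0

    def __iter__(self) -> Iterator[GenomicInterval]:
        for s, e in self.intervals:
            yield GenomicInterval(self.chrom, int(s), int(e), self.strand)

    def coverage_mask(self, span: tuple[int, int]) -> np.ndarray:
        """Boolean per-base mask of this set over ``span`` (oracle helper)."""
        s0, e0 = span
        mask = np.zeros(e0 - s0, dtype=bool)
        for s, e in self.intervals:
            s, e = max(int(s) - s0, 0), min(int(e) - s0, e0 - s0)
            if e > s:
                mask[s:e] = True
        return mask
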