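"""Half-open intervals on a circular coordinate system.

All coordinates in this package are 0-based positions on the nicked strand
of a circular plasmid, read 5'->3'. An interval ``[start, end)`` may wrap
past the origin (``end <= start``); its length is ``(end - start) mod L``
where ``L`` is the circle length. The full circle is not representable as a
single interval — excision of an entire molecule is treated as an error
upstream, so this is never a practical limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence


@dataclass(frozen=True)
class CircularInterval:
    """A half-open arc ``[start, end)`` on a circle.

    Parameters
    ----------
    start : int
        Inclusive 0-based start position.
    end : int
        Exclusive end position; ``end <= start`` means the arc wraps past
        the origin.

    The circle length is not stored; methods that need it take ``length``
    explicitly so intervals remain cheap value objects.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in interval [{self.start}, {self.end})")
        if self.start == self.end:
            raise ValueError("empty (or full-circle) interval is not representable")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, circle: int) -> int:
        n = (self.end - self.start) % circle
        if n == 0:
            raise ValueError("interval start == end mod circle length")
        return n

    def contains(self, pos: int, circle: int) -> bool:
        pos %= circle
        return (pos - self.start) % circle < self.length(circle)

    def positions(self, circle: int) -> Iterator[int]:
        start = self.start % circle
        for i in range(self.length(circle)):
            yield (start + i) % circle

    def overlaps(self, other: "CircularInterval", circle: int) -> bool:
        return (
            self.contains(other.start, circle)
            or other.contains(self.start, circle)
        )

    def shifted(self, k: int, circle: int) -> "CircularInterval":
        """Interval rotated by ``k`` positions around the circle."""
        return CircularInterval((self.start + k) % circle, (self.end + k) % circle)

    @classmethod
    def from_span(cls, first: int, last: int, circle: int) -> "CircularInterval":
        """Interval covering the inclusive span ``first..last`` (circular).

        Raises if the span would cover the full circle.
        """
        return cls(first % circle, (last + 1) % circle)


def circular_distance(a: int, b: int, circle: int) -> int:
    """Number of steps from ``a`` to ``b`` moving 3' (increasing coordinates)."""
    return (b - a) % circle


def signed_distance(a: int, b: int, circle: int) -> int:
    """Signed shortest offset from ``a`` to ``b``; positive means 3' of ``a``."""
    d = (b - a) % circle
    return d if d <= circle // 2 else d - circle


def merge_overlapping(intervals: Sequence[CircularInterval], circle: int) -> list[CircularInterval]:
    """Merge a set of possibly-overlapping circular intervals.

    Returns disjoint intervals sorted by start. Used to collapse hairpin
    hits into protection masks.
    """
    if not intervals:
        return []
    covered = sorted({p for iv in intervals for p in iv.positions(circle)})
    if len(covered) == circle:
        raise ValueError("merged intervals cover the entire circle")
    # break the circle at an uncovered position, then do linear run-merging
    covered_set = set(covered)
    anchor = next(p for p in range(circle) if p not in covered_set)
    rel = sorted((p - anchor) % circle for p in covered)
    out: list[CircularInterval] = []
    run_start = rel[0]
    prev = rel[0]
    for r in rel[1:]:
        if r != prev + 1:
            out.append(CircularInterval((run_start + anchor) % circle, (prev + 1 + anchor) % circle))
            run_start = r
        prev = r
    out.append(CircularInterval((run_start + anchor) % circle, (prev + 1 + anchor) % circle))
    return sorted(out, key=lambda iv: iv.start)
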