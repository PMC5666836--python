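"""Region objects shared by the AR scanner and the CBR detector.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Conversion to the 1-based inclusive convention used by some annotation
sources happens only at the I/O boundary (see :mod:`phytamyloid.sequence_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Region:
    """An interval called on a protein sequence.

    Parameters
    ----------
    start, end : int
        0-based half-open residue coordinates, ``0 <= start < end``.
    kind : str
        ``"AR"`` for a PSSM-predicted amyloidogenic region, ``"CBR"`` for a
        compositionally biased region.
    residue_class : str
        Residue class of a CBR (e.g. ``"QN"``, ``"E"``, ``"IWYF"``); empty
        for ARs.
    score : float
        For ARs the maximum positive window score inside the region; for
        CBRs the log10 binomial tail probability.
    """

    start: int
    end: int
    kind: str
    residue_class: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.kind not in ("AR", "CBR"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of residues shared by two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals.

    Touching intervals ([0,5) and [5,9)) are merged.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def total_length(intervals: list[tuple[int, int]]) -> int:
    """Total residue count of a set of intervals after unioning overlaps."""
    return sum(e - s for s, e in union_intervals(intervals))


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Intervals of ``[0, length)`` not covered by ``intervals``."""
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for s, e in union_intervals(intervals):
        s, e = max(0, s), min(length, e)
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        gaps.append((cursor, length))
    return gaps
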