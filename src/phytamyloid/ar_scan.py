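"""Sliding-window PSSM scanner for short amyloidogenic regions (ARs).

A position-specific scoring matrix of window length ``W`` (hexapeptides by
convention) assigns every length-``W`` window a score; windows at or above
the matrix threshold are amyloid-positive. Overlapping or directly adjacent
positive windows are merged into maximal regions, and — because very short
hits (6–9 residues) carry little specificity for full-length protein
amyloidogenicity — only merged regions of at least ``min_len`` residues
(default 10) are reported. A protein is flagged potentially amyloidogenic
iff at least one such region survives.

The scoring weights are input data: any matrix in the documented TSV format
can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .regions import Region
from .sequence_io import CANONICAL_AA, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class ScoringMatrix:
    """Per-position, per-residue window scores plus a positivity threshold.

    ``scores`` has shape (W, 20) with residue columns ordered as
    ``ACDEFGHIKLMNPQRSTVWY``; a window scores the sum over its positions of
    the matching entries, and is positive when the sum is >= ``threshold``.
    """

    window_length: int
    scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window length must be >= 1")
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (self.window_length, 20):
            raise ValueError(
                f"scores must have shape ({self.window_length}, 20), "
                f"got {scores.shape}"
            )
        object.__setattr__(self, "scores", scores)

    @classmethod
    def indicator(cls, residues: str, window_length: int = 6,
                  threshold: float = 4.0) -> "ScoringMatrix":
        """Matrix scoring 1 for the given residues at every position, else 0.

        Useful for tests and planted-region simulation; not a trained PSSM.
        """
        scores = np.zeros((window_length, 20))
        for aa in residues:
            scores[:, _AA_INDEX[aa]] = 1.0
        return cls(window_length=window_length, scores=scores, threshold=threshold)


def read_matrix(path: str | Path) -> ScoringMatrix:
    """Read a scoring matrix TSV.

    First line: ``W <int> T <float>``; then one row per residue:
    residue letter followed by W scores. All 20 canonical residues must be
    present.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "W" or header[2] != "T":
            raise ValueError(f"{path}: matrix header must be 'W <int> T <float>'")
        w, threshold = int(header[1]), float(header[3])
        scores = np.full((w, 20), np.nan)
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            aa, values = parts[0], parts[1:]
            if aa not in _AA_INDEX:
                raise ValueError(f"{path}:{lineno}: unknown residue {aa!r}")
            if len(values) != w:
                raise ValueError(f"{path}:{lineno}: expected {w} scores")
            scores[:, _AA_INDEX[aa]] = [float(v) for v in values]
    if np.isnan(scores).any():
        missing = [aa for aa, i in _AA_INDEX.items() if np.isnan(scores[0, i])]
        raise ValueError(f"{path}: missing scores for residues {missing}")
    return ScoringMatrix(window_length=w, scores=scores, threshold=threshold)


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"W {matrix.window_length} T {matrix.threshold!r}\n")
        for aa, i in _AA_INDEX.items():
            row = "\t".join(repr(float(v)) for v in matrix.scores[:, i])
            fh.write(f"{aa}\t{row}\n")


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[aa] for aa in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"noncanonical residue {exc.args[0]!r} in sequence") from exc


def score_window(window: str, matrix: ScoringMatrix) -> float:
    """Score one window: sum over positions of scores[position][residue]."""
    if len(window) != matrix.window_length:
        raise ValueError(
            f"window length {len(window)} != matrix window {matrix.window_length}"
        )
    idx = _encode(window)
    return float(matrix.scores[np.arange(matrix.window_length), idx].sum())


def scan_protein(
    record: ProteinRecord, matrix: ScoringMatrix
) -> list[tuple[int, float]]:
    """All positive windows of a protein as (start, score), ascending start.

    Proteins shorter than the window yield an empty list.
    """
    w = matrix.window_length
    n = record.length
    if n < w:
        return []
    idx = _encode(record.sequence)
    # scores[pos, residue] gathered per window via a strided view
    per_pos = matrix.scores[np.arange(w)[:, None], idx[None, :]]  # (w, n)
    window_scores = np.zeros(n - w + 1)
    for j in range(w):
        window_scores += per_pos[j, j : j + n - w + 1]
    starts = np.nonzero(window_scores >= matrix.threshold)[0]
    return [(int(s), float(window_scores[s])) for s in starts]


def merge_windows(
    windows: list[tuple[int, float]], window_length: int
) -> list[Region]:
    """Union overlapping or directly adjacent positive windows into regions.

    Region score is the maximum member-window score. Output regions are
    pairwise disjoint and non-adjacent.
    """
    if not windows:
        return []
    regions: list[Region] = []
    start, end = windows[0][0], windows[0][0] + window_length
    best = windows[0][1]
    for s, score in windows[1:]:
        if s <= end:  # overlap or directly adjacent
            end = max(end, s + window_length)
            best = max(best, score)
        else:
            regions.append(Region(start, end, "AR", "", best))
            start, end, best = s, s + window_length, score
    regions.append(Region(start, end, "AR", "", best))
    return regions


def filter_min_length(regions: list[Region], min_len: int = 10) -> list[Region]:
    """Drop regions shorter than ``min_len`` residues (length >= min_len kept)."""
    return [r for r in regions if r.length >= min_len]


def predict_ars(
    record: ProteinRecord, matrix: ScoringMatrix, min_len: int = 10
) -> list[Region]:
    """Scan, merge, and length-filter: the final AR calls for one protein.

    The protein is flagged potentially amyloidogenic iff the result is
    non-empty.
    """
    windows = scan_protein(record, matrix)
    return filter_min_length(merge_windows(windows, matrix.window_length), min_len)
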