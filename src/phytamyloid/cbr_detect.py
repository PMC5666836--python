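"""Detection of compositionally biased regions (CBRs) by binomial tail probability.

A CBR is a stretch statistically over-enriched in a residue class (Q/N,
E, or any user-defined class) relative to the background composition of the
proteome. For a candidate stretch of length ``L`` containing ``k`` class
members, enrichment is scored by the one-sided binomial upper tail

    P(X >= k),  X ~ Binomial(L, p)

with ``p`` the background frequency of the class. Stretches with tail
probability below a stringent threshold (default 1e-8) are reported.
Candidates are anchored — they start and end on a class member, which loses
nothing (trimming a non-member end always lowers the tail probability) and
caps the candidate count at O(m^2) for m member occurrences. Among all
sub-threshold candidates the detector greedily takes the lowest-probability
one (ties: longest, then leftmost), discards everything overlapping it, and
repeats; reported regions are therefore disjoint.

A protein is flagged potentially amyloidogenic on compositional grounds iff
it carries at least one Q/N-rich or E-rich CBR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .regions import Region
from .sequence_io import ProteinRecord

_LN10 = math.log(10.0)
# pair-axis chunk bounding the padded log-sum-exp workspace (~300 MB worst case)
_CHUNK = 4096


@dataclass(frozen=True)
class ResidueClass:
    """A residue class with its background frequency.

    ``background_p`` is the proteome-wide frequency of class members; it
    must be set (via :func:`background_frequencies` or explicitly) before
    scanning.
    """

    name: str
    members: frozenset[str]
    background_p: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("residue class must have at least one member")
        if self.background_p is not None and not (0.0 < self.background_p < 1.0):
            raise ValueError("background_p must lie strictly in (0, 1)")

    @classmethod
    def from_letters(cls, letters: str, background_p: float | None = None) -> "ResidueClass":
        return cls(name=letters, members=frozenset(letters), background_p=background_p)


#: Classes screened by default: Q/N-rich and E-rich stretches are the
#: amyloid-prone compositional biases; I/W/Y/F captures hydrophobic bias.
DEFAULT_CLASSES = (
    ResidueClass.from_letters("QN"),
    ResidueClass.from_letters("E"),
)


@dataclass(frozen=True)
class CbrParams:
    """Detector parameters: tail-probability threshold, strict (<) cut."""

    threshold: float = 1e-8
    min_anchored: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")

    @property
    def log10_threshold(self) -> float:
        return math.log10(self.threshold)


def log_binomial_tail(L, k, p):
    """log10 P(X >= k) for X ~ Binomial(L, p), elementwise on arrays.

    Computed as a log-sum-exp over exact log pmf terms (gammaln-based), so
    it stays finite and accurate (~1e-12 relative on the probability) even
    where the tail underflows double precision. ``k = 0`` returns exactly 0.
    """
    L_arr = np.asarray(L, dtype=np.int64)
    k_arr = np.asarray(k, dtype=np.int64)
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if np.any(L_arr < 1) or np.any(k_arr < 0) or np.any(k_arr > L_arr):
        raise ValueError("need L >= 1 and 0 <= k <= L")
    scalar = L_arr.ndim == 0
    L_arr = np.atleast_1d(L_arr)
    k_arr = np.atleast_1d(k_arr)
    out = np.empty(L_arr.shape, dtype=float)
    for lo in range(0, L_arr.size, _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        out[sl] = _log10_tail_block(L_arr[sl], k_arr[sl], p)
    out[k_arr == 0] = 0.0
    return float(out[0]) if scalar else out


def _log10_tail_block(L: np.ndarray, k: np.ndarray, p: float) -> np.ndarray:
    nterm = L - k + 1
    width = int(nterm.max())
    j = k[:, None] + np.arange(width)[None, :]
    valid = j <= L[:, None]
    j = np.minimum(j, L[:, None])  # clamp so gammaln args stay positive
    logpmf = (
        gammaln(L + 1)[:, None]
        - gammaln(j + 1)
        - gammaln(L[:, None] - j + 1)
        + j * math.log(p)
        + (L[:, None] - j) * math.log1p(-p)
    )
    logpmf[~valid] = -np.inf
    peak = logpmf.max(axis=1)
    with np.errstate(under="ignore"):
        total = np.exp(logpmf - peak[:, None]).sum(axis=1)
    return (peak + np.log(total)) / _LN10


def background_frequencies(
    proteome: Sequence[ProteinRecord], classes: Iterable[ResidueClass]
) -> list[ResidueClass]:
    """Fill each class's background_p from proteome-wide residue counts.

    background_p = (class-member residues) / (total residues) over the valid
    proteome. A class absent from the proteome has p = 0, which the binomial
    model cannot use — an error asks the caller to supply a floor instead.
    """
    if not proteome:
        raise ValueError("cannot estimate background from an empty proteome")
    counts: dict[str, int] = {}
    total = 0
    for rec in proteome:
        total += rec.length
        for aa in rec.sequence:
            counts[aa] = counts.get(aa, 0) + 1
    filled = []
    for cls in classes:
        members_count = sum(counts.get(aa, 0) for aa in cls.members)
        if members_count == 0:
            raise ValueError(
                f"class {cls.name!r} has zero background frequency in this "
                "proteome; supply an explicit background_p floor"
            )
        if members_count == total:
            raise ValueError(
                f"class {cls.name!r} covers the whole proteome (p = 1); "
                "the binomial model is degenerate"
            )
        filled.append(replace(cls, background_p=members_count / total))
    return filled


def find_cbrs(
    record: ProteinRecord, cls: ResidueClass, params: CbrParams = CbrParams()
) -> list[Region]:
    """Disjoint CBR calls for one protein and one residue class.

    Returns regions sorted by start; each region's ``score`` is the log10
    tail probability (always < log10 threshold).
    """
    if cls.background_p is None:
        raise ValueError(f"class {cls.name!r} has no background_p set")
    pos = np.array(
        [i for i, aa in enumerate(record.sequence) if aa in cls.members],
        dtype=np.int64,
    )
    m = pos.size
    if m == 0:
        return []
    ii, jj = np.triu_indices(m)
    starts = pos[ii]
    ends = pos[jj] + 1
    L = ends - starts
    k = jj - ii + 1
    log10t = log_binomial_tail(L, k, cls.background_p)
    below = log10t < params.log10_threshold
    if not below.any():
        return []
    cand = sorted(
        zip(log10t[below], -L[below], starts[below], ends[below]),
        key=lambda c: (c[0], c[1], c[2]),
    )
    chosen: list[tuple[int, int, float]] = []
    for score, negL, s, e in cand:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((int(s), int(e), float(score)))
    chosen.sort()
    return [
        Region(s, e, "CBR", cls.name, score) for s, e, score in chosen
    ]


def is_potentially_amyloidogenic_cbr(
    record: ProteinRecord, regions_by_class: Mapping[str, Sequence[Region]]
) -> bool:
    """True iff the protein carries >= 1 CBR in class QN or class E."""
    return bool(regions_by_class.get("QN")) or bool(regions_by_class.get("E"))
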