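"""Seeded synthetic proteomes with planted regions and annotations.

The generator draws background sequence i.i.d. from a residue-frequency
profile (uniform 0.05 per residue by default), then plants, in a controlled
fraction of proteins, (i) compositionally biased segments whose residues are
class members with a chosen purity and (ii) high-scoring PSSM window runs.
Annotation tables can be drawn with chosen term sizes and a planted
enrichment fold among the proteins carrying planted regions. Everything is
driven by a single integer seed, so each stage of the screen can be tested
for recovery of known truth without any external data.

What this emulates — and what it does not: background composition,
localized compositional bias, PSSM-positive stretches and term enrichment
are reproduced with known truth; real proteomes' gene families, domain
architecture, length/composition correlations and annotation density are
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ar_scan import ScoringMatrix, _AA_INDEX
from .regions import Region
from .sequence_io import CANONICAL_AA, AnnotationTable, GenomeSource, ProteinRecord


@dataclass(frozen=True)
class PlantedCbr:
    """Plant a biased segment: class members appear with probability ``purity``."""

    residue_class: str
    purity: float
    length: int
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedAr:
    """Plant a run of ``n_windows`` consecutive PSSM-positive windows."""

    matrix: ScoringMatrix
    n_windows: int
    fraction: float


@dataclass(frozen=True)
class AnnotationPlan:
    """Term assignment plan: sizes drawn uniformly from ``term_size_range``.

    The first ``len(enriched_folds)`` terms are planted enriched: proteins
    carrying a planted region receive the corresponding fold weight when
    term members are sampled.
    """

    n_terms: int
    term_size_range: tuple[int, int] = (20, 100)
    enriched_folds: tuple[float, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    n_proteins: int
    length_range: tuple[int, int] = (100, 600)
    background: dict[str, float] | None = None  # None = uniform 0.05
    planted_cbrs: tuple[PlantedCbr, ...] = ()
    planted_ars: tuple[PlantedAr, ...] = ()
    annotation_plan: AnnotationPlan | None = None
    seed: int = 0


@dataclass
class TruthTable:
    """Ground truth of one synthetic proteome."""

    planted_regions: dict[str, list[Region]] = field(default_factory=dict)
    enriched_terms: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def flagged(self) -> set[str]:
        return {pid for pid, regions in self.planted_regions.items() if regions}


def _background_vector(background: dict[str, float] | None) -> np.ndarray:
    if background is None:
        return np.full(20, 0.05)
    vec = np.zeros(20)
    for aa, freq in background.items():
        vec[_AA_INDEX[aa]] = freq
    if not np.isclose(vec.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    return vec / vec.sum()


def qn_background(class_p: float, members: str = "QN") -> dict[str, float]:
    """Background profile with the given total frequency on ``members``.

    Member residues share ``class_p`` equally; the remaining mass is spread
    uniformly over the other residues.
    """
    others = [aa for aa in CANONICAL_AA if aa not in members]
    profile = {aa: class_p / len(members) for aa in members}
    profile.update({aa: (1 - class_p) / len(others) for aa in others})
    return profile


def _ar_stretch(matrix: ScoringMatrix, n_windows: int) -> str:
    """A stretch of length W+n_windows-1 whose every window scores >= threshold.

    Each stretch position takes the residue maximizing its summed score over
    all matrix positions it occupies across the planted windows; raises if
    the matrix admits no such stretch.
    """
    w = matrix.window_length
    length = w + n_windows - 1
    residues = []
    for t in range(length):
        starts = range(max(0, t - w + 1), min(t, n_windows - 1) + 1)
        column = np.sum([matrix.scores[t - i] for i in starts], axis=0)
        residues.append(CANONICAL_AA[int(np.argmax(column))])
    stretch = "".join(residues)
    for i in range(n_windows):
        window = stretch[i : i + w]
        score = sum(matrix.scores[j, _AA_INDEX[aa]] for j, aa in enumerate(window))
        if score < matrix.threshold:
            raise ValueError(
                "scoring matrix admits no stretch with every window positive"
            )
    return stretch


def _place_segment(
    rng: np.random.Generator, length: int, seg_len: int,
    occupied: list[tuple[int, int]], tries: int = 200,
) -> tuple[int, int]:
    if seg_len > length:
        raise ValueError(
            f"planted segment of length {seg_len} does not fit a protein of "
            f"length {length}"
        )
    for _ in range(tries):
        start = int(rng.integers(0, length - seg_len + 1))
        end = start + seg_len
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start, end
    raise ValueError("could not place planted segment without overlap")


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], AnnotationTable, TruthTable]:
    """Generate a synthetic proteome, annotations, and its truth table.

    Deterministic for a fixed spec (including the seed). Protein ids are
    ``sp|P000000``-style running accessions ``syn0001`` ...
    """
    rng = np.random.default_rng(spec.seed)
    bg = _background_vector(spec.background)
    aa_array = np.frombuffer(CANONICAL_AA.encode(), dtype="S1").astype("U1")
    truth = TruthTable(seed=spec.seed)
    records: list[ProteinRecord] = []

    n = spec.n_proteins
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=n)

    # which proteins receive each plant: exactly round(fraction * n) of them
    cbr_targets = [
        set(rng.choice(n, size=int(round(plant.fraction * n)), replace=False).tolist())
        for plant in spec.planted_cbrs
    ]
    ar_targets = [
        set(rng.choice(n, size=int(round(plant.fraction * n)), replace=False).tolist())
        for plant in spec.planted_ars
    ]

    for i in range(n):
        length = int(lengths[i])
        seq = rng.choice(aa_array, size=length, p=bg)
        pid = f"syn{i + 1:04d}"
        truth.planted_regions[pid] = []
        occupied: list[tuple[int, int]] = []
        for plant, targets in zip(spec.planted_cbrs, cbr_targets):
            if i not in targets:
                continue
            start, end = _place_segment(rng, length, plant.length, occupied)
            members = np.array(sorted(plant.residue_class), dtype="U1")
            member_idx = [_AA_INDEX[aa] for aa in members]
            non_bg = bg.copy()
            non_bg[member_idx] = 0.0
            non_bg = non_bg / non_bg.sum()
            is_member = rng.random(plant.length) < plant.purity
            segment = np.where(
                is_member,
                rng.choice(members, size=plant.length),
                rng.choice(aa_array, size=plant.length, p=non_bg),
            )
            seq[start:end] = segment
            truth.planted_regions[pid].append(
                Region(start, end, "CBR", plant.residue_class)
            )
        for plant, targets in zip(spec.planted_ars, ar_targets):
            if i not in targets:
                continue
            stretch = _ar_stretch(plant.matrix, plant.n_windows)
            start, end = _place_segment(rng, length, len(stretch), occupied)
            seq[start:end] = list(stretch)
            truth.planted_regions[pid].append(Region(start, end, "AR", ""))
        records.append(
            ProteinRecord(id=pid, sequence="".join(seq), species="synthetic",
                          genome_source=GenomeSource.UNKNOWN)
        )

    annotations = AnnotationTable()
    if spec.annotation_plan is not None:
        plan = spec.annotation_plan
        flagged = truth.flagged
        ids = [rec.id for rec in records]
        weights_flagged = np.array([1.0 if pid in flagged else 0.0 for pid in ids])
        for t in range(plan.n_terms):
            term = f"TERM:{t + 1:05d}"
            size = int(rng.integers(plan.term_size_range[0],
                                    plan.term_size_range[1] + 1))
            size = min(size, n)
            if t < len(plan.enriched_folds):
                fold = plan.enriched_folds[t]
                weights = np.where(weights_flagged > 0, fold, 1.0)
                probs = weights / weights.sum()
                members = rng.choice(n, size=size, replace=False, p=probs)
                truth.enriched_terms[term] = fold
            else:
                members = rng.choice(n, size=size, replace=False)
            for j in members:
                annotations.go_terms.setdefault(ids[int(j)], set()).add(term)
    return records, annotations, truth


def evaluate_recovery(
    truth: TruthTable,
    called: dict[str, Sequence[Region]],
    tolerance: int = 5,
) -> tuple[float, float | None]:
    """(sensitivity, precision) of region calls against planted truth.

    A planted region is recovered iff some called region of the same kind
    and residue class overlaps it with both boundaries within ``tolerance``
    residues. Precision is the fraction of calls matching some planted
    region; with no calls it is undefined and returned as None.
    """

    def matches(planted: Region, call: Region) -> bool:
        return (
            call.kind == planted.kind
            and call.residue_class == planted.residue_class
            and min(call.end, planted.end) > max(call.start, planted.start)
            and abs(call.start - planted.start) <= tolerance
            and abs(call.end - planted.end) <= tolerance
        )

    n_planted = recovered = 0
    for pid, planted_list in truth.planted_regions.items():
        calls = called.get(pid, ())
        for planted in planted_list:
            n_planted += 1
            if any(matches(planted, c) for c in calls):
                recovered += 1
    n_calls = matched_calls = 0
    for pid, calls in called.items():
        planted_list = truth.planted_regions.get(pid, ())
        for c in calls:
            n_calls += 1
            if any(matches(planted, c) for planted in planted_list):
                matched_calls += 1
    sensitivity = recovered / n_planted if n_planted else 1.0
    precision = matched_calls / n_calls if n_calls else None
    return sensitivity, precision
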