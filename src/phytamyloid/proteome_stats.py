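"""Per-proteome summary statistics and cross-species comparison.

For each proteome the screen reports (i) the fraction of potentially
amyloidogenic proteins and (ii) the coverage of total proteome length by
predicted regions, plus length statistics of the regions themselves.
Species are compared pairwise by the flagged fraction with a two-sided
Fisher's exact test, Benjamini–Hochberg adjusted across all pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .regions import Region, total_length
from .sequence_io import GenomeSource, ProteinRecord


@dataclass
class ProteomeSummary:
    """Headline numbers for one proteome (counts, not percentages)."""

    species: str
    n_proteins: int
    n_flagged: int

    @property
    def pct_flagged(self) -> float:
        return 100.0 * self.n_flagged / self.n_proteins


def fraction_flagged(
    proteome: Sequence[ProteinRecord], flags: Mapping[str, bool]
) -> float:
    """Percentage of valid proteins flagged potentially amyloidogenic."""
    if not proteome:
        raise ValueError("empty proteome")
    n_flagged = sum(1 for rec in proteome if flags.get(rec.id, False))
    return 100.0 * n_flagged / len(proteome)


def coverage(
    proteome: Sequence[ProteinRecord],
    regions: Mapping[str, Sequence[Region]],
) -> float:
    """Percentage of total proteome residues covered by predicted regions.

    Regions of one protein are unioned first, so overlapping calls are not
    double counted.
    """
    if not proteome:
        raise ValueError("empty proteome")
    total_residues = sum(rec.length for rec in proteome)
    covered = sum(
        total_length([(r.start, r.end) for r in regions.get(rec.id, ())])
        for rec in proteome
    )
    return 100.0 * covered / total_residues


def length_stats(regions: Iterable[Region]) -> tuple[float, int]:
    """(median, mode) of region lengths; mode ties resolve to the smallest."""
    lengths = [r.length for r in regions]
    if not lengths:
        raise ValueError("no regions")
    counts = Counter(lengths)
    top = max(counts.values())
    mode = min(length for length, c in counts.items() if c == top)
    return float(median(lengths)), mode


def subset_by_genome(
    proteome: Sequence[ProteinRecord], source: GenomeSource | str
) -> list[ProteinRecord]:
    """Records encoded by the given genome (nuclear/chloroplast/mitochondrion)."""
    source = GenomeSource(source)
    return [rec for rec in proteome if rec.genome_source == source]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Two-sided by point-probability summation: the p-value sums the
    hypergeometric probabilities of every table (with the observed margins)
    no more likely than the observed one. Degenerate margins are rejected.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError(f"degenerate margin in table {cells}")
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def adjust_bh(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def compare_species(summaries: Sequence[ProteomeSummary]) -> pd.DataFrame:
    """Pairwise flagged-fraction comparison across species.

    Each pair gets a two-sided Fisher's exact test on the 2x2 table
    (flagged, unflagged) x (species A, species B); BH adjustment is applied
    jointly across all pairs. Returns a tidy frame with columns
    species_a, species_b, p, p_adjusted.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two proteome summaries to compare")
    rows = []
    for i, sa in enumerate(summaries):
        for sb in summaries[i + 1 :]:
            p = fisher_exact_2x2(
                sa.n_flagged, sa.n_proteins - sa.n_flagged,
                sb.n_flagged, sb.n_proteins - sb.n_flagged,
            )
            rows.append((sa.species, sb.species, p))
    frame = pd.DataFrame(rows, columns=["species_a", "species_b", "p"])
    frame["p_adjusted"] = adjust_bh(frame["p"].tolist())
    return frame
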