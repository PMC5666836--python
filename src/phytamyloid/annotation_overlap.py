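"""Co-occurrence of predicted regions with protein features and PFAM domains.

Two analyses live here. First, region/feature overlap: for every feature
type (transmembrane, signal peptide, domains, plus a synthetic
"unannotated" type covering residues assigned to no feature) the summed
length of region overlaps is divided by the total length of that feature
type — the fraction of the feature class occupied by predicted regions.
The distribution of PSSM-predicted ARs over CBR classes uses the same
arithmetic with CBRs of one residue class as the "feature".

Second, PFAM domain abundance among seed storage proteins: among proteins
annotated with nutrient reservoir activity (GO:0045735), each PFAM family
is summarised by how many of its proteins (and of the species carrying
them) bear a Q/N-rich CBR.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import Region, complement_intervals, union_intervals
from .regions import overlap_length as _interval_overlap
from .sequence_io import ProteinRecord

UNANNOTATED = "unannotated"

#: GO term for nutrient reservoir activity (seed storage proteins).
STORAGE_GO_TERM = "GO:0045735"


def overlap_length(region: Region, feature: tuple[int, int]) -> int:
    """Residues shared by a region and a feature interval on one protein."""
    return _interval_overlap((region.start, region.end), feature)


def add_unannotated(
    features: Mapping[str, Sequence[tuple[str, int, int]]],
    proteome: Sequence[ProteinRecord],
) -> dict[str, list[tuple[str, int, int]]]:
    """Extend feature tables with the synthetic "unannotated" feature type.

    Every residue of every protein not covered by any annotated feature is
    assigned to ``unannotated``, so the feature types partition each
    protein exactly once the same-type intervals are unioned.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    for rec in proteome:
        feats = list(features.get(rec.id, ()))
        covered = [(s, e) for _, s, e in feats]
        for s, e in complement_intervals(covered, rec.length):
            feats.append((UNANNOTATED, s, e))
        out[rec.id] = feats
    return out


def feature_overlap_fractions(
    regions: Mapping[str, Sequence[Region]],
    features: Mapping[str, Sequence[tuple[str, int, int]]],
) -> pd.Series:
    """Per feature type: summed region overlap / total feature length.

    Same-type intervals are unioned per protein before measuring, so
    overlapping annotations are not double counted in either the numerator
    or the denominator. Feature types with zero total length are omitted
    (the fraction is undefined).
    """
    total: dict[str, int] = {}
    hit: dict[str, int] = {}
    for pid, feats in features.items():
        by_type: dict[str, list[tuple[int, int]]] = {}
        for ftype, s, e in feats:
            by_type.setdefault(ftype, []).append((s, e))
        region_ivs = union_intervals(
            [(r.start, r.end) for r in regions.get(pid, ())]
        )
        for ftype, ivs in by_type.items():
            merged = union_intervals(ivs)
            total[ftype] = total.get(ftype, 0) + sum(e - s for s, e in merged)
            hit[ftype] = hit.get(ftype, 0) + sum(
                _interval_overlap(fi, ri) for fi in merged for ri in region_ivs
            )
    fractions = {
        ftype: hit[ftype] / total[ftype] for ftype in total if total[ftype] > 0
    }
    return pd.Series(fractions, dtype=float).sort_index()


def ar_distribution_over_cbrs(
    ars: Mapping[str, Sequence[Region]],
    cbrs: Mapping[str, Sequence[Region]],
) -> dict[str, float]:
    """Fraction of each CBR class's total length overlapped by ARs.

    For every residue class found among the CBRs: sum over proteins of
    |AR union ∩ CBR| divided by the total CBR length of that class.
    """
    total: dict[str, int] = {}
    hit: dict[str, int] = {}
    for pid, regions in cbrs.items():
        ar_ivs = union_intervals([(r.start, r.end) for r in ars.get(pid, ())])
        for cbr in regions:
            cls = cbr.residue_class
            total[cls] = total.get(cls, 0) + cbr.length
            hit[cls] = hit.get(cls, 0) + sum(
                _interval_overlap((cbr.start, cbr.end), iv) for iv in ar_ivs
            )
    return {cls: hit[cls] / total[cls] for cls in total}


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals (table formatting rule)."""
    if denominator == 0:
        return 0.0
    raw = Decimal(100 * numerator) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PfamSummaryRow:
    """One PFAM family's abundance among storage proteins."""

    pfam_id: str
    description: str
    n_proteins: int
    n_species: int
    n_qn_rich: int
    n_species_qn_rich: int

    @property
    def pct_qn_rich(self) -> float:
        return _pct(self.n_qn_rich, self.n_proteins)

    @property
    def pct_species_qn_rich(self) -> float:
        return _pct(self.n_species_qn_rich, self.n_species)


def pfam_summary(
    storage_proteins: Iterable[str],
    pfam: Mapping[str, set[str]],
    qn_flags: Mapping[str, bool],
    species_map: Mapping[str, str],
    descriptions: Mapping[str, str] | None = None,
) -> list[PfamSummaryRow]:
    """PFAM family abundance among storage proteins, with a Total row.

    For each PFAM accession carried by at least one storage protein:
    protein and species counts, and the counts restricted to Q/N-rich
    proteins (those bearing >= 1 QN CBR). The final ``Total`` row counts
    DISTINCT proteins and species across all listed accessions — proteins
    carrying several domains are counted once.
    """
    descriptions = descriptions or {}
    per_acc: dict[str, set[str]] = {}
    storage = set(storage_proteins)
    for pid in storage:
        for acc in pfam.get(pid, ()):
            per_acc.setdefault(acc, set()).add(pid)

    def summarize(acc: str, proteins: set[str], description: str) -> PfamSummaryRow:
        qn = {pid for pid in proteins if qn_flags.get(pid, False)}
        return PfamSummaryRow(
            pfam_id=acc,
            description=description,
            n_proteins=len(proteins),
            n_species=len({species_map.get(pid, "") for pid in proteins}),
            n_qn_rich=len(qn),
            n_species_qn_rich=len({species_map.get(pid, "") for pid in qn}),
        )

    rows = [
        summarize(acc, proteins, descriptions.get(acc, ""))
        for acc, proteins in per_acc.items()
    ]
    rows.sort(key=lambda r: (-r.n_proteins, -r.n_qn_rich, r.pfam_id))
    all_proteins = set().union(*per_acc.values()) if per_acc else set()
    rows.append(summarize("Total", all_proteins, ""))
    return rows


def pfam_summary_frame(rows: Sequence[PfamSummaryRow]) -> pd.DataFrame:
    """Tabular (TSV-ready) form of a PFAM summary."""
    return pd.DataFrame(
        [
            {
                "pfam_id": r.pfam_id,
                "description": r.description,
                "n_proteins": r.n_proteins,
                "n_species": r.n_species,
                "n_qn_rich": r.n_qn_rich,
                "n_species_qn_rich": r.n_species_qn_rich,
                "pct_qn_rich": r.pct_qn_rich,
                "pct_species_qn_rich": r.pct_species_qn_rich,
            }
            for r in rows
        ]
    )
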