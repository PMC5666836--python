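"""FASTA and TSV annotation I/O plus sequence validity filtering.

Screening tools of this kind exclude sequences the window scanner cannot
handle: anything with non-canonical amino-acid letters (B, J, O, U, X, Z)
or longer than 10,000 residues is dropped from the analysis entirely,
including from all denominators downstream.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .regions import Region

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Longest sequence the window scanner accepts.
MAX_SEQUENCE_LENGTH = 10_000


class GenomeSource(str, Enum):
    NUCLEAR = "nuclear"
    CHLOROPLAST = "chloroplast"
    MITOCHONDRION = "mitochondrion"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifiers and provenance."""

    id: str
    sequence: str
    species: str = ""
    genome_source: GenomeSource = GenomeSource.UNKNOWN

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationTable:
    """Per-protein annotations: GO terms, feature intervals, PFAM accessions.

    ``features`` maps protein id to a list of ``(feature_type, start, end)``
    tuples in 0-based half-open coordinates.
    """

    go_terms: dict[str, set[str]] = field(default_factory=dict)
    features: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    pfam: dict[str, set[str]] = field(default_factory=dict)
    genome_source: dict[str, GenomeSource] = field(default_factory=dict)

    def merge(self, other: "AnnotationTable") -> "AnnotationTable":
        for pid, terms in other.go_terms.items():
            self.go_terms.setdefault(pid, set()).update(terms)
        for pid, feats in other.features.items():
            self.features.setdefault(pid, []).extend(feats)
        for pid, accs in other.pfam.items():
            self.pfam.setdefault(pid, set()).update(accs)
        self.genome_source.update(other.genome_source)
        return self


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a FASTA proteome into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased. Duplicate ids and sequence data appearing
    before any header are rejected.
    """
    path = Path(path)
    _check_headers(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(id=entry.id, sequence=str(entry.seq).upper(), species=species)
        )
    return records


def _check_headers(path: Path) -> None:
    # Biopython silently skips leading junk; reject sequence-before-header here.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            return


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def filter_valid_sequences(
    records: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Partition records into (kept, excluded-with-reason).

    A record is kept iff its sequence is non-empty, uses only the 20
    canonical residues and is at most 10,000 residues long. Excluded
    records carry a reason code: ``"noncanonical"``, ``"too_long"`` or
    ``"empty"``.
    """
    kept: list[ProteinRecord] = []
    excluded: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        if not rec.sequence:
            excluded.append((rec, "empty"))
        elif not _CANONICAL_SET.issuperset(rec.sequence):
            excluded.append((rec, "noncanonical"))
        elif rec.length > MAX_SEQUENCE_LENGTH:
            excluded.append((rec, "too_long"))
        else:
            kept.append(rec)
    return kept, excluded


_ANNOTATION_COLUMNS = {
    "go": 2,
    "features": 4,
    "pfam": 2,
    "genome_source": 2,
}


def read_annotations(
    path: str | Path,
    kind: str,
    proteome: Iterable[ProteinRecord] | None = None,
) -> AnnotationTable:
    """Read one TSV annotation table of the given kind.

    kind ``"go"``: columns (protein_id, term_id); ``"features"``:
    (protein_id, feature_type, start, end) with 0-based half-open
    coordinates; ``"pfam"``: (protein_id, pfam_accession);
    ``"genome_source"``: (protein_id, source).

    If ``proteome`` is given, annotation lines for unknown protein ids are
    collected as warnings (not errors), and feature intervals are checked
    against protein lengths.
    """
    if kind not in _ANNOTATION_COLUMNS:
        raise ValueError(f"unknown annotation kind {kind!r}")
    ncol = _ANNOTATION_COLUMNS[kind]
    lengths = {r.id: r.length for r in proteome} if proteome is not None else None

    table = AnnotationTable()
    unknown: list[str] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol} tab-separated columns, got {len(row)}"
                )
            pid = row[0]
            if lengths is not None and pid not in lengths:
                unknown.append(pid)
                continue
            if kind == "go":
                table.go_terms.setdefault(pid, set()).add(row[1])
            elif kind == "pfam":
                table.pfam.setdefault(pid, set()).add(row[1])
            elif kind == "genome_source":
                table.genome_source[pid] = GenomeSource(row[1])
            else:  # features
                ftype, start, end = row[1], int(row[2]), int(row[3])
                if start < 0 or start >= end:
                    raise ValueError(
                        f"{path}:{lineno}: invalid interval [{start}, {end})"
                    )
                if lengths is not None and end > lengths[pid]:
                    raise ValueError(
                        f"{path}:{lineno}: feature end {end} exceeds length "
                        f"{lengths[pid]} of protein {pid}"
                    )
                table.features.setdefault(pid, []).append((ftype, start, end))
    if unknown:
        warnings.warn(
            f"{path}: {len(unknown)} annotation line(s) reference protein ids "
            f"absent from the proteome (e.g. {unknown[0]!r}); skipped",
            stacklevel=2,
        )
    return table


REGION_HEADER = ["protein_id", "kind", "residue_class", "start", "end", "score"]


def write_regions(
    regions: Iterable[tuple[str, Region]], path: str | Path
) -> None:
    """Write (protein id, Region) pairs as a TSV with a header row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REGION_HEADER)
        for pid, region in regions:
            writer.writerow(
                [pid, region.kind, region.residue_class, region.start,
                 region.end, repr(region.score)]
            )


def read_regions(path: str | Path) -> list[tuple[str, Region]]:
    """Read a region TSV written by :func:`write_regions` (lossless round-trip)."""
    out: list[tuple[str, Region]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != REGION_HEADER:
            raise ValueError(f"{path}: unexpected region TSV header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(REGION_HEADER):
                raise ValueError(f"{path}:{lineno}: malformed region row")
            pid, kind, rcls, start, end, score = row
            out.append(
                (pid, Region(start=int(start), end=int(end), kind=kind,
                             residue_class=rcls, score=float(score)))
            )
    return out


def to_one_based_inclusive(start: int, end: int) -> tuple[int, int]:
    """Convert 0-based half-open coordinates to 1-based inclusive."""
    return start + 1, end


def from_one_based_inclusive(first: int, last: int) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to 0-based half-open."""
    return first - 1, last
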