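"""End-to-end screening runs: scan -> stats -> enrichment -> overlap -> summary.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
validated before any compute, and executed stage by stage. Stages
communicate only through the documented TSV/FASTA formats, so each stage is
independently runnable; a manifest (inputs, parameters, package version,
timestamp, stage outputs) is written alongside the results. Identical
config and inputs give identical region TSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotation_overlap import (
    STORAGE_GO_TERM,
    add_unannotated,
    ar_distribution_over_cbrs,
    feature_overlap_fractions,
    pfam_summary,
    pfam_summary_frame,
)
from .ar_scan import predict_ars, read_matrix
from .cbr_detect import (
    CbrParams,
    ResidueClass,
    background_frequencies,
    find_cbrs,
    is_potentially_amyloidogenic_cbr,
)
from .enrichment import enrichment_matrix, term_enrichment
from .proteome_stats import coverage, fraction_flagged
from .sequence_io import (
    filter_valid_sequences,
    read_annotations,
    read_fasta,
    write_regions,
)

logger = logging.getLogger("phytamyloid")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one screening run.

    ``proteomes`` maps a species tag to its FASTA path. Annotation paths
    are optional; stages needing them are skipped when absent.
    """

    proteomes: dict[str, str]
    out_dir: str
    matrix: str | None = None
    min_ar_length: int = 10
    cbr_classes: tuple[str, ...] = ("QN", "E")
    cbr_threshold: float = 1e-8
    cbr_background: str = "proteome"  # or "fixed:<p>"
    go: str | None = None
    features: str | None = None
    pfam: str | None = None
    genome_source: str | None = None
    alpha: float = 0.01
    min_interest: int = 5
    top_k: int = 30
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cbr_classes"] = tuple(raw.get("cbr_classes", ("QN", "E")))
        return cls(**raw)

    def validate(self) -> None:
        if not self.proteomes:
            raise PipelineError("config: no proteomes given")
        for tag, path in self.proteomes.items():
            if not Path(path).exists():
                raise PipelineError(f"config: FASTA for {tag!r} not found: {path}")
        for name in ("matrix", "go", "features", "pfam", "genome_source"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {name} file not found: {value}")
        if not (0.0 < self.cbr_threshold < 1.0):
            raise PipelineError("config: cbr_threshold must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise PipelineError("config: alpha must lie in (0, 1)")


def run_screen(config: RunConfig) -> dict[str, Any]:
    """Run the full screen; returns the manifest (also written as JSON)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, config.log_level)
    manifest: dict[str, Any] = {
        "tool": "phytamyloid",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "min_ar_length": config.min_ar_length,
            "cbr_classes": list(config.cbr_classes),
            "cbr_threshold": config.cbr_threshold,
            "cbr_background": config.cbr_background,
            "alpha": config.alpha,
            "min_interest": config.min_interest,
            "top_k": config.top_k,
            "seed": config.seed,
        },
        "inputs": {
            "proteomes": dict(config.proteomes),
            "matrix": config.matrix,
            "go": config.go,
            "features": config.features,
            "pfam": config.pfam,
            "genome_source": config.genome_source,
        },
        "outputs": [],
        "summaries": {},
    }

    matrix = _stage("read_matrix", read_matrix, config.matrix) if config.matrix else None

    ar_rows, cbr_rows = [], []
    ar_flags: dict[str, dict[str, bool]] = {}
    cbr_flags: dict[str, dict[str, bool]] = {}
    universes: dict[str, set[str]] = {}
    go_by_species: dict[str, dict[str, set[str]]] = {}
    all_records: dict[str, Any] = {}
    species_map: dict[str, str] = {}
    ar_by_protein: dict[str, list] = {}
    cbr_by_protein: dict[str, list] = {}

    for species, fasta in config.proteomes.items():
        records = _stage("read_fasta", read_fasta, fasta, species)
        kept, excluded = filter_valid_sequences(records)
        logger.info(
            "%s: %d proteins read, %d kept, %d excluded",
            species, len(records), len(kept), len(excluded),
        )
        universes[species] = {r.id for r in kept}
        for rec in kept:
            all_records[rec.id] = rec
            species_map[rec.id] = species

        ar_flags[species] = {}
        if matrix is not None:
            for rec in kept:
                regions = _stage("ar_scan", predict_ars, rec, matrix,
                                 config.min_ar_length)
                ar_flags[species][rec.id] = bool(regions)
                ar_by_protein[rec.id] = regions
                ar_rows.extend((rec.id, r) for r in regions)

        if config.cbr_background.startswith("fixed:"):
            fixed_p = float(config.cbr_background.split(":", 1)[1])
            classes = [ResidueClass.from_letters(c, fixed_p)
                       for c in config.cbr_classes]
        else:
            classes = _stage(
                "cbr_background", background_frequencies, kept,
                [ResidueClass.from_letters(c) for c in config.cbr_classes],
            )
        params = CbrParams(threshold=config.cbr_threshold)
        cbr_flags[species] = {}
        for rec in kept:
            by_class = {
                cls.name: _stage("cbr_scan", find_cbrs, rec, cls, params)
                for cls in classes
            }
            cbr_flags[species][rec.id] = is_potentially_amyloidogenic_cbr(
                rec, by_class
            )
            merged = [r for regions in by_class.values() for r in regions]
            cbr_by_protein[rec.id] = merged
            cbr_rows.extend((rec.id, r) for r in merged)

        if config.go:
            go_by_species[species] = _stage(
                "read_annotations", read_annotations, config.go, "go", kept
            ).go_terms

        manifest["summaries"][species] = {
            "n_proteins": len(kept),
            "n_excluded": len(excluded),
            "pct_flagged_ar": (
                fraction_flagged(kept, ar_flags[species]) if matrix else None
            ),
            "pct_flagged_cbr": fraction_flagged(kept, cbr_flags[species]),
            "coverage_ar": (
                coverage(kept, {r.id: ar_by_protein.get(r.id, []) for r in kept})
                if matrix else None
            ),
            "coverage_cbr": coverage(
                kept, {r.id: cbr_by_protein.get(r.id, []) for r in kept}
            ),
        }

    if matrix is not None:
        _write(manifest, out_dir / "ar_regions.tsv",
               lambda p: write_regions(ar_rows, p))
    _write(manifest, out_dir / "cbr_regions.tsv",
           lambda p: write_regions(cbr_rows, p))

    if config.go:
        for label, flags in (("ar", ar_flags), ("cbr", cbr_flags)):
            if label == "ar" and matrix is None:
                continue
            per_species = {}
            for species in config.proteomes:
                interest = {pid for pid, f in flags[species].items() if f}
                per_species[species] = _stage(
                    "enrichment", term_enrichment, universes[species], interest,
                    go_by_species[species], config.min_interest, config.alpha,
                )
            mat = enrichment_matrix(per_species, top_k=config.top_k)
            _write(manifest, out_dir / f"enrichment_{label}.tsv",
                   lambda p, m=mat: m.to_csv(p, sep="\t"))

    if config.features:
        feats = _stage(
            "read_annotations", read_annotations, config.features, "features",
            list(all_records.values()),
        ).features
        feats = add_unannotated(feats, list(all_records.values()))
        if matrix is not None:
            frac = feature_overlap_fractions(ar_by_protein, feats)
            _write(manifest, out_dir / "overlap_ar.tsv",
                   lambda p: frac.to_csv(p, sep="\t", header=["fraction"]))
        frac_cbr = feature_overlap_fractions(cbr_by_protein, feats)
        _write(manifest, out_dir / "overlap_cbr.tsv",
               lambda p: frac_cbr.to_csv(p, sep="\t", header=["fraction"]))
        if matrix is not None:
            dist = ar_distribution_over_cbrs(ar_by_protein, cbr_by_protein)
            _write(
                manifest, out_dir / "ar_over_cbr.tsv",
                lambda p: Path(p).write_text(
                    "residue_class\tfraction\n"
                    + "".join(f"{k}\t{v}\n" for k, v in sorted(dist.items()))
                ),
            )

    if config.pfam and config.go:
        pfam_table = _stage(
            "read_annotations", read_annotations, config.pfam, "pfam",
            list(all_records.values()),
        ).pfam
        storage = {
            pid
            for species, terms in go_by_species.items()
            for pid, tset in terms.items()
            if STORAGE_GO_TERM in tset
        }
        qn_flags = {
            pid: any(r.residue_class == "QN" for r in cbr_by_protein.get(pid, ()))
            for pid in all_records
        }
        rows = pfam_summary(storage, pfam_table, qn_flags, species_map)
        frame = pfam_summary_frame(rows)
        _write(manifest, out_dir / "pfam_summary.tsv",
               lambda p: frame.to_csv(p, sep="\t", index=False))

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run complete: %d outputs", len(manifest["outputs"]))
    return manifest


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def _write(manifest: dict, path: Path, writer) -> None:
    writer(path)
    manifest["outputs"].append(str(path))


def _setup_logging(out_dir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    if not logger.handlers:
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    logfile = logging.FileHandler(out_dir / "run.log")
    logfile.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(logfile)
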