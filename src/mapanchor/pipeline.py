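"""End-to-end pipeline: map binning, anchoring, chimera splitting,
orientation, ordering, pseudomolecule construction and reporting.

Stages run in a fixed order (bin -> assign -> chimera -> split ->
re-assign/orient -> order -> build -> stats) and every number in the
resulting :class:`RunReport` is recomputable from the emitted files.
On any stage failure, partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import anchoring, assembly_stats, linkage_map
from .io_formats import (
    PlacementRow,
    SeqRecord,
    read_fasta,
    read_marker_map,
    read_placements,
    validate_placements,
    write_agp,
    write_fasta,
)
from .pseudomolecule import GapPolicy, Pseudomolecule, anchored_fraction, build_pseudomolecule

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    map_path: str
    placements: str
    out_dir: str
    gap_length: int = 10_000
    max_intra_lg_gap_cm: float = 20.0
    cm_precision: int = 2
    min_markers: int = 1
    lg_order: Sequence[str] | None = None


@dataclass
class RunReport:
    """Provenance-stamped accounting of one pipeline run."""

    parameters: dict
    input_digests: dict
    n_anchored_before: int
    n_split: int
    n_pieces: int
    n_anchored_after: int
    anchored_bp: int
    assembly_bp: int
    anchored_percent: float
    n_unplaced: int
    pseudomolecules: list[dict] = field(default_factory=list)
    assembly_stats: dict = field(default_factory=dict)
    pseudomolecule_stats: dict = field(default_factory=dict)
    timestamp: str = ""

    def verify(self) -> None:
        """Recompute derived numbers from the report's own fields."""
        expected = anchoring.anchoring_accounting(
            self.n_anchored_before, self.n_split, self.n_pieces
        )
        if self.n_anchored_after != expected:
            raise AssertionError(
                f"anchoring accounting broken: {self.n_anchored_after} != {expected}"
            )
        expected_pct = anchored_fraction(self.anchored_bp, self.assembly_bp)
        if self.anchored_percent != expected_pct:
            raise AssertionError(
                f"anchored percent broken: {self.anchored_percent} != {expected_pct}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_anchors_tsv(path: Path, anchors: Sequence[anchoring.ScaffoldAnchor]) -> None:
    with path.open("w") as fh:
        fh.write("scaffold_id\tlg\tposition_cm\torientation\tn_markers\tambiguous\n")
        for a in anchors:
            fh.write(
                f"{a.scaffold_id}\t{a.lg}\t{a.position_cm:.6f}\t{a.orientation}"
                f"\t{a.n_markers}\t{int(a.ambiguous_orientation)}\n"
            )


def _write_chimeras_tsv(path: Path, reports: dict[str, anchoring.ChimeraReport]) -> None:
    with path.open("w") as fh:
        fh.write("scaffold_id\treason\tbreakpoints_bp\tpiece_ids\n")
        for sid in sorted(reports):
            r = reports[sid]
            fh.write(
                f"{sid}\t{r.reason}\t{','.join(map(str, r.breakpoints_bp))}"
                f"\t{','.join(r.piece_ids)}\n"
            )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write FASTA/AGP/TSV/JSON outputs to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out_dir: Path, written: list[Path]) -> RunReport:
    logger.info("reading inputs")
    records = read_fasta(config.fasta)
    scaffold_map = {r.id: r for r in records}
    map_rows = read_marker_map(config.map_path)
    placements = read_placements(config.placements)
    lmap = linkage_map.LinkageMap(map_rows, lg_order=config.lg_order)
    validate_placements(placements, scaffold_map, lmap.markers)

    logger.info("binning %d markers", len(lmap))
    bins = linkage_map.build_bins(lmap, cm_precision=config.cm_precision)

    logger.info("assigning scaffolds")
    anchors_before = anchoring.assign_scaffolds(
        placements, bins, lmap, min_markers=config.min_markers
    )

    logger.info("detecting chimeras (gap threshold %.1f cM)", config.max_intra_lg_gap_cm)
    reports = {}
    for a in anchors_before:
        rep = anchoring.detect_chimeras(a, config.max_intra_lg_gap_cm)
        if rep is not None:
            reports[a.scaffold_id] = rep

    logger.info("splitting %d chimeric scaffolds", len(reports))
    revised: dict[str, SeqRecord] = dict(scaffold_map)
    for sid, rep in reports.items():
        pieces = anchoring.split_scaffold(scaffold_map[sid], rep)
        del revised[sid]
        for piece in pieces:
            revised[piece.id] = piece
    placements_after: list[PlacementRow] = anchoring.remap_placements(placements, reports)

    anchors_after = anchoring.assign_scaffolds(
        placements_after, bins, lmap, min_markers=config.min_markers
    )
    # Pieces that still anchor (with min_markers == 1 every piece does,
    # because breakpoints always fall between marker runs).
    piece_ids = {pid for r in reports.values() for pid in r.piece_ids}
    n_pieces = sum(1 for a in anchors_after if a.scaffold_id in piece_ids)
    n_anchored_after = anchoring.anchoring_accounting(
        len(anchors_before), len(reports), n_pieces
    )
    if len(anchors_after) != n_anchored_after:
        raise AssertionError(
            f"anchored-after count {len(anchors_after)} does not match "
            f"accounting {n_anchored_after}"
        )

    logger.info("ordering and building pseudomolecules")
    lengths = {rid: len(rec) for rid, rec in revised.items()}
    by_lg: dict[str, list[anchoring.ScaffoldAnchor]] = {}
    for a in anchors_after:
        by_lg.setdefault(a.lg, []).append(a)
    gap_policy = GapPolicy(gap_length=config.gap_length)
    pseudomolecules: list[Pseudomolecule] = []
    for i, lg in enumerate(lmap.linkage_groups, 1):
        lg_anchors = by_lg.get(lg)
        if not lg_anchors:
            continue
        ordered = anchoring.order_scaffolds(lg_anchors, lengths)
        pseudomolecules.append(
            build_pseudomolecule(f"chr{i}", ordered, revised, gap_policy)
        )

    anchored_ids = {a.scaffold_id for a in anchors_after}
    unplaced = sorted(set(revised) - anchored_ids)
    anchored_bp = sum(lengths[sid] for sid in anchored_ids)
    assembly_bp = sum(lengths.values())

    logger.info("writing outputs")
    outputs = {
        "pseudomolecules.fa": lambda p: write_fasta(
            [pm.to_record() for pm in pseudomolecules], p
        ),
        "pseudomolecules.agp": lambda p: write_agp(pseudomolecules, p),
        "split_scaffolds.fa": lambda p: write_fasta(
            [revised[pid] for pid in sorted(piece_ids)], p
        ),
        "anchors.tsv": lambda p: _write_anchors_tsv(p, anchors_after),
        "chimeras.tsv": lambda p: _write_chimeras_tsv(p, reports),
        "unplaced.txt": lambda p: p.write_text("".join(s + "\n" for s in unplaced)),
    }
    for name, writer in outputs.items():
        path = out_dir / name
        written.append(path)
        writer(path)

    report = RunReport(
        parameters={
            "gap_length": config.gap_length,
            "max_intra_lg_gap_cm": config.max_intra_lg_gap_cm,
            "cm_precision": config.cm_precision,
            "min_markers": config.min_markers,
        },
        input_digests={
            "fasta": _sha256(config.fasta),
            "map": _sha256(config.map_path),
            "placements": _sha256(config.placements),
        },
        n_anchored_before=len(anchors_before),
        n_split=len(reports),
        n_pieces=n_pieces,
        n_anchored_after=len(anchors_after),
        anchored_bp=anchored_bp,
        assembly_bp=assembly_bp,
        anchored_percent=anchored_fraction(anchored_bp, assembly_bp),
        n_unplaced=len(unplaced),
        pseudomolecules=[
            {
                "name": pm.name,
                "length_bp": len(pm),
                "n_components": pm.n_components,
                "n_gap_bases": pm.n_gap_bases,
            }
            for pm in pseudomolecules
        ],
        assembly_stats=dataclasses.asdict(
            assembly_stats.assembly_summary(list(revised.values()))
        ),
        pseudomolecule_stats=(
            dataclasses.asdict(
                assembly_stats.assembly_summary([pm.to_record() for pm in pseudomolecules])
            )
            if pseudomolecules
            else {}
        ),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    report.verify()
    report_path = out_dir / "report.json"
    written.append(report_path)
    report_path.write_text(report.to_json() + "\n")
    return report
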