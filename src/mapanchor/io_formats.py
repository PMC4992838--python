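"""Readers and writers for every on-disk format the pipeline touches.

All readers validate strictly and raise :class:`FormatError` naming the
offending line rather than silently coercing.  Internal coordinates are
0-based half-open; every file format here (placements, AGP) is 1-based
inclusive, and the conversion happens only at this I/O boundary.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .util import IUPAC_CODES


class FormatError(ValueError):
    """Malformed or internally inconsistent input file."""


# ---------------------------------------------------------------------------
# Domain rows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence, stored uppercase.

    The id must be non-empty and whitespace-free; the sequence must be
    non-empty and drawn from the IUPAC nucleotide alphabet.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"non-IUPAC character(s) {sorted(bad)} in record {self.id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MarkerRow:
    """One mapped SNP marker: id, linkage group and genetic position in cM."""

    marker_id: str
    lg: str
    cm: float


@dataclass(frozen=True)
class PlacementRow:
    """Physical position of a marker on a scaffold (1-based bp)."""

    marker_id: str
    scaffold_id: str
    pos_bp: int


@dataclass(frozen=True)
class KmerHistogramRow:
    depth: int
    count: int


@dataclass(frozen=True)
class HitRow:
    """One row of the de facto 12-column tabular pairwise-hit format."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 row; component rows (W) or gap rows (N).

    Coordinates are 1-based inclusive, as in the file format.
    """

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    # W fields
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # N fields
    gap_length: int | None = None
    gap_type: str = "map"
    linkage: str = "no"

    def span(self) -> int:
        return self.object_end - self.object_beg + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file into uppercase :class:`SeqRecord` objects.

    Duplicate ids, empty sequences and non-IUPAC characters are hard
    errors naming the offending record or line.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        if not chunks:
            raise FormatError(
                f"{path}: empty sequence for {cur_id!r} (line {header_line})"
            )
        records.append(SeqRecord(cur_id, "".join(chunks)))

    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                cur_id = header.split()[0]
                header_line = lineno
                if cur_id in seen:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate sequence id {cur_id!r}"
                    )
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                frag = line.strip().upper()
                bad = set(frag) - IUPAC_CODES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC character(s) "
                        f"{sorted(bad)} in record {cur_id!r}"
                    )
                chunks.append(frag)
        flush()
    return records


def write_fasta(
    records: Iterable[SeqRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records in input order, wrapping sequence lines at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# TSV readers (header-carrying)
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, required: Sequence[str]) -> Iterable[tuple[int, dict]]:
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in required}
        for lineno, row in enumerate(reader, 2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, {c: row[i] for c, i in idx.items()}


def _as_float(path: Path, lineno: int, name: str, raw: str) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-numeric {name} field {raw!r}"
        ) from None
    if not math.isfinite(value):
        raise FormatError(f"{path}:{lineno}: non-finite {name} field {raw!r}")
    return value


def _as_int(path: Path, lineno: int, name: str, raw: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer {name} field {raw!r}"
        ) from None


def read_marker_map(path: str | Path) -> list[MarkerRow]:
    """Read a marker map TSV with columns marker_id, lg, cm."""
    path = Path(path)
    rows: list[MarkerRow] = []
    seen: set[str] = set()
    for lineno, rec in _read_tsv(path, ("marker_id", "lg", "cm")):
        cm = _as_float(path, lineno, "cm", rec["cm"])
        if cm < 0:
            raise FormatError(f"{path}:{lineno}: negative cM value {cm}")
        marker_id = rec["marker_id"].strip()
        if not marker_id:
            raise FormatError(f"{path}:{lineno}: empty marker_id")
        if marker_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate marker_id {marker_id!r}")
        seen.add(marker_id)
        rows.append(MarkerRow(marker_id, rec["lg"].strip(), cm))
    return rows


def read_placements(path: str | Path) -> list[PlacementRow]:
    """Read marker-to-scaffold placements (columns marker_id, scaffold_id, pos_bp)."""
    path = Path(path)
    rows: list[PlacementRow] = []
    for lineno, rec in _read_tsv(path, ("marker_id", "scaffold_id", "pos_bp")):
        pos = _as_int(path, lineno, "pos_bp", rec["pos_bp"])
        if pos < 1:
            raise FormatError(f"{path}:{lineno}: pos_bp must be >= 1, got {pos}")
        rows.append(PlacementRow(rec["marker_id"].strip(), rec["scaffold_id"].strip(), pos))
    return rows


def read_kmer_histogram(path: str | Path) -> list[KmerHistogramRow]:
    """Read a k-mer depth histogram TSV (columns depth, count)."""
    path = Path(path)
    rows: list[KmerHistogramRow] = []
    last_depth = 0
    for lineno, rec in _read_tsv(path, ("depth", "count")):
        depth = _as_int(path, lineno, "depth", rec["depth"])
        count = _as_int(path, lineno, "count", rec["count"])
        if depth < 1:
            raise FormatError(f"{path}:{lineno}: depth must be >= 1, got {depth}")
        if count < 0:
            raise FormatError(f"{path}:{lineno}: negative count {count}")
        if depth <= last_depth:
            raise FormatError(
                f"{path}:{lineno}: depths must be strictly increasing "
                f"({depth} after {last_depth})"
            )
        last_depth = depth
        rows.append(KmerHistogramRow(depth, count))
    return rows


def read_hit_table(path: str | Path) -> list[HitRow]:
    """Read a 12-column tabular hit file (no header).

    Extra trailing columns are ignored with a warning; fewer than 12
    columns is a hard error.
    """
    path = Path(path)
    rows: list[HitRow] = []
    warned_extra = False
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(row)}"
                )
            if len(row) > 12 and not warned_extra:
                warnings.warn(
                    f"{path}: extra columns beyond 12 ignored (first at line {lineno})",
                    stacklevel=2,
                )
                warned_extra = True
            e_value = _as_float(path, lineno, "e_value", row[10])
            if e_value < 0:
                raise FormatError(f"{path}:{lineno}: negative e_value {e_value}")
            rows.append(
                HitRow(
                    query_id=row[0],
                    subject_id=row[1],
                    percent_identity=_as_float(path, lineno, "percent_identity", row[2]),
                    alignment_length=_as_int(path, lineno, "alignment_length", row[3]),
                    mismatches=_as_int(path, lineno, "mismatches", row[4]),
                    gap_opens=_as_int(path, lineno, "gap_opens", row[5]),
                    q_start=_as_int(path, lineno, "q_start", row[6]),
                    q_end=_as_int(path, lineno, "q_end", row[7]),
                    s_start=_as_int(path, lineno, "s_start", row[8]),
                    s_end=_as_int(path, lineno, "s_end", row[9]),
                    e_value=e_value,
                    bit_score=_as_float(path, lineno, "bit_score", row[11]),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted tree with branch lengths, preserving labels."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: unparseable Newick: {exc}") from exc
    return tree


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

_AGP_HEADER = "##agp-version\t2.1"


def _check_agp_contiguity(rows: Sequence[AgpRow]) -> None:
    by_object: dict[str, list[AgpRow]] = {}
    for row in rows:
        by_object.setdefault(row.object_id, []).append(row)
    for object_id, obj_rows in by_object.items():
        expected_beg = 1
        for part, row in enumerate(obj_rows, 1):
            if row.part_number != part:
                raise FormatError(
                    f"AGP object {object_id}: part_number {row.part_number} != {part}"
                )
            if row.object_beg != expected_beg:
                raise FormatError(
                    f"AGP object {object_id} part {part}: coordinate discontinuity "
                    f"(object_beg {row.object_beg}, expected {expected_beg})"
                )
            if row.component_type == "W":
                comp_span = row.component_end - row.component_beg + 1
                if comp_span != row.span():
                    raise FormatError(
                        f"AGP object {object_id} part {part}: component span "
                        f"{comp_span} != object span {row.span()}"
                    )
            elif row.component_type == "N":
                if row.gap_length != row.span():
                    raise FormatError(
                        f"AGP object {object_id} part {part}: gap_length "
                        f"{row.gap_length} != object span {row.span()}"
                    )
            else:
                raise FormatError(
                    f"AGP object {object_id} part {part}: unsupported component "
                    f"type {row.component_type!r}"
                )
            expected_beg = row.object_end + 1


def write_agp(pseudomolecules: Iterable, path: str | Path) -> None:
    """Write AGP v2.1 for objects exposing an ``agp_rows`` attribute.

    Accepts :class:`~mapanchor.pseudomolecule.Pseudomolecule` objects or
    bare lists of :class:`AgpRow`.
    """
    path = Path(path)
    all_rows: list[AgpRow] = []
    for obj in pseudomolecules:
        rows = getattr(obj, "agp_rows", obj)
        all_rows.extend(rows)
    _check_agp_contiguity(all_rows)
    with path.open("w") as fh:
        fh.write(_AGP_HEADER + "\n")
        for row in all_rows:
            if row.component_type == "W":
                fields = [
                    row.object_id,
                    row.object_beg,
                    row.object_end,
                    row.part_number,
                    "W",
                    row.component_id,
                    row.component_beg,
                    row.component_end,
                    row.orientation,
                ]
            else:
                fields = [
                    row.object_id,
                    row.object_beg,
                    row.object_end,
                    row.part_number,
                    "N",
                    row.gap_length,
                    row.gap_type,
                    row.linkage,
                    "na",
                ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    """Read AGP rows back (W and N rows only), validating contiguity."""
    path = Path(path)
    rows: list[AgpRow] = []
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not raw or raw[0].startswith("#"):
                continue
            if len(raw) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 AGP columns")
            ctype = raw[4]
            common = dict(
                object_id=raw[0],
                object_beg=_as_int(path, lineno, "object_beg", raw[1]),
                object_end=_as_int(path, lineno, "object_end", raw[2]),
                part_number=_as_int(path, lineno, "part_number", raw[3]),
                component_type=ctype,
            )
            if ctype == "W":
                rows.append(
                    AgpRow(
                        **common,
                        component_id=raw[5],
                        component_beg=_as_int(path, lineno, "component_beg", raw[6]),
                        component_end=_as_int(path, lineno, "component_end", raw[7]),
                        orientation=raw[8],
                    )
                )
            elif ctype == "N":
                rows.append(
                    AgpRow(
                        **common,
                        gap_length=_as_int(path, lineno, "gap_length", raw[5]),
                        gap_type=raw[6],
                        linkage=raw[7],
                    )
                )
            else:
                raise FormatError(
                    f"{path}:{lineno}: unsupported component type {ctype!r}"
                )
    _check_agp_contiguity(rows)
    return rows


# ---------------------------------------------------------------------------
# Cross-file validation
# ---------------------------------------------------------------------------


def validate_placements(
    placements: Sequence[PlacementRow],
    scaffolds: Mapping[str, SeqRecord] | None = None,
    marker_ids: Iterable[str] | None = None,
) -> None:
    """Cross-check placements against scaffold lengths and known markers."""
    if scaffolds is not None:
        for p in placements:
            rec = scaffolds.get(p.scaffold_id)
            if rec is None:
                raise FormatError(
                    f"placement of {p.marker_id!r} references unknown scaffold "
                    f"{p.scaffold_id!r}"
                )
            if p.pos_bp > len(rec):
                raise FormatError(
                    f"placement of {p.marker_id!r} at {p.pos_bp} exceeds length "
                    f"{len(rec)} of scaffold {p.scaffold_id!r}"
                )
    if marker_ids is not None:
        known = set(marker_ids)
        for p in placements:
            if p.marker_id not in known:
                raise FormatError(
                    f"placement references unknown marker {p.marker_id!r}"
                )
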