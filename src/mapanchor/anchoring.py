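"""Scaffold anchoring against a genetic map.

Assigns scaffolds to linkage-group positions through the markers they
carry, flags chimeric (multi-position) scaffolds and computes their split
coordinates, infers orientation from the marker trend, and orders
scaffolds along each linkage group.

A scaffold whose markers land on two linkage groups, or on well-separated
positions within one group, is treated as a mis-assembly and split at the
bp midpoint between the flanking markers.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import kendalltau

from .io_formats import PlacementRow, SeqRecord
from .linkage_map import LinkageMap, MapBin


@dataclass(frozen=True)
class AnchorMarker:
    """A mapped marker as seen from one scaffold."""

    marker_id: str
    pos_bp: int  # 1-based position on the scaffold
    cm: float  # bin cM position on the map
    lg: str


@dataclass
class ScaffoldAnchor:
    """Map assignment of one scaffold.

    ``position_cm`` is the mean of the member markers' bin cM (each marker
    counted once, so bins weigh by their marker count).  ``orientation``
    is '?' when fewer than two distinct (pos_bp, cm) supports exist;
    downstream it is treated as '+' with ``ambiguous_orientation`` set.
    """

    scaffold_id: str
    lg: str | None
    position_cm: float | None
    orientation: str
    markers: list[AnchorMarker] = field(default_factory=list)
    ambiguous_orientation: bool = False

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def distinct_cm(self) -> int:
        return len({m.cm for m in self.markers if m.lg == self.lg})


@dataclass(frozen=True)
class ChimeraReport:
    """Split plan for a multi-position scaffold.

    ``breakpoints_bp`` are 0-based split coordinates: a breakpoint b cuts
    the sequence into s[:b] and s[b:].  Pieces are named
    ``<scaffold_id>.1``, ``.2``, ... left to right and tile the scaffold.
    """

    scaffold_id: str
    breakpoints_bp: tuple[int, ...]
    reason: str  # 'multi_lg' or 'intra_lg_gap'

    @property
    def piece_ids(self) -> list[str]:
        return [f"{self.scaffold_id}.{i + 1}" for i in range(len(self.breakpoints_bp) + 1)]


def assign_scaffolds(
    placements: Sequence[PlacementRow],
    bins: Sequence[MapBin],
    lmap: LinkageMap,
    min_markers: int = 1,
) -> list[ScaffoldAnchor]:
    """Build one anchor per scaffold carrying >= ``min_markers`` mapped markers.

    A multi-LG scaffold (chimera candidate) is assigned to the linkage
    group holding most of its markers (ties broken by map LG order); all
    markers are retained on the anchor for chimera detection.  Scaffolds
    without placements simply receive no anchor (the unplaced pool).
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    bin_of: dict[str, tuple[str, float]] = {}
    for b in bins:
        for mid in b.marker_ids:
            bin_of[mid] = (b.lg, b.cm)
    by_scaffold: dict[str, list[AnchorMarker]] = {}
    for p in placements:
        if p.marker_id not in lmap.markers:
            raise ValueError(f"placement references unknown marker {p.marker_id!r}")
        lg, cm = bin_of[p.marker_id]
        by_scaffold.setdefault(p.scaffold_id, []).append(
            AnchorMarker(p.marker_id, p.pos_bp, cm, lg)
        )
    anchors: list[ScaffoldAnchor] = []
    for scaffold_id in sorted(by_scaffold):
        markers = sorted(by_scaffold[scaffold_id], key=lambda m: (m.pos_bp, m.marker_id))
        if len(markers) < min_markers:
            continue
        lg_counts: dict[str, int] = {}
        for m in markers:
            lg_counts[m.lg] = lg_counts.get(m.lg, 0) + 1
        lg = min(
            lg_counts,
            key=lambda g: (-lg_counts[g], lmap.lg_index(g)),
        )
        member = [m for m in markers if m.lg == lg]
        position_cm = sum(m.cm for m in member) / len(member)
        orientation = orient_scaffold([(m.pos_bp, m.cm) for m in member])
        anchors.append(
            ScaffoldAnchor(
                scaffold_id=scaffold_id,
                lg=lg,
                position_cm=position_cm,
                orientation="+" if orientation == "?" else orientation,
                markers=markers,
                ambiguous_orientation=orientation == "?",
            )
        )
    return anchors


def detect_chimeras(
    anchor: ScaffoldAnchor, max_intra_lg_gap_cm: float = 20.0
) -> ChimeraReport | None:
    """Flag a scaffold whose markers occupy multiple map positions.

    Walking markers in bp order, a break is placed between two adjacent
    markers when (a) they map to different linkage groups, or (b) their
    bin cM differ by more than ``max_intra_lg_gap_cm`` within one group.
    The breakpoint is the floor midpoint of the flanking marker bp;
    contiguous runs on the same side form one piece.  Returns ``None``
    for non-chimeric scaffolds.  Any cross-LG break makes the reason
    ``multi_lg``; otherwise ``intra_lg_gap``.
    """
    if not anchor.markers:
        raise ValueError(f"anchor {anchor.scaffold_id!r} has no markers")
    markers = sorted(anchor.markers, key=lambda m: (m.pos_bp, m.marker_id))
    breakpoints: list[int] = []
    multi_lg = False
    for prev, cur in zip(markers, markers[1:]):
        if cur.lg != prev.lg:
            breakpoints.append((prev.pos_bp + cur.pos_bp) // 2)
            multi_lg = True
        elif abs(cur.cm - prev.cm) > max_intra_lg_gap_cm:
            breakpoints.append((prev.pos_bp + cur.pos_bp) // 2)
    if not breakpoints:
        return None
    return ChimeraReport(
        scaffold_id=anchor.scaffold_id,
        breakpoints_bp=tuple(breakpoints),
        reason="multi_lg" if multi_lg else "intra_lg_gap",
    )


def split_scaffold(record: SeqRecord, report: ChimeraReport) -> list[SeqRecord]:
    """Cut a scaffold at the report's breakpoints into tiling pieces.

    The concatenation of the returned pieces equals the original
    sequence; piece ids follow the report.
    """
    if record.id != report.scaffold_id:
        raise ValueError(
            f"report is for {report.scaffold_id!r}, record is {record.id!r}"
        )
    length = len(record)
    prev = 0
    for b in report.breakpoints_bp:
        if not (prev < b < length):
            raise ValueError(
                f"breakpoint {b} outside sequence of length {length} "
                f"for {record.id!r}"
            )
        prev = b
    bounds = [0, *report.breakpoints_bp, length]
    return [
        SeqRecord(piece_id, record.sequence[lo:hi])
        for piece_id, lo, hi in zip(report.piece_ids, bounds, bounds[1:])
    ]


def remap_placements(
    placements: Sequence[PlacementRow],
    reports: Mapping[str, ChimeraReport],
) -> list[PlacementRow]:
    """Shift marker placements from split scaffolds onto their pieces."""
    out: list[PlacementRow] = []
    for p in placements:
        report = reports.get(p.scaffold_id)
        if report is None:
            out.append(p)
            continue
        pos0 = p.pos_bp - 1
        idx = bisect_right(report.breakpoints_bp, pos0)
        offset = report.breakpoints_bp[idx - 1] if idx > 0 else 0
        out.append(PlacementRow(p.marker_id, report.piece_ids[idx], pos0 - offset + 1))
    return out


def orient_scaffold(markers: Sequence[tuple[int, float]]) -> str:
    """Orientation from the rank trend of (bp position, cM).

    '+' for a positive Kendall correlation, '-' for negative, '?' when
    the correlation is exactly zero or fewer than two distinct cM (or bp)
    values exist.  Rank correlation keeps a single noisy marker from
    flipping the call.
    """
    if not markers:
        raise ValueError("empty marker list")
    pos = [m[0] for m in markers]
    cm = [m[1] for m in markers]
    if len(set(cm)) < 2 or len(set(pos)) < 2:
        return "?"
    tau = kendalltau(pos, cm).statistic
    if tau > 0:
        return "+"
    if tau < 0:
        return "-"
    return "?"


def order_scaffolds(
    anchors: Sequence[ScaffoldAnchor],
    lengths: Mapping[str, int] | None = None,
) -> list[ScaffoldAnchor]:
    """Order anchors of one linkage group along the map.

    Sorted by position_cm ascending; ties broken by descending scaffold
    length (when lengths are supplied), then lexicographic scaffold id.
    Deterministic under input permutation.
    """
    lgs = {a.lg for a in anchors}
    if len(lgs) > 1:
        raise ValueError(f"anchors span multiple linkage groups: {sorted(lgs)}")

    def key(a: ScaffoldAnchor):
        length = lengths.get(a.scaffold_id, 0) if lengths else 0
        return (a.position_cm, -length, a.scaffold_id)

    return sorted(anchors, key=key)


def anchoring_accounting(n_anchored_before: int, n_split: int, n_pieces: int) -> int:
    """Sequence count after replacing split scaffolds by their pieces.

    Splitting removes each chimeric scaffold and adds its pieces, so the
    anchored count becomes ``n_anchored_before - n_split + n_pieces``.
    """
    if n_split < 0 or n_pieces < 0 or n_anchored_before < 0:
        raise ValueError("counts must be non-negative")
    if n_split > n_anchored_before:
        raise ValueError("cannot split more scaffolds than were anchored")
    if n_split > 0 and n_pieces < 2 * n_split:
        raise ValueError("each split scaffold must yield at least two pieces")
    if n_split == 0 and n_pieces != 0:
        raise ValueError("pieces reported without any split scaffolds")
    return n_anchored_before - n_split + n_pieces
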