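"""In-memory model of a SNP linkage map and its co-segregation bins.

A *bin* groups markers that map to the same genetic position on a
linkage group (no recombination observed among them).  Map software
reports cM to limited precision, so the implemented binning rule is
"identical cM after rounding to ``cm_precision`` decimals".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import MarkerRow


@dataclass(frozen=True)
class MapBin:
    """Markers sharing one (linkage group, rounded cM) position."""

    lg: str
    cm: float
    marker_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.marker_ids)


class LinkageMap:
    """A genetic map: ordered linkage groups and markers indexed by id.

    Linkage-group order follows first appearance in the input rows unless
    an explicit ``lg_order`` is given.
    """

    def __init__(self, rows: Iterable[MarkerRow], lg_order: Sequence[str] | None = None):
        self.markers: dict[str, MarkerRow] = {}
        seen_lgs: list[str] = []
        for row in rows:
            if row.marker_id in self.markers:
                raise ValueError(f"duplicate marker id {row.marker_id!r}")
            self.markers[row.marker_id] = row
            if row.lg not in seen_lgs:
                seen_lgs.append(row.lg)
        if not self.markers:
            raise ValueError("linkage map has no markers")
        if lg_order is not None:
            missing = set(seen_lgs) - set(lg_order)
            if missing:
                raise ValueError(f"lg_order omits linkage group(s) {sorted(missing)}")
            self.linkage_groups = [lg for lg in lg_order if lg in set(seen_lgs)]
        else:
            self.linkage_groups = seen_lgs

    def __len__(self) -> int:
        return len(self.markers)

    def lg_index(self, lg: str) -> int:
        return self.linkage_groups.index(lg)


def build_bins(lmap: LinkageMap, cm_precision: int = 2) -> list[MapBin]:
    """Group markers sharing (lg, round(cm, cm_precision)) into bins.

    Bins are sorted by linkage-group order, then cM; the result partitions
    the marker set and is invariant to input row order.
    """
    if cm_precision < 0:
        raise ValueError("cm_precision must be >= 0")
    grouped: dict[tuple[str, float], set[str]] = {}
    for row in lmap.markers.values():
        cm = round(row.cm, cm_precision) + 0.0  # normalise -0.0
        grouped.setdefault((row.lg, cm), set()).add(row.marker_id)
    order = {lg: i for i, lg in enumerate(lmap.linkage_groups)}
    return [
        MapBin(lg, cm, frozenset(ids))
        for (lg, cm), ids in sorted(grouped.items(), key=lambda kv: (order[kv[0][0]], kv[0][1]))
    ]


def map_summary(lmap: LinkageMap, bins: Sequence[MapBin]) -> pd.DataFrame:
    """Per-LG marker/bin counts and map length, with a TOTAL row.

    Map length of an LG is max(cm) - min(cm) over its markers; the TOTAL
    row sums counts and lengths over linkage groups.
    """
    rows = []
    for lg in lmap.linkage_groups:
        cms = [m.cm for m in lmap.markers.values() if m.lg == lg]
        n_bins = sum(1 for b in bins if b.lg == lg)
        rows.append(
            {
                "lg": lg,
                "n_markers": len(cms),
                "n_bins": n_bins,
                "length_cm": max(cms) - min(cms),
            }
        )
    total = {
        "lg": "TOTAL",
        "n_markers": sum(r["n_markers"] for r in rows),
        "n_bins": sum(r["n_bins"] for r in rows),
        "length_cm": sum(r["length_cm"] for r in rows),
    }
    return pd.DataFrame(rows + [total], columns=["lg", "n_markers", "n_bins", "length_cm"])
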