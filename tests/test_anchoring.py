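import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapanchor.anchoring import (
    AnchorMarker,
    ChimeraReport,
    ScaffoldAnchor,
    anchoring_accounting,
    assign_scaffolds,
    detect_chimeras,
    order_scaffolds,
    orient_scaffold,
    remap_placements,
    split_scaffold,
)
from mapanchor.io_formats import MarkerRow, PlacementRow, SeqRecord
from mapanchor.linkage_map import LinkageMap, build_bins


def make_map(rows):
    lmap = LinkageMap([MarkerRow(*r) for r in rows])
    return lmap, build_bins(lmap)


def anchor_with(markers, scaffold_id="s1", lg="LG1"):
    ms = [AnchorMarker(f"m{i}", bp, cm, m_lg) for i, (bp, cm, m_lg) in enumerate(markers)]
    return ScaffoldAnchor(scaffold_id, lg, sum(m.cm for m in ms) / len(ms), "+", ms)


# --- assignment -----------------------------------------------------------


def test_assign_mean_bin_position():
    lmap, bins = make_map([("m1", "LG1", 4.0), ("m2", "LG1", 6.0)])
    placements = [PlacementRow("m1", "s1", 100), PlacementRow("m2", "s1", 900)]
    (a,) = assign_scaffolds(placements, bins, lmap)
    assert a.lg == "LG1" and a.position_cm == 5.0 and a.n_markers == 2


def test_assign_unknown_marker_is_hard_error():
    lmap, bins = make_map([("m1", "LG1", 4.0)])
    with pytest.raises(ValueError, match="unknown marker"):
        assign_scaffolds([PlacementRow("mX", "s1", 1)], bins, lmap)


def test_scaffold_without_placements_is_unanchored():
    lmap, bins = make_map([("m1", "LG1", 4.0)])
    anchors = assign_scaffolds([PlacementRow("m1", "s1", 5)], bins, lmap)
    assert {a.scaffold_id for a in anchors} == {"s1"}  # s2 etc. simply absent


def test_multi_lg_scaffold_assigned_to_majority_group():
    lmap, bins = make_map(
        [("m1", "LG1", 1.0), ("m2", "LG1", 2.0), ("m3", "LG2", 9.0)]
    )
    placements = [
        PlacementRow("m1", "s1", 100),
        PlacementRow("m2", "s1", 200),
        PlacementRow("m3", "s1", 900),
    ]
    (a,) = assign_scaffolds(placements, bins, lmap)
    assert a.lg == "LG1" and a.position_cm == 1.5
    assert a.n_markers == 3  # all markers retained for chimera detection


# --- chimera detection ----------------------------------------------------


def test_multi_lg_chimera_breakpoint_at_midpoint():
    a = anchor_with([(10_000, 1.0, "LG1"), (90_000, 3.0, "LG5")])
    rep = detect_chimeras(a)
    assert rep is not None
    assert rep.reason == "multi_lg"
    assert rep.breakpoints_bp == (50_000,)
    assert rep.piece_ids == ["s1.1", "s1.2"]


def test_single_bin_scaffold_is_not_chimeric():
    a = anchor_with([(10, 5.0, "LG1"), (500, 5.0, "LG1")])
    assert detect_chimeras(a) is None


def test_intra_lg_gap_chimera():
    a = anchor_with(
        [
            (10_000, 3.0, "LG1"),
            (20_000, 4.0, "LG1"),
            (80_000, 60.0, "LG1"),
            (90_000, 60.0, "LG1"),
        ]
    )
    rep = detect_chimeras(a, max_intra_lg_gap_cm=20.0)
    assert rep is not None
    assert rep.reason == "intra_lg_gap"
    assert rep.breakpoints_bp == (50_000,)
    assert len(rep.piece_ids) == 2


def test_gap_below_threshold_not_chimeric():
    a = anchor_with([(10_000, 3.0, "LG1"), (90_000, 22.9, "LG1")])
    assert detect_chimeras(a, max_intra_lg_gap_cm=20.0) is None


# --- splitting ------------------------------------------------------------


def test_split_tiles_sequence():
    rec = SeqRecord("s1", "A" * 40 + "C" * 60)
    rep = ChimeraReport("s1", (40,), "multi_lg")
    p1, p2 = split_scaffold(rec, rep)
    assert (p1.id, len(p1)) == ("s1.1", 40)
    assert (p2.id, len(p2)) == ("s1.2", 60)
    assert p1.sequence + p2.sequence == rec.sequence


def test_split_conserves_bases_with_two_breakpoints():
    rec = SeqRecord("s1", "ACGT" * 25)
    rep = ChimeraReport("s1", (13, 71), "multi_lg")
    pieces = split_scaffold(rec, rep)
    assert len(pieces) == 3
    assert sum(len(p) for p in pieces) == len(rec)
    assert "".join(p.sequence for p in pieces) == rec.sequence


def test_split_rejects_out_of_range_breakpoint():
    rec = SeqRecord("s1", "ACGT")
    with pytest.raises(ValueError, match="outside sequence"):
        split_scaffold(rec, ChimeraReport("s1", (4,), "multi_lg"))


def test_remap_placements_shifts_positions():
    rep = ChimeraReport("s1", (40,), "multi_lg")
    placements = [
        PlacementRow("m1", "s1", 40),
        PlacementRow("m2", "s1", 41),
        PlacementRow("m3", "s2", 7),
    ]
    out = remap_placements(placements, {"s1": rep})
    assert out[0] == PlacementRow("m1", "s1.1", 40)
    assert out[1] == PlacementRow("m2", "s1.2", 1)
    assert out[2] == PlacementRow("m3", "s2", 7)


# --- orientation ----------------------------------------------------------


@pytest.mark.parametrize(
    "markers, expected",
    [
        ([(10_000, 1.0), (50_000, 3.0), (90_000, 5.0)], "+"),
        ([(10_000, 5.0), (50_000, 3.0), (90_000, 1.0)], "-"),
        ([(10_000, 1.0)], "?"),
        ([(10_000, 2.0), (90_000, 2.0)], "?"),
        ([(10, 1.0), (20, 2.0), (30, 1.5)], "+"),  # rank trend beats one noisy marker
    ],
)
def test_orient_scaffold(markers, expected):
    assert orient_scaffold(markers) == expected


def test_orient_empty_is_error():
    with pytest.raises(ValueError):
        orient_scaffold([])


@settings(max_examples=60, derandomize=True)
@given(
    markers=st.lists(
        st.tuples(st.integers(1, 10**6), st.floats(0, 100, allow_nan=False)),
        min_size=1,
        max_size=15,
        unique_by=lambda m: m[0],
    )
)
def test_orientation_antisymmetry(markers):
    """Mirroring the bp axis flips '+' <-> '-' and fixes '?'."""
    flipped = [(10**6 + 1 - bp, cm) for bp, cm in markers]
    fwd, rev = orient_scaffold(markers), orient_scaffold(flipped)
    assert rev == {"+": "-", "-": "+", "?": "?"}[fwd]


# --- ordering -------------------------------------------------------------


def _anchor(sid, cm):
    return ScaffoldAnchor(sid, "LG1", cm, "+", [AnchorMarker("m" + sid, 1, cm, "LG1")])


def test_order_by_position_then_length_then_id():
    a, b, c = _anchor("sA", 2.0), _anchor("sB", 1.0), _anchor("sC", 5.0)
    d = _anchor("sD", 5.0)
    lengths = {"sA": 10, "sB": 10, "sC": 10_000, "sD": 50_000}
    ordered = order_scaffolds([a, b, c, d], lengths)
    assert [x.scaffold_id for x in ordered] == ["sB", "sA", "sD", "sC"]
    # permutation invariance
    assert order_scaffolds([d, c, b, a], lengths) == ordered


def test_order_rejects_mixed_lgs():
    a = _anchor("sA", 1.0)
    b = ScaffoldAnchor("sB", "LG2", 1.0, "+", [])
    with pytest.raises(ValueError, match="multiple linkage groups"):
        order_scaffolds([a, b])


# --- accounting -----------------------------------------------------------


@pytest.mark.parametrize(
    "before, split, pieces, expected",
    [(1505, 158, 355, 1702), (10, 0, 0, 10), (10, 2, 5, 13)],
)
def test_accounting(before, split, pieces, expected):
    assert anchoring_accounting(before, split, pieces) == expected


@pytest.mark.parametrize(
    "before, split, pieces", [(5, 6, 12), (5, 2, 3), (5, 0, 3), (-1, 0, 0)]
)
def test_accounting_rejects_incoherent_tallies(before, split, pieces):
    with pytest.raises(ValueError):
        anchoring_accounting(before, split, pieces)
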