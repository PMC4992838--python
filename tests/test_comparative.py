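import itertools
import math
import random

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mapanchor.comparative import (
    GeneCoords,
    GenePair,
    calibrate_times,
    dotplot_pairs,
    jukes_cantor,
    ks_histogram,
    ng86_ks,
    reciprocal_best_hits,
)
from mapanchor.io_formats import HitRow, read_newick

SENSE_CODONS = sorted(
    c
    for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if Seq(c).translate() != "*"
)


def hit(q, s, bits, evalue=1e-50, ident=90.0):
    return HitRow(q, s, ident, 100, 5, 0, 1, 100, 1, 100, evalue, bits)


# --- reciprocal best hits -------------------------------------------------


def test_rbh_simple_pair():
    pairs = reciprocal_best_hits([hit("a1", "b1", 200)], [hit("b1", "a1", 190)])
    assert pairs == [GenePair("a1", "b1")]


def test_rbh_requires_reciprocity():
    ab = [hit("a1", "b1", 200)]
    ba = [hit("b1", "a2", 300), hit("b1", "a1", 100)]
    assert reciprocal_best_hits(ab, ba) == []


def test_rbh_applies_evalue_cutoff():
    ab = [hit("a1", "b1", 200, evalue=1e-3)]
    ba = [hit("b1", "a1", 190, evalue=1e-3)]
    assert reciprocal_best_hits(ab, ba) == []
    assert reciprocal_best_hits(ab, ba, evalue_cutoff=1e-2) == [GenePair("a1", "b1")]


def brute_force_rbh(ab, ba, cutoff=1e-10):
    """Exhaustive check over all hit pairs."""

    def best(hits, q):
        cands = [h for h in hits if h.query_id == q and h.e_value <= cutoff]
        if not cands:
            return None
        return min(
            cands,
            key=lambda h: (-h.bit_score, h.e_value, -h.percent_identity, h.subject_id),
        ).subject_id

    queries = {h.query_id for h in ab}
    return sorted(
        (q, best(ab, q))
        for q in queries
        if best(ab, q) is not None and best(ba, best(ab, q)) == q
    )


def test_rbh_matches_brute_force_on_3x3_table():
    ab = [
        hit("a1", "b1", 300), hit("a1", "b2", 100),
        hit("a2", "b2", 250), hit("a2", "b1", 260),
        hit("a3", "b3", 200), hit("a3", "b1", 150),
    ]
    ba = [
        hit("b1", "a1", 310), hit("b1", "a2", 90),
        hit("b2", "a2", 255), hit("b2", "a1", 80),
        hit("b3", "a3", 210),
    ]
    expected = brute_force_rbh(ab, ba)
    assert expected == [("a1", "b1"), ("a3", "b3")]  # a2's best b1 prefers a1
    got = reciprocal_best_hits(ab, ba)
    assert [(p.gene_a, p.gene_b) for p in got] == expected
    # row-order invariance
    shuffled = reciprocal_best_hits(ab[::-1], ba[::-1])
    assert shuffled == got


# --- dot plot -------------------------------------------------------------


def test_dotplot_midpoints():
    pairs = [GenePair("gA", "gB")]
    coords_a = {"gA": GeneCoords("chr1", 100, 200)}
    coords_b = {"gB": GeneCoords("mt2", 1000, 1100, strand="-")}
    points, skipped = dotplot_pairs(pairs, coords_a, coords_b)
    assert skipped == 0
    (pt,) = points
    assert (pt.x_pos, pt.y_pos) == (150.0, 1050.0)
    assert pt.strand_concordant is False


def test_dotplot_empty_and_missing_coords():
    assert dotplot_pairs([], {}, {}) == ([], 0)
    with pytest.warns(UserWarning, match="skipped"):
        points, skipped = dotplot_pairs([GenePair("x", "y")], {}, {})
    assert (points, skipped) == ([], 1)


def test_dotplot_colinear_genes_are_monotone():
    pairs = [GenePair(f"a{i}", f"b{i}") for i in range(20)]
    coords_a = {f"a{i}": GeneCoords("c1", i * 1000, i * 1000 + 500) for i in range(20)}
    coords_b = {f"b{i}": GeneCoords("c2", i * 900, i * 900 + 400) for i in range(20)}
    points, _ = dotplot_pairs(pairs, coords_a, coords_b)
    ys = [p.y_pos for p in points]
    assert ys == sorted(ys)


# --- NG86 -----------------------------------------------------------------


def oracle_codon_sites(codon):
    """Synonymous-site count by direct enumeration of the 9 mutations."""
    s = 0.0
    for i, b in itertools.product(range(3), "ACGT"):
        if b == codon[i]:
            continue
        alt = codon[:i] + b + codon[i + 1 :]
        if str(Seq(alt).translate()) == str(Seq(codon).translate()):
            s += 1 / 3
    return s


def oracle_pathway_diffs(ca, cb):
    """Average syn/nonsyn steps over all orderings of single-base paths."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    sds, nds = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd = ca, 0, 0
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                sd += 1
            else:
                nd += 1
            cur = nxt
        sds.append(sd)
        nds.append(nd)
    return sum(sds) / len(sds), sum(nds) / len(nds)


def test_ng86_identical_sequences():
    r = ng86_ks("ATGGCT", "ATGGCT")
    assert r.s_diffs == r.n_diffs == 0
    assert r.ks == 0.0 and r.ka == 0.0


def test_ng86_single_codon_hand_example():
    r = ng86_ks("TTT", "TTA")
    assert r.s_sites == pytest.approx(0.5)
    assert r.n_sites == pytest.approx(2.5)
    assert r.s_diffs == 0 and r.n_diffs == 1
    assert r.ks == 0.0 and r.ka == pytest.approx(jukes_cantor(0.4))


def test_ng86_site_counts_match_enumeration_on_all_sense_codon_pairs():
    """Exhaustive 61x61 oracle: per-codon site fractions and pathway
    differences agree with direct enumeration, and S + N = 3 always."""
    rng = random.Random(0)
    pairs = list(itertools.product(SENSE_CODONS, repeat=2))
    for ca, cb in pairs:
        r = ng86_ks(ca, cb)
        s_expected = (oracle_codon_sites(ca) + oracle_codon_sites(cb)) / 2
        assert r.s_sites == pytest.approx(s_expected, abs=1e-12), (ca, cb)
        assert r.s_sites + r.n_sites == pytest.approx(3.0, abs=1e-12)
        sd, nd = oracle_pathway_diffs(ca, cb)
        assert r.s_diffs == pytest.approx(sd, abs=1e-12), (ca, cb)
        assert r.n_diffs == pytest.approx(nd, abs=1e-12), (ca, cb)
    # spot-check symmetry on a random subset (full 61x61 already covered above)
    for ca, cb in rng.sample(pairs, 100):
        fwd, rev = ng86_ks(ca, cb), ng86_ks(cb, ca)
        assert fwd.s_diffs == pytest.approx(rev.s_diffs)
        assert fwd.s_sites == pytest.approx(rev.s_sites)


def test_ng86_gap_and_stop_columns_excluded():
    with pytest.warns(UserWarning, match="stop codons"):
        r = ng86_ks("ATGTAAAAA", "ATGTAGAAA")  # middle codons are stops
    assert r.n_codons == 2
    assert r.n_stop_codons_excluded == 1
    r2 = ng86_ks("ATG---AAA", "ATGGCTAAA")
    assert r2.n_codons == 2


def test_ng86_saturated_ps_flagged_not_raised():
    # four-fold degenerate third positions maximally diverged won't reach
    # ps >= 0.75 easily; drive it with serine codons instead
    r = ng86_ks("TCT" * 1, "AGC" * 1)  # both serine; all steps through paths
    assert r.ks is None or r.ks >= 0  # no exception either way
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None


def test_ng86_fourfold_degenerate_mutations_are_pure_ks():
    # GGx (Gly) and CCx (Pro) are 4-fold degenerate: third-position changes
    # are all synonymous
    a = "GGA CCT GGC CCG".replace(" ", "")
    b = "GGT CCA GGG CCC".replace(" ", "")
    r = ng86_ks(a, b)
    assert r.n_diffs == 0 and r.ka == 0.0
    assert r.s_diffs == 4


def test_ng86_rejects_bad_input():
    with pytest.raises(ValueError, match="lengths differ"):
        ng86_ks("ATG", "ATGGCT")
    with pytest.raises(ValueError, match="multiple of 3"):
        ng86_ks("ATGG", "ATGG")
    with pytest.raises(ValueError, match="no comparable"):
        ng86_ks("---", "ATG")


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=20))
def test_ng86_site_conservation_and_symmetry(codons):
    a = "".join(codons)
    b = "".join(reversed(codons))
    ra = ng86_ks(a, b)
    assert ra.s_sites + ra.n_sites == pytest.approx(3 * ra.n_codons)
    rb = ng86_ks(b, a)
    assert ra.s_sites == pytest.approx(rb.s_sites)
    assert ra.s_diffs == pytest.approx(rb.s_diffs)


# --- Ks histogram ---------------------------------------------------------


def test_ks_histogram_counting():
    h = ks_histogram([0.05, 0.05, 0.15], bin_width=0.1)
    assert h.counts[0] == 2 and h.counts[1] == 1
    assert h.proportions[0] == pytest.approx(2 / 3)
    assert sum(h.proportions) == pytest.approx(1.0)


def test_ks_histogram_exclusions_counted():
    h = ks_histogram([0.05, None, float("nan"), 5.0], bin_width=0.1, max_ks=3.0)
    assert h.n_retained == 1 and h.n_undefined == 2 and h.n_over_max == 1


def test_ks_histogram_errors():
    with pytest.raises(ValueError):
        ks_histogram([0.1], bin_width=0)
    with pytest.raises(ValueError, match="no finite"):
        ks_histogram([None, None])


def test_ks_histogram_uniform_sampling_oracle():
    rng = random.Random(5)
    values = [rng.random() for _ in range(10_000)]
    h = ks_histogram(values, bin_width=0.1, max_ks=1.0)
    for share in h.proportions:
        assert abs(share - 0.1) < 0.02


# --- divergence times -----------------------------------------------------


def test_calibration_linear_scaling(tmp_path):
    f = tmp_path / "t.nwk"
    f.write_text("((A:1,B:1):3,Out:4);")
    tree = read_newick(f)
    res = calibrate_times(tree, ("A", "Out", 114.0))
    assert res.age("A", "Out") == pytest.approx(114.0)  # calibration fixed point
    assert res.age("A", "B") == pytest.approx(114.0 * 1 / 4)  # 28.5
    assert res.age("A") == 0.0


def test_calibration_invariant_to_global_rate(tmp_path):
    f1, f2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
    f1.write_text("((A:2,B:2):6,Out:8);")
    f2.write_text("((A:1,B:1):3,Out:4);")
    r1 = calibrate_times(read_newick(f1), ("A", "Out", 114.0))
    r2 = calibrate_times(read_newick(f2), ("A", "Out", 114.0))
    assert r1.age("A", "B") == pytest.approx(r2.age("A", "B"))


def test_calibration_star_tree_all_internal_ages_equal(tmp_path):
    f = tmp_path / "t.nwk"
    f.write_text("(A:2,B:2,C:2,D:2);")
    res = calibrate_times(read_newick(f), ("A", "B", 50.0))
    ages = {age for key, age in res.node_ages.items() if len(key) > 1}
    assert ages == {50.0}


def test_calibration_child_ages_never_exceed_parent(tmp_path):
    f = tmp_path / "t.nwk"
    f.write_text("(((A:1,B:3):2,C:1):1,Out:6);")
    res = calibrate_times(read_newick(f), ("A", "Out", 100.0))
    tree = res.tree
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        key = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
        pkey = tuple(sorted(l.taxon.label for l in node.parent_node.leaf_iter()))
        assert res.node_ages[key] <= res.node_ages[pkey] + 1e-12


def test_calibration_errors(tmp_path):
    f = tmp_path / "t.nwk"
    f.write_text("((A:1,B:1):3,Out:4);")
    tree = read_newick(f)
    with pytest.raises(ValueError, match="not in tree"):
        calibrate_times(tree, ("A", "Nope", 114.0))
    zero = tmp_path / "z.nwk"
    zero.write_text("((A:0,B:0):0,Out:0);")
    with pytest.raises(ValueError, match="zero height"):
        calibrate_times(read_newick(zero), ("A", "B", 114.0))
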