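"""Comparative-genomics computations.

* Reciprocal-best-hit (RBH) ortholog pairing from two tabular hit files.
* Synteny dot-plot point extraction from gene pairs and coordinates.
* Nei-Gojobori (1986) counting of synonymous/nonsynonymous sites and
  differences with Jukes-Cantor correction (Ka/Ks).
* Ks histograms.
* Conversion of tree branch lengths to divergence times under a uniform
  rate, calibrated at one node of known age.

NG86 counts, per codon, the fraction of the three possible changes at
each position that preserve the amino acid (changes to stop codons count
as nonsynonymous); site totals are averaged over the two sequences, so
S + N = 3 x number of compared codons always holds.  Codons differing at
several positions are resolved by averaging the synonymous/nonsynonymous
step counts over all orderings of single-step pathways.  The Jukes-Cantor
correction d = -3/4 ln(1 - 4p/3) is undefined at p >= 3/4; such values
are flagged rather than raised.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
from Bio.Data.CodonTable import standard_dna_table

# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str
    source: str = "rbh"


def _best_hits(hits, evalue_cutoff: float) -> dict[str, str]:
    """Best subject per query: highest bit score, then lowest e-value,
    then highest identity, then lexicographically smallest subject."""
    best: dict[str, tuple] = {}
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        key = (-h.bit_score, h.e_value, -h.percent_identity, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: key[3] for q, key in best.items()}


def reciprocal_best_hits(
    hits_ab: Sequence, hits_ba: Sequence, evalue_cutoff: float = 1e-10
) -> list[GenePair]:
    """Gene pairs that are each other's best hit across two searches.

    Hits above the e-value cutoff are discarded first.  Output is sorted
    by (gene_a, gene_b) and invariant to hit-table row order.
    """
    best_ab = _best_hits(hits_ab, evalue_cutoff)
    best_ba = _best_hits(hits_ba, evalue_cutoff)
    pairs = [
        GenePair(a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


# ---------------------------------------------------------------------------
# Dot plot
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCoords:
    molecule: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class DotPoint:
    x_mol: str
    x_pos: float
    y_mol: str
    y_pos: float
    strand_concordant: bool


def dotplot_pairs(
    pairs: Sequence[GenePair],
    coords_a: Mapping[str, GeneCoords],
    coords_b: Mapping[str, GeneCoords],
) -> tuple[list[DotPoint], int]:
    """One dot per gene pair at the two genes' midpoints.

    Pairs missing coordinates on either side are skipped; the skip count
    is returned alongside the sorted point list.
    """
    points: list[DotPoint] = []
    skipped = 0
    for p in pairs:
        ca = coords_a.get(p.gene_a)
        cb = coords_b.get(p.gene_b)
        if ca is None or cb is None:
            skipped += 1
            continue
        points.append(
            DotPoint(
                x_mol=ca.molecule,
                x_pos=(ca.start + ca.end) / 2,
                y_mol=cb.molecule,
                y_pos=(cb.start + cb.end) / 2,
                strand_concordant=ca.strand == cb.strand,
            )
        )
    if skipped:
        warnings.warn(f"{skipped} gene pair(s) lacked coordinates and were skipped")
    points.sort(key=lambda d: (d.x_mol, d.x_pos, d.y_mol, d.y_pos))
    return points, skipped


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_CODON_AA = dict(standard_dna_table.forward_table)
_CODON_AA.update({c: "*" for c in standard_dna_table.stop_codons})
_SENSE_CODONS = sorted(standard_dna_table.forward_table)


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a sense codon (0..3).

    Each position contributes the fraction of its three alternative
    bases that leave the amino acid unchanged; mutations to stop codons
    are nonsynonymous.
    """
    aa = _CODON_AA[codon]
    s = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _CODON_AA[alt] == aa:
                s += 1 / 3
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in _SENSE_CODONS}


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over all orderings of single-step mutation pathways."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def jukes_cantor(p: float) -> float | None:
    """JC69 distance -3/4 ln(1 - 4p/3); None when 4p/3 >= 1."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if 4 * p / 3 >= 1:
        return None
    return -0.75 * math.log(1 - 4 * p / 3) + 0.0  # normalise -0.0


@dataclass(frozen=True)
class KsResult:
    """Site and difference counts and corrected rates for one gene pair.

    ``ks``/``ka`` are ``None`` when the Jukes-Cantor correction is
    undefined (p >= 3/4) or when no sites of that class exist.
    """

    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    ps: float | None
    pn: float | None
    ks: float | None
    ka: float | None
    n_codons: int
    n_stop_codons_excluded: int = 0

    @property
    def ks_defined(self) -> bool:
        return self.ks is not None


def _is_plain_codon(codon: str) -> bool:
    return all(b in _BASES for b in codon)


def ng86_ks(seq_a: str, seq_b: str) -> KsResult:
    """Nei-Gojobori Ka/Ks between two aligned coding sequences.

    Sequences must be equal-length and a multiple of three.  Codon
    columns containing gaps or ambiguous bases are dropped; columns in
    which either codon is a stop are excluded with a warning.
    """
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise ValueError(f"aligned length {len(a)} is not a multiple of 3")

    s_sites = n_sites = s_diffs = n_diffs = 0.0
    n_codons = 0
    n_stop = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (_is_plain_codon(ca) and _is_plain_codon(cb)):
            continue
        if _CODON_AA[ca] == "*" or _CODON_AA[cb] == "*":
            n_stop += 1
            continue
        n_codons += 1
        s = (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2
        s_sites += s
        n_sites += 3 - s
        sd, nd = _pathway_diffs(ca, cb)
        s_diffs += sd
        n_diffs += nd
    if n_stop:
        warnings.warn(f"{n_stop} codon column(s) containing stop codons excluded")
    if n_codons == 0:
        raise ValueError("no comparable codon columns")

    ps = s_diffs / s_sites if s_sites > 0 else None
    pn = n_diffs / n_sites if n_sites > 0 else None
    return KsResult(
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        ps=ps,
        pn=pn,
        ks=jukes_cantor(ps) if ps is not None else None,
        ka=jukes_cantor(pn) if pn is not None else None,
        n_codons=n_codons,
        n_stop_codons_excluded=n_stop,
    )


# ---------------------------------------------------------------------------
# Ks histogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KsHistogram:
    bin_width: float
    max_ks: float
    counts: tuple[int, ...]
    proportions: tuple[float, ...]
    n_retained: int
    n_undefined: int
    n_over_max: int

    def bin_edges(self) -> list[tuple[float, float]]:
        return [
            (i * self.bin_width, (i + 1) * self.bin_width)
            for i in range(len(self.counts))
        ]


def ks_histogram(
    ks_values: Sequence[float | None], bin_width: float = 0.1, max_ks: float = 3.0
) -> KsHistogram:
    """Bin Ks values into half-open bins [i*w, (i+1)*w) up to ``max_ks``.

    ``None`` (undefined) and non-finite values are excluded and counted,
    as are values >= max_ks.  Proportions sum to 1 over retained values.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_ks <= 0:
        raise ValueError("max_ks must be positive")
    n_bins = math.ceil(max_ks / bin_width)
    counts = [0] * n_bins
    n_undefined = n_over = 0
    for v in ks_values:
        if v is None or not math.isfinite(v):
            n_undefined += 1
            continue
        if v < 0:
            raise ValueError(f"negative Ks value {v}")
        if v >= max_ks:
            n_over += 1
            continue
        counts[int(v / bin_width)] += 1
    n_retained = sum(counts)
    if n_retained == 0:
        raise ValueError("no finite Ks values below max_ks")
    return KsHistogram(
        bin_width=bin_width,
        max_ks=max_ks,
        counts=tuple(counts),
        proportions=tuple(c / n_retained for c in counts),
        n_retained=n_retained,
        n_undefined=n_undefined,
        n_over_max=n_over,
    )


# ---------------------------------------------------------------------------
# Divergence-time calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibratedNodeTimes:
    """Node ages (MYA) from uniform-rate scaling of a calibrated tree.

    ``node_ages`` maps the sorted tuple of descendant tip labels of each
    node to its age; use :meth:`age` to query by any set of tips (their
    most recent common ancestor's age is returned).
    """

    tree: dendropy.Tree
    calibration: tuple[str, str, float]
    node_ages: dict[tuple[str, ...], float] = field(default_factory=dict)

    def age(self, *taxa: str) -> float:
        node = self.tree.mrca(taxon_labels=list(taxa))
        if node is None:
            raise ValueError(f"no common ancestor found for {taxa}")
        key = _tip_key(node)
        return self.node_ages[key]


def _tip_key(node) -> tuple[str, ...]:
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def calibrate_times(
    tree: dendropy.Tree, calibration: tuple[str, str, float]
) -> CalibratedNodeTimes:
    """Convert branch lengths to node ages under a uniform rate.

    Each node's height is its mean path length to descendant tips (which
    ultrametricizes the tree); ages are the heights scaled so that the
    most recent common ancestor of the two calibration taxa has exactly
    the calibration age.  A final pass clips each node's age to its
    parent's, so ages are parent-monotone.
    """
    taxon_a, taxon_b, age_mya = calibration
    if age_mya <= 0:
        raise ValueError("calibration age must be positive")
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for t in (taxon_a, taxon_b):
        if t not in labels:
            raise ValueError(f"calibration taxon {t!r} not in tree")

    # Mean node-to-tip distance via one postorder pass.
    stats: dict[int, tuple[float, int]] = {}  # node id -> (sum of tip distances, n tips)
    heights: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[id(node)] = (0.0, 1)
        else:
            total = 0.0
            n = 0
            for child in node.child_nodes():
                csum, cn = stats[id(child)]
                edge = child.edge.length or 0.0
                if edge < 0:
                    raise ValueError("negative branch length")
                total += csum + cn * edge
                n += cn
            stats[id(node)] = (total, n)
        s, n = stats[id(node)]
        heights[id(node)] = s / n

    cal_node = tree.mrca(taxon_labels=[taxon_a, taxon_b])
    h_cal = heights[id(cal_node)]
    if h_cal <= 0:
        raise ValueError("calibration node has zero height; cannot scale")
    scale = age_mya / h_cal

    result = CalibratedNodeTimes(tree=tree, calibration=calibration)
    ages: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        age = heights[id(node)] * scale
        if node.parent_node is not None:
            age = min(age, ages[id(node.parent_node)])
        ages[id(node)] = age
        result.node_ages[_tip_key(node)] = age
    return result
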