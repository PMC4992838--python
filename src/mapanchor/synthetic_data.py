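"""Synthetic fragmented genomes with known truth, for pipeline validation.

The generator draws a multi-chromosome genome, fragments each chromosome
into scaffolds at uniformly random breakpoints, plants inversions and
cross-chromosome chimeric fusions at configurable rates, places markers
uniformly with genetic positions from a monotone linear cM(bp) map
(optionally jittered), and records truth tables so that recovery of
order, orientation and chimera status can be scored exactly.

All randomness flows from the single seed in :class:`SimulationConfig`;
two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .anchoring import ChimeraReport, ScaffoldAnchor, order_scaffolds
from .io_formats import KmerHistogramRow, MarkerRow, PlacementRow, SeqRecord
from .util import reverse_complement


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the structure of a clover-sized mapping project at
    desk scale: eight chromosomes, ~50 kb scaffolds, 100 markers/Mb,
    3.8 cM/Mb, 10% of scaffolds inverted and 5% fused across
    chromosomes.  ``cm_jitter_sd`` adds i.i.d. Gaussian noise (cM) to
    each marker's observed map position.
    """

    seed: int
    n_chromosomes: int = 8
    chromosome_length_bp: int = 2_000_000
    gc_content: float = 0.33
    markers_per_mb: float = 100.0
    cm_per_mb: float = 3.8
    mean_scaffold_bp: int = 50_000
    p_invert: float = 0.10
    p_chimera: float = 0.05
    cm_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_invert", "p_chimera"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for name in ("n_chromosomes", "chromosome_length_bp", "mean_scaffold_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.markers_per_mb <= 0 or self.cm_per_mb <= 0:
            raise ValueError("markers_per_mb and cm_per_mb must be positive")
        if self.cm_jitter_sd < 0:
            raise ValueError("cm_jitter_sd must be non-negative")


@dataclass(frozen=True)
class ComponentTruth:
    """One source interval of a scaffold: chromosome slice and strand."""

    chromosome: str
    start: int  # 0-based half-open on the chromosome
    end: int
    orientation: str  # '+' as drawn, '-' inverted


@dataclass(frozen=True)
class ScaffoldTruth:
    scaffold_id: str
    components: tuple[ComponentTruth, ...]
    is_chimera: bool


@dataclass(frozen=True)
class MarkerTruth:
    marker_id: str
    chromosome: str
    pos_bp: int  # 1-based true chromosome position
    cm: float  # true (un-jittered) map position


@dataclass
class SyntheticDataset:
    """A generated input set plus its truth tables."""

    config: SimulationConfig
    chromosomes: dict[str, str]
    scaffolds: list[SeqRecord]
    markers: list[MarkerRow]
    placements: list[PlacementRow]
    scaffold_truth: dict[str, ScaffoldTruth]
    marker_truth: dict[str, MarkerTruth]

    def lg_of_chromosome(self, chromosome: str) -> str:
        return "LG" + chromosome.removeprefix("CHR")

    def chromosome_of_lg(self, lg: str) -> str:
        return "CHR" + lg.removeprefix("LG")

    def write(self, outdir: str | Path) -> None:
        """Write scaffolds.fa, map.tsv, placements.tsv, truth tables and
        provenance.json into ``outdir``."""
        from .io_formats import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.scaffolds, outdir / "scaffolds.fa")
        with (outdir / "map.tsv").open("w") as fh:
            fh.write("marker_id\tlg\tcm\n")
            for m in self.markers:
                fh.write(f"{m.marker_id}\t{m.lg}\t{m.cm:.6f}\n")
        with (outdir / "placements.tsv").open("w") as fh:
            fh.write("marker_id\tscaffold_id\tpos_bp\n")
            for p in self.placements:
                fh.write(f"{p.marker_id}\t{p.scaffold_id}\t{p.pos_bp}\n")
        truth = outdir / "truth"
        truth.mkdir(exist_ok=True)
        with (truth / "scaffolds.tsv").open("w") as fh:
            fh.write(
                "scaffold_id\tis_chimera\tcomponents\n"
            )
            for sid in sorted(self.scaffold_truth):
                st = self.scaffold_truth[sid]
                comps = ";".join(
                    f"{c.chromosome}:{c.start}-{c.end}:{c.orientation}"
                    for c in st.components
                )
                fh.write(f"{sid}\t{int(st.is_chimera)}\t{comps}\n")
        with (truth / "markers.tsv").open("w") as fh:
            fh.write("marker_id\tchromosome\tpos_bp\tcm\n")
            for mid in sorted(self.marker_truth):
                mt = self.marker_truth[mid]
                fh.write(f"{mid}\t{mt.chromosome}\t{mt.pos_bp}\t{mt.cm:.6f}\n")
        with (outdir / "provenance.json").open("w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")


_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic input set with truth tables.

    Chromosomes are i.i.d. bases at the configured GC content; the map
    function is linear, cM = cm_per_mb * bp / 1e6, so the true marker
    order is known.  Scaffold pieces tile each chromosome exactly.
    """
    rng = np.random.default_rng(config.seed)
    chromosomes: dict[str, str] = {}
    pieces: list[dict] = []  # chromosome, start, end
    marker_specs: list[dict] = []

    for c in range(1, config.n_chromosomes + 1):
        name = f"CHR{c}"
        L = config.chromosome_length_bp
        chromosomes[name] = _random_sequence(rng, L, config.gc_content)
        n_pieces = max(1, round(L / config.mean_scaffold_bp))
        if n_pieces > 1:
            cuts = np.sort(rng.choice(np.arange(1, L), size=n_pieces - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), L]
        for lo, hi in zip(bounds, bounds[1:]):
            pieces.append({"chromosome": name, "start": lo, "end": hi})
        n_markers = round(config.markers_per_mb * L / 1e6)
        positions = np.sort(rng.choice(L, size=n_markers, replace=False)) + 1
        for pos in positions.tolist():
            cm_true = config.cm_per_mb * pos / 1e6
            marker_specs.append(
                {"chromosome": name, "pos_bp": int(pos), "cm_true": cm_true}
            )

    # Orientation of each piece.
    inverted = rng.random(len(pieces)) < config.p_invert

    # Cross-chromosome fusions: walk pieces in random order; each unused
    # piece heads a fusion with probability p_chimera, taking the next
    # unused piece from a different chromosome as its tail.
    perm = rng.permutation(len(pieces))
    used: set[int] = set()
    groups: list[list[int]] = []  # piece indices per scaffold
    for pos_in_perm, idx in enumerate(perm.tolist()):
        if idx in used:
            continue
        used.add(idx)
        if rng.random() < config.p_chimera:
            partner = None
            for jdx in perm[pos_in_perm + 1 :].tolist():
                if jdx in used:
                    continue
                if pieces[jdx]["chromosome"] != pieces[idx]["chromosome"]:
                    partner = jdx
                    break
            if partner is not None:
                used.add(partner)
                groups.append([idx, partner])
                continue
        groups.append([idx])

    # Scaffold ids follow the (random) group order so ids carry no
    # positional information.
    width = len(str(len(groups)))
    scaffolds: list[SeqRecord] = []
    scaffold_truth: dict[str, ScaffoldTruth] = {}
    piece_to_scaffold: dict[int, tuple[str, int]] = {}  # piece -> (scaffold, comp idx)
    for g, group in enumerate(groups, 1):
        sid = f"scf{g:0{width}d}"
        comp_truths = []
        seq_parts = []
        for ci, idx in enumerate(group):
            p = pieces[idx]
            strand = "-" if inverted[idx] else "+"
            sub = chromosomes[p["chromosome"]][p["start"] : p["end"]]
            seq_parts.append(reverse_complement(sub) if strand == "-" else sub)
            comp_truths.append(
                ComponentTruth(p["chromosome"], p["start"], p["end"], strand)
            )
            piece_to_scaffold[idx] = (sid, ci)
        scaffolds.append(SeqRecord(sid, "".join(seq_parts)))
        scaffold_truth[sid] = ScaffoldTruth(
            scaffold_id=sid,
            components=tuple(comp_truths),
            is_chimera=len(group) > 1,
        )
    scaffolds.sort(key=lambda r: r.id)

    # Piece lookup per chromosome for marker placement.
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, p in enumerate(pieces):
        by_chrom.setdefault(p["chromosome"], []).append((p["start"], p["end"], idx))
    for lst in by_chrom.values():
        lst.sort()

    scaffold_comp_offsets: dict[str, list[int]] = {}
    for sid, st in scaffold_truth.items():
        offsets = [0]
        for comp in st.components[:-1]:
            offsets.append(offsets[-1] + comp.end - comp.start)
        scaffold_comp_offsets[sid] = offsets

    markers: list[MarkerRow] = []
    placements: list[PlacementRow] = []
    marker_truth: dict[str, MarkerTruth] = {}
    jitter = (
        rng.normal(0.0, config.cm_jitter_sd, size=len(marker_specs))
        if config.cm_jitter_sd > 0
        else np.zeros(len(marker_specs))
    )
    m_width = len(str(len(marker_specs)))
    for m, spec in enumerate(marker_specs, 1):
        mid = f"mk{m:0{m_width}d}"
        chrom = spec["chromosome"]
        pos1 = spec["pos_bp"]
        cm_obs = max(0.0, spec["cm_true"] + float(jitter[m - 1]))
        # locate containing piece
        intervals = by_chrom[chrom]
        lo, hi = 0, len(intervals) - 1
        while lo < hi:
            midpt = (lo + hi) // 2
            if intervals[midpt][1] < pos1:
                lo = midpt + 1
            else:
                hi = midpt
        start, end, idx = intervals[lo]
        assert start < pos1 <= end
        sid, comp_i = piece_to_scaffold[idx]
        comp = scaffold_truth[sid].components[comp_i]
        within = pos1 - start  # 1-based within the piece
        if comp.orientation == "-":
            within = (end - start) - within + 1
        pos_on_scaffold = scaffold_comp_offsets[sid][comp_i] + within
        lg = f"LG{chrom.removeprefix('CHR')}"
        markers.append(MarkerRow(mid, lg, cm_obs))
        placements.append(PlacementRow(mid, sid, pos_on_scaffold))
        marker_truth[mid] = MarkerTruth(mid, chrom, pos1, spec["cm_true"])

    return SyntheticDataset(
        config=config,
        chromosomes=chromosomes,
        scaffolds=scaffolds,
        markers=markers,
        placements=placements,
        scaffold_truth=scaffold_truth,
        marker_truth=marker_truth,
    )


def simulate_kmer_histogram(
    genome_size_bp: int,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[KmerHistogramRow]:
    """Poisson-coverage k-mer depth histogram with an optional error spike.

    Each genomic position receives a Poisson(mean_depth) k-mer count;
    sequencing errors add ``error_rate * genome_size_bp * mean_depth``
    singleton k-mers at depth 1.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if error_rate < 0:
        raise ValueError("error_rate must be non-negative")
    rng = np.random.default_rng(seed)
    depths = rng.poisson(mean_depth, size=genome_size_bp)
    counts = np.bincount(depths)
    if len(counts) < 2:
        counts = np.pad(counts, (0, 2 - len(counts)))
    counts[1] += int(round(error_rate * genome_size_bp * mean_depth))
    return [
        KmerHistogramRow(depth, int(c))
        for depth, c in enumerate(counts.tolist())
        if depth >= 1
    ]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Pipeline-vs-truth scores; ``None`` marks an empty denominator."""

    orientation_accuracy: float | None
    order_spearman_per_lg: dict[str, float]
    chimera_sensitivity: float | None
    chimera_precision: float | None
    anchored_fraction: float

    @property
    def min_order_spearman(self) -> float | None:
        if not self.order_spearman_per_lg:
            return None
        return min(self.order_spearman_per_lg.values())


def evaluate_recovery(
    anchors: Sequence[ScaffoldAnchor],
    chimera_reports: Mapping[str, ChimeraReport],
    dataset: SyntheticDataset,
) -> RecoveryMetrics:
    """Score anchoring outputs against the dataset's truth tables.

    * orientation_accuracy: over non-chimeric scaffolds with >= 2
      distinct-cM markers; a '?' call counts as '+'.
    * chimera sensitivity: detected / planted fusions in which both
      components carry at least one mapped marker (a fusion with a
      marker-free side is invisible to any map-based detector).
    * chimera precision: detected true fusions / all detection calls.
    * order_spearman_per_lg: rank correlation between the pipeline's
      scaffold order and the true chromosome order of the non-chimeric
      scaffolds assigned to each linkage group.
    * anchored_fraction: anchored bases / total scaffold bases.
    """
    truth = dataset.scaffold_truth
    for a in anchors:
        if a.scaffold_id not in truth:
            raise ValueError(f"anchor for unknown scaffold {a.scaffold_id!r}")
    anchor_by_id = {a.scaffold_id: a for a in anchors}

    # Orientation over unambiguous, non-chimeric scaffolds.
    n_orient = n_orient_ok = 0
    for a in anchors:
        st = truth[a.scaffold_id]
        if st.is_chimera or a.distinct_cm() < 2:
            continue
        called = a.orientation if a.orientation in "+-" else "+"
        n_orient += 1
        if called == st.components[0].orientation:
            n_orient_ok += 1
    orientation_accuracy = n_orient_ok / n_orient if n_orient else None

    # Chimera detection vs planted fusions.
    markers_per_component: dict[str, set[int]] = {}
    for p in dataset.placements:
        st = truth[p.scaffold_id]
        if not st.is_chimera:
            continue
        chrom = dataset.marker_truth[p.marker_id].chromosome
        comp_idx = next(
            i for i, c in enumerate(st.components) if c.chromosome == chrom
        )
        markers_per_component.setdefault(p.scaffold_id, set()).add(comp_idx)
    planted = {sid for sid, st in truth.items() if st.is_chimera}
    detectable = {
        sid
        for sid in planted
        if len(markers_per_component.get(sid, set())) >= len(truth[sid].components)
    }
    called = set(chimera_reports)
    tp_sens = called & detectable
    chimera_sensitivity = len(tp_sens) / len(detectable) if detectable else None
    chimera_precision = len(called & planted) / len(called) if called else None

    # Per-LG ordering of non-chimeric anchored scaffolds.
    lengths = {r.id: len(r) for r in dataset.scaffolds}
    order_spearman: dict[str, float] = {}
    by_lg: dict[str, list[ScaffoldAnchor]] = {}
    for a in anchors:
        st = truth[a.scaffold_id]
        if st.is_chimera:
            continue
        if dataset.chromosome_of_lg(a.lg) != st.components[0].chromosome:
            continue  # mis-assigned; cannot be ranked against this LG
        by_lg.setdefault(a.lg, []).append(a)
    for lg, lg_anchors in sorted(by_lg.items()):
        if len(lg_anchors) < 2:
            continue
        ordered = order_scaffolds(lg_anchors, lengths)
        pipeline_rank = list(range(len(ordered)))
        true_pos = [truth[a.scaffold_id].components[0].start for a in ordered]
        rho = spearmanr(pipeline_rank, true_pos).statistic
        # round away float noise from the rank-correlation computation
        # (smallest genuine deviation, one adjacent swap, is O(1/n^3))
        order_spearman[lg] = round(float(rho), 12)

    total_bp = sum(lengths.values())
    anchored_bp = sum(lengths[sid] for sid in anchor_by_id)
    return RecoveryMetrics(
        orientation_accuracy=orientation_accuracy,
        order_spearman_per_lg=order_spearman,
        chimera_sensitivity=chimera_sensitivity,
        chimera_precision=chimera_precision,
        anchored_fraction=anchored_bp / total_bp if total_bp else 0.0,
    )
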