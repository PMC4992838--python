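"""Assembly summary statistics, completeness accounting and k-mer
genome-size estimation.

N50 uses the descending cumulative-length convention: the length of the
sequence at which the sorted cumulative sum first reaches half the total.
GC% is computed over unambiguous A/C/G/T bases only (N and IUPAC
ambiguity codes are excluded from the denominator).

Genome size is estimated from a k-mer depth histogram by the standard
valley/peak rule: the error spike at low depth is cut off at the first
local minimum, the coverage peak is the modal depth beyond it, and the
genome size is the total k-mer count beyond the valley divided by the
peak depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io_formats import KmerHistogramRow, SeqRecord
from .util import percent


@dataclass(frozen=True)
class AssemblyStatsReport:
    n_sequences: int
    total_bp: int
    max_bp: int
    min_bp: int
    mean_bp: int  # floor of the mean
    n50_bp: int
    gc_percent: float  # 1 decimal
    n_count: int


@dataclass(frozen=True)
class GenomeSizeEstimate:
    k: int
    valley_depth: int
    peak_depth: int
    genome_size_bp: int


def n50(lengths: Sequence[int]) -> int:
    """Length at which the descending cumulative sum first reaches total/2."""
    if not lengths:
        raise ValueError("empty length list")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc * 2 >= total:
            return length
    raise AssertionError("unreachable")


def mean_length(lengths: Sequence[int]) -> int:
    """Floor of the mean sequence length."""
    if not lengths:
        raise ValueError("empty length list")
    return sum(lengths) // len(lengths)


def assembly_summary(records: Sequence[SeqRecord]) -> AssemblyStatsReport:
    """Table-style summary of a sequence set."""
    if not records:
        raise ValueError("no sequences")
    lengths = [len(r) for r in records]
    gc = at = n_bases = 0
    for r in records:
        seq = r.sequence
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        n_bases += seq.count("N")
    if gc + at == 0:
        raise ValueError("no unambiguous A/C/G/T bases; GC% undefined")
    return AssemblyStatsReport(
        n_sequences=len(records),
        total_bp=sum(lengths),
        max_bp=max(lengths),
        min_bp=min(lengths),
        mean_bp=mean_length(lengths),
        n50_bp=n50(lengths),
        gc_percent=percent(gc, gc + at),
        n_count=n_bases,
    )


def completeness_percent(n_found: int, n_total: int) -> float:
    """Percent of reference genes recovered, 1 decimal, half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_found <= n_total:
        raise ValueError("n_found must be within [0, n_total]")
    return percent(n_found, n_total)


def estimate_genome_size(
    histogram: Sequence[KmerHistogramRow], min_depth: int = 2, k: int = 17
) -> GenomeSizeEstimate:
    """Valley/peak genome-size estimate from a k-mer depth histogram.

    The valley is the first local minimum at depth >= ``min_depth``
    (separating the sequencing-error spike from genuine coverage); when
    the histogram rises from the start (no error spike) the valley is
    forced to ``min_depth - 1``.  The peak is the most frequent depth
    beyond the valley, and the genome size is
    ``sum(depth * count for depth > valley) // peak_depth``.
    """
    if not histogram:
        raise ValueError("empty histogram")
    depths = [row.depth for row in histogram]
    counts = [row.count for row in histogram]
    n = len(histogram)

    valley_idx: int | None = None
    for i in range(n):
        if depths[i] < min_depth:
            continue
        left_ok = i > 0 and counts[i - 1] >= counts[i]
        right_ok = i + 1 < n and counts[i] <= counts[i + 1]
        if left_ok and right_ok:
            valley_idx = i
            break
    if valley_idx is not None:
        valley_depth = depths[valley_idx]
    else:
        # No interior minimum: either no error spike (monotone rise into
        # the peak) or no peak at all (monotone decay).
        tail = [(d, c) for d, c in zip(depths, counts) if d >= min_depth]
        if not tail or all(c2 <= c1 for (_, c1), (_, c2) in zip(tail, tail[1:])):
            raise ValueError("no coverage peak in k-mer histogram")
        valley_depth = min_depth - 1

    beyond = [(d, c) for d, c in zip(depths, counts) if d > valley_depth]
    if not beyond or all(c == 0 for _, c in beyond):
        raise ValueError("no coverage peak in k-mer histogram")
    peak_depth = max(beyond, key=lambda dc: (dc[1], -dc[0]))[0]
    total_kmers = sum(d * c for d, c in beyond)
    return GenomeSizeEstimate(
        k=k,
        valley_depth=valley_depth,
        peak_depth=peak_depth,
        genome_size_bp=total_kmers // peak_depth,
    )


def coverage_percent(assembly_bp: int, genome_size_bp: int) -> float:
    """Percent of the estimated genome covered by the assembly, 1 decimal."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    if assembly_bp <= 0:
        raise ValueError("assembly_bp must be positive")
    return percent(assembly_bp, genome_size_bp)
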