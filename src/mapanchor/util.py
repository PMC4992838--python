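"""Small shared helpers: rounding, reverse complement, IUPAC alphabet."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

#: Uppercase IUPAC nucleotide codes accepted in sequences.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero, as in printed report tables.

    Python's built-in ``round`` uses banker's rounding; report percentages
    follow the half-up convention instead (81.45 -> 81.5).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded."""
    if denominator == 0:
        raise ValueError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, decimals)
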