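"""Assembly and annotation summary arithmetic: Nxx, completeness ratios, GC.

These are the small checkable numbers of a genome report: N50/N90 of contig
or scaffold length sets, completeness percentages (CEGMA/BUSCO-style
found/total ratios), and GC content of sequences.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

__all__ = ["nxx", "n50", "completeness_percent", "gc_content", "length_summary"]


def nxx(lengths: Sequence[int], x: float = 50.0) -> int:
    """Nxx: the smallest length L such that sequences of length >= L cover at
    least x% of the total (descending cumulative sum, inclusive threshold)."""
    if not lengths:
        raise ValueError("empty length set")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    threshold = x / 100.0 * sum(ordered)
    cum = 0
    for l in ordered:
        cum += l
        if cum >= threshold:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def n50(lengths: Sequence[int]) -> int:
    return nxx(lengths, 50.0)


def completeness_percent(found: int, total: int, decimals: int = 2) -> float:
    """100 * found / total, rounded half-up to ``decimals`` places."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= found <= total:
        raise ValueError("found must be within [0, total]")
    pct = Decimal(100 * found) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def gc_content(seq: str) -> float:
    """GC percentage over A/C/G/T characters only (others excluded)."""
    seq = seq.upper()
    gc = sum(seq.count(b) for b in "GC")
    acgt = gc + sum(seq.count(b) for b in "AT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous nucleotides")
    return 100.0 * gc / acgt


def length_summary(lengths: Iterable[int]) -> dict[str, int | float]:
    """Count, total, max, N50 and N90 for a set of sequence lengths."""
    ls = list(lengths)
    return {
        "count": len(ls),
        "total_bp": sum(ls),
        "max_bp": max(ls),
        "n50_bp": nxx(ls, 50.0),
        "n90_bp": nxx(ls, 90.0),
    }
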