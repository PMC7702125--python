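"""Fourfold-degenerate transversion (4DTv) statistics for paralog pairs.

The 4DTv of a codon-aligned gene pair is the fraction of fourfold-degenerate
third-codon sites at which the two sequences differ by a transversion
(purine <-> pyrimidine).  Plotted over all duplicate pairs of a genome
(the paranome), the modal value dates whole-genome duplications: older
events sit at larger 4DTv.

The raw fraction saturates with time, so it is corrected with the
transversion-distance component of the HKY/TN93 model family,

    d_tv = -2 * piR * piY * ln(1 - Q / (2 * piR * piY)),

where Q is the raw transversion fraction and piR, piY the purine and
pyrimidine frequencies pooled over both sequences at the 4D sites.  At equal
base frequencies this reduces to the familiar -1/2 * ln(1 - 2Q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FOURFOLD_PREFIXES",
    "CodonAlignment",
    "FourfoldSiteSet",
    "DtvResult",
    "ParanomeSummary",
    "classify_fourfold_sites",
    "count_substitutions_4d",
    "raw_4dtv",
    "corrected_4dtv",
    "paranome_4dtv",
]

#: Codon prefixes (positions 1-2) whose third position is fourfold degenerate
#: under the standard genetic code: Ala, Arg4, Gly, Leu4, Pro, Ser4, Thr, Val.
FOURFOLD_PREFIXES = frozenset({"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"})

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of aligned coding sequences, in frame (length % 3 == 0)."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.pair_id}: aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.pair_id}: alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass(frozen=True)
class FourfoldSiteSet:
    """Third-position alignment columns classified as fourfold degenerate."""

    site_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        for i in self.site_indices:
            if i % 3 != 2:
                raise ValueError(f"site index {i} is not a third codon position")

    @property
    def n_4d(self) -> int:
        return len(self.site_indices)


@dataclass(frozen=True)
class DtvResult:
    pair_id: str
    n_4d: int
    n_transversion: int
    n_transition: int
    raw_4dtv: float | None
    corrected_4dtv: float | None
    base_freqs_4d: tuple[float, float, float, float] | None
    saturated: bool = False


@dataclass(frozen=True)
class ParanomeSummary:
    """Distribution of corrected 4DTv over a set of paralog pairs."""

    results: tuple[DtvResult, ...]
    bin_edges: np.ndarray
    counts: np.ndarray
    peak: float
    peak_tied: bool
    n_excluded_short: int
    n_excluded_saturated: int


def classify_fourfold_sites(aln: CodonAlignment) -> FourfoldSiteSet:
    """Select third-position columns that are fourfold degenerate in *both*
    sequences.

    A column qualifies iff the codon is gap-free and ACGT-only in both
    sequences, the two codons agree at positions 1-2, and that shared prefix
    belongs to a fourfold-degenerate codon family.  Codons where only one
    sequence is fourfold degenerate are excluded (strict agreement rule).
    """
    sites: list[int] = []
    a, b = aln.seq_a, aln.seq_b
    for c in range(aln.n_codons):
        ca = a[3 * c : 3 * c + 3]
        cb = b[3 * c : 3 * c + 3]
        if not (_acgt_only(ca) and _acgt_only(cb)):
            continue
        if ca[:2] != cb[:2]:
            continue
        if ca[:2] in FOURFOLD_PREFIXES:
            sites.append(3 * c + 2)
    return FourfoldSiteSet(site_indices=tuple(sites))


def _acgt_only(codon: str) -> bool:
    return all(ch in "ACGT" for ch in codon)


def count_substitutions_4d(
    aln: CodonAlignment, sites: FourfoldSiteSet
) -> tuple[int, int]:
    """Count (transversions, transitions) over the 4D columns of a pair."""
    n_tv = n_ts = 0
    for i in sites.site_indices:
        x, y = aln.seq_a[i], aln.seq_b[i]
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            n_ts += 1
        else:
            n_tv += 1
    return n_tv, n_ts


def raw_4dtv(n_transversion: int, n_4d: int) -> float | None:
    """4DT / 4D; None when there are no 4D sites (pair excluded, not an error)."""
    if n_4d == 0:
        return None
    return n_transversion / n_4d


def corrected_4dtv(
    raw_q: float, base_freqs_4d: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
) -> float | None:
    """Transversion distance correcting the raw 4DTv for multiple hits.

    Returns None (saturated) when raw_q >= 2 * piR * piY, the supremum of the
    observable transversion fraction under the model.
    """
    if raw_q < 0:
        raise ValueError("raw 4DTv cannot be negative")
    if raw_q == 0:
        return 0.0
    pa, pc, pg, pt = base_freqs_4d
    pi_r, pi_y = pa + pg, pc + pt
    ceiling = 2.0 * pi_r * pi_y
    if ceiling <= 0 or raw_q >= ceiling:
        return None
    return -ceiling * math.log1p(-raw_q / ceiling)


def analyze_pair(aln: CodonAlignment) -> DtvResult:
    """Full per-pair 4DTv computation: site classification, counts, raw and
    corrected values, with base frequencies pooled over both sequences at the
    4D sites."""
    sites = classify_fourfold_sites(aln)
    n_tv, n_ts = count_substitutions_4d(aln, sites)
    raw = raw_4dtv(n_tv, sites.n_4d)
    if raw is None:
        return DtvResult(aln.pair_id, 0, n_tv, n_ts, None, None, None)
    freqs = _pooled_freqs(aln, sites)
    corr = corrected_4dtv(raw, freqs)
    return DtvResult(
        pair_id=aln.pair_id,
        n_4d=sites.n_4d,
        n_transversion=n_tv,
        n_transition=n_ts,
        raw_4dtv=raw,
        corrected_4dtv=corr,
        base_freqs_4d=freqs,
        saturated=corr is None,
    )


def _pooled_freqs(
    aln: CodonAlignment, sites: FourfoldSiteSet
) -> tuple[float, float, float, float]:
    counts = {b: 0 for b in "ACGT"}
    for i in sites.site_indices:
        counts[aln.seq_a[i]] += 1
        counts[aln.seq_b[i]] += 1
    total = sum(counts.values())
    return tuple(counts[b] / total for b in "ACGT")  # type: ignore[return-value]


def paranome_4dtv(
    pairs: Sequence[CodonAlignment],
    min_4d_sites: int = 10,
    bin_width: float = 0.02,
    value: str = "corrected",
) -> ParanomeSummary:
    """Histogram the per-pair 4DTv values of a paranome and locate the modal
    bin, whose midpoint estimates the WGD signature.

    Pairs with fewer than ``min_4d_sites`` usable columns or a saturated
    correction are excluded and counted separately.  Ties between modal bins
    resolve to the leftmost bin and are flagged.
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    if value not in {"corrected", "raw"}:
        raise ValueError("value must be 'corrected' or 'raw'")
    results = tuple(analyze_pair(p) for p in pairs)
    n_short = sum(1 for r in results if r.n_4d < min_4d_sites)
    n_sat = sum(1 for r in results if r.n_4d >= min_4d_sites and r.saturated)
    usable = [
        (r.corrected_4dtv if value == "corrected" else r.raw_4dtv)
        for r in results
        if r.n_4d >= min_4d_sites and not r.saturated
    ]
    if not usable:
        raise ValueError("no usable pairs after exclusions")
    edges = np.arange(0.0, 2.0 + bin_width, bin_width)
    counts, edges = np.histogram(usable, bins=edges)
    peak_idx = int(np.argmax(counts))  # argmax takes the leftmost maximum
    peak = float((edges[peak_idx] + edges[peak_idx + 1]) / 2.0)
    tied = int((counts == counts[peak_idx]).sum()) > 1
    return ParanomeSummary(
        results=results,
        bin_edges=edges,
        counts=counts,
        peak=peak,
        peak_tied=tied,
        n_excluded_short=n_short,
        n_excluded_saturated=n_sat,
    )
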