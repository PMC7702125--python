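"""Centromeric-satellite detection from tandem-repeat tables.

Plant centromeres are marked by megabase-scale arrays of a species-specific
satellite monomer (order 100-200 bp).  The scan proceeds in four steps:

1. cluster tandem-repeat monomers by sequence identity, invariant to
   circular rotation and strand, since a tandem monomer has no defined
   phase or orientation;
2. take the cluster covering the most genomic bases as the base repeat;
3. map its representative monomer back onto the genome (internal
   seed-and-extend scan, or an external tabular hit file);
4. call per-chromosome centromeres as the densest fixed-size window
   (default 300 kb) of satellite coverage, merged with adjacent windows of
   at least half that density; chromosomes whose best window stays below a
   minimum satellite fraction get ``no_call``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .io_formats import SequenceRecord, TandemRepeatRecord
from .assembly_stats import gc_content

__all__ = [
    "SatelliteCluster",
    "CentromereCall",
    "MonomerHit",
    "rotation_identity",
    "cluster_monomers",
    "base_repeat",
    "map_monomer",
    "call_centromeres",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MonomerHit:
    chrom: str
    start0: int
    end0: int
    strand: str
    identity: float


@dataclass(frozen=True)
class SatelliteCluster:
    cluster_id: str
    representative_monomer: str
    member_records: tuple[TandemRepeatRecord, ...]
    total_copies: float
    total_bases: int


@dataclass(frozen=True)
class CentromereCall:
    chrom: str
    start0: int | None
    end0: int | None
    peak_density: float
    monomer_length: int | None
    monomer_gc: float | None
    status: str  # "called" | "no_call"


def rotation_identity(a: str, b: str) -> float:
    """Best identity between two monomers over all circular rotations of
    either, on either strand.

    Computed exactly by aligning the shorter monomer against a doubled copy
    of the longer (infix edit-distance), which realises every rotation.
    Identity = 1 - edit_distance / len(shorter).
    """
    a, b = a.upper(), b.upper()
    if len(a) > len(b):
        a, b = b, a
    best = min(
        edlib.align(a, b + b, mode="HW", task="distance")["editDistance"],
        edlib.align(_revcomp(a), b + b, mode="HW", task="distance")["editDistance"],
    )
    return 1.0 - best / len(a)


def cluster_monomers(
    repeats: Sequence[TandemRepeatRecord],
    min_identity: float = 0.80,
    period_range: tuple[int, int] = (50, 500),
) -> list[SatelliteCluster]:
    """Greedy single-linkage clustering of tandem-repeat monomers.

    Records outside ``period_range`` are dropped first.  Input order does not
    matter: records are canonically sorted before the greedy pass.  Clusters
    come back ordered by total bases covered, descending; the representative
    is the monomer of the member with the most copies.
    """
    if not repeats:
        raise ValueError("no tandem-repeat records supplied")
    lo, hi = period_range
    pool = sorted(
        (r for r in repeats if lo <= r.period <= hi),
        key=lambda r: (r.period, r.monomer, r.chrom, r.start),
    )
    if not pool:
        raise ValueError(f"no records with period in [{lo}, {hi}]")
    clusters: list[list[TandemRepeatRecord]] = []
    for rec in pool:
        joined = None
        for members in clusters:
            if any(rotation_identity(rec.monomer, m.monomer) >= min_identity for m in members):
                if joined is None:
                    members.append(rec)
                    joined = members
                else:  # single linkage: rec bridges two clusters -> merge
                    joined.extend(members)
                    members.clear()
        if joined is None:
            clusters.append([rec])
    out: list[SatelliteCluster] = []
    for members in clusters:
        if not members:
            continue
        rep = max(members, key=lambda m: (m.copy_number, -m.period))
        out.append(
            SatelliteCluster(
                cluster_id="",
                representative_monomer=rep.monomer,
                member_records=tuple(members),
                total_copies=sum(m.copy_number for m in members),
                total_bases=sum(m.span for m in members),
            )
        )
    out.sort(key=lambda c: (-c.total_bases, -len(c.representative_monomer)))
    return [
        SatelliteCluster(
            cluster_id=f"cluster{i:03d}",
            representative_monomer=c.representative_monomer,
            member_records=c.member_records,
            total_copies=c.total_copies,
            total_bases=c.total_bases,
        )
        for i, c in enumerate(out)
    ]


def base_repeat(clusters: Sequence[SatelliteCluster]) -> SatelliteCluster:
    """The cluster covering the most genomic bases (tie: longer monomer)."""
    if not clusters:
        raise ValueError("no clusters supplied")
    return max(
        clusters, key=lambda c: (c.total_bases, len(c.representative_monomer))
    )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 k-mer codes; positions containing non-ACGT get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c < 4
        out = out * 4 + np.where(c < 4, c, 0)
    out[~valid] = -1
    return out


def map_monomer(
    genome: Sequence[SequenceRecord],
    monomer: str,
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    seed_k: int = 12,
) -> list[MonomerHit]:
    """Locate copies of a satellite monomer by seed-and-extend scanning.

    Every ``seed_k``-mer shared between the monomer (either strand) and a
    chromosome nominates a candidate copy start; nearby candidates are
    merged, and each is verified by an edit-distance alignment of the
    monomer against the local genomic window.  A hit is kept iff its
    identity >= ``min_identity`` and the aligned fraction of the monomer
    >= ``min_coverage``.
    """
    monomer = monomer.upper()
    m = len(monomer)
    if m < 20:
        raise ValueError("monomer shorter than the minimum seed span (20 bp)")
    hits: list[MonomerHit] = []
    for strand, query in (("+", monomer), ("-", _revcomp(monomer))):
        q_codes = _kmer_codes(_encode(query), seed_k)
        kmer_to_offsets: dict[int, list[int]] = {}
        for off, code in enumerate(q_codes):
            if code >= 0:
                kmer_to_offsets.setdefault(int(code), []).append(off)
        q_set = np.fromiter(kmer_to_offsets.keys(), dtype=np.int64, count=len(kmer_to_offsets))
        for rec in genome:
            g_codes = _kmer_codes(_encode(rec.seq), seed_k)
            match_pos = np.flatnonzero(np.isin(g_codes, q_set))
            cand: dict[int, int] = {}
            for pos in match_pos:
                for off in kmer_to_offsets[int(g_codes[pos])]:
                    start = int(pos) - off
                    cand[start] = cand.get(start, 0) + 1
            for start in _merge_candidates(cand, m):
                lo = max(0, start - m // 2)
                hi = min(len(rec.seq), start + m + m // 2)
                res = edlib.align(query, rec.seq[lo:hi], mode="HW", task="locations")
                if not res["locations"]:
                    continue
                s, e = res["locations"][0]
                aln_len = e - s + 1
                identity = 1.0 - res["editDistance"] / m
                if identity >= min_identity and aln_len / m >= min_coverage:
                    hits.append(
                        MonomerHit(
                            chrom=rec.id,
                            start0=lo + s,
                            end0=lo + e + 1,
                            strand=strand,
                            identity=identity,
                        )
                    )
    hits.sort(key=lambda h: (h.chrom, h.start0, h.end0))
    return _dedupe_hits(hits, m)


def _merge_candidates(cand: Mapping[int, int], m: int) -> list[int]:
    """Collapse candidate starts within half a monomer of each other, keeping
    the best-supported position of each group."""
    out: list[int] = []
    group: list[tuple[int, int]] = []
    for start in sorted(cand):
        if group and start - group[-1][0] > m // 2:
            out.append(max(group, key=lambda t: t[1])[0])
            group = []
        group.append((start, cand[start]))
    if group:
        out.append(max(group, key=lambda t: t[1])[0])
    return out


def _dedupe_hits(hits: list[MonomerHit], m: int) -> list[MonomerHit]:
    """Drop hits overlapping a better previous hit by more than half the
    monomer length (plus/minus strand duplicates of the same copy)."""
    kept: list[MonomerHit] = []
    for h in hits:
        if kept and h.chrom == kept[-1].chrom and h.start0 < kept[-1].end0 - m // 2:
            if h.identity > kept[-1].identity:
                kept[-1] = h
            continue
        kept.append(h)
    return kept


def call_centromeres(
    hits: Sequence[MonomerHit],
    chrom_lengths: Mapping[str, int],
    window: int = 300_000,
    min_fraction: float = 0.05,
    base: SatelliteCluster | None = None,
) -> list[CentromereCall]:
    """Call one centromere per chromosome from satellite hit density.

    Satellite bp are summed in non-overlapping windows; the maximal window
    plus flanking windows of at least half its density are merged into the
    call.  When the best window's satellite fraction falls below
    ``min_fraction`` the chromosome is reported ``no_call``.  Monomer length
    and GC come from the base repeat when supplied.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mono_len = len(base.representative_monomer) if base else None
    mono_gc = round(gc_content(base.representative_monomer), 2) if base else None
    per_chrom: dict[str, list[MonomerHit]] = {c: [] for c in chrom_lengths}
    for h in hits:
        if h.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {h.chrom!r} absent from chrom_lengths")
        per_chrom[h.chrom].append(h)
    calls: list[CentromereCall] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_win = max(1, -(-length // window))
        density = np.zeros(n_win)
        for h in per_chrom[chrom]:
            _add_interval(density, h.start0, min(h.end0, length), window)
        peak_idx = int(np.argmax(density))
        peak = float(density[peak_idx])
        win_len = min(window, length - peak_idx * window)
        if win_len <= 0 or peak / win_len < min_fraction:
            calls.append(
                CentromereCall(chrom, None, None, peak, mono_len, mono_gc, "no_call")
            )
            continue
        lo = hi = peak_idx
        while lo > 0 and density[lo - 1] >= peak / 2.0:
            lo -= 1
        while hi < n_win - 1 and density[hi + 1] >= peak / 2.0:
            hi += 1
        calls.append(
            CentromereCall(
                chrom=chrom,
                start0=lo * window,
                end0=min((hi + 1) * window, length),
                peak_density=peak,
                monomer_length=mono_len,
                monomer_gc=mono_gc,
                status="called",
            )
        )
    return calls


def _add_interval(density: np.ndarray, start0: int, end0: int, window: int) -> None:
    """Distribute an interval's bp over the windows it crosses."""
    w = start0 // window
    while start0 < end0:
        boundary = min(end0, (w + 1) * window)
        density[w] += boundary - start0
        start0 = boundary
        w += 1
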