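"""Rule-based gene-family screening and tandem-array detection.

Candidate family members (e.g. the KCS elongases of the very-long-chain
fatty-acid pathway, or LEA proteins) are called by a two-part rule:

1. a homology filter on the best hit against the seed queries — E-value
   <= 1e-5, alignment identity >= 50% and query coverage >= 50% by default;
2. a Pfam-domain requirement: the candidate must carry all the query's
   diagnostic domains.

LEA proteins are additionally classified into subfamilies purely by
diagnostic Pfam domain (strict E-value < 0.01).  Tandem arrays — runs of
same-family genes produced by sequential local duplication — are detected by
chaining neighbouring members on a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainAnnotation, GeneModel, HomologyHit

__all__ = [
    "LEA_DOMAIN_MAP",
    "FamilyAssignment",
    "TandemArray",
    "filter_homology",
    "require_shared_domains",
    "classify_lea",
    "detect_tandem_arrays",
    "screen_family",
]

#: Diagnostic Pfam domain -> LEA subfamily label.
LEA_DOMAIN_MAP: Mapping[str, str] = {
    "PF03760": "LEA1",
    "PF03168": "LEA2",
    "PF03242": "LEA3",
    "PF02987": "LEA4",
    "PF00477": "LEA5",
    "PF00257": "dehydrin",
    "PF04927": "SMP",
}


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    family: str
    evidence: tuple[object, ...]
    ambiguous: bool = False


@dataclass(frozen=True)
class TandemArray:
    chrom: str
    gene_ids: tuple[str, ...]
    span_bp: int
    n_genes: int


def filter_homology(
    hits: Sequence[HomologyHit],
    max_evalue: float = 1e-5,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> set[str]:
    """Genes with at least one hit passing all three thresholds.

    Boundary values pass: E-value <= max_evalue, identity >= min_identity,
    coverage >= min_coverage.  The candidate gene is the query side of the
    hit (the proteome searched against the seed queries).
    """
    return {
        h.query_id
        for h in hits
        if h.evalue <= max_evalue
        and h.pct_identity >= min_identity
        and h.coverage >= min_coverage
    }


def require_shared_domains(
    candidates: Iterable[str],
    domains: Sequence[DomainAnnotation],
    query_domains: set[str] | frozenset[str],
    exact: bool = False,
) -> set[str]:
    """Keep candidates whose domain set contains every query domain.

    With ``exact=True`` the candidate's domain set must equal the query's
    instead of merely containing it.
    """
    if not query_domains:
        raise ValueError("query_domains must be non-empty")
    by_gene: dict[str, set[str]] = {}
    for d in domains:
        by_gene.setdefault(d.gene_id, set()).add(d.pfam_acc)
    wanted = set(query_domains)
    out: set[str] = set()
    for gid in candidates:
        have = by_gene.get(gid, set())
        if (have == wanted) if exact else (have >= wanted):
            out.add(gid)
    return out


def classify_lea(
    domains: Sequence[DomainAnnotation], max_evalue: float = 0.01
) -> list[FamilyAssignment]:
    """Assign genes to LEA subfamilies by diagnostic Pfam domain.

    A gene joins every subfamily whose domain it carries with a per-domain
    E-value strictly below ``max_evalue``; genes supporting several
    subfamilies are flagged ambiguous.  Accessions outside the LEA map are
    ignored with a warning.
    """
    per_gene: dict[str, dict[str, list[DomainAnnotation]]] = {}
    for d in domains:
        if d.pfam_acc not in LEA_DOMAIN_MAP:
            warnings.warn(
                f"ignoring non-LEA Pfam accession {d.pfam_acc} on {d.gene_id}",
                stacklevel=2,
            )
            continue
        if d.domain_evalue < max_evalue:
            fam = LEA_DOMAIN_MAP[d.pfam_acc]
            per_gene.setdefault(d.gene_id, {}).setdefault(fam, []).append(d)
    out: list[FamilyAssignment] = []
    for gid in sorted(per_gene):
        fams = per_gene[gid]
        ambiguous = len(fams) > 1
        for fam in sorted(fams):
            out.append(
                FamilyAssignment(
                    gene_id=gid,
                    family=fam,
                    evidence=tuple(fams[fam]),
                    ambiguous=ambiguous,
                )
            )
    return out


def detect_tandem_arrays(
    members: Sequence[GeneModel],
    all_genes: Sequence[GeneModel],
    max_gap_bp: int = 100_000,
    max_intervening: int = 5,
) -> list[TandemArray]:
    """Chain neighbouring family members into tandem arrays.

    Per chromosome, members sorted by start chain when consecutive members
    are within ``max_gap_bp`` (start-to-start) and separated by at most
    ``max_intervening`` non-member genes.  Maximal chains of >= 2 genes are
    reported with their span (end of last minus start of first).
    """
    known_chroms = {g.chrom for g in all_genes}
    member_ids = {g.gene_id for g in members}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in members:
        if g.chrom not in known_chroms:
            raise ValueError(f"member {g.gene_id} on unknown chromosome {g.chrom!r}")
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays: list[TandemArray] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda g: g.start)
        others = sorted(
            (g for g in all_genes if g.chrom == chrom and g.gene_id not in member_ids),
            key=lambda g: g.start,
        )
        chain: list[GeneModel] = [ms[0]]
        for prev, cur in zip(ms, ms[1:]):
            n_between = sum(1 for g in others if prev.end < g.start < cur.start)
            if cur.start - prev.start <= max_gap_bp and n_between <= max_intervening:
                chain.append(cur)
            else:
                _flush(chain, arrays)
                chain = [cur]
        _flush(chain, arrays)
    return arrays


def _flush(chain: list[GeneModel], arrays: list[TandemArray]) -> None:
    if len(chain) >= 2:
        arrays.append(
            TandemArray(
                chrom=chain[0].chrom,
                gene_ids=tuple(g.gene_id for g in chain),
                span_bp=chain[-1].end - chain[0].start,
                n_genes=len(chain),
            )
        )


def screen_family(
    hits: Sequence[HomologyHit],
    domains: Sequence[DomainAnnotation],
    query_domains: set[str] | frozenset[str],
    max_evalue: float = 1e-5,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    exact_domains: bool = False,
) -> set[str]:
    """The full two-part screen: homology filter then shared-domain rule."""
    passing = filter_homology(hits, max_evalue, min_identity, min_coverage)
    return require_shared_domains(passing, domains, query_domains, exact=exact_domains)
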