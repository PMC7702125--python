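"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are stored 1-based inclusive, exactly as they appear
in GFF3 and Tandem Repeats Finder output; the ``start0``/``end0`` properties
expose the 0-based half-open view used for window arithmetic so that interval
code never repeats the conversion.

Readers validate strictly and raise :class:`FormatError` with the offending
line number where one exists.  Writers are byte-stable: writing then reading
returns identical records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GeneModel",
    "HomologyHit",
    "DomainAnnotation",
    "TandemRepeatRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "read_blast_tab",
    "best_hits",
    "read_trf_dat",
    "read_domtbl",
    "write_gff3_genes",
    "write_blast_tab",
    "write_trf_dat",
    "write_domtbl",
]

_IUPAC_NT = set("ACGTRYSWKMBDHVN")
_PFAM_RE = re.compile(r"^PF\d{5}$")


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    description: str = ""
    #: True when the sequence contains characters outside A/C/G/T
    #: (lowercase input is upper-cased before this check).
    has_ambiguous: bool = False

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_label: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end


@dataclass(frozen=True)
class HomologyHit:
    """One row of a tabular (outfmt 6) protein/nucleotide homology search.

    ``coverage`` is derived at read time as 100 * aln_length / query_length,
    the "alignment coverage of the query" used by the gene-family screen.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_length: int
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"{self.query_id}: pct_identity out of [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative E-value")
        if self.query_length <= 0:
            raise ValueError(f"{self.query_id}: non-positive query length")
        object.__setattr__(
            self, "coverage", 100.0 * self.aln_length / self.query_length
        )


@dataclass(frozen=True)
class DomainAnnotation:
    gene_id: str
    pfam_acc: str
    domain_evalue: float

    def __post_init__(self) -> None:
        if not _PFAM_RE.match(self.pfam_acc):
            raise ValueError(f"{self.gene_id}: malformed Pfam accession {self.pfam_acc}")
        if self.domain_evalue < 0:
            raise ValueError(f"{self.gene_id}: negative domain E-value")


@dataclass(frozen=True)
class TandemRepeatRecord:
    """One tandem-repeat locus from a Tandem Repeats Finder .dat table."""

    chrom: str
    start: int
    end: int
    period: int
    copy_number: float
    monomer: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < self.period:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: interval shorter than period"
            )
        if self.copy_number < 1.0:
            raise ValueError(f"{self.chrom}:{self.start}: copy number < 1")
        if len(self.monomer) != self.period:
            raise ValueError(
                f"{self.chrom}:{self.start}: monomer length {len(self.monomer)} != period {self.period}"
            )

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased records.

    Raises :class:`FormatError` on an empty file or a duplicate id.  Records
    containing IUPAC ambiguity codes are kept with ``has_ambiguous=True``;
    downstream site classification skips non-ACGT columns.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - _IUPAC_NT - set("-.*")
        # Protein sequences are allowed through untouched; only flag
        # nucleotide-alphabet records that carry ambiguity codes.
        is_nt = not bad
        has_ambiguous = is_nt and bool(set(seq) - set("ACGT-"))
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, seq=seq, description=desc, has_ambiguous=has_ambiguous)
        )
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records with fixed 60-column wrapping (byte-stable round trip)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read features of type ``gene`` from a GFF3 file, in file order.

    Only the gene rows are kept; mRNA/exon/CDS hierarchy is ignored.  The
    optional ``family`` attribute populates ``family_label``.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end ({start} > {end})")
            attr_map = _parse_gff3_attributes(attrs)
            if "ID" not in attr_map:
                raise FormatError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            genes.append(
                GeneModel(
                    gene_id=attr_map["ID"],
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    family_label=attr_map.get("family"),
                )
            )
    return genes


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def read_blast_tab(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[HomologyHit]:
    """Read a 12-column tabular homology table (outfmt 6 dialect).

    ``query_lengths`` supplies the query sequence lengths (typically from the
    query FASTA) from which per-hit query coverage is derived.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            qid, sid = fields[0], fields[1]
            if qid not in query_lengths:
                raise FormatError(f"{path}:{lineno}: query {qid!r} absent from query lengths")
            try:
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric column") from exc
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=pident,
                    aln_length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                    query_length=query_lengths[qid],
                )
            )
    return hits


def best_hits(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Collapse multiple HSPs per (query, subject) pair to the best one.

    Best = lowest E-value, ties broken by highest bit-score.
    """
    by_pair: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = by_pair.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            by_pair[key] = h
    return list(by_pair.values())


def read_trf_dat(path: str | Path) -> list[TandemRepeatRecord]:
    """Read a Tandem Repeats Finder .dat table.

    The dialect: ``Sequence: <name>`` headers introduce each input sequence;
    data rows are whitespace-separated with start, end, period and copy
    number in columns 1-4 and the consensus monomer in column 14.
    """
    records: list[TandemRepeatRecord] = []
    chrom: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chrom = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Tandem", "Program", "Version", "Parameters")):
                continue
            fields = line.split()
            if not fields[0].isdigit():
                continue
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: data row before any Sequence header")
            if len(fields) < 14:
                raise FormatError(f"{path}:{lineno}: expected >= 14 columns, got {len(fields)}")
            try:
                start, end, period = int(fields[0]), int(fields[1]), int(fields[2])
                copies = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric column") from exc
            records.append(
                TandemRepeatRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    period=period,
                    copy_number=copies,
                    monomer=fields[13].upper(),
                )
            )
    return records


def read_domtbl(path: str | Path) -> list[DomainAnnotation]:
    """Read an HMMER domain table (domtblout dialect), one row per domain.

    Column 1 is the sequence (gene) name, column 5 the Pfam accession of the
    matched profile and column 13 the per-domain independent E-value.  Any
    version suffix on the accession (``PF03760.15``) is stripped.
    """
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 13:
                raise FormatError(f"{path}:{lineno}: expected >= 13 columns, got {len(fields)}")
            acc = fields[4].split(".")[0]
            try:
                evalue = float(fields[12])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric i-E-value") from exc
            try:
                out.append(DomainAnnotation(gene_id=fields[0], pfam_acc=acc, domain_evalue=evalue))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.family_label:
                attrs += f";family={g.family_label}"
            fh.write(
                f"{g.chrom}\tgenevol\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 12-column outfmt-6 dialect (coordinates synthesised
    from the alignment length, since only identity/length/E-value/bit-score
    carry information downstream)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        "0",
                        "0",
                        "1",
                        str(h.aln_length),
                        "1",
                        str(h.aln_length),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def write_trf_dat(records: Iterable[TandemRepeatRecord], path: str | Path) -> None:
    """Write records in the Tandem Repeats Finder .dat dialect, grouped under
    one ``Sequence:`` header per chromosome (file order preserved within)."""
    by_chrom: dict[str, list[TandemRepeatRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    with open(path, "w") as fh:
        fh.write("Tandem Repeats Finder Program\n\n")
        for chrom, recs in by_chrom.items():
            fh.write(f"Sequence: {chrom}\n\n")
            for r in recs:
                repeat_seq = (r.monomer * -(-r.span // r.period))[: r.span]
                fh.write(
                    f"{r.start} {r.end} {r.period} {r.copy_number:.1f} "
                    f"{r.period} 95 0 100 25 25 25 25 1.92 "
                    f"{r.monomer} {repeat_seq}\n"
                )


def write_domtbl(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    """Write a minimal HMMER domtblout-dialect table (13 columns through the
    per-domain independent E-value)."""
    with open(path, "w") as fh:
        fh.write("# target_name t_acc tlen query_name q_acc qlen e_full score "
                 "bias n of c_evalue i_evalue\n")
        for d in domains:
            fh.write(
                f"{d.gene_id} - 500 {d.pfam_acc} {d.pfam_acc} 100 "
                f"{d.domain_evalue:.3g} 50.0 0.1 1 1 {d.domain_evalue:.3g} "
                f"{d.domain_evalue:.3g}\n"
            )
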