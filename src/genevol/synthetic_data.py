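"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and emits
data in the same formats the readers in :mod:`genevol.io_formats` consume:

* codon-aligned paralog pairs diverged under an HKY process at a chosen
  third-position distance (for 4DTv recovery),
* LTR pairs of known insertion age evolved under Jukes-Cantor dynamics,
* chromosomes carrying a planted satellite array plus decoy repeats, with a
  matching Tandem Repeats Finder table,
* gene-family fixtures (GFF3 + homology + domain tables) in which every decoy
  violates exactly one screening criterion,
* overdispersed count matrices with planted stage-specific up-regulation.

HKY evolution uses the exact transition-probability matrix (matrix
exponential of the normalised rate matrix), so expected transversion
probabilities are computable in closed form and serve as independent oracles
for the estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .codon_evolution import FOURFOLD_PREFIXES, CodonAlignment, corrected_4dtv
from .io_formats import (
    DomainAnnotation,
    GeneModel,
    HomologyHit,
    SequenceRecord,
    TandemRepeatRecord,
)

__all__ = [
    "HKYParams",
    "SimulationTruth",
    "hky_rate_matrix",
    "hky_transition_matrix",
    "expected_raw_4dtv",
    "expected_transversion_distance",
    "distance_for_transversion_distance",
    "simulate_codon_pair_set",
    "simulate_ltr_cohort",
    "plant_satellite_chromosome",
    "make_family_fixture",
    "make_expression_fixture",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
#: (i, j) base-index pairs that are transversions.
_TV_PAIRS = [
    (i, j)
    for i in range(4)
    for j in range(4)
    if (_BASES[i] in "AG") != (_BASES[j] in "AG")
]


@dataclass(frozen=True)
class HKYParams:
    """HKY85 substitution model parameters.

    kappa is the transition/transversion *rate* ratio; base_freqs are the
    stationary frequencies (piA, piC, piG, piT).
    """

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(p <= 0 for p in self.base_freqs):
            raise ValueError("all base frequencies must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside each generated fixture."""

    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    items: dict[str, Any] = field(default_factory=dict)


def hky_rate_matrix(hky: HKYParams) -> np.ndarray:
    """HKY rate matrix normalised to one expected substitution per site per
    unit time at stationarity."""
    pi = np.asarray(hky.base_freqs)
    q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = {i, j} in ({0, 2}, {1, 3})  # A<->G or C<->T
            q[i, j] = (hky.kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


def hky_transition_matrix(distance: float, hky: HKYParams) -> np.ndarray:
    """P(distance) = exp(Q * distance) for the normalised HKY rate matrix."""
    if distance < 0:
        raise ValueError("distance cannot be negative")
    return expm(hky_rate_matrix(hky) * distance)


def expected_raw_4dtv(distance: float, hky: HKYParams) -> float:
    """Exact probability that two sequences separated by ``distance``
    substitutions/site differ by a transversion at a stationary site.

    This is the brute-force oracle for the raw 4DTv of simulated pairs:
    sum over transversion pairs (x, y) of pi_x * P(distance)_{xy}.
    """
    p = hky_transition_matrix(distance, hky)
    pi = np.asarray(hky.base_freqs)
    return float(sum(pi[i] * p[i, j] for i, j in _TV_PAIRS))


def expected_transversion_distance(distance: float, hky: HKYParams) -> float:
    """The transversion-distance component recovered by the 4DTv correction
    when applied to the exact expected raw fraction."""
    out = corrected_4dtv(expected_raw_4dtv(distance, hky), hky.base_freqs)
    assert out is not None
    return out


def distance_for_transversion_distance(target: float, hky: HKYParams) -> float:
    """Invert :func:`expected_transversion_distance`: the total HKY distance
    whose expected corrected 4DTv equals ``target``."""
    if target < 0:
        raise ValueError("target distance cannot be negative")
    if target == 0:
        return 0.0
    hi = 1.0
    while expected_transversion_distance(hi, hky) < target:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - unreachable for sane targets
            raise ValueError("target transversion distance unattainable")
    return float(
        brentq(lambda d: expected_transversion_distance(d, hky) - target, 0.0, hi)
    )


def _evolve(sites: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw descendant states for base-index array ``sites`` under transition
    matrix ``p`` (one multinomial draw per site, vectorised)."""
    cum = np.cumsum(p, axis=1)
    u = rng.random(sites.shape)
    return (u[..., None] > cum[sites]).sum(axis=-1).astype(np.int8)


# Non-stop codons whose third position is NOT fourfold degenerate; used as
# decoys to exercise site classification.
_NON4D_CODONS = ["TTT", "TTC", "ATG", "AAA", "AAG", "GAA", "GAT", "TGG", "CAT", "AGT"]


def simulate_codon_pair_set(
    n_pairs: int,
    n_codons: int,
    distance: float,
    hky: HKYParams = HKYParams(),
    seed: int = 0,
    non4d_fraction: float = 0.2,
) -> tuple[list[CodonAlignment], SimulationTruth]:
    """Simulate codon-aligned paralog pairs at a known third-position distance.

    Ancestral codons are drawn from fourfold-degenerate families (third
    position from the HKY stationary distribution), with a ``non4d_fraction``
    admixture of non-degenerate decoy codons.  Codon positions 1-2 are copied
    unchanged to both descendants; third positions evolve independently down
    two branches of length ``distance / 2`` under the exact HKY transition
    matrix, so the expected pairwise distance at third positions is
    ``distance``.
    """
    if distance < 0:
        raise ValueError("distance cannot be negative")
    if n_codons < 1:
        raise ValueError("need at least one codon")
    rng = np.random.default_rng(seed)
    p_half = hky_transition_matrix(distance / 2.0, hky)
    pi = np.asarray(hky.base_freqs)
    prefixes = sorted(FOURFOLD_PREFIXES)
    pairs: list[CodonAlignment] = []
    for k in range(n_pairs):
        is_4d = rng.random(n_codons) >= non4d_fraction
        anc_third = rng.choice(4, size=n_codons, p=pi).astype(np.int8)
        third_a = _evolve(anc_third, p_half, rng)
        third_b = _evolve(anc_third, p_half, rng)
        codons_a: list[str] = []
        codons_b: list[str] = []
        for c in range(n_codons):
            if is_4d[c]:
                prefix = prefixes[rng.integers(len(prefixes))]
                codons_a.append(prefix + _BASES[third_a[c]])
                codons_b.append(prefix + _BASES[third_b[c]])
            else:
                decoy = _NON4D_CODONS[rng.integers(len(_NON4D_CODONS))]
                codons_a.append(decoy)
                codons_b.append(decoy)
        pairs.append(
            CodonAlignment(
                pair_id=f"pair{k:04d}", seq_a="".join(codons_a), seq_b="".join(codons_b)
            )
        )
    exp_raw = expected_raw_4dtv(distance, hky)
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_pairs": n_pairs,
            "n_codons": n_codons,
            "distance": distance,
            "kappa": hky.kappa,
            "base_freqs": list(hky.base_freqs),
            "non4d_fraction": non4d_fraction,
        },
        items={
            "true_distance": distance,
            "expected_raw_4dtv": exp_raw,
            "expected_corrected_4dtv": (
                expected_transversion_distance(distance, hky) if distance > 0 else 0.0
            ),
        },
    )
    return pairs, truth


def _jc_transition_matrix(k: float) -> np.ndarray:
    """Jukes-Cantor P matrix for branch length k substitutions/site."""
    same = 0.25 + 0.75 * math.exp(-4.0 * k / 3.0)
    diff = (1.0 - same) / 3.0
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def simulate_ltr_cohort(
    n: int,
    ages_mya: float | Sequence[float],
    rate: float = 1.3e-8,
    ltr_length: int = 1000,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Simulate LTR pairs of known insertion age.

    ``ages_mya`` is a scalar (all elements share the age), a length-``n``
    list (per-element ages), or a shorter list sampled from uniformly (an age
    mixture).  Each element's ancestral LTR evolves independently down two
    branches of ``age`` years at ``rate`` substitutions/site/year under
    Jukes-Cantor dynamics; records are emitted as ``<id>_5p`` / ``<id>_3p``
    consecutive FASTA pairs.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    rng = np.random.default_rng(seed)
    if np.isscalar(ages_mya):
        ages = np.full(n, float(ages_mya))  # type: ignore[arg-type]
    else:
        pool = np.asarray(list(ages_mya), dtype=float)
        ages = pool if len(pool) == n else pool[rng.integers(len(pool), size=n)]
    if np.any(ages < 0):
        raise ValueError("ages cannot be negative")
    records: list[SequenceRecord] = []
    true_ages: dict[str, float] = {}
    for i in range(n):
        eid = f"elt{i:04d}"
        anc = rng.integers(4, size=ltr_length).astype(np.int8)
        p = _jc_transition_matrix(rate * ages[i] * 1e6)
        ltr5 = _evolve(anc, p, rng)
        ltr3 = _evolve(anc, p, rng)
        records.append(SequenceRecord(id=f"{eid}_5p", seq=_decode(ltr5)))
        records.append(SequenceRecord(id=f"{eid}_3p", seq=_decode(ltr3)))
        true_ages[eid] = float(ages[i])
    truth = SimulationTruth(
        seed=seed,
        params={"n": n, "rate": rate, "ltr_length": ltr_length},
        items={"true_ages_mya": true_ages},
    )
    return records, truth


def _decode(idx: np.ndarray) -> str:
    return "".join(_BASES[i] for i in idx)


def _mutate(seq: str, per_base_rate: float, rng: np.random.Generator) -> str:
    if per_base_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < per_base_rate
    for pos in np.flatnonzero(hit):
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def plant_satellite_chromosome(
    chrom_length: int,
    monomer: str,
    n_copies: int,
    locus_start: int,
    per_copy_mutation: float = 0.05,
    seed: int = 0,
    chrom_name: str = "chrS",
    n_decoys: int = 20,
) -> tuple[SequenceRecord, list[TandemRepeatRecord], SimulationTruth]:
    """Plant a tandem satellite array of known monomer and locus.

    The background is uniform random ACGT; ``n_copies`` tandem monomers, each
    independently mutated at ``per_copy_mutation`` per base, are written at
    0-based ``locus_start``.  ``n_decoys`` low-copy tandem repeats with random
    monomers are planted elsewhere.  Returns the chromosome, a matching
    Tandem Repeats Finder-style table, and the truth.
    """
    monomer = monomer.upper()
    array_len = n_copies * len(monomer)
    if locus_start + array_len > chrom_length:
        raise ValueError("satellite array exceeds chromosome length")
    rng = np.random.default_rng(seed)
    chrom = rng.integers(4, size=chrom_length).astype(np.int8)
    seq = np.frombuffer(_decode(chrom).encode(), dtype=np.uint8).copy()
    dat: list[TandemRepeatRecord] = []
    if n_copies > 0:
        copies = [_mutate(monomer, per_copy_mutation, rng) for _ in range(n_copies)]
        array = "".join(copies)
        seq[locus_start : locus_start + array_len] = np.frombuffer(
            array.encode(), dtype=np.uint8
        )
        dat.append(
            TandemRepeatRecord(
                chrom=chrom_name,
                start=locus_start + 1,
                end=locus_start + array_len,
                period=len(monomer),
                copy_number=float(n_copies),
                monomer=monomer,
            )
        )
    occupied = [(locus_start, locus_start + array_len)] if n_copies > 0 else []
    for d in range(n_decoys):
        dlen = int(rng.integers(30, 400))
        dcopies = int(rng.integers(2, 5))
        dmono = _decode(rng.integers(4, size=dlen).astype(np.int8))
        for _ in range(100):
            start = int(rng.integers(0, chrom_length - dlen * dcopies))
            span = (start, start + dlen * dcopies)
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                break
        else:  # pragma: no cover - only on absurdly full chromosomes
            continue
        occupied.append(span)
        seq[span[0] : span[1]] = np.frombuffer(
            (dmono * dcopies).encode(), dtype=np.uint8
        )
        dat.append(
            TandemRepeatRecord(
                chrom=chrom_name,
                start=span[0] + 1,
                end=span[1],
                period=dlen,
                copy_number=float(dcopies),
                monomer=dmono,
            )
        )
    record = SequenceRecord(id=chrom_name, seq=seq.tobytes().decode())
    truth = SimulationTruth(
        seed=seed,
        params={
            "chrom_length": chrom_length,
            "n_copies": n_copies,
            "per_copy_mutation": per_copy_mutation,
            "n_decoys": n_decoys,
        },
        items=(
            {
                "monomer": monomer,
                "locus": [locus_start, locus_start + array_len],
                "chrom": chrom_name,
            }
            if n_copies > 0
            else {}
        ),
    )
    return record, dat, truth


_VIOLATIONS = ("evalue", "identity", "coverage", "domain")
DEFAULT_QUERY_DOMAINS = frozenset({"PF08392", "PF02797"})


def make_family_fixture(
    n_genes: int,
    n_true_members: int,
    tandem_cluster_spec: tuple[str, int, int] | None = None,
    seed: int = 0,
    query_domains: frozenset[str] | set[str] = DEFAULT_QUERY_DOMAINS,
    family: str = "KCS",
) -> tuple[
    list[GeneModel], list[HomologyHit], list[DomainAnnotation], SimulationTruth
]:
    """Gene-family screening fixture with per-gene pass/fail truth.

    True members receive a homology hit passing all thresholds (E-value
    1e-10, identity 80%, coverage 80%) and every query Pfam domain; each
    decoy violates exactly one criterion (cycling through E-value, identity,
    coverage, missing domain).  ``tandem_cluster_spec = (chrom, k, span_bp)``
    places the first ``k`` true members on ``chrom`` so that the array spans
    exactly ``span_bp`` (end of last minus start of first); remaining genes
    are spread far apart on other chromosomes.
    """
    if n_true_members > n_genes:
        raise ValueError("more true members than genes")
    gene_width = 2000
    rng = np.random.default_rng(seed)
    member_ids = [f"g{i:04d}" for i in range(n_true_members)]
    decoy_ids = [f"g{i:04d}" for i in range(n_true_members, n_genes)]

    genes: list[GeneModel] = []
    cluster_ids: list[str] = []
    placed: set[str] = set()
    if tandem_cluster_spec is not None:
        chrom, k, span_bp = tandem_cluster_spec
        if k > n_true_members:
            raise ValueError("cluster larger than the true member set")
        if k >= 2 and span_bp < k * gene_width:
            raise ValueError("span too small for requested gene count")
        cluster_ids = member_ids[:k]
        first_start = 100_001
        if k == 1:
            starts = [first_start]
        else:
            # last gene's end = first start + span_bp, so the array's
            # (end of last - start of first) equals span_bp exactly
            last_start = first_start + span_bp - gene_width + 1
            starts = [
                first_start
                + round(i * (last_start - first_start) / (k - 1))
                for i in range(k)
            ]
        for gid, s in zip(cluster_ids, starts):
            genes.append(GeneModel(gid, chrom, s, s + gene_width - 1, "+", family))
            placed.add(gid)
    # Spread everything else >500 kb apart on rotating chromosomes so no
    # accidental tandem arrays arise.
    spread_chroms = ["chr1", "chr2", "chr3"]
    offsets = {c: 1_000_001 for c in spread_chroms}
    for gid in member_ids + decoy_ids:
        if gid in placed:
            continue
        c = spread_chroms[int(rng.integers(len(spread_chroms)))]
        s = offsets[c]
        offsets[c] += 500_000
        fam = family if gid in member_ids else None
        genes.append(GeneModel(gid, c, s, s + gene_width - 1, "+", fam))

    hits: list[HomologyHit] = []
    domains: list[DomainAnnotation] = []
    labels: dict[str, str] = {}
    qlen = 500

    def add_hit(gid: str, evalue: float, ident: float, cov_pct: float) -> None:
        hits.append(
            HomologyHit(
                query_id=gid,
                subject_id="ATQUERY1",
                pct_identity=ident,
                aln_length=int(round(cov_pct / 100.0 * qlen)),
                evalue=evalue,
                bitscore=200.0,
                query_length=qlen,
            )
        )

    for gid in member_ids:
        add_hit(gid, 1e-10, 80.0, 80.0)
        for acc in sorted(query_domains):
            domains.append(DomainAnnotation(gid, acc, 1e-10))
        labels[gid] = "member"
    for i, gid in enumerate(decoy_ids):
        violation = _VIOLATIONS[i % len(_VIOLATIONS)]
        labels[gid] = f"decoy:{violation}"
        ev, ident, cov = 1e-10, 80.0, 80.0
        if violation == "evalue":
            ev = 1e-3
        elif violation == "identity":
            ident = 30.0
        elif violation == "coverage":
            cov = 20.0
        add_hit(gid, ev, ident, cov)
        accs = sorted(query_domains)
        if violation == "domain":
            accs = accs[:-1]  # one query domain missing
        for acc in accs:
            domains.append(DomainAnnotation(gid, acc, 1e-10))

    truth = SimulationTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_true_members": n_true_members,
            "query_domains": sorted(query_domains),
            "tandem_cluster_spec": list(tandem_cluster_spec)
            if tandem_cluster_spec
            else None,
        },
        items={
            "labels": labels,
            "members": member_ids,
            "cluster_gene_ids": cluster_ids,
        },
    )
    return genes, hits, domains, truth


def make_expression_fixture(
    n_genes: int,
    samples: Sequence[str],
    upregulated: tuple[Sequence[int], float, tuple[str, str]] | None = None,
    seed: int = 0,
    n_reps: int = 3,
    dispersion: float = 0.005,
) -> tuple["pd.DataFrame", "pd.Series", SimulationTruth]:
    """Overdispersed count matrix with planted stage-specific up-regulation.

    ``samples`` lists the stage labels; each gets ``n_reps`` replicate columns
    named ``<stage>_r<i>``.  ``upregulated = (gene_indices, fold, (a, b))``
    multiplies the expected counts of those genes by ``fold`` in the later
    stage ``b``.  Counts are gamma-Poisson (negative-binomial-like); the
    default dispersion models tight pooled-material replicates, and planted
    genes get at least median baseline expression — fold-change nomination
    targets expressed candidates, and three replicates cannot recover folds
    of near-silent genes.  Gene lengths are uniform on [500, 5000] bp.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    columns = [f"{st}_r{r + 1}" for st in samples for r in range(n_reps)]
    base_mean = np.exp(rng.normal(math.log(100.0), 1.0, size=n_genes))
    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes), index=gene_ids, name="length"
    )
    up_ids: list[str] = []
    fold = 1.0
    stage_b = None
    if upregulated is not None:
        idxs, fold, (stage_a, stage_b) = upregulated
        if fold <= 0:
            raise ValueError("fold must be positive")
        for st in (stage_a, stage_b):
            if st not in samples:
                raise ValueError(f"unknown stage {st!r}")
        up_ids = [gene_ids[i] for i in idxs]
        for i in idxs:
            base_mean[i] = max(base_mean[i], 100.0)  # at least median expression
    counts = np.empty((n_genes, len(columns)), dtype=np.int64)
    for j, col in enumerate(columns):
        stage = col.rsplit("_r", 1)[0]
        mean = base_mean.copy()
        if stage_b is not None and stage == stage_b:
            sel = np.isin(gene_ids, up_ids)
            mean[sel] *= fold
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
        counts[:, j] = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=gene_ids, columns=columns)
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "samples": list(samples),
            "n_reps": n_reps,
            "dispersion": dispersion,
        },
        items={
            "upregulated": up_ids,
            "fold": fold,
            "stage_pair": list(upregulated[2]) if upregulated else None,
        },
    )
    return frame, lengths, truth
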