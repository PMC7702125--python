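import numpy as np
import pytest

from genevol.centromere_scan import (
    MonomerHit,
    base_repeat,
    call_centromeres,
    cluster_monomers,
    map_monomer,
    rotation_identity,
)
from genevol.io_formats import SequenceRecord, TandemRepeatRecord
from genevol.synthetic_data import plant_satellite_chromosome


def _random_monomer(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _rec(monomer, chrom="chr1", start=1000, copies=10.0):
    span = int(len(monomer) * copies)
    return TandemRepeatRecord(
        chrom=chrom, start=start, end=start + span - 1,
        period=len(monomer), copy_number=copies, monomer=monomer,
    )


_REVCOMP = str.maketrans("ACGT", "TGCA")


class TestRotationIdentity:
    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        m = _random_monomer(rng, 100)
        rotated = m[37:] + m[:37]
        assert rotation_identity(m, rotated) == 1.0

    def test_strand_invariance(self):
        rng = np.random.default_rng(1)
        m = _random_monomer(rng, 100)
        assert rotation_identity(m, m.translate(_REVCOMP)[::-1]) == 1.0

    def test_unrelated_monomers_low(self):
        rng = np.random.default_rng(2)
        a, b = _random_monomer(rng, 150), _random_monomer(rng, 150)
        assert rotation_identity(a, b) < 0.8


class TestClustering:
    def test_rotated_and_reverse_complement_join(self):
        rng = np.random.default_rng(3)
        m = _random_monomer(rng, 120)
        records = [
            _rec(m, start=1000),
            _rec(m[50:] + m[:50], start=10_000),
            _rec(m.translate(_REVCOMP)[::-1], start=20_000),
        ]
        clusters = cluster_monomers(records)
        assert len(clusters) == 1 and len(clusters[0].member_records) == 3

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        records = [_rec(_random_monomer(rng, 80), start=1000 * (i + 1)) for i in range(6)]
        a = cluster_monomers(records)
        b = cluster_monomers(records[::-1])
        assert [c.representative_monomer for c in a] == [c.representative_monomer for c in b]

    def test_period_filter_and_empty_error(self):
        rng = np.random.default_rng(5)
        records = [_rec(_random_monomer(rng, 10), start=100)]
        with pytest.raises(ValueError, match="period"):
            cluster_monomers(records, period_range=(50, 500))

    def test_planted_satellite_is_top_cluster(self):
        rng = np.random.default_rng(6)
        monomer = _random_monomer(rng, 161)
        _, dat, _ = plant_satellite_chromosome(
            1_000_000, monomer, 200, 300_000, 0.05, seed=6
        )
        clusters = cluster_monomers(dat)
        top = clusters[0]
        assert len(top.representative_monomer) == 161
        assert top.representative_monomer == monomer
        assert [m.monomer for m in top.member_records] == [monomer]


class TestBaseRepeat:
    def test_single_cluster_returned(self):
        rng = np.random.default_rng(7)
        clusters = cluster_monomers([_rec(_random_monomer(rng, 100))])
        assert base_repeat(clusters) is clusters[0]

    def test_tie_prefers_longer_monomer(self):
        rng = np.random.default_rng(8)
        m161, m100 = _random_monomer(rng, 161), _random_monomer(rng, 100)
        # equal total bases: 161*100 = 100*161
        clusters = cluster_monomers(
            [_rec(m161, start=1000, copies=100.0), _rec(m100, start=50_000, copies=161.0)]
        )
        assert len(base_repeat(clusters).representative_monomer) == 161


class TestMapMonomer:
    def test_exact_copy_found_once(self):
        rng = np.random.default_rng(9)
        monomer = _random_monomer(rng, 60)
        background = _random_monomer(rng, 5000)
        genome = [SequenceRecord("c", background[:2000] + monomer + background[2000:])]
        hits = map_monomer(genome, monomer)
        assert len(hits) == 1
        assert hits[0].start0 == 2000 and hits[0].strand == "+"

    def test_reverse_complement_copy_minus_strand(self):
        rng = np.random.default_rng(10)
        monomer = _random_monomer(rng, 60)
        rc = monomer.translate(_REVCOMP)[::-1]
        background = _random_monomer(rng, 4000)
        genome = [SequenceRecord("c", background[:1000] + rc + background[1000:])]
        hits = map_monomer(genome, monomer)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_short_monomer_rejected(self):
        with pytest.raises(ValueError):
            map_monomer([SequenceRecord("c", "ACGT" * 100)], "ACGTACGT")

    def test_mutated_array_mostly_recovered(self):
        rng = np.random.default_rng(11)
        monomer = _random_monomer(rng, 161)
        chrom, _, truth = plant_satellite_chromosome(
            2_000_000, monomer, 500, 900_000, 0.05, seed=11
        )
        hits = map_monomer([chrom], monomer)
        locus = truth.items["locus"]
        inside = [h for h in hits if locus[0] - 200 <= h.start0 <= locus[1]]
        assert len(inside) >= 0.95 * 500


class TestCallCentromeres:
    def test_density_conservation(self):
        hits = [
            MonomerHit("c", 10, 200, "+", 1.0),
            MonomerHit("c", 299_900, 300_400, "+", 1.0),  # straddles a boundary
            MonomerHit("c", 700_000, 700_161, "+", 1.0),
        ]
        calls = call_centromeres(hits, {"c": 1_000_000}, window=300_000, min_fraction=0.0)
        total_hit_bp = sum(h.end0 - h.start0 for h in hits)
        # peak window density cannot exceed total, and the peak is positive
        assert 0 < calls[0].peak_density <= total_hit_bp

    def test_no_hits_no_call(self):
        calls = call_centromeres([], {"c": 1_000_000})
        assert calls[0].status == "no_call"

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="absent"):
            call_centromeres([MonomerHit("x", 0, 100, "+", 1.0)], {"c": 100})

    def test_two_chromosomes_one_planted(self):
        hits = [MonomerHit("a", 900_000 + 161 * i, 900_161 + 161 * i, "+", 1.0) for i in range(300)]
        calls = call_centromeres(hits, {"a": 2_000_000, "b": 2_000_000}, min_fraction=0.01)
        by = {c.chrom: c for c in calls}
        assert by["a"].status == "called" and by["b"].status == "no_call"
        assert by["a"].start0 <= 900_000 < by["a"].end0


class TestEndToEnd:
    def test_plant_cluster_map_call_recovers_locus(self):
        rng = np.random.default_rng(12)
        monomer = _random_monomer(rng, 161)
        chrom, dat, truth = plant_satellite_chromosome(
            2_000_000, monomer, 300, 900_000, 0.10, seed=12
        )
        clusters = cluster_monomers(dat)
        base = base_repeat(clusters)
        assert len(base.representative_monomer) == 161
        hits = map_monomer([chrom], base.representative_monomer)
        calls = call_centromeres(hits, {chrom.id: len(chrom.seq)}, base=base)
        call = calls[0]
        locus = truth.items["locus"]
        assert call.status == "called"
        assert call.start0 <= locus[0] + 300_000 and call.end0 >= locus[1] - 300_000
        assert call.monomer_length == 161
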