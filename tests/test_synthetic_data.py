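import numpy as np
import pytest

from genevol import io_formats as io
from genevol.codon_evolution import analyze_pair
from genevol.ltr_dating import date_pair
from genevol.synthetic_data import (
    HKYParams,
    distance_for_transversion_distance,
    expected_raw_4dtv,
    hky_rate_matrix,
    hky_transition_matrix,
    make_expression_fixture,
    make_family_fixture,
    plant_satellite_chromosome,
    simulate_codon_pair_set,
    simulate_ltr_cohort,
)


class TestHkyModel:
    def test_rate_matrix_normalised_and_stationary(self):
        hky = HKYParams(kappa=3.0, base_freqs=(0.3, 0.2, 0.3, 0.2))
        q = hky_rate_matrix(hky)
        pi = np.array(hky.base_freqs)
        np.testing.assert_allclose(q.sum(axis=1), 0, atol=1e-12)
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0)
        np.testing.assert_allclose(pi @ q, 0, atol=1e-12)  # stationarity

    def test_transition_matrix_rows_are_distributions(self):
        p = hky_transition_matrix(0.7, HKYParams())
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    def test_expected_raw_4dtv_zero_at_zero_distance(self):
        assert expected_raw_4dtv(0.0, HKYParams()) == pytest.approx(0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HKYParams(kappa=-1)
        with pytest.raises(ValueError):
            HKYParams(base_freqs=(0.5, 0.5, 0.5, 0.5))

    def test_distance_inversion_round_trips(self):
        hky = HKYParams(kappa=2.5, base_freqs=(0.3, 0.25, 0.2, 0.25))
        d = distance_for_transversion_distance(0.5, hky)
        from genevol.synthetic_data import expected_transversion_distance

        assert expected_transversion_distance(d, hky) == pytest.approx(0.5, abs=1e-9)


class TestCodonPairs:
    def test_zero_distance_identical_sequences(self):
        pairs, _ = simulate_codon_pair_set(10, 50, 0.0, seed=1)
        assert all(p.seq_a == p.seq_b for p in pairs)
        assert all(analyze_pair(p).raw_4dtv == 0.0 for p in pairs)

    def test_determinism(self):
        a, _ = simulate_codon_pair_set(5, 30, 0.4, seed=7)
        b, _ = simulate_codon_pair_set(5, 30, 0.4, seed=7)
        assert a == b

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_pair_set(1, 10, -0.1)

    def test_mean_raw_4dtv_matches_exact_probability(self):
        """Estimator vs the closed-form P-matrix transversion probability."""
        hky = HKYParams(kappa=2.0)
        pairs, truth = simulate_codon_pair_set(500, 300, 0.6, hky, seed=7)
        raws = np.array([analyze_pair(p).raw_4dtv for p in pairs])
        se = raws.std(ddof=1) / np.sqrt(len(raws))
        assert abs(raws.mean() - truth.items["expected_raw_4dtv"]) <= 3 * se

    def test_non4d_fraction_excluded_by_classification(self):
        pairs, _ = simulate_codon_pair_set(5, 200, 0.2, seed=3, non4d_fraction=0.5)
        for p in pairs:
            res = analyze_pair(p)
            assert res.n_4d < 200  # decoy codons were planted and excluded


class TestLtrCohort:
    def test_zero_age_identical_ltrs(self):
        recs, _ = simulate_ltr_cohort(5, 0.0, seed=2)
        for a, b in zip(recs[::2], recs[1::2]):
            assert a.seq == b.seq

    def test_determinism(self):
        a, _ = simulate_ltr_cohort(5, 1.5, seed=3)
        b, _ = simulate_ltr_cohort(5, 1.5, seed=3)
        assert a == b

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_ltr_cohort(5, 1.0, rate=0.0)

    def test_age_recovery_within_three_se(self):
        recs, truth = simulate_ltr_cohort(200, 1.5, seed=1)
        est = np.array(
            [
                date_pair("e", a.seq, b.seq).T_mya
                for a, b in zip(recs[::2], recs[1::2])
            ]
        )
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 1.5) <= 3 * se

    def test_mixture_ages_recorded_per_element(self):
        recs, truth = simulate_ltr_cohort(50, [1.0, 4.5], seed=4)
        ages = set(truth.items["true_ages_mya"].values())
        assert ages <= {1.0, 4.5} and len(ages) == 2


class TestSatellite:
    def test_locus_arithmetic(self):
        rng = np.random.default_rng(5)
        monomer = "".join("ACGT"[i] for i in rng.integers(4, size=161))
        _, _, truth = plant_satellite_chromosome(
            10_000_000, monomer, 500, 3_000_000, 0.05, seed=3, n_decoys=0
        )
        assert truth.items["locus"] == [3_000_000, 3_080_500]

    def test_zero_copies_empty_truth(self):
        _, dat, truth = plant_satellite_chromosome(
            100_000, "ACGT" * 40, 0, 0, seed=1, n_decoys=0
        )
        assert truth.items == {} and dat == []

    def test_determinism(self):
        args = (200_000, "ACGT" * 40, 50, 50_000, 0.05)
        a, _, _ = plant_satellite_chromosome(*args, seed=9)
        b, _, _ = plant_satellite_chromosome(*args, seed=9)
        assert a.seq == b.seq

    def test_oversized_array_rejected(self):
        with pytest.raises(ValueError):
            plant_satellite_chromosome(1000, "ACGT" * 40, 100, 0)

    def test_output_parses_through_io(self, tmp_path):
        rng = np.random.default_rng(6)
        monomer = "".join("ACGT"[i] for i in rng.integers(4, size=100))
        chrom, dat, _ = plant_satellite_chromosome(
            300_000, monomer, 100, 100_000, 0.05, seed=6
        )
        io.write_fasta([chrom], tmp_path / "c.fa")
        io.write_trf_dat(dat, tmp_path / "c.dat")
        assert io.read_fasta(tmp_path / "c.fa")[0].seq == chrom.seq
        back = io.read_trf_dat(tmp_path / "c.dat")
        assert back == dat


class TestFamilyFixture:
    def test_zero_members(self):
        _, hits, doms, truth = make_family_fixture(10, 0, seed=1)
        assert truth.items["members"] == []

    def test_cluster_span_exact(self):
        genes, _, _, truth = make_family_fixture(30, 12, ("chr4", 10, 270_000), seed=2)
        cluster = [g for g in genes if g.gene_id in truth.items["cluster_gene_ids"]]
        cluster.sort(key=lambda g: g.start)
        assert cluster[-1].end - cluster[0].start == 270_000

    def test_too_small_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            make_family_fixture(30, 12, ("chr4", 10, 10_000), seed=2)

    def test_round_trip_through_io(self, tmp_path):
        genes, hits, doms, _ = make_family_fixture(15, 5, seed=4)
        io.write_gff3_genes(genes, tmp_path / "g.gff3")
        io.write_blast_tab(hits, tmp_path / "h.tsv")
        io.write_domtbl(doms, tmp_path / "d.tbl")
        assert io.read_gff3_genes(tmp_path / "g.gff3") == genes
        qlens = {h.query_id: h.query_length for h in hits}
        back = io.read_blast_tab(tmp_path / "h.tsv", qlens)
        assert [(h.query_id, h.coverage) for h in back] == [
            (h.query_id, h.coverage) for h in hits
        ]
        assert io.read_domtbl(tmp_path / "d.tbl") == doms


class TestExpressionFixture:
    def test_determinism(self):
        a, _, _ = make_expression_fixture(20, ["a", "b"], seed=5)
        b, _, _ = make_expression_fixture(20, ["a", "b"], seed=5)
        assert a.equals(b)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            make_expression_fixture(10, ["a", "b"], ([0], 2.0, ("a", "nope")))

    def test_fold_one_plants_nothing(self):
        counts, lengths, truth = make_expression_fixture(
            50, ["a", "b"], ([0], 1.0, ("a", "b")), seed=6
        )
        assert truth.items["fold"] == 1.0

    def test_bad_fold_rejected(self):
        with pytest.raises(ValueError):
            make_expression_fixture(10, ["a", "b"], ([0], -2.0, ("a", "b")))
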