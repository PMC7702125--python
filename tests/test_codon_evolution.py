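import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genevol.codon_evolution import (
    CodonAlignment,
    FourfoldSiteSet,
    analyze_pair,
    classify_fourfold_sites,
    corrected_4dtv,
    count_substitutions_4d,
    paranome_4dtv,
    raw_4dtv,
)

# The worked 6-codon alignment: every codon is fourfold degenerate in both
# sequences; differences at third positions are A/T (tv), T/C (ts), A/G (ts),
# A/T (tv), none, G/A (ts).
WORKED_A = "GGACTTCCAGTAACCGCG"
WORKED_B = "GGTCTCCCGGTTACCGCA"


def brute_force_counts(aln: CodonAlignment):
    """Independent per-column classifier over all third positions."""
    n4d = tv = ts = 0
    purines = {"A", "G"}
    fourfold = {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}
    for c in range(len(aln.seq_a) // 3):
        ca, cb = aln.seq_a[3 * c : 3 * c + 3], aln.seq_b[3 * c : 3 * c + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca[:2] != cb[:2] or ca[:2] not in fourfold:
            continue
        n4d += 1
        x, y = ca[2], cb[2]
        if x != y:
            if (x in purines) == (y in purines):
                ts += 1
            else:
                tv += 1
    return n4d, tv, ts


class TestSiteClassification:
    @pytest.mark.parametrize(
        "ca,cb,included",
        [
            ("GGA", "GGG", True),   # Gly family, fourfold
            ("TTT", "TTC", False),  # Phe, twofold
            ("AGA", "CGA", False),  # prefixes differ
            ("GG-", "GGA", False),  # gap in codon
            ("GGN", "GGA", False),  # ambiguity in codon
        ],
    )
    def test_rules(self, ca, cb, included):
        aln = CodonAlignment("p", ca, cb)
        sites = classify_fourfold_sites(aln)
        assert (sites.n_4d == 1) == included

    def test_worked_alignment_counts(self):
        aln = CodonAlignment("w", WORKED_A, WORKED_B)
        sites = classify_fourfold_sites(aln)
        assert sites.n_4d == 6
        tv, ts = count_substitutions_4d(aln, sites)
        assert (tv, ts) == (2, 3)
        assert raw_4dtv(tv, sites.n_4d) == pytest.approx(1 / 3)

    def test_identical_sequences_zero(self):
        aln = CodonAlignment("i", WORKED_A, WORKED_A)
        sites = classify_fourfold_sites(aln)
        assert count_substitutions_4d(aln, sites) == (0, 0)

    def test_all_transversion_saturation(self):
        # every third position purine <-> pyrimidine
        aln = CodonAlignment("s", "GGAGGAGGA", "GGTGGCGGT")
        sites = classify_fourfold_sites(aln)
        tv, ts = count_substitutions_4d(aln, sites)
        assert tv == sites.n_4d == 3 and ts == 0

    def test_third_position_indices(self):
        with pytest.raises(ValueError):
            FourfoldSiteSet(site_indices=(0,))

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT-N"))
        for _ in range(100):
            n = int(rng.integers(1, 40)) * 3
            a = "".join(rng.choice(bases, size=n, p=[0.23] * 4 + [0.04, 0.04]))
            b = "".join(rng.choice(bases, size=n, p=[0.23] * 4 + [0.04, 0.04]))
            aln = CodonAlignment("r", a, b)
            sites = classify_fourfold_sites(aln)
            tv, ts = count_substitutions_4d(aln, sites)
            n4d_o, tv_o, ts_o = brute_force_counts(aln)
            assert (sites.n_4d, tv, ts) == (n4d_o, tv_o, ts_o)


class TestRaw4dtv:
    def test_zero_and_saturated_extremes(self):
        assert raw_4dtv(0, 10) == 0.0
        assert raw_4dtv(10, 10) == 1.0

    def test_no_sites_flagged_not_raised(self):
        assert raw_4dtv(0, 0) is None


class TestCorrected4dtv:
    def test_zero(self):
        assert corrected_4dtv(0.0) == 0.0

    def test_equal_freq_value(self):
        # -1/2 ln(1 - 2*0.2) = -1/2 ln(0.6)
        assert corrected_4dtv(0.2) == pytest.approx(-0.5 * math.log(0.6), abs=1e-12)
        assert corrected_4dtv(0.2) == pytest.approx(0.25541, abs=1e-5)

    def test_boundary_saturated(self):
        assert corrected_4dtv(0.5) is None

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equal_freqs_reduce_to_two_parameter_form(self, q):
        got = corrected_4dtv(q)
        assert got is not None
        assert got == pytest.approx(-0.5 * math.log(1 - 2 * q), abs=1e-12)

    @given(
        st.floats(min_value=0.0, max_value=0.4),
        st.floats(min_value=0.001, max_value=0.05),
        st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_and_at_least_raw(self, q, dq, raw_freqs):
        total = sum(raw_freqs)
        freqs = tuple(f / total for f in raw_freqs)
        lo, hi = corrected_4dtv(q, freqs), corrected_4dtv(q + dq, freqs)
        if hi is None:
            return  # q + dq crossed the saturation ceiling
        assert lo is not None and hi > lo
        assert lo >= q * (1 - 1e-12)  # equality up to rounding at tiny q


class TestParanome:
    def test_single_pair_peak_is_its_bin_midpoint(self):
        aln = CodonAlignment("w", WORKED_A * 10, WORKED_B * 10)
        summary = paranome_4dtv([aln], min_4d_sites=10)
        r = summary.results[0]
        bin_idx = int(r.corrected_4dtv // 0.02)
        assert summary.peak == pytest.approx(0.02 * bin_idx + 0.01)

    def test_tie_reports_leftmost_and_flags(self):
        # two pairs in different bins, one pair each -> tie, leftmost wins
        unit_a = "GGAGGTGGCGGGGGA"
        unit_b = "GGAGGTGGCGGGGGT"  # one A<->T transversion per 5 codons
        a1 = CodonAlignment("p1", unit_a * 4, unit_a * 4)  # corrected 0
        a2 = CodonAlignment("p2", unit_a * 4, unit_b * 4)  # raw 0.2
        summary = paranome_4dtv([a1, a2], min_4d_sites=10)
        assert summary.peak_tied
        assert summary.peak == pytest.approx(0.01)

    def test_short_pairs_excluded_and_counted(self):
        short = CodonAlignment("s", "GGA", "GGA")
        ok = CodonAlignment("o", "GGA" * 20, "GGA" * 20)
        summary = paranome_4dtv([short, ok], min_4d_sites=10)
        assert summary.n_excluded_short == 1

    def test_all_excluded_raises(self):
        short = CodonAlignment("s", "GGA", "GGA")
        with pytest.raises(ValueError, match="no usable pairs"):
            paranome_4dtv([short], min_4d_sites=10)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            paranome_4dtv([])


def test_analyze_pair_invariants():
    res = analyze_pair(CodonAlignment("w", WORKED_A, WORKED_B))
    assert res.n_transversion + res.n_transition <= res.n_4d
    assert res.corrected_4dtv >= res.raw_4dtv
    assert sum(res.base_freqs_4d) == pytest.approx(1.0)
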