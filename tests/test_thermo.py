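"""Primer enumeration and physicochemical properties."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from phisigns.consensus import ConservedRegion
from phisigns.genome_io import reverse_complement
from phisigns.thermo import (
    ThermoParams,
    compute_properties,
    degeneracy,
    dg_3prime,
    enumerate_primers,
    gc_clamp,
    gc_content,
    hairpin_run,
    load_nn_table,
    max_complementary_run,
    tm_basic,
    tm_nn,
    tm_salt,
)
from conftest import random_iupac
from oracles import brute_hairpin_run, brute_max_run, nn_tm_oracle

IUPAC_CODES = "ACGTRYSWKMBDHVN"


def _region(seq, start=1):
    return ConservedRegion(region_id="R001", start=start, stop=start + len(seq) - 1, seq=seq)


class TestEnumerate:
    def test_window_count_for_short_region(self):
        cands = enumerate_primers(_region("ACGTACGTACGT"), 10, 28)
        assert len(cands) == 3 + 2 + 1  # lengths 10, 11, 12

    def test_region_shorter_than_min_length(self):
        assert enumerate_primers(_region("ACGTACGTA"), 10, 28) == []

    def test_windows_match_substring_oracle(self):
        rng = random.Random(3)
        for _ in range(100):
            seq = random_iupac(rng, rng.randint(12, 30))
            region = _region(seq, start=rng.randint(1, 50))
            for c in enumerate_primers(region, 10, 28):
                off = c.start - region.start
                assert c.seq == seq[off: off + (c.stop - c.start + 1)]

    def test_reverse_orientation_is_window_revcomp(self):
        region = _region("ACGTACGTACGT", start=11)
        fwd = {(c.start, c.stop): c.seq for c in enumerate_primers(region, 10, 12)}
        for c in enumerate_primers(region, 10, 12, orientation="reverse"):
            assert c.seq == reverse_complement(fwd[(c.start, c.stop)])


class TestSimpleProperties:
    @pytest.mark.parametrize("seq,expected", [
        ("ACHGARGGYGARATHG", 72),   # 3*2*2*2*3
        ("ACGT", 1),
        ("NN", 16),
    ])
    def test_degeneracy(self, seq, expected):
        assert degeneracy(seq) == expected

    def test_degeneracy_rejects_gap(self):
        with pytest.raises(ValueError):
            degeneracy("AC-T")

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet=IUPAC_CODES, min_size=1, max_size=15),
           st.text(alphabet=IUPAC_CODES, min_size=1, max_size=15))
    def test_degeneracy_multiplicative(self, x, y):
        assert degeneracy(x + y) == degeneracy(x) * degeneracy(y)

    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 100.0), ("ACGT", 50.0), ("ACRT", 37.5),
    ])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAAAAGG", 2),
        ("AAAAAGGGGG", 5),
        ("AAAAASS", 2),     # S guarantees G or C
        ("AAAAARR", 0),     # R does not
    ])
    def test_gc_clamp(self, seq, expected):
        assert gc_clamp(seq) == expected


class TestMeltingTemperatures:
    def test_wallace_rule_short(self):
        assert tm_basic("AAAATTTT") == (16.0, 16.0, 16.0)
        assert tm_basic("GGGGCCCC") == (32.0, 32.0, 32.0)

    def test_long_sequence_formula(self):
        lo, hi, mid = tm_basic("ACGTACGTACGTAC")
        assert mid == pytest.approx(64.9 + 41 * (7 - 16.4) / 14, abs=1e-9)
        assert lo == hi == mid

    def test_salt_term_vanishes_at_reference_concentration(self):
        assert tm_salt("AAAATTTT", ThermoParams(na_conc=0.05))[2] == pytest.approx(16.0)

    def test_salt_long_formula(self):
        import math
        got = tm_salt("ACGTACGTACGTAC", ThermoParams(na_conc=0.05))[2]
        expected = 81.5 + 16.6 * math.log10(0.05) + 0.41 * 50 - 675 / 14
        assert got == pytest.approx(expected, abs=1e-9)

    def test_salt_monotonic_in_sodium(self):
        rng = random.Random(8)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 24)))
            tms = [tm_salt(seq, ThermoParams(na_conc=c))[2] for c in (0.01, 0.05, 0.2, 1.0)]
            assert tms == sorted(tms)

    def test_nn_matches_independent_oracle(self):
        rng = random.Random(21)
        rows = load_nn_table()
        params = ThermoParams()
        for _ in range(100):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 28)))
            expected = nn_tm_oracle(seq, rows, params.na_conc, params.primer_conc)
            assert tm_nn(seq, params)[2] == pytest.approx(expected, abs=0.01)

    def test_nn_smallest_duplex(self):
        rows = load_nn_table()
        params = ThermoParams()
        assert tm_nn("AT", params)[2] == pytest.approx(
            nn_tm_oracle("AT", rows, params.na_conc, params.primer_conc), abs=0.01)

    def test_duplication_raises_nn_tm(self):
        rng = random.Random(33)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 14)))
            assert tm_nn(seq + seq)[2] > tm_nn(seq)[2]

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet=IUPAC_CODES, min_size=5, max_size=28))
    def test_triplet_ordering_and_degenerate_spread(self, seq):
        for fn in (tm_basic, lambda s: tm_salt(s), lambda s: tm_nn(s)):
            lo, hi, mid = fn(seq)
            assert lo <= mid <= hi
            if degeneracy(seq) == 1:
                assert lo == hi


class TestFreeEnergy:
    def test_at_rich_end_passes_floor(self):
        assert dg_3prime("GGGGGAATAT") > -9.0

    def test_gc_end_more_stable_than_at_end(self):
        assert dg_3prime("AAAAAGCGCG") < dg_3prime("GGGGGAATAT")

    def test_gc_substitution_monotonic(self):
        rng = random.Random(44)
        table = load_nn_table()
        for _ in range(50):
            core = "".join(rng.choice("ACGT") for _ in range(10))
            weak = core + "AATAT"
            strong = core + "GCGCC"
            assert dg_3prime(strong) <= dg_3prime(weak)

    def test_degenerate_takes_most_stable_disambiguation(self):
        # S resolves to G or C; most stable must equal the best plain variant
        got = dg_3prime("AAAAASSSSS")
        best = min(dg_3prime("AAAAA" + "".join(p))
                   for p in __import__("itertools").product("GC", repeat=5))
        assert got == pytest.approx(best)


class TestComplementarity:
    def test_palindromic_site_self_anneals_fully(self):
        assert max_complementary_run("GAATTC", "GAATTC") == 6

    def test_homopolymer_a_cannot_pair_itself(self):
        assert max_complementary_run("AAAA", "AAAA") == 0

    def test_hairpin_with_minimum_loop(self):
        assert hairpin_run("GGGGAAAACCCC") == 4

    def test_dimer_run_matches_brute_force_on_random_pairs(self):
        rng = random.Random(55)
        for _ in range(500):
            a = random_iupac(rng, rng.randint(8, 28))
            b = random_iupac(rng, rng.randint(8, 28))
            assert max_complementary_run(a, b) == brute_max_run(a, b)

    def test_hairpin_matches_brute_force(self):
        rng = random.Random(56)
        for _ in range(300):
            s = random_iupac(rng, rng.randint(8, 28))
            assert hairpin_run(s) == brute_hairpin_run(s)

    def test_property_block_consistent(self):
        props = compute_properties("ACHGARGGYGARATHG")
        assert props.degeneracy == 72
        assert props.length == 16
        assert props.self_dimer_run == max_complementary_run("ACHGARGGYGARATHG",
                                                             "ACHGARGGYGARATHG")
        assert props.dg_min <= 0.0
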