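from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitobreaks.genome import CircularGenome, GenomeError, circular_distance
from mitobreaks.motifs import (
    MOTIF_REGISTRY,
    MotifMatchSet,
    binned_profile_correlation,
    distance_percentages,
    klet_shuffle,
    motif_background,
    nearest_distance_array,
    nearest_motif_distance,
    scan_motif,
)

from conftest import random_genome

dna = st.text(alphabet="ACGT", min_size=10, max_size=120)


class TestScanMotif:
    def test_nn_matches_every_position_on_circle(self):
        g = CircularGenome("x", "ACGTACG")
        assert scan_motif(g, "NN").count == 7

    def test_planted_literal_matches_once(self):
        seq = "T" * 50 + "CCCCACCCC" + "T" * 41
        assert scan_motif(CircularGenome("x", seq), "CCCCACCCC").starts == (51,)

    def test_wrap_spanning_match(self):
        seq = "CC" + "T" * 96 + "CC"  # circularly CCCC at the origin
        m = scan_motif(CircularGenome("x", seq), "CCCC")
        assert m.starts == (99,)
        assert scan_motif(CircularGenome("x", seq), "CCCC", circular=False).count == 0

    def test_overlap_exclusion_flag(self):
        seq = "AAAAA" + "C" * 95
        m = scan_motif(CircularGenome("x", seq), "AA", circular=False)
        m_no = scan_motif(CircularGenome("x", seq), "AA", circular=False, allow_overlap=False)
        assert m.count == 4 and m_no.count == 2

    def test_invalid_code_errors(self):
        with pytest.raises(GenomeError, match="IUPAC"):
            scan_motif(CircularGenome("x", "ACGT" * 10), "AXC")

    @settings(deadline=None, max_examples=60)
    @given(dna, st.integers(0, 2**16))
    def test_literal_scan_equals_substring_search(self, seq, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        start = int(rng.integers(0, len(seq) - k + 1)) if len(seq) > k else 0
        motif = seq[start : start + k]
        got = scan_motif(seq, motif, circular=False).starts
        expected = tuple(
            i + 1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif
        )
        assert got == expected

    def test_degenerate_codes_expand_correctly(self):
        # Y=C/T, M=A/C, H=A/C/T on a sequence enumerating candidates
        m = scan_motif("CATT", "YMH", circular=False)
        assert m.starts == (1,)  # C~Y, A~M, T~H; ATT fails because T is not M


class TestDistances:
    def make_matches(self, starts, length, L=200):
        return MotifMatchSet("X" * length, tuple(starts), L)

    def test_breakpoint_inside_match_is_zero(self):
        m = self.make_matches([50], 11)
        assert nearest_motif_distance(55, m) == 0

    def test_left_of_match(self):
        m = self.make_matches([50], 11)
        assert nearest_motif_distance(47, m) == 3

    def test_wrapping_distance(self):
        m = self.make_matches([1], 5, L=100)
        assert nearest_motif_distance(98, m) == 3

    def test_empty_match_set_errors(self):
        with pytest.raises(GenomeError):
            nearest_motif_distance(5, MotifMatchSet("AC", (), 100))

    def test_matches_exhaustive_oracle_and_distance_array(self, rng):
        L = 300
        starts = sorted(set(rng.integers(1, L + 1, size=8).tolist()))
        m = self.make_matches(starts, 7, L=L)
        arr = nearest_distance_array(m)
        for b in range(1, L + 1):
            oracle = min(
                min(
                    circular_distance(b, (s - 1 + k) % L + 1, L)
                    for k in range(7)
                )
                for s in starts
            )
            assert nearest_motif_distance(b, m) == oracle
            assert arr[b - 1] == oracle

    def test_percentage_thresholds_and_monotonicity(self, rng):
        L = 500
        m = self.make_matches(sorted(rng.integers(1, L + 1, size=5).tolist()), 9, L=L)
        bps = rng.integers(1, L + 1, size=200).tolist()
        pct = distance_percentages(bps, m, thresholds=(0, 5, 20, 50), inclusive=(True,) * 4)
        vals = [pct[t] for t in (0, 5, 20, 50)]
        assert vals == sorted(vals)

    def test_all_breakpoints_inside_matches(self):
        m = self.make_matches([10], 20, L=100)
        pct = distance_percentages([12, 15, 25], m)
        assert pct[5] == 1.0 and pct[20] == 1.0

    def test_strict_versus_inclusive_threshold(self):
        m = self.make_matches([50], 11, L=200)  # span 50..60
        pct = distance_percentages([45, 40], m, thresholds=(5, 20), inclusive=(False, True))
        # breakpoint 45 is 5 bp away: excluded by the strict <5, included by <=20
        assert pct[5] == 0.0 and pct[20] == 1.0


def kmer_counts(seq, k):
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


class TestKletShuffle:
    def test_k1_preserves_composition(self):
        out = klet_shuffle("AACG", 1, seed=0)
        assert Counter(out) == Counter("AACG")

    @settings(deadline=None, max_examples=40)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=200), st.integers(0, 2**16))
    def test_k3_preserves_all_lower_order_counts(self, seq, seed):
        out = klet_shuffle(seq, 3, seed=seed)
        for k in (1, 2, 3):
            assert kmer_counts(out, k) == kmer_counts(seq, k)

    def test_deterministic_under_seed(self):
        seq = "ACGTTGCAACGT" * 10
        assert klet_shuffle(seq, 3, seed=5) == klet_shuffle(seq, 3, seed=5)
        assert klet_shuffle(seq, 1, seed=5) == klet_shuffle(seq, 1, seed=5)

    def test_actually_shuffles(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        outs = {klet_shuffle(seq, 3, seed=s) for s in range(5)}
        assert len(outs) > 1

    def test_too_short_errors(self):
        with pytest.raises(GenomeError):
            klet_shuffle("AC", 3)


class TestMotifBackground:
    def test_degenerate_motif_flagged(self):
        g = CircularGenome("x", "ACGT" * 30)
        res = motif_background(g, "N", n_shuffles=5, k=1, seed=0)
        assert res.degenerate
        assert res.observed == 120 and res.null_mean == 120

    def test_planted_motif_strongly_enriched(self, rng):
        # uniform background gives CCNCC a healthy null count; 30 extra planted
        # copies must stand far outside the shuffle distribution
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        for i in range(30):
            pos = 100 * i
            seq = seq[:pos] + "CCACC" + seq[pos + 5 :]
        g = CircularGenome("x", seq)
        res = motif_background(g, "CCNCC", n_shuffles=20, k=1, seed=1)
        assert not res.degenerate
        assert res.observed >= 30
        assert res.z > 3

    def test_registry_patterns_are_valid_iupac(self):
        g = CircularGenome("x", "ACGT" * 10)
        for pattern in MOTIF_REGISTRY.values():
            scan_motif(g, pattern)  # must not raise


class TestBinnedCorrelation:
    def test_identical_profiles_give_rho_one(self):
        L = 1_000
        pos = [10, 150, 320, 480, 630, 770, 910]
        m = MotifMatchSet("ACGT", tuple(pos), L)
        rho, _ = binned_profile_correlation(pos, m, bin_size=100)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        L = 500
        bps = [1] * 5 + [101] * 4 + [201] * 3 + [301] * 2 + [401]
        motif_starts = [1] + [101] * 2 + [201] * 3 + [301] * 4 + [401] * 5
        m = MotifMatchSet("AC", tuple(motif_starts), L)
        rho, _ = binned_profile_correlation(bps, m, bin_size=100)
        assert rho == pytest.approx(-1.0)

    def test_too_few_bins_errors(self):
        m = MotifMatchSet("AC", (1,), 100)
        with pytest.raises(GenomeError):
            binned_profile_correlation([1], m, bin_size=50)
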