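import math

import numpy as np
import pytest

from mitobreaks.curvature import (
    bendability_profile_values,
    compute_profile,
    curvature_profile_values,
    genome_mean_ratio,
    local_maxima,
    peak_bin_density,
    ratio_profile,
)
from mitobreaks.genome import CircularGenome, GenomeError, reverse_complement
from mitobreaks.geometry_tables import BENDABILITY, WEDGE_ANGLES, roll_tilt_twist

from conftest import random_genome


def path_curvature_oracle(seq: str, window: int) -> np.ndarray:
    """Independent 3D helical-axis reconstruction.

    Builds the duplex axis by composing per-step rotations (twist about the
    local z axis, then roll about y and tilt about x) and measures, for each
    centered window, the angle between the entry and exit tangent vectors,
    scaled to degrees per helical turn.
    """

    def rot_x(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def rot_y(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-c * 0 - s, 0, c]])

    def rot_z(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    L = len(seq)
    ext = seq + seq
    frames = [np.eye(3)]
    for k in range(2 * L - 1):
        din = ext[k : k + 2]
        if din in WEDGE_ANGLES:
            roll, tilt, twist = roll_tilt_twist(din)
        else:
            roll, tilt, twist = 0.0, 0.0, 34.3
        step = rot_z(math.radians(twist)) @ rot_y(math.radians(roll)) @ rot_x(
            math.radians(tilt)
        )
        frames.append(frames[-1] @ step)
    tangents = np.array([f[:, 2] for f in frames])
    half = window // 2
    out = np.empty(L)
    for p in range(L):
        lo = p - half + L if p - half < 0 else p - half
        hi = lo + window - 1
        cosang = float(np.clip(np.dot(tangents[lo], tangents[hi]), -1.0, 1.0))
        out[p] = math.degrees(math.acos(cosang)) / (window - 1) * 10.5
    return out


class TestGeometryTables:
    def test_all_dinucleotides_and_trinucleotides_present(self):
        assert len(WEDGE_ANGLES) == 16
        assert len(BENDABILITY) == 64
        for tri, v in BENDABILITY.items():
            assert BENDABILITY[reverse_complement(tri)] == v

    def test_wedge_table_complement_symmetry(self):
        for din, (tw, we, di) in WEDGE_ANGLES.items():
            tw2, we2, di2 = WEDGE_ANGLES[reverse_complement(din)]
            assert (tw, we) == (tw2, we2)
            assert di == pytest.approx(-di2) or abs(di) == 180.0 or di == 0.0


class TestCurvatureProfile:
    def test_homogeneous_repeat_is_flat(self):
        g = CircularGenome("p", "A" * 120)
        prof = curvature_profile_values(g, window=31)
        assert np.allclose(prof, prof[0])

    def test_phased_a_tracts_exceed_shuffled_control(self, rng):
        unit = "AAAAA" + "".join(rng.choice(list("CGT"), size=5))
        phased = unit * 20
        shuffled = "".join(rng.permutation(list(phased)))
        g1, g2 = CircularGenome("p", phased), CircularGenome("s", shuffled)
        assert curvature_profile_values(g1, 31).max() > curvature_profile_values(g2, 31).max()
        # same ordering under the independent 3D reconstruction
        assert path_curvature_oracle(phased, 31).max() > path_curvature_oracle(shuffled, 31).max()

    def test_rotation_invariance(self, rng):
        g = random_genome(200, rng)
        k = 37
        rotated = CircularGenome("r", g.sequence[-k:] + g.sequence[:-k])
        a = curvature_profile_values(g, 31)
        b = curvature_profile_values(rotated, 31)
        assert np.allclose(np.roll(a, k), b)

    def test_amplitude_scaling_does_not_decrease_peak(self, rng):
        g = random_genome(300, rng)
        doubled = {
            din: (tw, 2 * we, di) for din, (tw, we, di) in WEDGE_ANGLES.items()
        }
        assert (
            curvature_profile_values(g, 31, table=doubled).max()
            >= curvature_profile_values(g, 31).max()
        )

    def test_short_sequence_errors(self):
        with pytest.raises(GenomeError):
            curvature_profile_values(CircularGenome("x", "ACGT" * 3), window=31)


class TestBendability:
    def test_homogeneous_repeat_is_flat(self):
        g = CircularGenome("p", "ACG" * 40)
        prof = bendability_profile_values(g, window=3, shift=0.0)
        assert np.allclose(prof, prof[0])

    def test_window_average_is_hand_computable(self):
        # circular 5-mer AACGT: center trinucleotides at each position
        g = CircularGenome("m", "AACGT")
        prof = bendability_profile_values(g, window=3, shift=0.0)
        tri_at = ["TAA", "AAC", "ACG", "CGT", "GTA"]  # centered at positions 1..5
        vals = [BENDABILITY[t] for t in tri_at]
        expected2 = np.mean([vals[0], vals[1], vals[2]])  # window centered at pos 2
        assert prof[1] == pytest.approx(expected2)

    def test_reverse_complement_mirrors_profile(self, rng):
        for _ in range(5):
            g = random_genome(50, rng)
            rc = CircularGenome("rc", reverse_complement(g.sequence))
            a = bendability_profile_values(g, window=3, shift=0.0)
            b = bendability_profile_values(rc, window=3, shift=0.0)
            # base i (1-based) maps to base L-i+1 of the reverse complement
            assert np.allclose(a, b[::-1])


class TestRatioAndPeaks:
    def test_ratio_one_when_profiles_equal(self):
        x = np.full(10, 2.5)
        assert np.allclose(ratio_profile(x, x), 1.0)

    def test_masked_positions_excluded_from_mean(self):
        curv = np.array([1.0, 1.0, 1.0, 1.0])
        bend = np.array([1.0, 0.0, 2.0, -1.0])
        r = ratio_profile(curv, bend)
        assert np.isnan(r[1]) and np.isnan(r[3])
        assert genome_mean_ratio(r) == pytest.approx(np.mean([1.0, 0.5]))

    def test_fully_masked_errors(self):
        with pytest.raises(GenomeError):
            ratio_profile(np.ones(4), np.zeros(4))

    def test_single_planted_peak(self):
        prof = np.zeros(200)
        prof[120] = 5.0
        assert local_maxima(prof, min_separation=20) == [121]

    def test_plateau_reports_leftmost(self):
        prof = np.zeros(100)
        prof[40:45] = 3.0
        assert local_maxima(prof, min_separation=10) == [41]

    def test_matches_bruteforce_scan(self, rng):
        prof = rng.random(300)
        half = 7
        expected = []
        for p in range(300):
            left = [prof[(p - o) % 300] for o in range(1, half + 1)]
            right = [prof[(p + o) % 300] for o in range(1, half + 1)]
            if all(prof[p] > v for v in left) and all(prof[p] >= v for v in right):
                expected.append(p + 1)
        got = local_maxima(prof, min_separation=2 * half)
        assert sorted(got) == expected

    def test_peak_bin_density_arithmetic(self):
        L = 16_569
        dens = peak_bin_density([1_000, 1_010, 1_020, 1_049, 951], [1_000], L, halfwidth=50)
        assert dens[1_000] == pytest.approx(5 / 101 * 100)

    def test_no_breakpoints_near_peak(self):
        dens = peak_bin_density([5_000], [1_000], 16_569, halfwidth=50)
        assert dens[1_000] == 0.0


def test_compute_profile_shapes(mito_truth):
    prof = compute_profile(mito_truth.genome)
    L = mito_truth.genome.length
    assert len(prof.curvature) == len(prof.bendability) == len(prof.ratio) == L
    assert np.nanmin(prof.curvature) >= 0.0
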