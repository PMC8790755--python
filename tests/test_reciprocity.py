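import itertools

import numpy as np
import pytest
from scipy import stats

from voxattrib.igattrib import AttributionGrid
from voxattrib.reciprocity import (ChannelPair, baseline_pair_distance,
                                   complementary_pairs, consistency_study,
                                   distance_study,
                                   magnitude_distance_correlation,
                                   mann_whitney_u, occupancy_pair,
                                   pair_distance, pair_magnitude)
from voxattrib.scorers import LinearScorer
from voxattrib.voxelizer import VoxelGrid, default_scheme


def make_attr(values, spacing=1.0):
    return AttributionGrid(values=np.asarray(values, dtype=float),
                           origin=np.zeros(3), spacing=spacing,
                           baseline_id="zeros", steps=10, completeness_gap=0.0)


def brute_force_mwu_p(x, y):
    """Oracle: exhaustive enumeration of group assignments, pair-count U."""
    combined = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_of(xs, ys):
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    center = n * m / 2.0
    obs = abs(u_of(x, y) - center)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        u = u_of(combined[mask], combined[~mask])
        count += abs(u - center) >= obs - 1e-9
        total += 1
    return count / total


class TestChannelPairs:
    def test_five_complementary_pairs(self):
        pairs = complementary_pairs()
        assert len(pairs) == 5
        scheme = default_scheme()
        occ = occupancy_pair()
        assert occ.protein_channel == scheme.index("protein", "heavy")
        assert occ.ligand_channel == scheme.index("ligand", "heavy")


class TestPairDistance:
    def test_same_voxel_zero(self):
        values = np.zeros((16, 8, 8, 8))
        occ = occupancy_pair()
        values[occ.protein_channel, 2, 2, 2] = 1.0
        values[occ.ligand_channel, 2, 2, 2] = -0.5
        assert pair_distance(make_attr(values), occ) == 0.0

    def test_adjacent_voxels_one_angstrom(self):
        values = np.zeros((16, 8, 8, 8))
        occ = occupancy_pair()
        values[occ.protein_channel, 2, 2, 2] = 1.0
        values[occ.ligand_channel, 3, 2, 2] = 1.0
        assert pair_distance(make_attr(values), occ) == pytest.approx(1.0)

    def test_face_edge_diagonal_sqrt_two(self):
        values = np.zeros((16, 8, 8, 8))
        occ = occupancy_pair()
        values[occ.protein_channel, 2, 2, 2] = 1.0
        values[occ.ligand_channel, 3, 3, 2] = 1.0
        assert pair_distance(make_attr(values), occ) == pytest.approx(np.sqrt(2))

    def test_zero_channel_undefined(self):
        values = np.zeros((16, 8, 8, 8))
        occ = occupancy_pair()
        values[occ.protein_channel, 1, 1, 1] = 1.0
        assert pair_distance(make_attr(values), occ) is None
        assert pair_magnitude(make_attr(values), occ) is None


class TestBaselineDistance:
    def _grid(self, values):
        return VoxelGrid(values=np.asarray(values, dtype=float),
                         origin=np.zeros(3), spacing=1.0, source_id="b")

    def test_single_qualifying_voxel_is_forced(self):
        values = np.zeros((16, 8, 8, 8))
        occ = occupancy_pair()
        values[occ.protein_channel, 0, 0, 0] = 0.8
        values[occ.ligand_channel, 4, 0, 0] = 0.9
        for seed in (0, 1, 2):
            assert baseline_pair_distance(self._grid(values), occ,
                                          seed) == pytest.approx(4.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        values = rng.random((16, 8, 8, 8))
        g = self._grid(values)
        occ = occupancy_pair()
        assert baseline_pair_distance(g, occ, 7) == baseline_pair_distance(g, occ, 7)

    def test_threshold_is_exclusive_of_low_occupancy(self):
        values = np.zeros((16, 8, 8, 8))
        occ = occupancy_pair()
        values[occ.protein_channel, 0, 0, 0] = 0.70  # below 0.75: not selectable
        values[occ.ligand_channel, 1, 1, 1] = 0.9
        assert baseline_pair_distance(self._grid(values), occ, 0) is None


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0

    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 7), rng.integers(3, 7)
        x = rng.normal(size=n)
        y = rng.normal(size=m) + rng.normal() * 0.5
        if seed % 2:  # exercise midrank ties
            x = np.round(x)
            y = np.round(y)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.8
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        mags = np.array([1.0, 2.0, 3.0, 4.0])
        dists = 10.0 - 2.0 * mags
        assert magnitude_distance_correlation(mags, dists) == pytest.approx(-1.0)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(11)
        mags = rng.random(20)
        dists = rng.random(20)
        r1 = magnitude_distance_correlation(mags, dists)
        r2 = magnitude_distance_correlation(np.tile(mags, 2), np.tile(dists, 2))
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_variable_undefined(self):
        assert magnitude_distance_correlation([1, 1, 1], [1, 2, 3]) is None

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            magnitude_distance_correlation([1, 2], [2, 1])


class TestStudies:
    def test_distance_study_produces_tidy_records(self, small_clashed):
        posed, _ = small_clashed
        rng = np.random.default_rng(0)
        w = np.zeros((16, 24, 24, 24))
        occ = occupancy_pair()
        w[occ.protein_channel] = rng.random((24, 24, 24))
        w[occ.ligand_channel] = rng.random((24, 24, 24))
        scorer = LinearScorer(w)
        result = distance_study([posed], scorer, pairs=[occ], seed=5, steps=4)
        assert set(result.records.columns) == {
            "complex_id", "pair", "distance", "baseline_distance", "magnitude"}
        assert len(result.records) == 1
        assert "occupancy" in result.pair_stats or result.records["distance"].notna().any()

    def test_consistency_study_counts_bounded(self, small_clashed):
        posed, _ = small_clashed
        occ = occupancy_pair()
        w = np.zeros((16, 24, 24, 24))
        w[occ.ligand_channel, 12, 12, 12] = 5.0  # always highlight box center
        scorer = LinearScorer(w)
        out = consistency_study(posed, scorer, n_variants=4, mode="rotation",
                                seed=3, steps=2)
        assert 1 <= out.ligand_repeat_count <= 4
        assert out.baseline_expected_repeat >= 1.0
        assert out.n_variants_used == 4

    def test_consistency_study_validates_inputs(self, small_clashed):
        posed, _ = small_clashed
        scorer = LinearScorer(np.zeros((16, 24, 24, 24)))
        with pytest.raises(ValueError):
            consistency_study(posed, scorer, n_variants=1)
        with pytest.raises(ValueError):
            consistency_study(posed, scorer, mode="jitter")
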