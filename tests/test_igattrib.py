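import numpy as np
import pytest

from voxattrib.igattrib import (AttributionGrid, atom_attribution,
                                completeness_gap, integrated_gradients,
                                top_regions)
from voxattrib.scorers import LinearScorer, build_scorer
from voxattrib.structio import ComplexStructure
from voxattrib.voxelizer import VoxelGrid, default_scheme, voxelize

from conftest import make_atom


def make_grid(values, origin=(0.0, 0.0, 0.0), spacing=1.0):
    return VoxelGrid(values=np.asarray(values), origin=np.array(origin),
                     spacing=spacing, source_id="test")


def make_attr(values, origin=(0.0, 0.0, 0.0), spacing=1.0):
    return AttributionGrid(values=np.asarray(values, dtype=float),
                           origin=np.array(origin), spacing=spacing,
                           baseline_id="zeros", steps=10, completeness_gap=0.0)


class TestIntegratedGradients:
    @pytest.mark.parametrize("steps", [1, 3, 100])
    def test_exact_for_linear_scorer(self, steps):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((16, 6, 6, 6))
        x = rng.random((16, 6, 6, 6))
        grid = make_grid(x)
        attr = integrated_gradients(LinearScorer(w, bias=2.0), grid, steps=steps)
        np.testing.assert_allclose(attr.values, w * x, atol=1e-12)
        assert attr.completeness_gap <= 1e-9

    def test_constant_scorer_attributes_nothing(self):
        grid = make_grid(np.random.default_rng(1).random((16, 6, 6, 6)))
        attr = integrated_gradients(LinearScorer(np.zeros((16, 6, 6, 6)), 3.0),
                                    grid, steps=5)
        assert not np.any(attr.values)
        assert attr.completeness_gap <= 1e-12

    def test_input_equal_to_baseline_gives_zero(self):
        x = np.random.default_rng(2).random((16, 6, 6, 6))
        grid = make_grid(x)
        baseline = make_grid(x.copy())
        s = LinearScorer(np.ones((16, 6, 6, 6)))
        attr = integrated_gradients(s, grid, steps=10, baseline=baseline)
        assert not np.any(attr.values)
        assert attr.completeness_gap <= 1e-12

    def test_cnn_gap_small_and_converging(self, small_clashed):
        posed, _ = small_clashed
        grid = voxelize(posed, dtype=np.float64)
        scorer = build_scorer("clash", seed=3)
        f_x = float(scorer.forward(np.asarray(grid.values)[None])[0])
        f_b = float(scorer.forward(np.zeros_like(grid.values)[None])[0])
        gaps = []
        for steps in (100, 200, 400):
            attr = integrated_gradients(scorer, grid, steps=steps)
            gaps.append(attr.completeness_gap)
        assert gaps[0] <= max(1e-6, 0.01 * abs(f_x - f_b))
        assert gaps[1] <= gaps[0] + 1e-8
        assert gaps[2] <= gaps[1] + 1e-8

    def test_recomputed_gap_matches(self):
        rng = np.random.default_rng(4)
        w = rng.standard_normal((16, 6, 6, 6))
        grid = make_grid(rng.random((16, 6, 6, 6)))
        s = LinearScorer(w)
        attr = integrated_gradients(s, grid, steps=7)
        assert completeness_gap(attr, s, grid) == pytest.approx(
            attr.completeness_gap, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        grid = make_grid(np.zeros((16, 6, 6, 6)))
        baseline = make_grid(np.zeros((16, 4, 4, 4)))
        with pytest.raises(ValueError):
            integrated_gradients(LinearScorer(np.zeros((16, 6, 6, 6))),
                                 grid, baseline=baseline)

    def test_non_differentiable_scorer_rejected(self):
        grid = make_grid(np.zeros((16, 6, 6, 6)))
        with pytest.raises(TypeError):
            integrated_gradients(lambda x: 0.0, grid)


class TestTopRegions:
    def test_single_nonzero_voxel(self):
        values = np.zeros((16, 8, 8, 8))
        values[5, 2, 3, 4] = -0.7
        summary = top_regions(make_attr(values))
        assert summary.selected_channels == [5]
        assert summary.region(5).top_voxel == (2, 3, 4)
        assert summary.region(5).value == pytest.approx(-0.7)

    def test_tie_broken_by_lowest_linear_index(self):
        values = np.zeros((16, 4, 4, 4))
        values[0, 1, 0, 0] = 1.0
        values[0, 2, 0, 0] = 1.0
        summary = top_regions(make_attr(values))
        assert summary.region(0).top_voxel == (1, 0, 0)

    def test_corner_neighborhood_has_seven_voxels(self):
        values = np.zeros((16, 24, 24, 24))
        values[3, 0, 0, 0] = 2.0
        summary = top_regions(make_attr(values))
        neighbors = summary.region(3).neighbors
        assert len(neighbors) == 7
        assert (0, 0, 0) not in neighbors

    def test_all_zero_gives_flagged_empty_summary(self):
        summary = top_regions(make_attr(np.zeros((16, 4, 4, 4))))
        assert summary.empty
        assert summary.regions == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal((16, 6, 6, 6))
        summary = top_regions(make_attr(values))
        # oracle: full scan over every channel and voxel
        flat_best = sorted(
            ((abs(v), -lin) for lin, v in enumerate(values.ravel())),
            reverse=True)[:5]
        expected_channels = []
        for absv, neglin in flat_best:
            ch = (-neglin) // (6 * 6 * 6)
            if ch not in expected_channels:
                expected_channels.append(ch)
        assert summary.selected_channels == expected_channels
        for ch in range(16):
            lin = np.argmax(np.abs(values[ch]).ravel())
            assert summary.region(ch).top_voxel == np.unravel_index(
                lin, (6, 6, 6))


class TestAtomAttribution:
    def _complex(self):
        ligand = [make_atom("C", (0, 0, 0), hydrophobic=True),
                  make_atom("C", (2, 0, 0), hydrophobic=True)]
        protein = [make_atom("N", (0, 3, 0), source="protein", donor=True)]
        return ComplexStructure(protein, ligand, "aa")

    def test_single_atom_ligand_is_top(self):
        ligand = [make_atom("C", (0, 0, 0), hydrophobic=True)]
        c = ComplexStructure([], ligand, "single")
        grid = voxelize(c, size=8)
        scheme = default_scheme()
        values = np.zeros((16, 8, 8, 8))
        values[scheme.index("ligand", "hydrophobic"), 3, 3, 3] = 1.0
        attr = make_attr(values, origin=grid.origin)
        out = atom_attribution(attr, c)
        assert out.top_ligand_atom == 0
        assert out.top_protein_atom is None

    def test_atom_at_top_voxel_selected(self):
        c = self._complex()
        grid = voxelize(c, size=8)
        scheme = default_scheme()
        values = np.zeros((16, 8, 8, 8))
        idx = grid.nearest_voxel(c.ligand_atoms[1].position)
        values[(scheme.index("ligand", "hydrophobic"),) + idx] = 2.0
        out = atom_attribution(make_attr(values, origin=grid.origin), c)
        assert out.top_ligand_atom == 1

    def test_equidistant_tie_goes_to_lower_index(self):
        ligand = [make_atom("C", (-1.0, 0, 0), hydrophobic=True),
                  make_atom("C", (1.0, 0, 0), hydrophobic=True)]
        c = ComplexStructure([], ligand, "tie")
        scheme = default_scheme()
        values = np.zeros((16, 3, 3, 3))
        values[scheme.index("ligand", "hydrophobic"), 1, 1, 1] = 1.0
        # voxel (1,1,1) at the exact midpoint of the two atoms
        attr = make_attr(values, origin=(-1.0, -1.0, -1.0))
        out = atom_attribution(attr, c)
        assert out.top_ligand_atom == 0

    def test_unmatched_channel_reported(self):
        c = self._complex()  # no metal atoms anywhere
        scheme = default_scheme()
        values = np.zeros((16, 8, 8, 8))
        values[scheme.index("ligand", "metal"), 0, 0, 0] = 1.0
        out = atom_attribution(make_attr(values), c)
        assert scheme.index("ligand", "metal") in out.unassigned_channels
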