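"""Height-map gridding: cell means, validity mask, thickness, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memdeform as md
from memdeform.heightmap import (
    GridSpec,
    build_height_map,
    global_mean_height,
    local_thickness_map,
)
from memdeform.model import AtomRecord, Frame, Topology

from conftest import make_map


def _mini_system(positions, box=(20.0, 25.0)):
    """Topology of upper-head P atoms at given positions."""
    topo = Topology([AtomRecord(i, "P", 30.974, "upper_head_heavy")
                     for i in range(len(positions))])
    return topo, Frame(time=0.0, positions=np.asarray(positions, float), box=box)


class TestGridSpec:
    def test_default_rectangle_has_4608_cells(self):
        grid = GridSpec.from_box((320.0, 360.0), 5.0)
        assert (grid.nx, grid.ny) == (64, 72)
        assert grid.nx * grid.ny == 4608

    def test_non_tiling_spacing_raises(self):
        with pytest.raises(ValueError, match="tile"):
            GridSpec.from_box((320.0, 360.0), 7.0)


class TestBuildHeightMap:
    def test_single_atom_single_cell(self):
        topo, frame = _mini_system([(2.5, 2.5, 10.0)])
        hm = build_height_map(frame, topo, "upper", GridSpec(spacing=5.0, nx=4, ny=5))
        assert hm.heights[0, 0] == 10.0
        assert hm.n_valid == 1

    def test_cell_mean_of_two_atoms(self):
        topo, frame = _mini_system([(2.5, 2.5, 10.0), (2.0, 2.0, 20.0)])
        hm = build_height_map(frame, topo, "upper", GridSpec(spacing=5.0, nx=4, ny=5))
        assert hm.heights[0, 0] == 15.0

    def test_far_edge_atom_wraps_to_origin(self):
        topo, frame = _mini_system([(20.0, 25.0, 5.0)])  # exactly at the far corner
        hm = build_height_map(frame, topo, "upper", GridSpec(spacing=5.0, nx=4, ny=5))
        assert hm.heights[0, 0] == 5.0

    def test_no_atoms_of_role_raises(self, flat_system):
        _, traj, _, _ = flat_system
        topo = Topology([AtomRecord(0, "C", 12.011, "protein")])
        frame = Frame(0.0, [(1.0, 1.0, 1.0)], (20.0, 25.0))
        with pytest.raises(ValueError, match="no atoms"):
            build_height_map(frame, topo, "upper", GridSpec(spacing=5.0, nx=4, ny=5))

    def test_invalid_cells_are_masked_not_sentinel(self):
        topo, frame = _mini_system([(2.5, 2.5, 10.0)])
        hm = build_height_map(frame, topo, "upper", GridSpec(spacing=5.0, nx=4, ny=5))
        assert np.isnan(hm.heights[~hm.valid]).all()

    def test_permutation_invariance(self, default_system):
        _, traj, topology, _ = default_system
        rng = np.random.default_rng(0)
        frame = traj.frames[0]
        perm = rng.permutation(len(topology))
        topo2 = Topology([topology[i] for i in perm])
        # renumber roles along the permutation; positions follow
        frame2 = Frame(frame.time, frame.positions[perm], frame.box)
        a = build_height_map(frame, topology, "upper")
        b = build_height_map(frame2, topo2, "upper")
        assert np.array_equal(a.valid, b.valid)
        assert np.allclose(a.heights[a.valid], b.heights[b.valid])

    def test_translation_covariance_in_z(self, default_system):
        _, traj, topology, _ = default_system
        frame = traj.frames[0]
        shifted = Frame(frame.time, frame.positions + [0.0, 0.0, 3.25], frame.box)
        a = build_height_map(frame, topology, "upper")
        b = build_height_map(shifted, topology, "upper")
        assert np.allclose(b.heights[b.valid], a.heights[a.valid] + 3.25)
        assert global_mean_height(b) == pytest.approx(global_mean_height(a) + 3.25)

    def test_periodic_consistency(self, default_system):
        _, traj, topology, _ = default_system
        frame = traj.frames[0]
        moved = Frame(frame.time, frame.positions + [frame.box[0], 0.0, 0.0], frame.box)
        a = build_height_map(frame, topology, "upper")
        b = build_height_map(moved, topology, "upper")
        assert np.array_equal(a.valid, b.valid)
        assert np.allclose(a.heights[a.valid], b.heights[b.valid])

    def test_refinement_consistency_with_surface_function(self):
        # dense noiseless single mode: cell means at Δ=5 and Δ=2.5 both
        # track the generating surface to within the curvature bound A·(πΔ/λ)²
        A, lam = 4.0, 40.0
        params = md.SyntheticParams(
            n_frames=1, seed=13, noise_sigma=0.0, head_density=9.0,
            modes=(md.Mode.from_wavelength(A, lam),),
            include_protein=False, bump_amplitude=0.0, with_forces=False)
        traj, topology, _ = md.generate(params)
        from memdeform.synthetic import in_hexagon, surface_height
        for spacing in (5.0, 2.5):
            grid = GridSpec.from_box(params.rect, spacing)
            hm = build_height_map(traj.frames[0], topology, "upper", grid)
            ii, jj = np.nonzero(hm.valid)
            xc = (ii + 0.5) * spacing
            yc = (jj + 0.5) * spacing
            # only cells whose whole area lies in the hexagon sample it
            # uniformly; boundary cells see a biased sub-region
            interior = np.ones_like(xc, dtype=bool)
            for dx in (-0.5, 0.5):
                for dy in (-0.5, 0.5):
                    interior &= in_hexagon(xc + dx * spacing, yc + dy * spacing,
                                           params.center, params.hex_circumradius)
            truth_h = 21.0 + surface_height(params, xc, yc, 0.0)
            bound = A * (np.pi * spacing / lam) ** 2
            assert np.max(np.abs(hm.heights[ii, jj] - truth_h)[interior]) < bound


class TestGlobalMean:
    def test_small_mean(self):
        assert global_mean_height(make_map([20.0, 22.0, 24.0])) == 22.0

    def test_uniform_identity(self):
        assert global_mean_height(make_map([7.5] * 9)) == 7.5

    def test_matches_enumeration_oracle(self, random_map):
        hm = random_map(np.random.default_rng(1))
        total, count = 0.0, 0
        for i in range(hm.grid.nx):
            for j in range(hm.grid.ny):
                if hm.valid[i, j]:
                    total += hm.heights[i, j]
                    count += 1
        assert global_mean_height(hm) == pytest.approx(total / count, rel=1e-12)

    def test_empty_map_raises(self):
        hm = make_map([1.0], valid=np.zeros(20, dtype=bool))
        with pytest.raises(ValueError, match="no valid cells"):
            global_mean_height(hm)


class TestThickness:
    def test_flat_leaflets_give_exact_42(self, flat_system):
        _, traj, topology, _ = flat_system
        up = build_height_map(traj.frames[0], topology, "upper")
        lo = build_height_map(traj.frames[0], topology, "lower")
        thickness, joint, avg = local_thickness_map(up, lo)
        assert avg == 42.0
        assert np.all(thickness[joint] == 42.0)

    def test_hand_average(self):
        up = make_map([40.0, 42.0, 44.0])
        lo = make_map([0.0, 0.0, 0.0])
        _, _, avg = local_thickness_map(up, lo)
        assert avg == 42.0

    def test_common_mode_undulation_cancels(self):
        # same u(x, y, t) on both leaflets: thickness stays d0 everywhere
        params = md.SyntheticParams(
            n_frames=2, seed=21, noise_sigma=0.0, head_density=0.4,
            modes=(md.Mode.from_wavelength(5.0, 80.0),),
            include_protein=False, bump_amplitude=0.0, with_forces=False)
        traj, topology, _ = md.generate(params)
        up = build_height_map(traj.frames[0], topology, "upper")
        lo = build_height_map(traj.frames[0], topology, "lower")
        thickness, joint, avg = local_thickness_map(up, lo)
        # leaflet lattices differ, so cell means sample u at different points;
        # the residual is bounded by the within-cell variation of the mode
        assert abs(avg - 42.0) < 0.05
        assert np.max(np.abs(thickness[joint] - 42.0)) < 1.0

    def test_mismatched_grids_raise(self):
        up = make_map([1.0], nx=4, ny=5)
        lo = make_map([1.0], nx=5, ny=4)
        with pytest.raises(ValueError, match="different grids"):
            local_thickness_map(up, lo)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(shift=st.floats(-50, 50), zshift=st.floats(-30, 30))
def test_xy_translation_plus_wrap_preserves_global_mean(shift, zshift):
    """Shifting atoms by whole boxes in x and any amount in z behaves as
    pure z-translation of the map statistics."""
    rng = np.random.default_rng(3)
    pos = np.column_stack([rng.uniform(0, 20, 30), rng.uniform(0, 25, 30),
                           rng.normal(0, 2, 30)])
    topo, frame = _mini_system(pos)
    grid = GridSpec(spacing=5.0, nx=4, ny=5)
    base = global_mean_height(build_height_map(frame, topo, "upper", grid))
    moved = Frame(0.0, pos + [20.0 * round(shift / 20), 0.0, zshift], frame.box)
    out = global_mean_height(build_height_map(moved, topo, "upper", grid))
    assert out == pytest.approx(base + zshift, abs=1e-9)
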