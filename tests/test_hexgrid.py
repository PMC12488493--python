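"""Lattice coordinate assignment, landmarks, neighbourhoods, flattening."""

import numpy as np
import pytest

from eyemapper import SyntheticConfig, assign_lattice_coords, find_landmarks
from eyemapper.hexgrid import (
    ColumnGrid,
    NEIGHBOR_OFFSETS,
    align_lattices,
    lattice_symmetries,
    local_flatten,
    reference_neighborhood,
    regular_positions,
    ring_offsets,
)
from eyemapper.synthetic import generate_eye_lattice, generate_medulla_grid, marker_band_ids


def small_medulla(seed=0, jitter=0.0, anisotropy=1.0):
    cfg = SyntheticConfig(seed=seed, position_jitter_frac=jitter,
                          medulla_anisotropy=anisotropy)
    omm = generate_eye_lattice(cfg)
    return generate_medulla_grid(omm, cfg)


class TestCoordConvention:
    def test_six_neighbor_offsets_preserve_parity(self):
        for dh, dv in NEIGHBOR_OFFSETS:
            assert (dh + dv) % 2 == 0

    def test_ring_sizes(self):
        assert len(ring_offsets(0)) == 1
        assert len(ring_offsets(1)) == 6
        assert len(ring_offsets(2)) == 12
        assert len(ring_offsets(3)) == 18

    def test_twelve_point_group_operations(self):
        ops = lattice_symmetries()
        assert len(ops) == 12
        # all distinct, all map the neighbour set onto itself
        from eyemapper.hexgrid import _coords_to_cube, _cube_to_coords

        nb = _coords_to_cube(np.array(NEIGHBOR_OFFSETS))
        keys = set()
        for op in ops:
            mapped = nb @ op.T
            keys.add(mapped.tobytes())
            back = _cube_to_coords(mapped)
            assert {tuple(r) for r in back} == set(NEIGHBOR_OFFSETS)
        assert len(keys) == 12


class TestAssignment:
    def test_perfect_lattice_recovered_exactly_up_to_symmetry(self):
        grid = small_medulla(jitter=0.0)
        rec = assign_lattice_coords(grid.positions)
        assert rec.assigned.all()
        assert align_lattices(rec.coords, grid.coords) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovery_with_20_percent_jitter(self, seed):
        cfg = SyntheticConfig(seed=seed, position_jitter_frac=0.2)
        omm = generate_eye_lattice(cfg)
        grid = generate_medulla_grid(omm, cfg)
        rec = assign_lattice_coords(grid.positions)
        assert rec.assigned.all()
        assert align_lattices(rec.coords, grid.coords) == 1.0

    def test_displaced_point_is_flagged_unassigned(self):
        grid = small_medulla(jitter=0.0)
        pts = grid.positions.copy()
        # push one interior point 0.6 of a pitch toward its neighbour
        i = grid.coord_index[(0, 0)]
        j = grid.coord_index[(1, 1)]
        pitch = np.linalg.norm(pts[j] - pts[i])
        pts[i] = pts[i] + 0.6 * (pts[j] - pts[i]) / np.linalg.norm(pts[j] - pts[i]) * pitch
        rec = assign_lattice_coords(pts)
        assert not rec.assigned[i]
        assert rec.assigned.sum() >= len(pts) - 2

    def test_rigid_transform_and_scale_invariance(self):
        grid = small_medulla(jitter=0.1, seed=3)
        rec0 = assign_lattice_coords(grid.positions)
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        pts = 3.7 * grid.positions @ q.T + np.array([10.0, -4.0, 2.0])
        rec1 = assign_lattice_coords(pts)
        assert rec1.assigned.all()
        assert align_lattices(rec1.coords, rec0.coords) == 1.0

    def test_coord_neighbors_are_spatially_near(self):
        grid = small_medulla(jitter=0.1, seed=4, anisotropy=0.7)
        rec = assign_lattice_coords(grid.positions)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(rec.positions).query(rec.positions, k=2)
        med = np.median(d[:, 1])
        for i in range(len(rec)):
            if not rec.assigned[i]:
                continue
            for j in rec.neighbors_of(i):
                assert np.linalg.norm(rec.positions[i] - rec.positions[j]) < 1.8 * med

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            assign_lattice_coords(np.random.default_rng(0).normal(size=(5, 3)))


class TestLandmarks:
    def test_marker_band_of_four_rows_selects_a_middle_row(self):
        grid = small_medulla(jitter=0.0)
        markers = marker_band_ids(grid)  # rows v in {-1, 0, 1, 2}
        out = find_landmarks(grid, markers)
        v0 = np.unique(out.coords[out.equator_row, 1])
        assert len(v0) == 1 and v0[0] in (0, 1)

    def test_central_meridian_splits_counts_in_half(self):
        grid = small_medulla(jitter=0.0)
        out = find_landmarks(grid, marker_band_ids(grid))
        h0 = np.unique(out.coords[out.central_meridian, 0])
        assert len(h0) == 1
        hs = out.coords[out.assigned, 0]
        assert abs(int(np.sum(hs < h0[0])) - int(np.sum(hs > h0[0]))) <= 0.05 * len(hs)

    def test_rigid_shift_does_not_change_assignment(self):
        grid = small_medulla(jitter=0.05, seed=2)
        out1 = find_landmarks(grid, marker_band_ids(grid))
        eq1, cm1 = out1.equator_row.copy(), out1.central_meridian.copy()
        shifted = ColumnGrid(ids=grid.ids, positions=grid.positions + 100.0,
                             coords=grid.coords, assigned=grid.assigned,
                             mirrored_h=grid.mirrored_h)
        out2 = find_landmarks(shifted, marker_band_ids(shifted))
        assert np.array_equal(eq1, out2.equator_row)
        assert np.array_equal(cm1, out2.central_meridian)

    def test_non_adjacent_marker_rows_rejected(self):
        grid = small_medulla(jitter=0.0)
        ids_v = {int(i): int(v) for i, v in zip(grid.ids, grid.coords[:, 1])}
        bad = [i for i, v in ids_v.items() if v == 0][:5] + \
              [i for i, v in ids_v.items() if v == 4][:5]
        with pytest.raises(ValueError):
            find_landmarks(grid, bad)


class TestReferenceNeighborhood:
    def test_interior_column_has_19_points(self):
        grid = small_medulla(jitter=0.0)
        present, missing = reference_neighborhood(grid, (0, 0), rings=2)
        assert len(present) == 19 and not missing

    def test_rings_1_gives_7(self):
        grid = small_medulla(jitter=0.0)
        present, missing = reference_neighborhood(grid, (0, 0), rings=1)
        assert len(present) == 7 and not missing

    def test_boundary_column_reports_missing(self):
        grid = small_medulla(jitter=0.0)
        vmax = grid.coords[grid.assigned, 1].max()
        h = grid.coords[grid.assigned][grid.coords[grid.assigned, 1] == vmax][0, 0]
        present, missing = reference_neighborhood(grid, (int(h), int(vmax)), rings=2)
        assert missing and len(present) + len(missing) == 19

    def test_unknown_centre_rejected(self):
        grid = small_medulla(jitter=0.0)
        with pytest.raises(KeyError):
            reference_neighborhood(grid, (999, 999))

    def test_deterministic_order(self):
        grid = small_medulla(jitter=0.0)
        a, _ = reference_neighborhood(grid, (0, 0))
        b, _ = reference_neighborhood(grid, (0, 0))
        assert a == b and a[0] == (0, 0)


class TestLocalFlatten:
    def test_coplanar_points_preserve_distances_exactly(self):
        grid = small_medulla(jitter=0.0)  # flat sheet, z = 0
        present, _ = reference_neighborhood(grid, (0, 0))
        idx = [grid.coord_index[c] for c in present]
        xy, _ = local_flatten(grid, idx)
        d3 = np.linalg.norm(grid.positions[idx][:, None] - grid.positions[idx][None], axis=2)
        d2 = np.linalg.norm(xy[:, None] - xy[None], axis=2)
        np.testing.assert_allclose(d2, d3, atol=1e-9)

    def test_v_axis_points_up_and_h_positive(self):
        grid = small_medulla(jitter=0.0)
        present, _ = reference_neighborhood(grid, (0, 0))
        idx = [grid.coord_index[c] for c in present]
        xy, _ = local_flatten(grid, idx)
        hv = grid.coords[idx].astype(float)
        A = np.column_stack([np.ones(len(idx)), hv])
        sol, *_ = np.linalg.lstsq(A, xy, rcond=None)
        assert sol[2][1] > 0 and abs(sol[2][0]) < 1e-9  # +v -> +y
        assert sol[1][0] > 0                            # +h -> +x

    def test_spherical_cap_5deg_distortion_below_half_percent(self):
        # unit hexagon (5° ring radius) on the unit sphere
        cfg = SyntheticConfig(seed=1, position_jitter_frac=0.0)
        omm = generate_eye_lattice(cfg)
        grid = omm.as_grid()
        present, _ = reference_neighborhood(grid, (0, 0), rings=1)
        idx = [grid.coord_index[c] for c in present]
        xy, _ = local_flatten(grid, idx)
        d3 = np.linalg.norm(grid.positions[idx][:, None] - grid.positions[idx][None], axis=2)
        d2 = np.linalg.norm(xy[:, None] - xy[None], axis=2)
        mask = d3 > 0
        assert np.max(np.abs(d2[mask] - d3[mask]) / d3[mask]) < 0.005

    def test_handedness_flip_is_deterministic(self):
        grid = small_medulla(jitter=0.0)
        present, _ = reference_neighborhood(grid, (0, 0))
        idx = [grid.coord_index[c] for c in present]
        xy1, _ = local_flatten(grid, idx)
        mirrored = ColumnGrid(ids=grid.ids,
                              positions=grid.positions * np.array([-1.0, 1.0, 1.0]),
                              coords=grid.coords, assigned=grid.assigned)
        xy2, _ = local_flatten(mirrored, idx)
        # the orientation rule (+v -> +y, +h -> +x) makes the image of the
        # ideal lattice identical whichever handedness the input has
        np.testing.assert_allclose(xy1, xy2, atol=1e-9)
        hv = grid.coords[idx].astype(float)
        A = np.column_stack([np.ones(len(idx)), hv])
        sol, *_ = np.linalg.lstsq(A, xy2, rcond=None)
        assert sol[2][1] > 0 and sol[1][0] > 0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        g = ColumnGrid(ids=np.arange(5), positions=pts,
                       coords=np.column_stack([np.arange(5) * 2, np.zeros(5, int)]),
                       assigned=np.ones(5, bool))
        with pytest.raises(ValueError):
            local_flatten(g, [0, 1, 2, 3, 4])

    def test_extra_points_projected_with_neighborhood(self):
        grid = small_medulla(jitter=0.0)
        present, _ = reference_neighborhood(grid, (0, 0))
        idx = [grid.coord_index[c] for c in present]
        extra = grid.positions[idx[0]] + np.array([0.5, 0.25, 0.0])
        xy, exy = local_flatten(grid, idx, extra[None, :])
        assert exy.shape == (1, 2)
        assert np.linalg.norm(exy[0] - xy[0]) == pytest.approx(
            np.linalg.norm([0.5, 0.25]), abs=1e-9
        )


def test_regular_positions_hexagonal_pitch():
    pos = regular_positions(NEIGHBOR_OFFSETS, pitch=1.0, kind="hexagonal")
    np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 1.0, atol=1e-12)
    sq = regular_positions([(1, 1), (0, 2)], pitch=1.0, kind="square")
    np.testing.assert_allclose(np.linalg.norm(sq, axis=1),
                               [np.sqrt(2) / 2, 1.0], atol=1e-12)
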