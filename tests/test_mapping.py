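"""Kernel regression, eye map construction, PD mapping & interpolation."""

import numpy as np
import pytest

from eyemapper import SyntheticConfig
from eyemapper.eye import OmmatidiaSet
from eyemapper.hexgrid import ColumnGrid
from eyemapper.mapping import (
    KernelModel,
    TangentVectorField,
    bandwidth_select,
    interpolate_pd_field,
    llkr_fit_predict,
    map_pd_to_eye,
    map_pd_to_grid,
    match_grids,
)
from eyemapper.opticflow import rotation_flow
from eyemapper.pipeline import build_world, interior_columns, planted_h_pd
from eyemapper.skeleton import PDVector
from eyemapper.synthetic import (
    _local_axes,
    generate_eye_lattice,
    generate_medulla_grid,
    generate_t4_skeleton,
)


class TestLLKR:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.X = self.rng.uniform(-2, 2, (40, 2))
        self.q = self.rng.uniform(-1, 1, (10, 2))

    def test_reproduces_affine_functions(self):
        y = 3.0 + self.X @ [1.5, -2.0]
        for model in (KernelModel("fixed", bandwidth=0.5),
                      KernelModel("adaptive_nn", k=8)):
            pred = llkr_fit_predict(self.X, y, self.q, model)
            np.testing.assert_allclose(pred, 3.0 + self.q @ [1.5, -2.0], atol=1e-8)

    def test_vector_valued_targets_componentwise(self):
        Y = np.column_stack([self.X @ [1.0, 0], self.X @ [0, -1.0], self.X.sum(1)])
        pred = llkr_fit_predict(self.X, Y, self.q, KernelModel("fixed", bandwidth=0.7))
        expected = np.column_stack([self.q @ [1.0, 0], self.q @ [0, -1.0], self.q.sum(1)])
        np.testing.assert_allclose(pred, expected, atol=1e-8)

    def test_small_bandwidth_interpolates_training_values(self):
        y = np.exp(-np.sum(self.X**2, axis=1))
        pred = llkr_fit_predict(self.X, y, self.X[:5], KernelModel("fixed", bandwidth=0.05))
        np.testing.assert_allclose(pred, y[:5], atol=1e-3)

    def test_infinite_bandwidth_equals_global_least_squares(self):
        y = self.X @ [2.0, 1.0] + self.rng.normal(0, 0.5, 40)
        pred = llkr_fit_predict(self.X, y, self.q, KernelModel("fixed", bandwidth=1e9))
        A = np.column_stack([np.ones(40), self.X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(
            pred, np.column_stack([np.ones(10), self.q]) @ beta, atol=1e-6
        )

    def test_translation_and_scale_equivariance_in_x(self):
        y = np.sin(self.X[:, 0]) + self.X[:, 1] ** 2
        p0 = llkr_fit_predict(self.X, y, self.q, KernelModel("fixed", bandwidth=0.5))
        p1 = llkr_fit_predict(3 * self.X + 7, y, 3 * self.q + 7,
                              KernelModel("fixed", bandwidth=1.5))
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_linearity_in_y(self):
        y1 = np.sin(self.X[:, 0])
        y2 = self.X[:, 1] ** 2
        m = KernelModel("fixed", bandwidth=0.6)
        pa = llkr_fit_predict(self.X, 2.0 * y1 - 3.0 * y2, self.q, m)
        pb = 2.0 * llkr_fit_predict(self.X, y1, self.q, m) - \
            3.0 * llkr_fit_predict(self.X, y2, self.q, m)
        np.testing.assert_allclose(pa, pb, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            llkr_fit_predict(self.X[:3], np.ones(3), self.q,
                             KernelModel("fixed", bandwidth=1.0))


class TestBandwidthSelect:
    def test_affine_data_selects_ladder_maximum(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (30, 2))
        y = X @ [1.0, 2.0]
        bw = bandwidth_select(X, y, KernelModel("fixed"))
        # largest candidate: 4x the span norm
        span = np.linalg.norm(X.max(0) - X.min(0))
        assert bw == pytest.approx(4 * span, rel=1e-9)

    def test_pure_noise_selects_maximal_smoothing(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (30, 2))
        y = rng.normal(size=30)
        bw = bandwidth_select(X, y, KernelModel("fixed"))
        span = np.linalg.norm(X.max(0) - X.min(0))
        assert bw == pytest.approx(4 * span, rel=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (25, 1))
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.2, 25)
        assert bandwidth_select(X, y) == bandwidth_select(X, y)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bandwidth_select(np.ones((20, 1)), np.arange(20.0))


class TestMatchGrids:
    def test_identical_lattices_perfect_bijection(self, default_world):
        emap = default_world.eyemap
        assert len(emap.pairs) == len(default_world.ommatidia)
        assert not emap.unmatched_columns and not emap.unmatched_ommatidia
        # matched pairs share the mirrored lattice coordinate
        omm = default_world.ommatidia
        grid = default_world.columns
        omm_row = {int(i): j for j, i in enumerate(omm.ids)}
        for i in range(0, len(grid), 37):
            cid = int(grid.ids[i])
            eye_c = emap.column_coord_to_eye(tuple(grid.coords[i]))
            assert tuple(omm.coords[omm_row[emap.pairs[cid]]]) == eye_c

    def test_chiasm_mirroring_h3_matches_minus_h3(self, default_world):
        grid, omm = default_world.columns, default_world.ommatidia
        emap = default_world.eyemap
        i = grid.coord_index[(3, 1)]
        omm_row = {int(ii): j for j, ii in enumerate(omm.ids)}
        j = omm_row[emap.pairs[int(grid.ids[i])]]
        assert tuple(omm.coords[j]) == (-3, 1)

    def test_missing_boundary_ring_leaves_interior_matched(self):
        cfg = SyntheticConfig(seed=6, position_jitter_frac=0.0)
        omm = generate_eye_lattice(cfg)
        grid = generate_medulla_grid(omm, cfg)
        # remove the ommatidia boundary ring (points without 6 neighbours)
        complete = omm.complete_neighbour_set()
        sub = OmmatidiaSet(
            ids=omm.ids[complete], directions=omm.directions[complete],
            coords=omm.coords[complete], assigned=omm.assigned[complete],
            equator_row=omm.equator_row[complete],
            central_meridian=omm.central_meridian[complete],
        )
        emap = match_grids(grid, sub)
        assert emap.unmatched_columns == set(grid.ids[~complete])
        assert len(emap.pairs) == int(complete.sum())

    def test_no_inner_photoreceptor_columns_excluded(self):
        cfg = SyntheticConfig(seed=6, position_jitter_frac=0.0)
        omm = generate_eye_lattice(cfg)
        grid = generate_medulla_grid(omm, cfg)
        grid.no_inner_photoreceptor[:5] = True
        emap = match_grids(grid, omm)
        assert set(grid.ids[:5]) <= emap.unmatched_columns
        assert all(int(i) not in emap.pairs for i in grid.ids[:5])

    def test_missing_landmarks_rejected(self):
        cfg = SyntheticConfig(seed=6)
        omm = generate_eye_lattice(cfg)
        grid = generate_medulla_grid(omm, cfg)
        grid.equator_row[:] = False
        with pytest.raises(ValueError):
            match_grids(grid, omm)

    def test_auxiliary_points_one_ring_beyond_boundary(self, default_world):
        emap = default_world.eyemap
        matched_eye = {
            tuple(default_world.ommatidia.coords[j])
            for j in range(len(default_world.ommatidia))
        }
        assert emap.auxiliary
        for c, aux in emap.auxiliary.items():
            assert c not in matched_eye
            assert np.linalg.norm(aux["direction"]) == pytest.approx(1.0, abs=1e-9)


class TestMapPDToGrid:
    def test_regular_grid_identity(self):
        cfg = SyntheticConfig(seed=1, position_jitter_frac=0.0,
                              medulla_anisotropy=1.0, medulla_pitch_um=1.0)
        omm = generate_eye_lattice(cfg)
        grid = generate_medulla_grid(omm, cfg)
        home = (4, 0)
        centre = grid.positions[grid.coord_index[home]]
        pdv = PDVector(centre=centre, direction=np.array([1.0, 0, 0]),
                       length=1.5, width=0.5, home_coord=home)
        out = map_pd_to_grid(pdv, grid)
        assert out.length_grid_units == pytest.approx(1.5, abs=1e-6)
        np.testing.assert_allclose(out.centre[:2], [0, 0], atol=1e-6)

    def test_anisotropic_grid_rescales_h_length_by_inverse(self):
        cfg = SyntheticConfig(seed=1, position_jitter_frac=0.0,
                              medulla_anisotropy=0.7, medulla_pitch_um=1.0)
        omm = generate_eye_lattice(cfg)
        grid = generate_medulla_grid(omm, cfg)
        home = (4, 0)
        centre, e_h, _, _ = _local_axes(grid, home)
        pdv = PDVector(centre=centre, direction=e_h, length=1.0, width=0.5,
                       home_coord=home)
        out = map_pd_to_grid(pdv, grid)
        assert out.length_grid_units == pytest.approx(1.0 / 0.7, rel=0.02)

    def test_planted_identical_t4s_cluster_tightly(self, default_world):
        """Mapped head/tail scatter stays below half the inter-column pitch."""
        w = default_world
        cols = interior_columns(w)
        rng = np.random.default_rng(0)
        homes = [cols[i] for i in rng.choice(len(cols), 50, replace=False)]
        from eyemapper.skeleton import pd_vector

        heads, tails = [], []
        for k, home in enumerate(homes):
            t4 = generate_t4_skeleton(w.columns, home, 0.0, w.config, cell_id=k)
            p = pd_vector(t4.tree)
            p.home_coord = home
            m = map_pd_to_grid(p, w.columns, KernelModel("adaptive_nn", k=9))
            heads.append(m.centre[:2] + m.direction[:2] * m.length_grid_units / 2)
            tails.append(m.centre[:2] - m.direction[:2] * m.length_grid_units / 2)
        for pts in (np.asarray(heads), np.asarray(tails)):
            sd = np.sqrt(np.mean(np.sum((pts - pts.mean(0)) ** 2, axis=1)))
            assert sd < 0.5  # grid pitch = 1

    def test_boundary_home_rejected(self, default_world):
        grid = default_world.columns
        vmax = grid.coords[grid.assigned, 1].max()
        row = grid.coords[grid.assigned]
        h = int(row[row[:, 1] == vmax][0, 0])
        pdv = PDVector(centre=np.zeros(3), direction=np.array([1.0, 0, 0]),
                       length=1.0, width=0.5, home_coord=(h, int(vmax)))
        with pytest.raises(ValueError):
            map_pd_to_grid(pdv, grid)


class TestMapPDToEye:
    def test_tangency_and_span(self, default_world):
        w = default_world
        home = interior_columns(w)[0]
        pdv = planted_h_pd(w, home)
        base, vec, span = map_pd_to_eye(pdv, w.eyemap, w.columns, w.ommatidia,
                                        KernelModel("adaptive_nn", k=9))
        assert abs(vec @ base) < 1e-9
        assert np.linalg.norm(vec) == pytest.approx(span, abs=1e-9)
        assert 2.0 < span < 20.0  # a ~1.5-hexagon PD spans several degrees

    def test_matched_column_regression_residuals_small(self, clean_world):
        """Leave-one-out medulla→eye regression of column positions lands
        within a fraction of the local inter-ommatidial angle."""
        from eyemapper.hexgrid import local_flatten, reference_neighborhood
        from eyemapper.eye import hexagon_metrics

        w = clean_world
        grid, omm, emap = w.columns, w.ommatidia, w.eyemap
        omm_row = {int(i): j for j, i in enumerate(omm.ids)}
        ratios = []
        for home in interior_columns(w)[::12]:
            present, _ = reference_neighborhood(grid, home, 2)
            rows = [grid.coord_index[c] for c in present]
            dirs = np.array([
                omm.directions[omm_row[emap.pairs[int(grid.ids[i])]]] for i in rows
            ])
            xy, _ = local_flatten(grid, rows)
            pred = llkr_fit_predict(xy[1:], dirs[1:], xy[0],
                                    KernelModel("adaptive_nn", k=9))
            pred /= np.linalg.norm(pred)
            resid = np.degrees(np.arccos(np.clip(pred @ dirs[0], -1, 1)))
            m = hexagon_metrics(omm, omm_row[emap.pairs[int(grid.ids[rows[0]])]])
            ratios.append(resid / m.delta_phi)
        assert np.median(ratios) < 0.3

    def test_unmatched_home_rejected(self, default_world):
        w = default_world
        home = interior_columns(w)[0]
        pdv = planted_h_pd(w, home)
        import copy

        emap = copy.deepcopy(w.eyemap)
        cid = int(w.columns.ids[w.columns.coord_index[home]])
        del emap.pairs[cid]
        with pytest.raises(ValueError):
            map_pd_to_eye(pdv, emap, w.columns, w.ommatidia)


class TestInterpolateField:
    def test_constant_field_stays_constant(self, clean_world):
        omm = clean_world.ommatidia
        rng = np.random.default_rng(0)
        idx = rng.choice(len(omm), 60, replace=False)
        base = omm.directions[idx]
        # constant tangent pattern: project a fixed vector at each base
        v0 = np.array([0.0, 0.0, 1.0])
        vec = v0 - (base @ v0)[:, None] * base
        sparse = TangentVectorField(base=base, vectors=vec)
        dense = interpolate_pd_field(sparse, omm)
        expected = v0 - (omm.directions @ v0)[:, None] * omm.directions
        ang = np.degrees(
            np.arccos(np.clip(
                np.sum(dense.vectors * expected, axis=1)
                / np.maximum(np.linalg.norm(dense.vectors, axis=1)
                             * np.linalg.norm(expected, axis=1), 1e-12),
                -1, 1))
        )
        interior = omm.complete_neighbour_set() & (np.linalg.norm(expected, axis=1) > 0.3)
        assert np.median(ang[interior]) < 1.0

    def test_yaw_flow_sampled_at_30_percent_recovered(self, clean_world):
        omm = clean_world.ommatidia
        flow = rotation_flow(omm, np.array([0.0, 0, 1.0]))
        rng = np.random.default_rng(1)
        idx = rng.choice(len(omm), int(0.3 * len(omm)), replace=False)
        sparse = TangentVectorField(base=omm.directions[idx],
                                    vectors=flow.vectors[idx])
        dense = interpolate_pd_field(sparse, omm)
        va, vb = dense.vectors, flow.vectors
        ok = (np.linalg.norm(va, axis=1) > 1e-9) & (np.linalg.norm(vb, axis=1) > 0.2)
        cosang = np.sum(va[ok] * vb[ok], axis=1) / (
            np.linalg.norm(va[ok], axis=1) * np.linalg.norm(vb[ok], axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.median(ang) < 2.0

    def test_outputs_tangent(self, clean_world):
        omm = clean_world.ommatidia
        flow = rotation_flow(omm, np.array([0.0, 1.0, 0]))
        rng = np.random.default_rng(2)
        idx = rng.choice(len(omm), 40, replace=False)
        sparse = TangentVectorField(base=omm.directions[idx],
                                    vectors=flow.vectors[idx])
        dense = interpolate_pd_field(sparse, omm)
        assert dense.tangency_error() < 1e-9

    def test_empty_or_tiny_sparse_field_rejected(self, clean_world):
        omm = clean_world.ommatidia
        with pytest.raises(ValueError):
            interpolate_pd_field(
                TangentVectorField(base=np.zeros((0, 3)), vectors=np.zeros((0, 3))),
                omm,
            )
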