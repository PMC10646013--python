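"""Leaflet assignment, surface interpolation, thickness maps, well fit."""

import numpy as np
import pytest

import memdeform as md
from memdeform.thickness import assign_leaflets, leaflet_surface


class TestAssignLeaflets:
    def test_noiseless_bilayer_splits_exactly(self, flat_traj, flat_spec, p_mask):
        a = assign_leaflets(flat_traj.coordinates[0], p_mask)
        assert a.n_upper == flat_spec.n_per_leaflet
        assert a.n_lower == flat_spec.n_per_leaflet

    def test_atom_at_midplane_goes_upper(self):
        # 9 atoms: 4 up, 4 down, 1 exactly at the median
        z = np.array([5.0, 5, 5, 5, -5, -5, -5, -5, 0.0])
        coords = np.zeros((9, 3))
        coords[:, 2] = z
        mask = md.SelectionMask(np.arange(9), role="phosphorus")
        a = assign_leaflets(coords, mask)
        assert a.upper[8]
        assert a.n_upper == 5

    def test_order_invariance(self, flat_traj, p_mask):
        coords = flat_traj.coordinates[0]
        a = assign_leaflets(coords, p_mask)
        perm = np.random.default_rng(3).permutation(len(p_mask.indices))
        coords2 = coords[p_mask.indices][perm]
        a2 = assign_leaflets(coords2, md.SelectionMask(np.arange(len(perm))))
        assert np.array_equal(a2.upper, a.upper[perm])

    def test_lopsided_leaflet_errors_naming_frame(self):
        coords = np.zeros((10, 3))
        coords[:, 2] = [5, 5, 5, 5, 5, 5, 5, -5, -5, -5]
        mask = md.SelectionMask(np.arange(10))
        with pytest.raises(ValueError, match="frame 7"):
            assign_leaflets(coords, mask, frame_index=7)


class TestLeafletSurface:
    def test_linear_field_reproduced_exactly(self, grid):
        rng = np.random.default_rng(42)
        pts = np.empty((100, 3))
        pts[:, 0] = rng.uniform(-10, grid.x_max + 10, 100)
        pts[:, 1] = rng.uniform(-10, grid.y_max + 10, 100)
        pts[:, 2] = 2 * pts[:, 0] + 3 * pts[:, 1] + 1
        surface, defined = leaflet_surface(pts, grid)
        gx, gy = grid.meshgrid()
        expected = 2 * gx + 3 * gy + 1
        assert np.all(np.abs(surface[defined] - expected[defined]) < 1e-6)

    def test_flat_leaflet_gives_constant_surface(self, flat_traj, flat_spec,
                                                 p_mask, grid):
        coords = flat_traj.coordinates[0]
        a = assign_leaflets(coords, p_mask)
        pts = coords[p_mask.indices][a.upper]
        surface, defined = leaflet_surface(pts, grid, flat_traj.boxes[0])
        np.testing.assert_allclose(surface[defined], 20.0, atol=1e-6)

    def test_interpolates_through_data_points(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(10, 50, size=(30, 3))
        grid = md.GridSpec2D(0, 60, 0, 60, spacing=2.0)
        from scipy.interpolate import CloughTocher2DInterpolator
        interp = CloughTocher2DInterpolator(pts[:, :2], pts[:, 2])
        at_points = interp(pts[:, :2])
        np.testing.assert_allclose(at_points, pts[:, 2], atol=1e-9)

    def test_periodic_margin_covers_full_box(self, grid):
        spec = md.SyntheticBilayerSpec(T0=40, noise_z=0.0, n_per_leaflet=256,
                                       n_frames=1, seed=21)
        traj = md.generate_bilayer_trajectory(spec)
        p = md.select_phosphorus(traj.topology)
        coords = traj.coordinates[0]
        a = assign_leaflets(coords, p)
        pts = coords[p.indices][a.upper]
        _, defined = leaflet_surface(pts, grid, traj.boxes[0])
        assert defined.all()
        # without the periodic margin the hull cannot reach the box edges
        _, defined_bare = leaflet_surface(pts, grid, box=None)
        assert defined_bare.sum() < defined.sum()

    def test_degenerate_points_rejected(self, grid):
        line = np.zeros((10, 3))
        line[:, 0] = np.arange(10)
        with pytest.raises(ValueError):
            leaflet_surface(line, grid)


class TestThicknessMap:
    def test_flat_bilayer_exact_everywhere(self, flat_traj, p_mask, grid):
        tmap = md.thickness_map(flat_traj, p_mask, grid)
        assert tmap.defined_mask.any()
        np.testing.assert_allclose(tmap.mean_thickness[tmap.defined_mask],
                                   40.0, atol=1e-6)

    def test_identical_replicates_equal_single(self, flat_traj, p_mask, grid):
        single = md.thickness_map(flat_traj, p_mask, grid)
        triple = md.thickness_map([flat_traj, flat_traj, flat_traj], p_mask, grid)
        np.testing.assert_allclose(triple.mean_thickness, single.mean_thickness,
                                   equal_nan=True, atol=1e-12)

    def test_mean_equals_count_weighted_replicate_mean(self, p_mask, grid,
                                                       flat_spec):
        trajs = [md.generate_bilayer_trajectory(flat_spec, r) for r in range(2)]
        tmap = md.thickness_map(trajs, p_mask, grid)
        counts = tmap.replicate_n_samples.astype(float)
        with np.errstate(invalid="ignore"):
            weighted = np.nansum(
                np.where(counts > 0, tmap.per_replicate * counts, 0.0), axis=0
            ) / counts.sum(axis=0)
        d = tmap.defined_mask
        np.testing.assert_allclose(tmap.mean_thickness[d], weighted[d],
                                   atol=1e-9)

    def test_weighted_mean_equals_pooled_frames(self, p_mask, grid, flat_spec):
        a = md.generate_bilayer_trajectory(flat_spec, 0)
        b = md.generate_bilayer_trajectory(flat_spec, 1)
        pooled_coords = np.concatenate([a.coordinates, b.coordinates])
        pooled = md.Trajectory(topology=a.topology, coordinates=pooled_coords,
                               times=np.arange(1, len(pooled_coords) + 1, dtype=float),
                               boxes=np.concatenate([a.boxes, b.boxes]))
        tmap_rep = md.thickness_map([a, b], p_mask, grid)
        tmap_pool = md.thickness_map(pooled, p_mask, grid)
        d = tmap_rep.defined_mask & tmap_pool.defined_mask
        np.testing.assert_allclose(tmap_rep.mean_thickness[d],
                                   tmap_pool.mean_thickness[d], atol=1e-9)

    def test_translation_invariance(self, flat_spec, p_mask):
        traj = md.generate_bilayer_trajectory(flat_spec)
        grid = md.GridSpec2D(20, 100, 20, 100, spacing=2.0)
        tmap = md.thickness_map(traj, p_mask, grid)
        shift = np.array([7.0, -4.0, 3.0])
        moved = md.Trajectory(topology=traj.topology,
                              coordinates=traj.coordinates + shift,
                              times=traj.times, boxes=traj.boxes)
        grid2 = md.GridSpec2D(20 + shift[0], 100 + shift[0],
                              20 + shift[1], 100 + shift[1], spacing=2.0)
        tmap2 = md.thickness_map(moved, p_mask, grid2)
        d = tmap.defined_mask & tmap2.defined_mask
        np.testing.assert_allclose(tmap2.mean_thickness[d],
                                   tmap.mean_thickness[d], atol=1e-6)

    def test_label_swap_detected(self, flat_traj, p_mask, grid, monkeypatch):
        # a swapped pipeline negates per-frame thickness everywhere; the
        # averaged map must reject the resulting non-positive means
        from memdeform import thickness as th

        orig = th.assign_leaflets

        def swapped(coords, mask, frame_index=None):
            a = orig(coords, mask, frame_index)
            a.upper = ~a.upper
            return a

        monkeypatch.setattr(th, "assign_leaflets", swapped)
        with pytest.raises(ValueError, match="swap"):
            th.thickness_map(flat_traj, p_mask, grid)

    def test_zero_defined_cells_errors(self, flat_traj, p_mask):
        far_grid = md.GridSpec2D(1000, 1100, 1000, 1100, spacing=2.0)
        with pytest.raises(ValueError):
            md.thickness_map(flat_traj, p_mask, far_grid)


class TestThicknessTimeseries:
    def test_stationary_flat_windows_equal_nominal(self, flat_traj, p_mask, grid):
        ts = md.thickness_timeseries(flat_traj, p_mask, window=3.0, grid=grid)
        assert len(ts.thickness) == 3
        np.testing.assert_allclose(ts.thickness, 40.0, atol=1e-6)

    def test_single_window_equals_global_spatial_mean(self, flat_traj, p_mask,
                                                      grid):
        span = flat_traj.times[-1] - flat_traj.times[0]
        ts = md.thickness_timeseries(flat_traj, p_mask, window=span, grid=grid)
        assert len(ts.thickness) == 1
        global_map = md.thickness_map(flat_traj, p_mask, grid)
        assert ts.thickness[0] == pytest.approx(global_map.spatial_mean(),
                                                abs=1e-9)

    def test_ramped_well_gives_decreasing_windows(self, p_mask, grid):
        spec = md.SyntheticBilayerSpec(T0=40, D=8, sigma_w=25, noise_z=0.0,
                                       step_xy=1.0, n_per_leaflet=64,
                                       n_frames=20, seed=4)
        half = 10 * spec.dt

        def ramp(t):
            return spec.D * min(t / half, 1.0)

        traj = md.generate_bilayer_trajectory(spec, depth_at=ramp)
        ts = md.thickness_timeseries(traj, p_mask, window=5.0, grid=grid)
        early = ts.thickness[:2]
        assert early[1] < early[0]

    def test_window_longer_than_trajectory_errors(self, flat_traj, p_mask, grid):
        with pytest.raises(ValueError, match="window"):
            md.thickness_timeseries(flat_traj, p_mask, window=1e6, grid=grid)


class TestLateralDensity:
    def test_static_atom_all_density_in_one_cell(self, grid):
        top = [md.AtomRecord("CA", "C", "ALA", 1, "A")]
        coords = np.full((5, 1, 3), 33.0)
        traj = md.Trajectory(topology=top, coordinates=coords,
                             times=np.arange(1.0, 6.0),
                             boxes=np.zeros((5, 3, 3)))
        dens = md.lateral_density(traj, md.SelectionMask(np.array([0])), grid)
        assert dens.density.max() == pytest.approx(1.0)
        assert (dens.density > 0).sum() == 1

    def test_normalization(self, flat_traj, p_mask, grid):
        dens = md.lateral_density(flat_traj, p_mask, grid)
        assert dens.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert (dens.density >= 0).all()

    def test_uniform_atoms_match_multinomial(self):
        grid = md.GridSpec2D(0, 120, 0, 120, spacing=12.0)  # 10 x 10 cells
        rng = np.random.default_rng(9)
        n_frames, n_atoms = 60, 400
        top = [md.AtomRecord("P", "P", "LIP", i + 1, "L") for i in range(n_atoms)]
        coords = np.zeros((n_frames, n_atoms, 3))
        coords[..., 0] = rng.uniform(grid.x_min, grid.x_max, (n_frames, n_atoms))
        coords[..., 1] = rng.uniform(grid.y_min, grid.y_max, (n_frames, n_atoms))
        traj = md.Trajectory(topology=top, coordinates=coords,
                             times=np.arange(1.0, n_frames + 1),
                             boxes=np.zeros((n_frames, 3, 3)))
        dens = md.lateral_density(traj, md.SelectionMask(np.arange(n_atoms)),
                                  grid)
        n_cells = grid.nx * grid.ny
        p = 1.0 / n_cells
        n_total = n_frames * n_atoms
        se = np.sqrt(p * (1 - p) / n_total)
        assert np.all(np.abs(dens.density - p) < 4 * se)

    def test_empty_mask_errors(self, flat_traj, grid):
        with pytest.raises(ValueError, match="empty"):
            md.lateral_density(flat_traj, md.SelectionMask(np.array([], int)),
                               grid)


class TestThinningWellFit:
    def _map_from_analytic(self, spec, grid):
        gx, gy = grid.meshgrid()
        t = md.analytic_thickness(spec, gx, gy)
        ones = np.ones_like(t, dtype=int)
        return md.ThicknessMap(grid=grid, mean_thickness=t, per_replicate=t[None],
                               n_samples=ones, defined_mask=ones.astype(bool),
                               replicate_n_samples=ones[None])

    def test_noiseless_map_recovered_exactly(self):
        spec = md.SyntheticBilayerSpec(T0=40, D=8, sigma_w=15)
        grid = md.GridSpec2D(0, spec.Lx, 0, spec.Ly, spacing=2.0)
        tmap = self._map_from_analytic(spec, grid)
        T0, D, sigma = md.fit_thinning_well(tmap, tuple(spec.well_center))
        assert T0 == pytest.approx(40.0, abs=1e-6)
        assert D == pytest.approx(8.0, abs=1e-6)
        assert sigma == pytest.approx(15.0, abs=1e-6)

    def test_flat_map_fits_zero_depth(self):
        spec = md.SyntheticBilayerSpec(T0=40, D=0.0, sigma_w=15)
        grid = md.GridSpec2D(0, spec.Lx, 0, spec.Ly, spacing=2.0)
        tmap = self._map_from_analytic(spec, grid)
        _, D, _ = md.fit_thinning_well(tmap, tuple(spec.well_center))
        assert D < 0.01

    def test_results_object_reports_uncertainties_and_summary(self):
        spec = md.SyntheticBilayerSpec(T0=40, D=8, sigma_w=15)
        grid = md.GridSpec2D(0, spec.Lx, 0, spec.Ly, spacing=2.0)
        tmap = self._map_from_analytic(spec, grid)
        res = md.ThinningWellModel(tmap, tuple(spec.well_center)).fit()
        assert res.resid_rms == pytest.approx(0.0, abs=1e-6)
        text = res.summary()
        assert "T0" in text and "sigma" in text
        assert len(res.bse) == 3

    def test_too_few_cells_rejected(self):
        grid = md.GridSpec2D(0, 10, 0, 10, spacing=2.0)
        t = np.full((grid.nx, grid.ny), np.nan)
        t[0, 0] = 40.0
        defined = ~np.isnan(t)
        tmap = md.ThicknessMap(grid=grid, mean_thickness=t, per_replicate=t[None],
                               n_samples=defined.astype(int),
                               defined_mask=defined,
                               replicate_n_samples=defined.astype(int)[None])
        with pytest.raises(ValueError, match="20"):
            md.ThinningWellModel(tmap, (5, 5))


class TestMapOutput:
    def test_tsv_and_sidecar(self, tmp_path, flat_traj, p_mask, grid):
        import pandas as pd
        tmap = md.thickness_map(flat_traj, p_mask, grid)
        path = tmp_path / "map.tsv"
        md.write_map_tsv(str(path), tmap, sidecar={"seed": 11})
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["x_center", "y_center", "value", "n_samples"]
        assert len(df) == grid.nx * grid.ny
        import json
        meta = json.loads((tmp_path / "map.tsv.json").read_text())
        assert meta["grid"]["spacing"] == grid.spacing
        assert meta["seed"] == 11
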