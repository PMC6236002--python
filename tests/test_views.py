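import numpy as np
import pytest

from spikescape import binning, views


def _grid(rates, pop="EX", dl=0.5, L=4.0, dt=1.0, T=None):
    T = T if T is not None else rates.shape[2] * dt
    return binning.BinnedRates(pop, rates, dt, dl, L, T)


@pytest.fixture
def sparse_binned():
    rates = np.zeros((8, 8, 10))
    rates[2, 5, 3] = 1000.0
    rates[6, 1, 3] = 2000.0
    return {"EX": _grid(rates)}


class TestColormap:
    def test_shape_and_anchors(self):
        lut = views.colormap()
        assert lut.shape == (256, 3)
        np.testing.assert_array_equal(lut[0], [0, 0, 0])
        np.testing.assert_array_equal(lut[-1], [255, 255, 255])

    def test_monotone_lightness(self):
        lut = views.colormap().astype(int)
        assert np.all(np.diff(lut.sum(axis=1)) >= 0)

    def test_lookup_monotone_in_value(self):
        frame = views.FrameImage("EX", 0, np.linspace(0, 100, 50)[None, :], 100.0)
        idx = frame.lookup_indices()[0]
        assert np.all(np.diff(idx) >= 0)


class TestView1:
    def test_zero_slice_is_black(self, sparse_binned):
        frame = views.view1_frame(sparse_binned["EX"], 0)
        assert np.all(frame.to_rgb() == 0)

    def test_single_pixel_placement(self, sparse_binned):
        frame = views.view1_frame(sparse_binned["EX"], 3)
        idx = frame.lookup_indices()
        nz = {tuple(p) for p in np.argwhere(idx > 0)}
        assert nz == {(2, 5), (6, 1)}

    def test_max_value_hits_top_entry(self, sparse_binned):
        frame = views.view1_frame(sparse_binned["EX"], 3)
        assert frame.lookup_indices().max() == 255

    def test_out_of_range_k(self, sparse_binned):
        with pytest.raises(IndexError):
            views.view1_frame(sparse_binned["EX"], 10)


class TestView2:
    def test_zero_bins_emit_no_cube(self, sparse_binned):
        layout = views.view2_layout(sparse_binned, 0)
        assert len(layout.centers["EX"]) == 0

    def test_volume_scaling(self, sparse_binned):
        layout = views.view2_layout(sparse_binned, 3)
        edges = dict(zip(map(tuple, layout.centers["EX"]), layout.edges["EX"]))
        vals = dict(zip(map(tuple, layout.centers["EX"]), layout.values["EX"]))
        big = max(edges.values())
        small = min(edges.values())
        assert big == pytest.approx(0.5)  # max edge = bin width
        assert big / small == pytest.approx(2 ** (1 / 3))
        assert max(vals.values()) / min(vals.values()) == pytest.approx(2.0)

    def test_linear_scaling(self, sparse_binned):
        layout = views.view2_layout(sparse_binned, 3, scale_mode="linear")
        e = np.sort(layout.edges["EX"])
        assert e[1] / e[0] == pytest.approx(2.0)

    def test_one_hot_projection(self):
        rates = np.zeros((8, 8, 5))
        rates[3, 6, 2] = 500.0
        layout = views.view2_layout({"EX": _grid(rates)}, 2)
        x_prof, y_prof = layout.projections["EX"]
        assert x_prof[3] == 500.0 and x_prof.sum() == 500.0
        assert y_prof[6] == 500.0 and y_prof.sum() == 500.0

    def test_consistency_with_view1(self, sparse_binned):
        frame = views.view1_frame(sparse_binned["EX"], 3)
        layout = views.view2_layout(sparse_binned, 3)
        from_frame = {tuple(p) for p in np.argwhere(frame.values > 0)}
        g = sparse_binned["EX"]
        from_cubes = {
            (int((cx + g.L / 2) / g.dl_bin), int((cy + g.L / 2) / g.dl_bin))
            for cx, cy in layout.centers["EX"]
        }
        assert from_frame == from_cubes


class TestView3:
    def test_single_population_fraction_one(self, sparse_binned):
        series = views.view3_series(sparse_binned, 3, 2)
        nz = series.nu_k > 0
        np.testing.assert_allclose(series.fractions["EX"][nz], 1.0)

    def test_window_clipped_at_start(self, sparse_binned):
        series = views.view3_series(sparse_binned, 1, 5)
        assert series.k_indices[0] == 0
        assert series.k_indices[-1] == 6

    def test_hiding_population_keeps_total(self):
        rates = np.zeros((8, 8, 10))
        rates[0, 0, :] = 640.0
        grids = {"EX": _grid(rates), "STIM": _grid(rates.copy(), "STIM")}
        full = views.view3_series(grids, 5, 4)
        hidden = views.view3_series(grids, 5, 4, hidden=("STIM",))
        np.testing.assert_allclose(hidden.nu_k, full.nu_k)
        assert "STIM" not in hidden.fractions
        np.testing.assert_allclose(hidden.fractions["EX"], 0.5)


class TestView4:
    def _radial_volume(self, A=1000.0):
        # radial field A exp(-d^2) over (x, y, lag), d in cell units
        n = 21
        ax = np.arange(n) - n // 2
        X, Y, K = np.meshgrid(ax, ax, ax, indexing="ij")
        d2 = (X**2 + Y**2 + K**2) / 16.0
        return A * np.exp(-d2)

    def test_constant_below_threshold_empty(self):
        rates = np.full((8, 8, 10), 50.0)
        mesh = views.view4_isosurface(_grid(rates), 5, 4, iso_value=100.0)
        assert mesh.is_empty

    def test_radial_iso_surface_radius(self):
        vol = self._radial_volume()
        g = binning.BinnedRates("EX", vol, 1.0, 1.0, 21.0, 21.0)
        iso = 300.0
        mesh = views.view4_isosurface(g, 10, 10, iso_value=iso)
        # analytic iso-radius of A exp(-d^2/16) = iso
        r_expected = np.sqrt(16.0 * np.log(1000.0 / iso))
        center = np.array([0.0, 0.0, 0.0])
        d = np.linalg.norm(mesh.vertices - center, axis=1)
        cell_diag = np.sqrt(3.0)
        assert abs(d.mean() - r_expected) < cell_diag

    def test_monotone_shrinkage(self):
        vol = self._radial_volume()
        g = binning.BinnedRates("EX", vol, 1.0, 1.0, 21.0, 21.0)
        vols = [views.enclosed_volume(g, iso, 10, 10)
                for iso in (100.0, 195.0, 360.0, 900.0)]
        assert vols == sorted(vols, reverse=True)
        assert views.view4_isosurface(g, 10, 10, 2000.0).is_empty

    def test_watertight_interior_surface(self):
        vol = self._radial_volume()
        g = binning.BinnedRates("EX", vol, 1.0, 1.0, 21.0, 21.0)
        mesh = views.view4_isosurface(g, 10, 10, iso_value=500.0)
        edges = {}
        for tri in mesh.faces:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                e = tuple(sorted((tri[a], tri[b])))
                edges[e] = edges.get(e, 0) + 1
        assert set(edges.values()) == {2}

    def test_tie_values_are_nudged(self):
        rates = np.zeros((8, 8, 10))
        rates[3:5, 3:5, 4:6] = 100.0
        mesh = views.view4_isosurface(_grid(rates), 5, 4, iso_value=100.0)
        assert not mesh.is_empty


class TestRawFrame:
    def _data(self):
        ids = np.array([1, 2, 3, 4, 5, 6])
        x = np.linspace(-1, 1, 6)
        y = np.zeros(6)
        sp_ids = np.array([1, 2, 3, 4, 5, 6, 1])
        times = np.array([0.31, 0.32, 0.35, 0.39, 0.30, 0.33, 0.51])
        return ids, x, y, sp_ids, times

    def test_marker_count_matches_step(self):
        ids, x, y, sp_ids, times = self._data()
        markers = views.raw_frame(sp_ids, times, ids, x, y, "EX", k=3, dt=0.1)
        assert len(markers["ids"]) == 6
        markers5 = views.raw_frame(sp_ids, times, ids, x, y, "EX", k=5, dt=0.1)
        assert len(markers5["ids"]) == 1

    def test_dilution_keeps_every_nth_unit(self):
        ids, x, y, sp_ids, times = self._data()
        markers = views.raw_frame(sp_ids, times, ids, x, y, "EX", k=3, dt=0.1,
                                  dilution=5)
        assert set(markers["ids"].tolist()) == {1, 6}

    def test_empty_step(self):
        ids, x, y, sp_ids, times = self._data()
        markers = views.raw_frame(sp_ids, times, ids, x, y, "EX", k=9, dt=0.1)
        assert len(markers["ids"]) == 0


class TestExports:
    def test_png_svg_obj_written(self, tmp_path, sparse_binned):
        frame = views.view1_frame(sparse_binned["EX"], 3)
        views.save_frame_png(frame, tmp_path / "frame.png")
        views.save_frame_svg(frame, tmp_path / "frame.svg")
        vol = np.full((8, 8, 10), 50.0)
        vol[3:5, 3:5, 3:6] = 500.0
        mesh = views.view4_isosurface(_grid(vol), 5, 4, iso_value=100.0)
        views.write_obj(mesh, tmp_path / "mesh.obj")
        text = (tmp_path / "mesh.obj").read_text()
        assert text.count("\nv ") + text.startswith("v ") == len(mesh.vertices)
        assert (tmp_path / "frame.png").stat().st_size > 0
        assert (tmp_path / "frame.svg").stat().st_size > 0
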