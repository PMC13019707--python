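"""Scan-export ingestion: parsing, gridding, cropping, patching, fixtures."""

import numpy as np
import pandas as pd
import pytest

from vibroelast import (
    GridSpec,
    HarmonicSource,
    ViscoelasticMedium,
    crop_boundaries,
    extract_patches,
    ingest_fixture_dir,
    interpolate_to_grid,
    read_scan_export,
    simulate_wavefield,
    write_fixture,
    write_scan_export,
)
from vibroelast.errors import (
    EmptyInputError,
    FormatError,
    GeometryError,
    InterpolationError,
)
from vibroelast.sldv_io import FULL_SCAN_GRID, add_complex_noise
from vibroelast.wavesim import WavefieldGrid


def _write(tmp_path, text, name="scan.txt"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadScanExport:
    def test_well_formed_file(self, tmp_path):
        path = _write(
            tmp_path,
            "# point_id x y v_re v_im\n"
            "1 0.0 0.0 1.0 -0.5\n"
            "2 0.001 0.0 0.5 0.25\n"
            "3 0.0 0.001 -0.1 0.9\n",
        )
        table = read_scan_export(path)
        assert len(table) == 3
        assert list(table.columns) == ["point_id", "x", "y", "v_re", "v_im"]

    def test_round_trip(self, tmp_path, rng):
        table = pd.DataFrame(
            {
                "point_id": np.arange(1, 21),
                "x": rng.uniform(0, 0.01, 20),
                "y": rng.uniform(0, 0.01, 20),
                "v_re": rng.standard_normal(20),
                "v_im": rng.standard_normal(20),
            }
        )
        path = tmp_path / "rt.txt"
        write_scan_export(path, table)
        back = read_scan_export(path)
        for col in ("x", "y", "v_re", "v_im"):
            np.testing.assert_allclose(back[col], table[col], rtol=1e-9)

    def test_non_numeric_velocity_names_line(self, tmp_path):
        path = _write(
            tmp_path, "# h\n1 0.0 0.0 1.0 0.0\n2 0.0 0.001 oops 0.0\n"
        )
        with pytest.raises(FormatError, match=":3"):
            read_scan_export(path)

    def test_missing_column_rejected(self, tmp_path):
        path = _write(tmp_path, "# h\n1 0.0 0.0 1.0\n")
        with pytest.raises(FormatError, match="columns"):
            read_scan_export(path)

    def test_empty_file_rejected(self, tmp_path):
        path = _write(tmp_path, "# only a header\n")
        with pytest.raises(EmptyInputError):
            read_scan_export(path)

    def test_duplicate_point_id_rejected(self, tmp_path):
        path = _write(tmp_path, "# h\n1 0 0 1 0\n1 0 0.001 1 0\n2 0.001 0 1 0\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_scan_export(path)


class TestInterpolateToGrid:
    def test_identity_on_grid_points(self, rng):
        grid = GridSpec(9, 7, pitch=1e-3)
        X, Y = grid.meshgrid()
        v = rng.standard_normal(X.shape) + 1j * rng.standard_normal(X.shape)
        table = pd.DataFrame(
            {
                "point_id": np.arange(v.size),
                "x": X.ravel(),
                "y": Y.ravel(),
                "v_re": v.real.ravel(),
                "v_im": v.imag.ravel(),
            }
        )
        out = interpolate_to_grid(table, grid)
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_planar_field_reproduced_exactly(self, rng):
        grid = GridSpec(8, 8, pitch=1e-3)
        pts = rng.uniform(-2e-3, 9e-3, size=(200, 2))
        a, b, c = 0.3, 40.0, -25.0
        v = a + b * pts[:, 0] + c * pts[:, 1]
        table = pd.DataFrame(
            {"point_id": np.arange(200), "x": pts[:, 0], "y": pts[:, 1],
             "v_re": v, "v_im": 2 * v}
        )
        out = interpolate_to_grid(table, grid)
        X, Y = grid.meshgrid()
        np.testing.assert_allclose(out.values.real, a + b * X + c * Y, atol=1e-9)
        np.testing.assert_allclose(out.values.imag, 2 * (a + b * X + c * Y), atol=1e-9)

    def test_scattered_resampling_of_simulated_field(self, rng):
        grid = GridSpec(40, 30, pitch=0.5e-3)
        medium = ViscoelasticMedium(3e3)
        source = HarmonicSource(grid.center[0], grid.center[1] - 0.030)
        direct = simulate_wavefield(medium, source, grid)
        # scattered interior points plus a sampled perimeter, as a scan
        # covering the full region would provide
        pts = rng.uniform(
            [grid.x[0], grid.y[0]], [grid.x[-1], grid.y[-1]], size=(4000, 2)
        )
        ex = np.linspace(grid.x[0], grid.x[-1], 80)
        ey = np.linspace(grid.y[0], grid.y[-1], 80)
        perimeter = np.vstack(
            [np.column_stack([ex, np.full_like(ex, grid.y[0])]),
             np.column_stack([ex, np.full_like(ex, grid.y[-1])]),
             np.column_stack([np.full_like(ey, grid.x[0]), ey]),
             np.column_stack([np.full_like(ey, grid.x[-1]), ey])]
        )
        pts = np.vstack([pts, perimeter])
        k = 2 * np.pi * 350.0 * np.sqrt(1000.0 / medium.complex_shear_modulus)
        r = np.hypot(pts[:, 0] - source.x, pts[:, 1] - source.y)
        from scipy.special import hankel2

        v = hankel2(0, k * r)
        table = pd.DataFrame(
            {"point_id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1],
             "v_re": v.real, "v_im": v.imag}
        )
        out = interpolate_to_grid(table, grid)
        rel_l2 = np.linalg.norm(out.values - direct.values) / np.linalg.norm(
            direct.values
        )
        assert rel_l2 < 0.05

    def test_collinear_points_rejected(self):
        table = pd.DataFrame(
            {"point_id": range(5), "x": np.linspace(0, 1e-2, 5),
             "y": np.zeros(5), "v_re": np.ones(5), "v_im": np.zeros(5)}
        )
        with pytest.raises(InterpolationError):
            interpolate_to_grid(table, GridSpec(3, 3, pitch=1e-3))

    def test_outside_hull_errors_unless_filled(self, rng):
        grid = GridSpec(5, 5, pitch=1e-3)
        pts = rng.uniform(1e-3, 3e-3, size=(50, 2))  # hull smaller than grid
        table = pd.DataFrame(
            {"point_id": range(50), "x": pts[:, 0], "y": pts[:, 1],
             "v_re": np.ones(50), "v_im": np.zeros(50)}
        )
        with pytest.raises(InterpolationError, match="convex hull"):
            interpolate_to_grid(table, grid)
        out = interpolate_to_grid(table, grid, fill_value=0.0)
        assert np.all(np.isfinite(out.values))


class TestCropBoundaries:
    def _field(self, n_rows=79, n_cols=52):
        grid = GridSpec(n_rows, n_cols)
        values = (np.arange(n_rows * n_cols) + 0j).reshape(n_rows, n_cols)
        return WavefieldGrid(values, grid)

    def test_ledger_geometry(self):
        out = crop_boundaries(self._field(), 4)
        assert out.values.shape == (71, 44)
        np.testing.assert_array_equal(
            out.values, self._field().values[4:-4, 4:-4]
        )

    def test_zero_margin_is_identity(self):
        field = self._field(10, 8)
        out = crop_boundaries(field, 0)
        np.testing.assert_array_equal(out.values, field.values)

    def test_margin_too_large_rejected(self):
        with pytest.raises(GeometryError):
            crop_boundaries(self._field(), 40)
        with pytest.raises(GeometryError):
            crop_boundaries(self._field(), -1)


class TestExtractPatches:
    def _cropped(self):
        grid = GridSpec(71, 44)
        rng = np.random.default_rng(0)
        v = rng.standard_normal((71, 44)) + 1j * rng.standard_normal((71, 44))
        return WavefieldGrid(v, grid)

    def test_four_column_strips(self):
        field = self._cropped()
        patches = extract_patches(field, label=1, normalize=False)
        assert len(patches) == 4
        for p, c0 in zip(patches, (0, 11, 22, 33)):
            assert p.values.shape == (71, 11, 2)
            np.testing.assert_array_equal(
                p.values[..., 0], field.values.real[:, c0:c0 + 11]
            )
            assert p.label == 1

    def test_partition_reconstructs_field(self):
        field = self._cropped()
        patches = extract_patches(field, normalize=False)
        rebuilt = np.concatenate(
            [p.values[..., 0] + 1j * p.values[..., 1] for p in patches], axis=1
        )
        np.testing.assert_allclose(rebuilt, field.values)

    def test_too_small_fields_fail_loudly(self):
        with pytest.raises(GeometryError):
            extract_patches(WavefieldGrid(np.zeros((70, 44)), GridSpec(70, 44)))
        with pytest.raises(GeometryError):
            extract_patches(WavefieldGrid(np.zeros((71, 10)), GridSpec(71, 10)))


class TestFixtures:
    def test_thirteen_images_yield_52_patches_per_class(self, tmp_path):
        write_fixture(tmp_path, (1.0, 5.0), n_images_per_class=13,
                      snr_db=None, seed=11)
        ds = ingest_fixture_dir(tmp_path)
        assert len(ds) == 104
        assert ds.class_counts().tolist() == [52, 52]
        assert all(s.values.shape == (71, 11, 2) for s in ds)

    def test_noiseless_fixture_matches_direct_simulation(self, tmp_path):
        paths = write_fixture(tmp_path, (2.0,), n_images_per_class=1,
                              snr_db=None, seed=3)
        ds = ingest_fixture_dir(tmp_path)
        table = read_scan_export(paths[0])
        field = interpolate_to_grid(table, FULL_SCAN_GRID)
        cropped = crop_boundaries(field, 4)
        direct = extract_patches(cropped, label=0, image_id=paths[0].stem)
        for a, b in zip(ds, direct):
            np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_noise_snr_calibration(self, rng):
        # ≥10⁴ points: empirical SNR within 1 dB of the 20 dB target
        values = np.exp(1j * rng.uniform(0, 2 * np.pi, 120 * 120))
        noisy = add_complex_noise(values, 20.0, rng)
        noise_power = np.mean(np.abs(noisy - values) ** 2)
        signal_power = np.mean(np.abs(values) ** 2)
        snr_db = 10 * np.log10(signal_power / noise_power)
        assert snr_db == pytest.approx(20.0, abs=1.0)

    def test_fixture_deterministic_under_seed(self, tmp_path):
        a = write_fixture(tmp_path / "a", (1.0,), n_images_per_class=2,
                          snr_db=20.0, seed=9)
        b = write_fixture(tmp_path / "b", (1.0,), n_images_per_class=2,
                          snr_db=20.0, seed=9)
        for pa, pb in zip(a, b):
            assert pa.read_text() == pb.read_text()
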