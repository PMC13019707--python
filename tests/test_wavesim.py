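"""Wavefield-simulation physics: dispersion, attenuation, quadrature, sampling."""

import numpy as np
import pytest
from scipy.special import hankel2
from scipy.stats import chisquare

from vibroelast import (
    GridSpec,
    HarmonicSource,
    SourcePlacementSpec,
    ViscoelasticMedium,
    complex_wavenumber,
    estimate_wavelength,
    greens_field,
    make_synthetic_dataset,
    sample_patch,
    simulate_wavefield,
    wavelength,
)
from vibroelast.errors import (
    ConfigError,
    GeometryError,
    InvalidParameterError,
    LabelError,
)
from vibroelast.wavesim import dominant_spatial_frequency


def oracle_wavenumber(mu, eta, rho, f):
    """Independent complex-arithmetic oracle: k = ω √(ρ/μ′(1+iη))."""
    return 2 * np.pi * f * (rho / (mu * (1 + 1j * eta))) ** 0.5


class TestComplexWavenumber:
    def test_lossless_limit_is_real(self):
        k = complex_wavenumber(ViscoelasticMedium(1e3, 0.0, 1000.0), 350.0)
        assert k.imag == 0.0
        assert k.real == pytest.approx(2199.115, abs=1e-3)
        assert 2 * np.pi / k.real == pytest.approx(2.857e-3, rel=1e-3)

    @pytest.mark.parametrize(
        "mu_kpa, expected_k, expected_lam_mm",
        [
            (1.0, 2180.858702 - 162.654560j, 2.8811),
            (5.0, 975.309661 - 72.741331j, 6.4422),
        ],
    )
    def test_lossy_values_match_oracle(self, mu_kpa, expected_k, expected_lam_mm):
        medium = ViscoelasticMedium(mu_kpa * 1e3, 0.15, 1000.0)
        k = complex_wavenumber(medium, 350.0)
        assert k == pytest.approx(expected_k, rel=1e-6)
        assert wavelength(medium, 350.0) * 1e3 == pytest.approx(
            expected_lam_mm, abs=1e-3
        )

    @pytest.mark.parametrize("mu_kpa", [1, 2, 3, 4, 5])
    def test_all_classes_match_oracle_tightly(self, mu_kpa):
        k = complex_wavenumber(ViscoelasticMedium(mu_kpa * 1e3), 350.0)
        k_oracle = oracle_wavenumber(mu_kpa * 1e3, 0.15, 1000.0, 350.0)
        assert abs(k - k_oracle) / abs(k_oracle) < 1e-10
        assert k.real > 0 and k.imag <= 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ViscoelasticMedium(-1.0)
        with pytest.raises(InvalidParameterError):
            ViscoelasticMedium(1e3, density=0.0)
        with pytest.raises(InvalidParameterError):
            complex_wavenumber(ViscoelasticMedium(1e3), 0.0)


class TestGreensField:
    k = complex_wavenumber(ViscoelasticMedium(1e3), 350.0)

    def test_amplitude_decays_with_distance(self):
        assert abs(greens_field(self.k, 10e-3)) > abs(greens_field(self.k, 20e-3))
        r = np.linspace(2e-3, 40e-3, 200)
        mags = np.abs(greens_field(self.k, r))
        assert np.all(np.diff(mags) < 0)

    def test_far_field_phase_advances_by_wavelength(self):
        lam = 2 * np.pi / self.k.real
        r = 20e-3
        dphi = np.angle(greens_field(self.k, r + lam)) - np.angle(
            greens_field(self.k, r)
        )
        assert dphi % (2 * np.pi) == pytest.approx(0.0, abs=0.05) or (
            dphi % (2 * np.pi)
        ) == pytest.approx(2 * np.pi, abs=0.05)

    @pytest.mark.parametrize("r_mm", [5.0, 10.0, 20.0])
    def test_matches_special_function_oracle(self, r_mm):
        r = r_mm * 1e-3
        expected = hankel2(0, self.k * r)
        assert abs(greens_field(self.k, r) - expected) <= 1e-10 * abs(expected)

    def test_singularity_rejected(self):
        with pytest.raises(GeometryError):
            greens_field(self.k, 0.0)
        with pytest.raises(GeometryError):
            greens_field(self.k, -1e-3)


class TestSimulateWavefield:
    medium = ViscoelasticMedium(1e3)

    def test_output_shape_and_finiteness(self, patch_grid):
        source = HarmonicSource(x=-0.02, y=0.01)
        field = simulate_wavefield(self.medium, source, patch_grid)
        assert field.values.shape == (71, 11)
        assert np.all(np.isfinite(field.values))

    def test_linearity_in_amplitude(self, patch_grid):
        s1 = HarmonicSource(-0.02, 0.01, amplitude=1.0)
        s2 = HarmonicSource(-0.02, 0.01, amplitude=2.0)
        f1 = simulate_wavefield(self.medium, s1, patch_grid)
        f2 = simulate_wavefield(self.medium, s2, patch_grid)
        np.testing.assert_allclose(f2.values, 2.0 * f1.values, rtol=1e-12)

    def test_source_inside_footprint_rejected_without_clamp(self, patch_grid):
        cx, cy = patch_grid.center
        inside = HarmonicSource(cx, cy)
        with pytest.raises(GeometryError):
            simulate_wavefield(self.medium, inside, patch_grid)
        clamped = simulate_wavefield(
            self.medium, inside, patch_grid, min_distance=patch_grid.pitch
        )
        assert np.all(np.isfinite(clamped.values))

    def test_zero_crossing_spacing_near_half_wavelength(self, patch_grid):
        # source on the long-axis extension: propagation aligned with rows
        cx, cy = patch_grid.center
        source = HarmonicSource(cx, cy - 0.025)
        field = simulate_wavefield(self.medium, source, patch_grid)
        col = field.values[:, 5].real
        crossings = np.flatnonzero(np.diff(np.signbit(col)))
        spacing = np.diff(crossings).mean() * patch_grid.pitch
        lam = wavelength(self.medium, 350.0)
        assert spacing == pytest.approx(lam / 2, abs=patch_grid.pitch)

    def test_quadrature_channel_is_90_degrees_late(self, patch_grid):
        source = HarmonicSource(-0.02, 0.01)
        field = simulate_wavefield(self.medium, source, patch_grid)
        shifted = field.values * np.exp(-1j * np.pi / 2)
        np.testing.assert_allclose(field.values.imag, shifted.real, rtol=1e-12)


class TestDispersion:
    @pytest.mark.parametrize("mu_kpa", [1, 2, 3, 4, 5])
    def test_dominant_spatial_frequency_matches_re_k(self, mu_kpa):
        """FFT peak of a clean radial profile sits within one bin of Re(k)/2π."""
        medium = ViscoelasticMedium(mu_kpa * 1e3)
        grid = GridSpec(71, 11)
        cx, cy = grid.center
        source = HarmonicSource(cx, cy - 0.030)
        field = simulate_wavefield(medium, source, grid)
        profile = field.values[:, 5]
        f_est = dominant_spatial_frequency(profile, grid.pitch)
        f_true = complex_wavenumber(medium, 350.0).real / (2 * np.pi)
        bin_width = 1.0 / ((grid.n_rows - 1) * grid.pitch)
        assert abs(f_est - f_true) <= bin_width

    @pytest.mark.parametrize("mu_kpa", [1, 3, 5])
    def test_radial_amplitude_monotone_under_loss(self, mu_kpa):
        medium = ViscoelasticMedium(mu_kpa * 1e3, 0.15)
        grid = GridSpec(71, 11)
        cx, cy = grid.center
        source = HarmonicSource(cx, cy - 0.030)
        field = simulate_wavefield(medium, source, grid)
        r = np.abs(grid.y - source.y)
        order = np.argsort(r)
        mags = np.abs(field.values[:, 5])[order]
        assert np.all(np.diff(mags) <= 0)


class TestSamplePatch:
    def test_same_seed_bit_identical(self):
        a = sample_patch(1.0, seed=7)
        b = sample_patch(1.0, seed=7)
        assert np.array_equal(a.values, b.values)
        assert a.meta["source_x"] == b.meta["source_x"]

    def test_shape_label_and_normalization(self):
        p = sample_patch(5.0, seed=3, classes_kpa=(1.0, 5.0))
        assert p.values.shape == (71, 11, 2)
        assert p.label == 1
        assert np.max(np.abs(p.values)) == pytest.approx(1.0)

    def test_class_outside_configured_set_rejected(self):
        with pytest.raises(LabelError):
            sample_patch(2.5, seed=0)

    def test_source_angles_uniform(self):
        angles = np.array(
            [sample_patch(1.0, seed=s).meta["source_angle"] for s in range(1000)]
        )
        counts, _ = np.histogram(angles, bins=10, range=(0, 2 * np.pi))
        assert chisquare(counts).pvalue > 0.01

    def test_wavelength_statistic_separates_extreme_classes(self):
        lam1 = [
            estimate_wavelength(sample_patch(1.0, seed=s).values, 0.5e-3)
            for s in range(50)
        ]
        lam5 = [
            estimate_wavelength(sample_patch(5.0, seed=1000 + s).values, 0.5e-3)
            for s in range(50)
        ]
        assert max(lam1) < min(lam5)  # zero overlap

    def test_annulus_too_small_for_grid_rejected(self, patch_grid):
        tight = SourcePlacementSpec(r_min=0.005, r_max=0.010)
        with pytest.raises(GeometryError):
            sample_patch(1.0, placement=tight, grid=patch_grid, seed=0)


class TestMakeSyntheticDataset:
    def test_balanced_counts_and_labels(self):
        ds = make_synthetic_dataset((1.0, 5.0), 52, seed=5)
        assert len(ds) == 104
        assert ds.class_counts().tolist() == [52, 52]
        assert ds.class_names == ["1kPa", "5kPa"]

    def test_single_sample_dataset(self):
        ds = make_synthetic_dataset((1.0,), 1, seed=0)
        assert len(ds) == 1 and ds[0].label == 0

    def test_duplicate_classes_rejected(self):
        with pytest.raises(ConfigError):
            make_synthetic_dataset((1.0, 1.0), 2, seed=0)

    def test_labels_ascend_with_stiffness(self):
        ds = make_synthetic_dataset((5.0, 1.0, 3.0), 2, seed=0)
        assert ds.class_names == ["1kPa", "3kPa", "5kPa"]
        for s in ds:
            assert ds.class_names[s.label] == f"{s.meta['mu_kpa']:g}kPa"

    def test_different_seeds_differ_but_stay_balanced(self):
        a = make_synthetic_dataset((1.0, 5.0), 3, seed=1)
        b = make_synthetic_dataset((1.0, 5.0), 3, seed=2)
        assert not np.array_equal(a[0].values, b[0].values)
        assert a.class_counts().tolist() == b.class_counts().tolist()
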