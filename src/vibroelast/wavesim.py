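"""Analytical harmonic shear-wavefield simulation for viscoelastic media.

A homogeneous, isotropic viscoelastic medium with complex shear modulus
μ* = μ′(1 + iη) supports shear waves with complex wavenumber

    k = ω √(ρ / μ*),      ω = 2πf,

whose real part sets the wavelength (λ = 2π / Re k) and whose imaginary part
the attenuation.  The surface response to a harmonic point source driven
through the sample thickness is modelled as an outgoing cylindrical wave:
the zeroth-order Hankel function H0⁽²⁾(kr) under the e^{+iωt} time
convention, so that Im(k) ≤ 0 (principal square root) produces amplitude
decay with distance.

Training examples are 71×11 patches of such fields with the point source
placed uniformly at random inside an annulus around the patch center: the
wave pattern changes with source position while the material class — encoded
in the wavelength and attenuation — does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import hankel2

from .errors import ConfigError, GeometryError, InvalidParameterError, LabelError
from .patches import PatchSample, LabeledDataset, patch_from_complex

DEFAULT_FREQUENCY_HZ = 350.0
DEFAULT_DENSITY = 1000.0  # kg/m³, soft-tissue-like
DEFAULT_LOSS_RATIO = 0.15
DEFAULT_PITCH_M = 0.5e-3

#: stiffness classes in kPa: binary task uses (1, 5); multiclass all five
BINARY_CLASSES_KPA = (1.0, 5.0)
MULTICLASS_CLASSES_KPA = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class ViscoelasticMedium:
    """Material parameters of a homogeneous isotropic viscoelastic medium.

    Parameters
    ----------
    mu_storage : float
        Shear storage modulus μ′ in Pa.
    loss_ratio : float
        Ratio of shear loss to shear storage modulus, η = μ″/μ′.
    density : float
        Mass density ρ in kg/m³.
    """

    mu_storage: float
    loss_ratio: float = DEFAULT_LOSS_RATIO
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if self.mu_storage <= 0:
            raise InvalidParameterError(f"mu_storage must be > 0, got {self.mu_storage}")
        if self.loss_ratio < 0:
            raise InvalidParameterError(f"loss_ratio must be ≥ 0, got {self.loss_ratio}")
        if self.density <= 0:
            raise InvalidParameterError(f"density must be > 0, got {self.density}")

    @property
    def complex_shear_modulus(self) -> complex:
        """μ* = μ′ (1 + iη) in Pa."""
        return self.mu_storage * (1.0 + 1j * self.loss_ratio)


@dataclass(frozen=True)
class HarmonicSource:
    """A harmonic point source at (x, y) in the grid's physical frame."""

    x: float
    y: float
    frequency: float = DEFAULT_FREQUENCY_HZ
    amplitude: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InvalidParameterError(f"frequency must be > 0, got {self.frequency}")


@dataclass(frozen=True)
class GridSpec:
    """Regular scan grid: n_rows × n_cols points at a physical pitch.

    Row index increases with y, column index with x; ``origin`` is the
    physical coordinate of the point at row 0, column 0.
    """

    n_rows: int
    n_cols: int
    pitch: float = DEFAULT_PITCH_M
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("grid must have at least one row and column")
        if self.pitch <= 0:
            raise InvalidParameterError(f"pitch must be > 0, got {self.pitch}")

    @property
    def x(self) -> np.ndarray:
        """Physical x coordinate of each column."""
        return self.origin[0] + self.pitch * np.arange(self.n_cols)

    @property
    def y(self) -> np.ndarray:
        """Physical y coordinate of each row."""
        return self.origin[1] + self.pitch * np.arange(self.n_rows)

    @property
    def center(self) -> tuple[float, float]:
        return (
            self.origin[0] + self.pitch * (self.n_cols - 1) / 2.0,
            self.origin[1] + self.pitch * (self.n_rows - 1) / 2.0,
        )

    @property
    def half_diagonal(self) -> float:
        """Distance from the grid center to a corner point."""
        return 0.5 * self.pitch * np.hypot(self.n_rows - 1, self.n_cols - 1)

    def contains(self, x: float, y: float) -> bool:
        """Whether (x, y) lies inside the grid's bounding box."""
        return (
            self.x[0] <= x <= self.x[-1] and self.y[0] <= y <= self.y[-1]
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols)."""
        return np.meshgrid(self.x, self.y)


@dataclass
class WavefieldGrid:
    """Complex-valued surface velocity on a regular grid at one frequency."""

    values: np.ndarray
    grid: GridSpec
    frequency: float = DEFAULT_FREQUENCY_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        expected = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise GeometryError(
                f"values shape {self.values.shape} does not match grid {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("wavefield values must be finite everywhere")


@dataclass(frozen=True)
class SourcePlacementSpec:
    """Annulus around the patch center in which the point source is drawn.

    The radii must exceed the patch's half-diagonal so the source (and its
    singularity) never falls inside the patch footprint.
    """

    r_min: float = 0.020
    r_max: float = 0.040

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise InvalidParameterError(
                f"need r_max > r_min > 0, got r_min={self.r_min}, r_max={self.r_max}"
            )

    def validate_for_grid(self, grid: GridSpec) -> None:
        if self.r_min <= grid.half_diagonal:
            raise GeometryError(
                f"annulus r_min={self.r_min} must exceed the patch half-diagonal "
                f"{grid.half_diagonal:.4f} m so the source stays outside the patch"
            )

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        """Uniform draw over the annulus area; returns (radius, angle)."""
        u = rng.uniform()
        radius = float(np.sqrt(self.r_min**2 + u * (self.r_max**2 - self.r_min**2)))
        angle = float(rng.uniform(0.0, 2.0 * np.pi))
        return radius, angle


def complex_wavenumber(medium: ViscoelasticMedium, frequency: float) -> complex:
    """Complex shear wavenumber k = ω √(ρ/μ*) in rad/m.

    The principal square root gives Re(k) > 0 and Im(k) ≤ 0; under the
    e^{+iωt} time convention the outgoing factor e^{-ikr} then decays with
    distance for any lossy medium.
    """
    if frequency <= 0:
        raise InvalidParameterError(f"frequency must be > 0, got {frequency}")
    omega = 2.0 * np.pi * frequency
    return omega * complex(np.sqrt(medium.density / medium.complex_shear_modulus))


def wavelength(medium: ViscoelasticMedium, frequency: float) -> float:
    """Shear wavelength λ = 2π / Re(k) in meters."""
    return 2.0 * np.pi / complex_wavenumber(medium, frequency).real


def greens_field(k: complex, r: np.ndarray | float) -> np.ndarray | complex:
    """Outgoing cylindrical wave H0⁽²⁾(kr) of a surface point source.

    Decays monotonically in r for Im(k) < 0 (attenuation plus geometric
    spreading); its far-field form is √(2/(πkr)) · e^{-i(kr - π/4)}.
    """
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr <= 0):
        raise GeometryError("greens_field requires r > 0 (source singularity)")
    out = hankel2(0, k * r_arr)
    if np.isscalar(r):
        return complex(out)
    return out


def simulate_wavefield(
    medium: ViscoelasticMedium,
    source: HarmonicSource,
    grid: GridSpec,
    min_distance: float | None = None,
) -> WavefieldGrid:
    """Evaluate the point-source field over every grid point.

    The source must lie outside the grid's bounding box unless
    ``min_distance`` is given, in which case distances are clamped from
    below (keeps the singularity out of the sampled values).
    """
    if min_distance is None and grid.contains(source.x, source.y):
        raise GeometryError(
            f"source at ({source.x}, {source.y}) lies inside the grid footprint; "
            "move it outside or pass min_distance to clamp"
        )
    k = complex_wavenumber(medium, source.frequency)
    X, Y = grid.meshgrid()
    r = np.hypot(X - source.x, Y - source.y)
    if min_distance is not None:
        r = np.maximum(r, min_distance)
    values = source.amplitude * greens_field(k, r)
    return WavefieldGrid(values, grid, source.frequency)


def _class_label(class_mu_kpa: float, classes_kpa: Sequence[float]) -> int:
    ordered = sorted(classes_kpa)
    for i, c in enumerate(ordered):
        if np.isclose(class_mu_kpa, c):
            return i
    raise LabelError(
        f"class_mu={class_mu_kpa} kPa is not in the configured class set {ordered}"
    )


def sample_patch(
    class_mu_kpa: float,
    placement: SourcePlacementSpec = SourcePlacementSpec(),
    grid: GridSpec | None = None,
    seed: int | np.random.Generator = 0,
    classes_kpa: Sequence[float] = MULTICLASS_CLASSES_KPA,
    loss_ratio: float = DEFAULT_LOSS_RATIO,
    density: float = DEFAULT_DENSITY,
    frequency: float = DEFAULT_FREQUENCY_HZ,
) -> PatchSample:
    """Draw one 71×11×2 training patch for the given stiffness class.

    The source position is drawn uniformly (over area) in the placement
    annulus centered on the patch; the patch is normalized by its maximum
    absolute value and carries full provenance in ``meta``.
    """
    label = _class_label(class_mu_kpa, classes_kpa)
    if grid is None:
        grid = GridSpec(n_rows=71, n_cols=11)
    placement.validate_for_grid(grid)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    radius, angle = placement.draw(rng)
    cx, cy = grid.center
    sx = cx + radius * np.cos(angle)
    sy = cy + radius * np.sin(angle)
    medium = ViscoelasticMedium(class_mu_kpa * 1e3, loss_ratio, density)
    source = HarmonicSource(sx, sy, frequency)
    fieldgrid = simulate_wavefield(medium, source, grid)
    meta = {
        "mu_kpa": class_mu_kpa,
        "loss_ratio": loss_ratio,
        "source_x": sx,
        "source_y": sy,
        "source_radius": radius,
        "source_angle": angle,
        "frequency": frequency,
        "origin": "synthetic",
    }
    return patch_from_complex(fieldgrid.values, label, meta)


def make_synthetic_dataset(
    classes_kpa: Sequence[float],
    n_per_class: int,
    placement: SourcePlacementSpec = SourcePlacementSpec(),
    grid: GridSpec | None = None,
    seed: int = 0,
    loss_ratio: float = DEFAULT_LOSS_RATIO,
    density: float = DEFAULT_DENSITY,
    frequency: float = DEFAULT_FREQUENCY_HZ,
) -> LabeledDataset:
    """Balanced synthetic dataset: ``n_per_class`` patches per stiffness class.

    Labels are indexed 0..C−1 in ascending stiffness. Reproducible from the
    single seed (per-sample streams are spawned from it).
    """
    if n_per_class < 1:
        raise ConfigError(f"n_per_class must be ≥ 1, got {n_per_class}")
    if len(set(classes_kpa)) != len(classes_kpa):
        raise ConfigError(f"duplicate class values in {list(classes_kpa)}")
    ordered = sorted(classes_kpa)
    samples: list[PatchSample] = []
    streams = np.random.SeedSequence(seed).spawn(len(ordered) * n_per_class)
    for ci, mu in enumerate(ordered):
        for j in range(n_per_class):
            rng = np.random.default_rng(streams[ci * n_per_class + j])
            s = sample_patch(
                mu, placement, grid, rng,
                classes_kpa=ordered, loss_ratio=loss_ratio,
                density=density, frequency=frequency,
            )
            s.meta["sample_index"] = j
            samples.append(s)
    class_names = [f"{mu:g}kPa" for mu in ordered]
    return LabeledDataset(samples, class_names)


# ---------------------------------------------------------------------------
# Wavelength estimation (zero-crossing statistic)
# ---------------------------------------------------------------------------

def _crossing_rate(values: np.ndarray, axis: int, pitch: float) -> float:
    """Mean zero-crossing rate (crossings per meter) along one grid axis."""
    sign = np.signbit(values)
    crossings = np.sum(np.diff(sign, axis=axis) != 0)
    n_lines = values.shape[1 - axis]
    length = (values.shape[axis] - 1) * pitch * n_lines
    return float(crossings) / length


def estimate_wavelength(values: np.ndarray, pitch: float) -> float:
    """Estimate the wavelength of a 2-D harmonic field from zero crossings.

    A plane-ish wave at angle θ to the row axis crosses zero at rate
    c_row = 2|cos θ|/λ along columns and c_col = 2|sin θ|/λ along rows, so
    √(c_row² + c_col²) = 2/λ independently of propagation direction.
    Accepts a complex field, a real snapshot, or a 71×11×2 channel stack
    (the real channel is used).
    """
    values = np.asarray(values)
    if values.ndim == 3:
        values = values[..., 0]
    if np.iscomplexobj(values):
        values = values.real
    c_row = _crossing_rate(values, 0, pitch)
    c_col = _crossing_rate(values, 1, pitch)
    rate = np.hypot(c_row, c_col)
    if rate == 0:
        return np.inf
    return 2.0 / rate


def dominant_spatial_frequency(profile: np.ndarray, pitch: float) -> float:
    """Dominant spatial frequency (cycles/m) of a 1-D field profile via FFT."""
    profile = np.asarray(profile)
    if np.iscomplexobj(profile):
        profile = profile.real
    profile = profile - profile.mean()
    spectrum = np.abs(np.fft.rfft(profile))
    freqs = np.fft.rfftfreq(len(profile), d=pitch)
    return float(freqs[np.argmax(spectrum)])
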