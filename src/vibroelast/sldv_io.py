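"""SLDV scan-export ingestion, gridding, cropping and patch extraction.

A scanning laser Doppler vibrometer reports one complex velocity per
measurement point at the chosen excitation frequency. The canonical text
dialect used by this package (both reader and fixture writer) is:

    # point_id x y v_re v_im
    1 0.000000 0.000000 1.234e+00 -5.678e-01
    ...

whitespace-separated columns, one comment-prefixed header line, coordinates
in meters and velocity components in μm/s (units are carried, not enforced).

The physical scans this emulates are not distributed with the package, so
:func:`write_fixture` produces physically structured stand-ins: simulated
point-source wavefields on the scan grid plus additive circularly-symmetric
complex Gaussian noise at a configured SNR.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .errors import (
    EmptyInputError,
    FormatError,
    GeometryError,
    InterpolationError,
)
from .patches import PATCH_SHAPE, PatchSample, LabeledDataset, patch_from_complex
from .wavesim import (
    DEFAULT_FREQUENCY_HZ,
    GridSpec,
    HarmonicSource,
    SourcePlacementSpec,
    ViscoelasticMedium,
    WavefieldGrid,
    simulate_wavefield,
)

SCAN_COLUMNS = ("point_id", "x", "y", "v_re", "v_im")

#: full scan grid before cropping; a 4-point boundary crop yields 71×44,
#: which tiles into exactly four 71×11 patches
FULL_SCAN_GRID = GridSpec(n_rows=79, n_cols=52)
DEFAULT_CROP_MARGIN = 4

#: annulus for fixture-image sources; wider than the patch default because
#: the full 79×52 footprint has a half-diagonal of ≈23.3 mm
FIXTURE_PLACEMENT = SourcePlacementSpec(r_min=0.025, r_max=0.045)


def read_scan_export(path: str | Path) -> pd.DataFrame:
    """Parse a scan-export text file into a table of scan points.

    Returns a DataFrame with columns ``point_id, x, y, v_re, v_im``.
    Malformed rows raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    rows: list[tuple[int, float, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != len(SCAN_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(SCAN_COLUMNS)} columns "
                    f"{SCAN_COLUMNS}, got {len(parts)}"
                )
            try:
                rows.append(
                    (int(parts[0]), float(parts[1]), float(parts[2]),
                     float(parts[3]), float(parts[4]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if not rows:
        raise EmptyInputError(f"{path}: no data rows")
    table = pd.DataFrame(rows, columns=list(SCAN_COLUMNS))
    if table["point_id"].duplicated().any():
        dupes = table.loc[table["point_id"].duplicated(), "point_id"].tolist()
        raise FormatError(f"{path}: duplicate point_id values {dupes}")
    if not np.all(np.isfinite(table[["x", "y", "v_re", "v_im"]].to_numpy())):
        raise FormatError(f"{path}: non-finite coordinate or velocity")
    return table


def write_scan_export(path: str | Path, table: pd.DataFrame) -> None:
    """Write a scan-point table in the canonical text dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# " + " ".join(SCAN_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{int(row.point_id)} {row.x:.9e} {row.y:.9e} "
                f"{row.v_re:.9e} {row.v_im:.9e}\n"
            )


def interpolate_to_grid(
    table: pd.DataFrame,
    grid: GridSpec,
    frequency: float = DEFAULT_FREQUENCY_HZ,
    fill_value: complex | None = None,
) -> WavefieldGrid:
    """Linearly interpolate scattered scan points onto a regular grid.

    Real and imaginary parts are interpolated independently on a Delaunay
    triangulation. Grid points outside the convex hull of the scan points
    are an error unless ``fill_value`` is given.
    """
    if len(table) < 4:
        raise InterpolationError(
            f"need at least 4 scan points for interpolation, got {len(table)}"
        )
    points = table[["x", "y"]].to_numpy()
    v = table["v_re"].to_numpy() + 1j * table["v_im"].to_numpy()
    try:
        interp = LinearNDInterpolator(points, v)
    except QhullError as exc:
        raise InterpolationError(f"degenerate scan-point geometry: {exc}") from exc
    X, Y = grid.meshgrid()
    values = interp(X, Y)
    outside = ~np.isfinite(values)
    if np.any(outside):
        if fill_value is None:
            raise InterpolationError(
                f"{int(outside.sum())} grid points fall outside the convex hull "
                "of the scan points (pass fill_value to allow)"
            )
        values = np.where(outside, fill_value, values)
    return WavefieldGrid(values, grid, frequency)


def crop_boundaries(field: WavefieldGrid, margin: int) -> WavefieldGrid:
    """Remove ``margin`` points from every side of the grid."""
    if margin < 0:
        raise GeometryError(f"margin must be ≥ 0, got {margin}")
    if margin == 0:
        return WavefieldGrid(field.values.copy(), field.grid, field.frequency)
    g = field.grid
    if 2 * margin >= min(g.n_rows, g.n_cols):
        raise GeometryError(
            f"margin {margin} too large for a {g.n_rows}×{g.n_cols} grid"
        )
    cropped = field.values[margin:-margin, margin:-margin]
    new_grid = GridSpec(
        n_rows=g.n_rows - 2 * margin,
        n_cols=g.n_cols - 2 * margin,
        pitch=g.pitch,
        origin=(g.origin[0] + margin * g.pitch, g.origin[1] + margin * g.pitch),
    )
    return WavefieldGrid(cropped.copy(), new_grid, field.frequency)


def extract_patches(
    field: WavefieldGrid,
    label: int = 0,
    image_id: str = "",
    normalize: bool = True,
) -> list[PatchSample]:
    """Tile a cropped field into non-overlapping 71×11 column strips.

    A 71×44 cropped image yields exactly 4 patches at columns 0–10, 11–21,
    22–32, 33–43; together they reconstruct the field with no gaps or
    overlaps. Each strip becomes a normalized two-channel (Re/Im) patch.
    """
    n_rows_p, n_cols_p, _ = PATCH_SHAPE
    g = field.grid
    if g.n_rows != n_rows_p:
        raise GeometryError(
            f"patch extraction requires exactly {n_rows_p} rows, got {g.n_rows} "
            "(crop the field to the canonical patch height first)"
        )
    if g.n_cols < n_cols_p:
        raise GeometryError(
            f"field has {g.n_cols} columns, fewer than one {n_cols_p}-wide patch"
        )
    n_patches = g.n_cols // n_cols_p
    patches = []
    for p in range(n_patches):
        window = field.values[:, p * n_cols_p:(p + 1) * n_cols_p]
        meta = {"image_id": image_id, "patch_index": p, "origin": "scan"}
        patches.append(patch_from_complex(window, label, meta, normalize=normalize))
    return patches


def add_complex_noise(
    values: np.ndarray, snr_db: float | None, rng: np.random.Generator
) -> np.ndarray:
    """Add circularly-symmetric complex Gaussian noise at a per-image SNR.

    ``snr_db=None`` (or +inf) returns the input unchanged. The noise power
    is set relative to the mean signal power over the image.
    """
    if snr_db is None or np.isinf(snr_db):
        return values.copy()
    signal_power = float(np.mean(np.abs(values) ** 2))
    noise_power = signal_power / 10.0 ** (snr_db / 10.0)
    sigma = np.sqrt(noise_power / 2.0)
    noise = sigma * (
        rng.standard_normal(values.shape) + 1j * rng.standard_normal(values.shape)
    )
    return values + noise


def write_fixture(
    out_dir: str | Path,
    classes_kpa: Sequence[float],
    n_images_per_class: int = 13,
    snr_db: float | None = 20.0,
    grid: GridSpec = FULL_SCAN_GRID,
    placement: SourcePlacementSpec = FIXTURE_PLACEMENT,
    seed: int = 0,
    loss_ratio: float = 0.15,
    density: float = 1000.0,
    frequency: float = DEFAULT_FREQUENCY_HZ,
) -> list[Path]:
    """Write per-image scan-export fixture files emulating physical scans.

    Each file holds one simulated point-source wavefield on the full scan
    grid plus complex Gaussian noise at ``snr_db``; scan points coincide
    with grid points so noiseless round-trips are exact. Filenames encode
    class and image index: ``class<i>_<mu>kPa_img<j>.txt``. Deterministic
    under ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(set(classes_kpa))
    if len(ordered) != len(classes_kpa):
        raise FormatError(f"duplicate class values in {list(classes_kpa)}")
    placement_check_grid = grid
    if placement.r_min <= placement_check_grid.half_diagonal:
        raise GeometryError(
            f"placement r_min={placement.r_min} must exceed the scan grid "
            f"half-diagonal {grid.half_diagonal:.4f} m"
        )
    streams = np.random.SeedSequence(seed).spawn(len(ordered) * n_images_per_class)
    X, Y = grid.meshgrid()
    paths = []
    for ci, mu in enumerate(ordered):
        medium = ViscoelasticMedium(mu * 1e3, loss_ratio, density)
        for j in range(n_images_per_class):
            rng = np.random.default_rng(streams[ci * n_images_per_class + j])
            radius, angle = placement.draw(rng)
            cx, cy = grid.center
            source = HarmonicSource(
                cx + radius * np.cos(angle), cy + radius * np.sin(angle), frequency
            )
            field = simulate_wavefield(medium, source, grid)
            noisy = add_complex_noise(field.values, snr_db, rng)
            table = pd.DataFrame(
                {
                    "point_id": np.arange(1, noisy.size + 1),
                    "x": X.ravel(),
                    "y": Y.ravel(),
                    "v_re": noisy.real.ravel(),
                    "v_im": noisy.imag.ravel(),
                }
            )
            path = out_dir / f"class{ci}_{mu:g}kPa_img{j:02d}.txt"
            write_scan_export(path, table)
            paths.append(path)
    return paths


def ingest_fixture_dir(
    in_dir: str | Path,
    grid: GridSpec = FULL_SCAN_GRID,
    margin: int = DEFAULT_CROP_MARGIN,
    frequency: float = DEFAULT_FREQUENCY_HZ,
) -> LabeledDataset:
    """Read every fixture scan export in a directory into a patch dataset.

    Files must follow the ``class<i>_<name>_img<j>.txt`` naming produced by
    :func:`write_fixture`; the pipeline per image is read → interpolate →
    crop boundaries → extract patches.
    """
    in_dir = Path(in_dir)
    files = sorted(in_dir.glob("class*_img*.txt"))
    if not files:
        raise EmptyInputError(f"no scan exports matching class*_img*.txt in {in_dir}")
    samples: list[PatchSample] = []
    class_names: dict[int, str] = {}
    for path in files:
        stem_parts = path.stem.split("_")
        label = int(stem_parts[0].removeprefix("class"))
        class_names[label] = stem_parts[1]
        table = read_scan_export(path)
        field = interpolate_to_grid(table, grid, frequency)
        cropped = crop_boundaries(field, margin)
        for s in extract_patches(cropped, label=label, image_id=path.stem):
            samples.append(s)
    names = [class_names[i] for i in sorted(class_names)]
    if sorted(class_names) != list(range(len(names))):
        raise FormatError(f"class indices {sorted(class_names)} are not contiguous from 0")
    return LabeledDataset(samples, names)
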