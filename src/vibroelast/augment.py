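"""Offline, label-preserving augmentation of training patches.

All transforms are affine-style manipulations of the 71×11×2 patch that keep
the class label valid. Because the class is encoded in the spatial
wavelength of the field, the pipeline bounds matter: crop-and-zoom rescales
the apparent wavelength by 1/keep_fraction, so keep_fraction is bounded
below (default 0.9) so that no zoom can reorder the stiffness-class
wavelengths; reflection and small translations leave wavelength statistics
invariant; "brightness" is an amplitude gain on both quadrature channels.

Augmentation is applied to training indices only; validation and test
samples are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom as ndi_zoom

from .errors import InvalidParameterError, ProtocolError
from .patches import PATCH_SHAPE, PatchSample, LabeledDataset

DEFAULT_MAX_SHIFT = 2
# crop-zoom rescales apparent wavelength by 1/keep_fraction; adjacent
# five-class wavelengths differ by √(μb/μa) ≥ √(5/4) ≈ 1.118, so the lower
# bound must exceed √(4/5) ≈ 0.894 for the ordering to be provably preserved
DEFAULT_KEEP_FRACTION_RANGE = (0.9, 1.0)
DEFAULT_GAIN_RANGE = (0.7, 1.3)
DEFAULT_MULTIPLIER = 4


def reflect(sample: PatchSample, axis: int = 0) -> PatchSample:
    """Mirror the patch along a grid axis (default: the 71-point axis).

    Mirroring leaves wavelength statistics invariant, so the label is
    preserved. Channel pairing (Re = channel 0) is untouched.
    """
    if axis not in (0, 1):
        raise InvalidParameterError(f"axis must be 0 or 1, got {axis}")
    return PatchSample(np.flip(sample.values, axis=axis).copy(), sample.label,
                       {**sample.meta, "augment": "reflect"})


def translate(
    sample: PatchSample, dx: int, dy: int, max_shift: int = DEFAULT_MAX_SHIFT
) -> PatchSample:
    """Shift patch content by (dx columns, dy rows), zero-filling vacated cells."""
    if abs(dx) > max_shift or abs(dy) > max_shift:
        raise InvalidParameterError(
            f"shift ({dx}, {dy}) exceeds the ±{max_shift}-point bound"
        )
    out = np.zeros_like(sample.values)
    n_rows, n_cols, _ = sample.values.shape
    src_r = slice(max(0, -dy), min(n_rows, n_rows - dy))
    dst_r = slice(max(0, dy), min(n_rows, n_rows + dy))
    src_c = slice(max(0, -dx), min(n_cols, n_cols - dx))
    dst_c = slice(max(0, dx), min(n_cols, n_cols + dx))
    out[dst_r, dst_c, :] = sample.values[src_r, src_c, :]
    return PatchSample(out, sample.label, {**sample.meta, "augment": "translate"})


def crop_zoom(
    sample: PatchSample,
    keep_fraction: float,
    keep_range: tuple[float, float] = DEFAULT_KEEP_FRACTION_RANGE,
) -> PatchSample:
    """Take a central sub-window of the patch and re-interpolate to 71×11.

    Rescales the apparent wavelength by 1/keep_fraction, so the fraction is
    bounded below (default 0.9) so adjacent class wavelengths cannot cross.
    keep_fraction = 1 is the identity.
    """
    lo, hi = keep_range
    if not (lo <= keep_fraction <= hi):
        raise InvalidParameterError(
            f"keep_fraction {keep_fraction} outside [{lo}, {hi}]"
        )
    if keep_fraction == 1.0:
        return PatchSample(sample.values.copy(), sample.label,
                           {**sample.meta, "augment": "crop_zoom"})
    n_rows, n_cols, _ = sample.values.shape
    keep_r = max(2, int(round(n_rows * keep_fraction)))
    keep_c = max(2, int(round(n_cols * keep_fraction)))
    r0 = (n_rows - keep_r) // 2
    c0 = (n_cols - keep_c) // 2
    window = sample.values[r0:r0 + keep_r, c0:c0 + keep_c, :]
    out = ndi_zoom(
        window, (n_rows / keep_r, n_cols / keep_c, 1.0), order=1, mode="nearest"
    )
    # interpolation can land a point or two off; force the exact shape
    out = out[:n_rows, :n_cols, :]
    if out.shape != sample.values.shape:
        padded = np.zeros_like(sample.values)
        padded[: out.shape[0], : out.shape[1], :] = out
        out = padded
    return PatchSample(out, sample.label, {**sample.meta, "augment": "crop_zoom"})


def brightness(sample: PatchSample, gain: float) -> PatchSample:
    """Scale both channels by a positive amplitude gain.

    The inputs are signed velocity fields, so "brightness" is a joint
    amplitude gain on both quadrature channels, not a display-level offset.
    """
    if gain <= 0:
        raise InvalidParameterError(f"gain must be > 0, got {gain}")
    return PatchSample(sample.values * gain, sample.label,
                       {**sample.meta, "augment": "brightness"})


@dataclass(frozen=True)
class AugmentConfig:
    """Pipeline bounds for random augmentation draws."""

    multiplier: int = DEFAULT_MULTIPLIER
    max_shift: int = DEFAULT_MAX_SHIFT
    keep_fraction_range: tuple[float, float] = DEFAULT_KEEP_FRACTION_RANGE
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise InvalidParameterError(
                f"multiplier must be ≥ 1, got {self.multiplier}"
            )
        lo, hi = self.keep_fraction_range
        if not (0 < lo <= hi <= 1):
            raise InvalidParameterError(
                f"keep_fraction_range must satisfy 0 < lo ≤ hi ≤ 1, got {self.keep_fraction_range}"
            )
        glo, ghi = self.gain_range
        if not (0 < glo <= ghi):
            raise InvalidParameterError(
                f"gain_range must be positive, got {self.gain_range}"
            )


def random_augment(
    sample: PatchSample, rng: np.random.Generator, config: AugmentConfig
) -> PatchSample:
    """One random composition of reflect / translate / crop-zoom / gain."""
    out = sample
    # independent mirror draws on both axes: covers the four-fold symmetry
    # of the source-placement annulus
    if rng.uniform() < 0.5:
        out = reflect(out, axis=0)
    if rng.uniform() < 0.5:
        out = reflect(out, axis=1)
    dx = int(rng.integers(-config.max_shift, config.max_shift + 1))
    dy = int(rng.integers(-config.max_shift, config.max_shift + 1))
    out = translate(out, dx, dy, max_shift=config.max_shift)
    kf = float(rng.uniform(*config.keep_fraction_range))
    out = crop_zoom(out, kf, keep_range=config.keep_fraction_range)
    gain = float(rng.uniform(*config.gain_range))
    out = brightness(out, gain)
    return out


def augment_training_set(
    dataset: LabeledDataset,
    split: "DataSplit",
    config: AugmentConfig = AugmentConfig(),
    seed: int = 0,
    which: str = "train",
) -> tuple[LabeledDataset, "DataSplit"]:
    """Append augmented copies of the TRAINING samples only.

    With multiplier m, each training sample gains m−1 augmented copies, so
    the training count is multiplied by m. Validation and test indices are
    returned unchanged; requesting augmentation of any other split is a
    protocol violation. Deterministic under ``seed``.
    """
    from .training import DataSplit  # local import: avoid module cycle

    if which != "train":
        raise ProtocolError(
            f"augmentation is only permitted on the training split, not {which!r}"
        )
    new_samples = [s.copy() for s in dataset.samples]
    new_train = list(split.train)
    rng = np.random.default_rng(seed)
    for _ in range(config.multiplier - 1):
        for idx in split.train:
            aug = random_augment(dataset.samples[idx], rng, config)
            aug.meta["augmented_from"] = int(idx)
            new_train.append(len(new_samples))
            new_samples.append(aug)
    new_dataset = LabeledDataset(new_samples, list(dataset.class_names))
    new_split = DataSplit(
        train=tuple(new_train), val=tuple(split.val), test=tuple(split.test)
    )
    return new_dataset, new_split
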