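"""Patch samples and labeled datasets.

A patch is one training example: a 71×11 window of a complex harmonic
wavefield stored as two real channels (channel 0 = real part, channel 1 =
imaginary part, i.e. the field 90° later in phase), normalized per sample so
that classification rests on the spatial wave pattern rather than on the
arbitrary absolute velocity amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, LabelError

#: canonical patch geometry: (rows, cols, channels)
PATCH_SHAPE = (71, 11, 2)


@dataclass
class PatchSample:
    """One labeled training example of shape 71×11×2 plus provenance."""

    values: np.ndarray
    label: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != PATCH_SHAPE:
            raise LabelError(
                f"patch values must have shape {PATCH_SHAPE}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise LabelError("patch values must be finite")
        if self.label < 0:
            raise LabelError(f"label must be non-negative, got {self.label}")

    def copy(self) -> "PatchSample":
        return PatchSample(self.values.copy(), self.label, dict(self.meta))


def normalize_patch(values: np.ndarray) -> np.ndarray:
    """Divide both channels by the sample's maximum absolute value.

    Leaves an all-zero patch unchanged rather than dividing by zero.
    """
    values = np.asarray(values, dtype=np.float64)
    peak = np.max(np.abs(values))
    if peak == 0.0:
        return values.copy()
    return values / peak


def patch_from_complex(
    window: np.ndarray,
    label: int,
    meta: dict[str, Any] | None = None,
    normalize: bool = True,
) -> PatchSample:
    """Convert a 71×11 complex window into a two-channel real patch."""
    window = np.asarray(window)
    values = np.stack([window.real, window.imag], axis=-1)
    if normalize:
        values = normalize_patch(values)
    return PatchSample(values, label, meta or {})


@dataclass
class LabeledDataset:
    """An ordered collection of patches with a fixed class vocabulary."""

    samples: list[PatchSample]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ConfigError("class_names must be unique")
        for s in self.samples:
            if s.label >= len(self.class_names):
                raise LabelError(
                    f"label {s.label} out of range for {len(self.class_names)} classes"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[PatchSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> PatchSample:
        return self.samples[i]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def as_arrays(
        self, indices: Sequence[int] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) with X of shape (n, 71, 11, 2)."""
        if indices is None:
            indices = range(len(self.samples))
        X = np.stack([self.samples[i].values for i in indices])
        y = np.array([self.samples[i].label for i in indices], dtype=np.int64)
        return X, y

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def save(self, path: str | Path) -> None:
        """Persist as an .npz array container plus a CSV metadata sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        X, y = self.as_arrays()
        np.savez_compressed(
            path, values=X, labels=y, class_names=np.array(self.class_names)
        )
        meta = pd.DataFrame(
            [{"index": i, "label": s.label, **_flatten_meta(s.meta)}
             for i, s in enumerate(self.samples)]
        )
        meta.to_csv(path.with_suffix(".meta.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "LabeledDataset":
        path = Path(path)
        with np.load(path, allow_pickle=False) as data:
            X = data["values"]
            y = data["labels"]
            class_names = [str(c) for c in data["class_names"]]
        meta_path = path.with_suffix(".meta.csv")
        metas: list[dict[str, Any]] = [{} for _ in range(len(y))]
        if meta_path.exists():
            table = pd.read_csv(meta_path)
            for _, row in table.iterrows():
                d = row.to_dict()
                idx = int(d.pop("index"))
                d.pop("label", None)
                metas[idx] = {k: v for k, v in d.items() if pd.notna(v)}
        samples = [
            PatchSample(X[i], int(y[i]), metas[i]) for i in range(len(y))
        ]
        return cls(samples, class_names)


def _flatten_meta(meta: dict[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in meta.items():
        if isinstance(v, (dict, list, tuple)):
            out[k] = json.dumps(v)
        else:
            out[k] = v
    return out
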