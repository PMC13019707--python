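"""Wavefield snapshot rendering (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .wavesim import WavefieldGrid  # noqa: E402


def plot_wavefield(field: WavefieldGrid, path: str | Path,
                   title: str = "") -> Path:
    """Save side-by-side real/imaginary snapshots of a harmonic wavefield.

    The imaginary image is the real image 90° later in phase; the shared
    symmetric color scale makes the wavelength (class) visually comparable
    between snapshots.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = field.grid
    extent = [g.x[0] * 1e3, g.x[-1] * 1e3, g.y[0] * 1e3, g.y[-1] * 1e3]
    vmax = float(abs(field.values).max())
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), constrained_layout=True)
    for ax, part, name in ((axes[0], field.values.real, "real"),
                           (axes[1], field.values.imag, "imaginary")):
        im = ax.imshow(part, origin="lower", extent=extent, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, aspect="equal")
        ax.set_xlabel("x [mm]")
        ax.set_ylabel("y [mm]")
        ax.set_title(name)
    fig.colorbar(im, ax=axes, shrink=0.85, label="velocity [arb.]")
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
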