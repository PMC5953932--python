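"""Plots of the four massed sub-curves on the Fermat spiral."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .descriptor import massed_points
from .sequence_io import ALPHABET, NucleotideSequence
from .spiral import RepresentationParams


def plot_spiral_panels(
    seq: NucleotideSequence, params: RepresentationParams, path: str | Path
) -> pd.DataFrame:
    """Draw the A/C/G/T sub-curves as a 2x2 panel; point area tracks mass.

    The grey background curve is the spiral itself over the sequence's span.
    Returns the plotted data (base, position, x, y, mass) so the figure's
    contents can be checked and exported deterministically.
    """
    points = massed_points(seq, params)
    rows = [
        {"base": b, "position": p.position, "x": p.x, "y": p.y, "mass": p.mass}
        for b in ALPHABET
        for p in points[b]
    ]
    data = pd.DataFrame(rows, columns=["base", "position", "x", "y", "mass"])

    theta_max = 2 * np.pi * (len(seq) - 1) / (params.L - 1)
    t = np.linspace(0, max(theta_max, 1e-9), 512)
    spiral_x, spiral_y = np.sqrt(t) * np.cos(t), np.sqrt(t) * np.sin(t)

    fig, axes = plt.subplots(2, 2, figsize=(8, 8), sharex=True, sharey=True)
    for ax, base in zip(axes.ravel(), ALPHABET):
        ax.plot(spiral_x, spiral_y, color="0.85", lw=0.8, zorder=1)
        sub = data[data["base"] == base]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], s=60 * sub["mass"], zorder=2)
        ax.set_title(f"{base} subsequence (n={len(sub)})")
        ax.set_aspect("equal")
    fig.suptitle(f"{seq.id}: massive points on the Fermat spiral (L={params.L})")
    fig.tight_layout()
    fig.savefig(str(Path(path)), dpi=150)
    plt.close(fig)
    return data
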