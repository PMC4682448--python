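"""Optional diagnostic plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bands import Band, BandProfile
from .genotype import ClusterModel


def plot_band_profile(profile: BandProfile, bands: list[Band], path: str, percentile: float = 85.0) -> None:
    """Summed lane profile with called bands and the background threshold."""
    fig, ax = plt.subplots(figsize=(8, 3))
    v = profile.values
    ax.plot(v, color="tab:blue", lw=1, label="summed intensity b(n)")
    thr = np.percentile(v, percentile)
    ax.axhline(thr, color="tab:red", lw=1, ls="--", label=f"{percentile:g}th percentile")
    if bands:
        pos = [b.position for b in bands]
        ax.stem(pos, [v[p] for p in pos], linefmt="g-", markerfmt="go", basefmt=" ", label="called bands")
    ax.set_xlabel("migration position (px)")
    ax.set_ylabel("summed intensity")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_offset_histogram(offsets: list[float], model: ClusterModel, path: str) -> None:
    """Band-offset histogram with fitted cluster centroids marked."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.hist(offsets, bins=60, color="0.6")
    for c in model.clusters:
        ax.axvline(c.mean, color="red", lw=1)
        ax.plot(c.mean, 0, "ro", clip_on=False)
    ax.set_xlabel("band offset relative to reference (px)")
    ax.set_ylabel("band count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
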