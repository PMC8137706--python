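"""Contour figures for absorbance surfaces, maps and extracted regions."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .grids import make_canonical_grids
from .rf_regions import ImportanceMap
from .statmap import RegionMask, StatMap


def _axes_grids():
    freq_grid, press_grid = make_canonical_grids()
    return freq_grid.centres, press_grid.values


def _finish(ax, title: str) -> None:
    ax.set_xscale("log")
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("Pressure (daPa)")
    ax.set_title(title)


def plot_surface(values: np.ndarray, title: str, path: Path | str) -> Path:
    """Filled contour of one 107 x 51 field (frequency on a log axis)."""
    f, p = _axes_grids()
    fig, ax = plt.subplots(figsize=(6, 4))
    cs = ax.contourf(f, p, values.T, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax)
    _finish(ax, title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_overlay(
    imp_map: ImportanceMap,
    p_masks: dict[float, RegionMask],
    path: Path | str,
) -> Path:
    """Importance map with p-value region contours at each fraction."""
    f, p = _axes_grids()
    fig, ax = plt.subplots(figsize=(6, 4))
    cs = ax.contourf(f, p, imp_map.imp.T, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="averaged forest importance")
    for fraction, mask in sorted(p_masks.items()):
        ax.contour(f, p, mask.mask.T.astype(float), levels=[0.5], colors="white",
                   linewidths=1.2)
        ax.plot([], [], color="white", label=f"top {fraction:.0%} p-value region")
    ax.legend(loc="lower right", fontsize=7)
    _finish(ax, "Forest importances with significance contours")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_statmap(statmap: StatMap, path: Path | str) -> Path:
    f, p = _axes_grids()
    fig, ax = plt.subplots(figsize=(6, 4))
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(np.maximum(statmap.p, 1e-300))
    cs = ax.contourf(f, p, neglogp.T, levels=20, cmap="magma")
    fig.colorbar(cs, ax=ax, label=r"$-\log_{10} p$")
    _finish(ax, "Pointwise rank-sum significance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
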