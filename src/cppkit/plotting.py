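"""Plot helpers: PMF profiles, metric time series, occupancy heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .membrane import OrderParameterProfile
from .pmf import PMFProfile

__all__ = ["plot_pmf", "plot_timeseries", "plot_order_parameter", "plot_occupancy"]


def plot_pmf(profile: PMFProfile, path: str | Path, title: str = "PMF") -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.grid, profile.free_energy, lw=1.5)
    for idx in profile.stage_boundaries[1:]:
        ax.axvline(profile.grid[idx], color="0.85", lw=0.8, zorder=0)
    ax.set_xlabel("reaction coordinate z ($\\AA$)")
    ax.set_ylabel("free energy (kcal/mol)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_timeseries(
    values: np.ndarray, path: str | Path, ylabel: str, title: str = ""
) -> Path:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(np.arange(len(values)), values, lw=1.0)
    ax.set_xlabel("frame")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_order_parameter(profile: OrderParameterProfile, path: str | Path) -> Path:
    ks, means, sds = profile.as_arrays()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(ks, means, yerr=sds, marker="o", lw=1.2, capsize=3)
    ax.set_xlabel("tail carbon index")
    ax.set_ylabel("$S$")
    ax.set_ylim(-0.55, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_occupancy(table: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.3 * len(table)))
    data = table.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_yticks(range(len(table)), [str(i) for i in table.index])
    ax.set_xticks(
        range(data.shape[1]), ["/".join(map(str, c)) for c in table.columns],
        rotation=45, ha="right",
    )
    ax.set_ylabel("peptide residue")
    fig.colorbar(im, ax=ax, label="occupancy (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
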