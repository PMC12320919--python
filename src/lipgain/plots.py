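"""Figure builders for the standard report: map activity, decoded traces,
weight maps, information maps and GFI curves.  Every function returns a
matplotlib Figure; the CLI's ``report`` command saves them to disk."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .decoder import DecodeResult, DecoderWeights, weight_map
from .experiment import TrialRecord
from .gfi import trial_average

__all__ = [
    "plot_map_activity",
    "plot_decode",
    "plot_weight_maps",
    "plot_info_map",
    "plot_gfi_curves",
]


def _extent(centers: np.ndarray, time: np.ndarray) -> list[float]:
    return [time[0], time[-1], centers[0], centers[-1]]


def plot_map_activity(records: list[TrialRecord], centers: np.ndarray):
    """Trial-averaged activity of both LIP maps over time.

    Each panel collapses the map onto one axis (top: eye-position
    selectivity, max over the retinal axis; bottom: stimulus selectivity,
    max over the eye axis)."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    time = records[0].time
    for col, pop in enumerate(("lip_cd", "lip_pc")):
        avg = trial_average(records, pop)
        for row, (axis, label) in enumerate(((2, "eye position"), (1, "stimulus position"))):
            img = avg.max(axis=axis).T
            ax = axes[row, col]
            ax.imshow(img, aspect="auto", origin="lower",
                      extent=_extent(centers, time), cmap="viridis")
            ax.set_title(f"{pop} ({label} axis)")
            ax.axvline(0, color="w", ls="--", lw=0.8)
            if row == 1:
                ax.set_xlabel("time re saccade onset (ms)")
            ax.set_ylabel(f"{label} (deg)")
    fig.tight_layout()
    return fig


def plot_decode(results: dict[str, DecodeResult]):
    """Decoded (red) vs target (black) eye position, one panel per offset."""
    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.2),
                             sharey=True, squeeze=False)
    for ax, (name, res) in zip(axes[0], results.items()):
        ax.plot(res.time, res.target, "k", lw=1.5, label="target EP")
        ax.plot(res.time, res.decoded, "r", lw=1.2, label="decoded")
        ax.set_title(f"{name} (RMSE {res.rmse:.2f} deg)")
        ax.set_xlabel("time re saccade onset (ms)")
        ax.axvline(0, color="grey", ls=":", lw=0.8)
    axes[0, 0].set_ylabel("eye position (deg)")
    axes[0, 0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_weight_maps(weights: DecoderWeights, centers: np.ndarray):
    """Per-map decoder weights on the (eye x retinal) grid, diverging cmap."""
    maps = weight_map(weights)
    fig, axes = plt.subplots(1, len(maps), figsize=(5 * len(maps), 4), squeeze=False)
    vmax = max(abs(m).max() for m in maps.values()) or 1.0
    for ax, (pop, m) in zip(axes[0], maps.items()):
        im = ax.imshow(m.T, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       extent=[centers[0], centers[-1], centers[0], centers[-1]])
        ax.set_title(f"{pop} weights (offset {weights.offset:+.0f} ms)")
        ax.set_xlabel("eye-position selectivity (deg)")
        ax.set_ylabel("stimulus selectivity (deg)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig


def plot_info_map(time: np.ndarray, matrix: np.ndarray, centers: np.ndarray,
                  title: str = "eye position information"):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(matrix.T, aspect="auto", origin="lower",
              extent=_extent(centers, time), cmap="magma")
    ax.axvline(0, color="w", ls="--", lw=0.8)
    ax.set_xlabel("time re saccade onset (ms)")
    ax.set_ylabel("position (deg)")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_gfi_curves(curves: dict[str, tuple[np.ndarray, np.ndarray]]):
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {"pooled_mean": ("k", "mean (pooled)"),
              "low_to_high": ("tab:blue", "median low-to-high"),
              "high_to_low": ("tab:orange", "median high-to-low")}
    for name, (time, curve) in curves.items():
        color, label = styles.get(name, ("grey", name))
        ax.plot(time, curve, color=color, label=label)
    ax.set_xlabel("time re saccade onset (ms)")
    ax.set_ylabel("gain field index")
    ax.set_ylim(-0.1, 1.1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
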