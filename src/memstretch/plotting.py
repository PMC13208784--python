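"""Figure helpers: strain maps, deflection surface, rose plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_strain_contour(results, path: str | Path, region_outline: bool = True):
    """Von Mises strain map with the culture region outlined."""
    x, y = results.model.grid.axes(results.model.spec)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    im = ax.pcolormesh(x * 1e3, y * 1e3, 100 * results.strain.eps_vm.T, shading="auto")
    fig.colorbar(im, ax=ax, label="von Mises strain (%)")
    if region_outline:
        f = np.sqrt(results.model.region.area_fraction)
        a, b = results.model.spec.length_a * 1e3, results.model.spec.width_b * 1e3
        ax.add_patch(
            plt.Rectangle(
                ((1 - f) / 2 * a, (1 - f) / 2 * b),
                f * a,
                f * b,
                fill=False,
                edgecolor="white",
                linestyle="--",
            )
        )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_deflection_surface(results, path: str | Path):
    """3-D surface of the transverse deflection."""
    x, y = results.model.grid.axes(results.model.spec)
    X, Y = np.meshgrid(x * 1e3, y * 1e3, indexing="ij")
    fig = plt.figure(figsize=(7, 4))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(X, Y, results.deflection.w * 1e6, cmap="viridis", linewidth=0)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("w (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rose(stats, path: str | Path, title: str | None = None):
    """Polar rose of the axial orientation histogram (mirrored at +180)."""
    edges = np.radians(stats.rose_edges)
    weights = stats.rose_weights
    centers = (edges[:-1] + edges[1:]) / 2
    width = np.diff(edges)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centers, weights, width=width, alpha=0.8)
    ax.bar(centers + np.pi, weights, width=width, alpha=0.8, color="C0")
    ax.set_yticklabels([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
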