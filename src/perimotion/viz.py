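"""Plot and surface exports for the adhesion analysis."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import DisparityHistogram, KSMatrix


def plot_histogram(h: DisparityHistogram, path: str | Path, title: str = "") -> None:
    """Frequency distribution of normalized motion differences (0-1)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (h.edges[:-1] + h.edges[1:])
    ax.plot(centers, h.counts, lw=1.5)
    ax.fill_between(centers, h.counts, alpha=0.25)
    ax.set_xlabel("normalized motion difference")
    ax.set_ylabel("frequency")
    ax.set_xlim(0.0, 1.0)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phase_histograms(
    per_phase_counts: list[np.ndarray], edges: np.ndarray, t_star: int, path: str | Path
) -> None:
    """Per-phase distribution curves with the optimal phase highlighted."""
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (edges[:-1] + edges[1:])
    for k, counts in enumerate(per_phase_counts):
        if k == t_star:
            ax.plot(centers, counts, color="red", lw=2.0, label="t*")
        else:
            ax.plot(centers, counts, color="tab:blue", lw=0.8, alpha=0.6)
    ax.set_xlabel("normalized motion difference")
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ks_matrix(ks: KSMatrix, path: str | Path) -> None:
    """Heatmap of the pairwise phase-to-phase KS statistics."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(ks.d, cmap="viridis", origin="lower")
    ax.set_xticks(range(len(ks.phase_labels)), [f"{p}%" for p in ks.phase_labels])
    ax.set_yticks(range(len(ks.phase_labels)), [f"{p}%" for p in ks.phase_labels])
    ax.set_xlabel("cardiac phase")
    ax.set_ylabel("cardiac phase")
    fig.colorbar(im, ax=ax, label="KS statistic")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_disparity_surface(
    points_mm: np.ndarray,
    normalized_values: np.ndarray,
    path: str | Path,
    invert_colors: bool = False,
) -> None:
    """Export EAT points colored by normalized disparity as a PLY cloud.

    Default convention: cooler colors mark larger displacement differences
    (free motion) and warmer colors restricted motion; ``invert_colors``
    flips the mapping.
    """
    import trimesh

    values = np.clip(np.asarray(normalized_values, dtype=float), 0.0, 1.0)
    if invert_colors:
        values = 1.0 - values
    # warm (red) at 0 -> cool (blue) at 1
    cmap = matplotlib.colormaps["coolwarm_r"]
    colors = (cmap(values) * 255).astype(np.uint8)
    cloud = trimesh.PointCloud(np.asarray(points_mm, dtype=float), colors=colors)
    cloud.export(str(path))
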