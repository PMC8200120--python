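"""Post-training analysis of first-layer convolution kernels.

The learned 3x3x3 kernels of each branch are reduced to 3x3 tiles by
averaging input channels and then the depth axis, clustered with hierarchical
agglomerative clustering (Euclidean distance, Ward linkage) over a sweep of
cluster counts, scored with the mean silhouette, and rendered as grayscale
"boards": one row per k, one tile per cluster, each tile the min–max
normalized cluster mean mapped on a white(0)→black(1) gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ValidationError

__all__ = [
    "KernelSet",
    "ClusterReport",
    "depth_average",
    "cluster_kernels",
    "silhouette_sweep",
    "cluster_report",
    "render_boards",
]

DEFAULT_K_RANGE = tuple(range(2, 10))


@dataclass
class KernelSet:
    """Depth-averaged 3x3 kernels of one branch."""

    kernels: np.ndarray  # (n, 3, 3)
    branch: str = ""

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=float)
        if k.ndim != 3 or k.shape[1:] != (3, 3):
            raise ValidationError(f"expected (n, 3, 3) kernels, got {k.shape}")
        if not np.all(np.isfinite(k)):
            raise ValidationError("kernels must be finite")
        self.kernels = k

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def flat(self) -> np.ndarray:
        return self.kernels.reshape(len(self.kernels), -1)


@dataclass
class ClusterReport:
    """Clustering assignments, silhouette scores, and normalized cluster means."""

    branch: str
    k_values: tuple[int, ...]
    assignments: dict[int, np.ndarray]
    silhouettes: dict[int, float]
    cluster_means: dict[int, np.ndarray]  # per k: (k, 3, 3), each tile in [0, 1]

    @property
    def best_k(self) -> int:
        return max(self.silhouettes, key=lambda k: (self.silhouettes[k], -k))


def depth_average(kernels_3d: np.ndarray, branch: str = "") -> KernelSet:
    """Average 3x3x3 kernels over depth (and input channels, if present).

    Accepts ``(n, 3, 3, 3)`` or multi-channel ``(n, c, 3, 3, 3)`` arrays; the
    depth axis is the last one, matching the volume (x, y, slice) convention.
    """
    k = np.asarray(kernels_3d, dtype=float)
    if k.ndim == 5 and k.shape[2:] == (3, 3, 3):
        k = k.mean(axis=1)
    if k.ndim != 4 or k.shape[1:] != (3, 3, 3):
        raise ValidationError(f"expected (n, [c,] 3, 3, 3) kernels, got {np.shape(kernels_3d)}")
    return KernelSet(kernels=k.mean(axis=3), branch=branch)


def cluster_kernels(kernel_set: KernelSet, k: int, linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering of the flattened 9-vectors; deterministic."""
    n = len(kernel_set)
    if not (2 <= k <= n):
        raise ValidationError(f"k={k} outside valid range [2, {n}]")
    from sklearn.cluster import AgglomerativeClustering

    model = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage=linkage)
    return model.fit_predict(kernel_set.flat)


def _silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over points (singleton clusters score 0, the convention)."""
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(X, labels, metric="euclidean"))


def silhouette_sweep(
    kernel_set: KernelSet, k_range: Sequence[int] = DEFAULT_K_RANGE, linkage: str = "ward"
) -> dict[int, float]:
    """Mean silhouette of the agglomerative partition at each k."""
    scores = {}
    for k in k_range:
        labels = cluster_kernels(kernel_set, k, linkage=linkage)
        scores[k] = _silhouette(kernel_set.flat, labels)
    return scores


def _normalize_tile(tile: np.ndarray) -> np.ndarray:
    lo, hi = float(tile.min()), float(tile.max())
    if hi > lo:
        return (tile - lo) / (hi - lo)
    return np.full_like(tile, 0.5)  # constant tile -> mid-gray


def cluster_report(
    kernel_set: KernelSet, k_range: Sequence[int] = DEFAULT_K_RANGE, linkage: str = "ward"
) -> ClusterReport:
    """Full sweep: assignments, silhouettes and normalized cluster-mean tiles."""
    assignments, silhouettes, means = {}, {}, {}
    for k in k_range:
        labels = cluster_kernels(kernel_set, k, linkage=linkage)
        assignments[k] = labels
        silhouettes[k] = _silhouette(kernel_set.flat, labels)
        tiles = np.stack(
            [_normalize_tile(kernel_set.kernels[labels == c].mean(axis=0)) for c in range(k)]
        )
        means[k] = tiles
    return ClusterReport(
        branch=kernel_set.branch,
        k_values=tuple(k_range),
        assignments=assignments,
        silhouettes=silhouettes,
        cluster_means=means,
    )


def render_boards(report: ClusterReport, out_dir: str | Path,
                  tile_pixels: int = 32, pad: int = 4) -> Path:
    """Write per-(k, cluster) tiles assembled into a row-per-k grid PNG.

    Values 0..1 map to a white→black gradient, matching the convention that
    dark pixels are large normalized weights.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ks = sorted(report.cluster_means)
    kmax = max(ks)
    height = len(ks) * (tile_pixels + pad) + pad
    width = kmax * (tile_pixels + pad) + pad
    board = np.full((height, width), 1.0)  # white background
    for row, k in enumerate(ks):
        for col in range(k):
            tile = report.cluster_means[k][col]
            big = np.kron(1.0 - tile, np.ones((tile_pixels // 3 + 1, tile_pixels // 3 + 1)))
            big = big[:tile_pixels, :tile_pixels]
            r0 = pad + row * (tile_pixels + pad)
            c0 = pad + col * (tile_pixels + pad)
            board[r0 : r0 + tile_pixels, c0 : c0 + tile_pixels] = big
    fig, ax = plt.subplots(figsize=(width / 40, height / 40))
    ax.imshow(board, cmap="gray", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_yticks([pad + r * (tile_pixels + pad) + tile_pixels / 2 for r in range(len(ks))])
    ax.set_yticklabels([f"k={k}" for k in ks])
    ax.set_xticks([])
    ax.set_title(f"cluster means ({report.branch or 'kernels'})")
    path = out_dir / f"boards_{report.branch or 'kernels'}.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
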