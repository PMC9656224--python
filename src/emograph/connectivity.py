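"""Pairwise mutual-information functional connectivity of EEG channels.

MI is estimated with an equal-width joint-histogram plug-in (default 8 bins
per variable, log base 2) and assembled into a symmetric nonnegative
adjacency matrix per analysis window.  No thresholding is applied: the
connectivity graph stays complete and weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Window

__all__ = ["DEFAULT_BINS", "AdjacencyMatrix", "histogram_mi", "connectivity_matrix"]

DEFAULT_BINS = 8


@dataclass
class AdjacencyMatrix:
    """Symmetric nonnegative weighted graph over EEG channels."""

    weights: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.node_labels = tuple(self.node_labels)
        n = len(self.node_labels)
        if n < 2:
            raise ValueError("adjacency matrix needs >= 2 nodes")
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} node labels"
            )
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def _bin_indices(x: np.ndarray, bins: int) -> np.ndarray | None:
    """Equal-width bin index per sample over [min, max]; None if degenerate."""
    lo = x.min()
    span = x.max() - lo
    if span == 0:
        return None
    idx = ((x - lo) * (bins / span)).astype(np.intp)
    return np.minimum(idx, bins - 1)


def _mi_from_indices(ix: np.ndarray, iy: np.ndarray, bins: int) -> float:
    n = ix.size
    joint = np.bincount(ix * bins + iy, minlength=bins * bins).astype(np.float64)
    joint = joint.reshape(bins, bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = px[:, None] * py[None, :]
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))
    return max(mi, 0.0)


def histogram_mi(x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Plug-in MI estimate in bits over a bins x bins joint histogram.

    Bin edges are equal-width per variable, spanning [min, max]; a constant
    input has a degenerate marginal and yields MI = 0.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if bins < 1:
        raise ValueError("bins must be a positive integer")
    if x.size != y.size or x.size < bins:
        raise ValueError(
            f"inputs must have equal length >= bins ({bins}), "
            f"got {x.size} and {y.size}"
        )
    if x.tobytes() > y.tobytes():
        x, y = y, x  # canonical order: estimate is bitwise symmetric
    ix = _bin_indices(x, bins)
    iy = _bin_indices(y, bins)
    if ix is None or iy is None:
        return 0.0
    return _mi_from_indices(ix, iy, bins)


def connectivity_matrix(window: Window, bins: int = DEFAULT_BINS) -> AdjacencyMatrix:
    """MI between every unordered pair of EEG channels of one window."""
    eeg = np.asarray(window.eeg, dtype=np.float64)
    labels = window.eeg_channels
    n = eeg.shape[0]
    if n < 2:
        raise ValueError("connectivity needs >= 2 EEG channels")
    # bin each channel once, then count joint occupancy per pair
    indices = [_bin_indices(eeg[i], bins) for i in range(n)]
    weights = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        if indices[i] is None:
            continue
        for j in range(i + 1, n):
            if indices[j] is None:
                continue
            try:
                mi = _mi_from_indices(indices[i], indices[j], bins)
            except Exception as exc:  # pragma: no cover - defensive context
                raise RuntimeError(
                    f"MI failed for pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            weights[i, j] = weights[j, i] = mi
    return AdjacencyMatrix(weights=weights, node_labels=labels)
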