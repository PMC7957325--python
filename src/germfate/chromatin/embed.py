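"""Sample-level PCA and element-level batch SOM on accessibility matrices.

PCA operates on the log-transformed, column-centered element x sample
matrix and embeds the *samples*, exposing the stage/cell-type structure
of the accessibility landscape.  The self-organizing map operates on the
additionally row-centered matrix — each element row is then a log-fold
change profile — and quantizes elements onto a small unit grid (3x3 by
default, nine clusters) with a Gaussian neighborhood shrinking over
batch epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import SignalMatrix

__all__ = ["pca_embed", "som_cluster", "SomFit", "PcaResult"]


@dataclass
class PcaResult:
    """Per-sample coordinates from column-centered SVD."""

    coordinates: pd.DataFrame      # samples x components
    variance_explained: np.ndarray
    components: np.ndarray         # element-space loadings, one column each


def pca_embed(sm: SignalMatrix, n_components: int = 2) -> PcaResult:
    """Embed samples by SVD of the column-centered signal matrix."""
    sm.require("log")
    x = sm.values.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)  # idempotent if already centered
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; "
                      "clipping", stacklevel=2)
        n_components = rank
    var = s ** 2
    var_explained = var[:n_components] / var.sum() if var.sum() > 0 else var[:0]
    coords = (vt[:n_components].T * s[:n_components])
    frame = pd.DataFrame(coords, index=sm.values.columns,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return PcaResult(coordinates=frame, variance_explained=var_explained,
                     components=u[:, :n_components])


@dataclass
class SomFit:
    """A fitted self-organizing map over element profiles."""

    grid: tuple[int, int]
    codebook: np.ndarray           # units x features
    assignment: np.ndarray         # element -> unit index (row-major)
    quantization_error: np.ndarray  # per epoch
    seed: int

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    def unit_coords(self) -> np.ndarray:
        r, c = self.grid
        return np.array([(i // c, i % c) for i in range(r * c)], dtype=float)


def som_cluster(sm: SignalMatrix, grid: tuple[int, int] = (3, 3),
                epochs: int = 100, seed: int = 0,
                sigma_start: float | None = None,
                sigma_end: float = 0.25) -> SomFit:
    """Batch SOM of element rows onto a unit grid.

    The codebook is initialized from randomly drawn data rows; each epoch
    assigns every row to its best-matching unit and recomputes every
    unit as the neighborhood-weighted mean of all rows, with the Gaussian
    neighborhood width decaying geometrically from ``sigma_start``
    (default: half the larger grid dimension) to ``sigma_end``.  The
    quantization error (mean Euclidean distance of rows to their BMU) is
    recorded each epoch.
    """
    sm.require("log", "row-centered")
    x = sm.values.to_numpy(dtype=float)
    n, d = x.shape
    rows, cols = grid
    n_units = rows * cols
    if n_units > n:
        raise ValueError(f"grid {grid} has more units than elements ({n})")
    rng = np.random.default_rng(seed)
    codebook = x[rng.choice(n, size=n_units, replace=False)].copy()
    coords = np.array([(i // cols, i % cols) for i in range(n_units)],
                      dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    if sigma_start is None:
        sigma_start = max(rows, cols) / 2.0

    qe = np.empty(epochs)
    assignment = np.zeros(n, dtype=int)
    for t in range(epochs):
        sigma = sigma_start * (sigma_end / sigma_start) ** (t / max(epochs - 1, 1))
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        assignment = d2.argmin(axis=1)
        qe[t] = float(np.sqrt(d2[np.arange(n), assignment]).mean())
        h = np.exp(-grid_d2[:, assignment] / (2 * sigma ** 2))  # units x rows
        denom = h.sum(axis=1, keepdims=True)
        nonempty = denom[:, 0] > 0
        codebook[nonempty] = (h @ x)[nonempty] / denom[nonempty]
    # final assignment against the last codebook
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    assignment = d2.argmin(axis=1)
    return SomFit(grid=grid, codebook=codebook, assignment=assignment,
                  quantization_error=qe, seed=seed)
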