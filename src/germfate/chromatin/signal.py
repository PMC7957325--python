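"""Element x sample accessibility signal matrices and their transforms.

Open-chromatin scores are assigned to candidate elements by summing
extended cut-site signal in a fixed window (default 601 bp) centered on
the element midpoint, divided by the sample's library size.  For PCA the
matrix is log-transformed and column (sample) centered; for SOM an
additional row (element) centering makes the map operate on log-fold
change values.  The transform state is tracked so downstream steps can
assert their preconditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cutsites import CutSiteTrack

__all__ = ["SignalMatrix", "signal_matrix", "log_transform",
           "center_columns", "center_rows"]


@dataclass
class SignalMatrix:
    """Real-valued element x sample matrix with its transform history."""

    values: pd.DataFrame
    window: int
    transforms: tuple[str, ...] = ()
    truncated: np.ndarray | None = None  # elements whose window hit a boundary

    @property
    def state(self) -> str:
        return "raw" if not self.transforms else self.transforms[-1]

    def require(self, *needed: str) -> None:
        for t in needed:
            if t not in self.transforms:
                raise ValueError(f"matrix must be {t} first "
                                 f"(applied: {self.transforms or ('raw',)})")


def signal_matrix(elements: pd.DataFrame,
                  tracks: dict[str, CutSiteTrack],
                  window: int = 601,
                  normalize: bool = True) -> SignalMatrix:
    """Window sums of cut-site signal around element midpoints.

    ``elements`` needs chrom/start/end columns; ``tracks`` maps sample id
    to an (unnormalized) cut-site track, typically built with the short
    5-bp extension.  Windows extending past a chromosome end are
    truncated and flagged.  When ``normalize`` is set each column is
    divided by its track's library size, making the column invariant to
    uniform duplication of the sample's fragments.
    """
    half = window // 2
    mids = ((elements["start"].to_numpy() + elements["end"].to_numpy()) // 2)
    chroms = elements["chrom"].astype(str).to_numpy()
    n = len(elements)
    cols = {}
    truncated = np.zeros(n, dtype=bool)
    for sample, track in tracks.items():
        vals = np.zeros(n)
        for i in range(n):
            cov = track.coverage.get(chroms[i])
            if cov is None:
                continue
            lo = int(mids[i]) - half
            hi = lo + window
            if lo < 0 or hi > len(cov):
                truncated[i] = True
            vals[i] = cov[max(lo, 0):min(hi, len(cov))].sum()
        if normalize:
            vals = vals / track.library_size
        cols[sample] = vals
    idx = elements.index if elements.index.is_unique else pd.RangeIndex(n)
    return SignalMatrix(values=pd.DataFrame(cols, index=idx), window=window,
                        truncated=truncated)


def log_transform(sm: SignalMatrix, scale: float = 1e6,
                  pseudocount: float = 1.0) -> SignalMatrix:
    """log(signal * scale + pseudocount).

    The scale puts library-normalized signal on a per-million basis
    before the log so the pseudocount has a stable meaning.
    """
    if "log" in sm.transforms:
        raise ValueError("matrix already log-transformed")
    return replace(sm, values=np.log(sm.values * scale + pseudocount),
                   transforms=sm.transforms + ("log",))


def center_columns(sm: SignalMatrix) -> SignalMatrix:
    """Subtract each column (sample) mean."""
    return replace(sm, values=sm.values - sm.values.mean(axis=0),
                   transforms=sm.transforms + ("column-centered",))


def center_rows(sm: SignalMatrix) -> SignalMatrix:
    """Subtract each row (element) mean, leaving log-fold-change-like rows."""
    return replace(sm, values=sm.values.sub(sm.values.mean(axis=1), axis=0),
                   transforms=sm.transforms + ("row-centered",))
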