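"""Differential chromatin accessibility between cell types.

Per-element cut-site counts are tested with the same negative-binomial
Wald machinery as the transcriptome counts; a peak is called
differentially accessible only when, in addition to |logFC| > 1 and
padj < 0.05, its fold enrichment over the genomic background exceeds 4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..expression import CountMatrix, DiffResult, differential_counts

__all__ = ["diff_accessibility", "element_counts"]


def element_counts(elements: pd.DataFrame, tracks: dict, window: int | None = None
                   ) -> pd.DataFrame:
    """Integer Tn5 cut-site counts per element per sample.

    Counts cut sites falling in each element's own interval (or in a
    fixed window around its midpoint when ``window`` is given), straight
    from the track's sorted cut positions, so the value is independent
    of the extension the track was built with.
    """
    cols = {}
    chroms = elements["chrom"].astype(str).to_numpy()
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    if window is not None:
        mids = (starts + ends) // 2
        starts = mids - window // 2
        ends = starts + window
    for sample, track in tracks.items():
        if not track.cut_positions:
            raise ValueError("track carries no cut-site positions")
        vals = np.zeros(len(elements), dtype=np.int64)
        for i in range(len(elements)):
            pos = track.cut_positions.get(chroms[i])
            if pos is None:
                continue
            vals[i] = int(np.searchsorted(pos, ends[i])
                          - np.searchsorted(pos, starts[i]))
        cols[sample] = vals
    return pd.DataFrame(cols, index=elements.index)


def diff_accessibility(peak_counts: CountMatrix, group_a, group_b,
                       fold_enrichment: pd.Series | None = None, *,
                       lfc_threshold: float = 1.0,
                       padj_threshold: float = 0.05,
                       fe_threshold: float = 4.0,
                       **kwargs) -> DiffResult:
    """NB Wald test on per-peak counts with a fold-enrichment gate.

    ``fold_enrichment`` (per peak, e.g. from the peak caller) is compared
    against ``fe_threshold``; peaks at or below it are never called
    significant regardless of their p value.
    """
    res = differential_counts(peak_counts, group_a, group_b,
                              lfc_threshold=lfc_threshold,
                              padj_threshold=padj_threshold, **kwargs)
    if fold_enrichment is not None:
        fe = fold_enrichment.reindex(res.table.index)
        res.table["fold_enrichment"] = fe
        res.table["significant"] &= fe.to_numpy() > fe_threshold
        res.fold_enrichment_threshold = fe_threshold
    return res
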