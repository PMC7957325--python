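"""Genomic-feature annotation of elements relative to gene models.

Elements are labelled by their midpoint with precedence
promoter (within 1 kb up- or downstream of a TSS) > exon > intron >
intergenic, and each element also reports the signed distance from its
midpoint to the closest TSS (negative = upstream of that TSS, using the
TSS strand for orientation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["annotate_elements", "tss_distance_ecdf", "PROMOTER_RADIUS"]

PROMOTER_RADIUS = 1000  # bp up- and downstream of the TSS


def _point_in(intervals: pd.DataFrame, chrom: str, pos: int) -> bool:
    g = intervals[intervals["chrom"] == chrom]
    return bool(((g["start"] <= pos) & (pos < g["end"])).any())


def annotate_elements(elements: pd.DataFrame,
                      gene_models: dict,
                      promoter_radius: int = PROMOTER_RADIUS) -> pd.DataFrame:
    """Label elements and measure their distance to the closest TSS.

    ``gene_models`` carries ``tss`` (chrom, pos, strand, gene_id),
    ``exons`` (chrom, start, end, gene_id) and optionally ``genes``
    (chrom, start, end, gene_id; derived from exon spans if absent).
    Empty gene models yield all-intergenic labels with infinite distance.
    """
    tss = gene_models.get("tss", pd.DataFrame(columns=["chrom", "pos",
                                                       "strand", "gene_id"]))
    exons = gene_models.get("exons", pd.DataFrame(columns=["chrom", "start",
                                                           "end", "gene_id"]))
    genes = gene_models.get("genes")
    if genes is None and len(exons):
        genes = (exons.groupby(["gene_id", "chrom"], as_index=False)
                 .agg(start=("start", "min"), end=("end", "max")))
    elif genes is None:
        genes = pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])

    labels = []
    distances = []
    mids = (elements["start"].to_numpy() + elements["end"].to_numpy()) // 2
    chroms = elements["chrom"].astype(str).to_numpy()
    for chrom, mid in zip(chroms, mids):
        t = tss[tss["chrom"] == chrom]
        if len(t) == 0:
            if len(tss) == 0:
                labels.append("intergenic")
                distances.append(np.inf)
                continue
            dist = np.inf
            signed = np.inf
        else:
            delta = mid - t["pos"].to_numpy()
            j = int(np.argmin(np.abs(delta)))
            strand = t["strand"].iloc[j] if "strand" in t.columns else "+"
            signed = int(delta[j]) if strand == "+" else -int(delta[j])
            dist = abs(int(delta[j]))
        if dist <= promoter_radius:
            labels.append("promoter")
        elif _point_in(exons, chrom, mid):
            labels.append("exon")
        elif _point_in(genes, chrom, mid):
            labels.append("intron")
        else:
            labels.append("intergenic")
        distances.append(signed)
    return elements.assign(feature=labels, tss_distance=distances)


def tss_distance_ecdf(annotated: pd.DataFrame) -> pd.DataFrame:
    """Empirical cumulative distribution of |distance to closest TSS|.

    Returns a frame with columns ``distance`` (sorted ascending) and
    ``cumulative_fraction`` rising monotonically from >0 to 1; elements
    with infinite distance (no TSS on their chromosome) are excluded.
    """
    d = np.abs(annotated["tss_distance"].to_numpy(dtype=float))
    d = np.sort(d[np.isfinite(d)])
    frac = np.arange(1, len(d) + 1) / len(d) if len(d) else np.array([])
    return pd.DataFrame({"distance": d, "cumulative_fraction": frac})
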