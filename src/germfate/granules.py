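"""Germ-granule / nucleus contact geometry from labeled cell masks.

During PGC migration the germ granules relocalize from dispersed
cytoplasmic aggregates to a disaggregated perinuclear arrangement.  The
contact-ratio score quantifies this on a segmented cell image: for each
granule, the length of its boundary lying against the nucleus is divided
by the total granule area of the cell, and each granule contributes one
such ratio.  Knockdown of the germ plasm organizer shifts these ratios
down (granules detach and reaggregate), which is tested per condition
against control with a two-sample Wilcoxon rank-sum test.

Masks are integer grids: 0 background, 1 the nucleus, labels >= 2 the
granules.  Areas are pixel counts times spacing^2; perimeters and
contact lengths count exposed pixel edges times spacing, so analytic
shapes give exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["CellGeometry", "ContactResult", "measure_regions",
           "contact_ratio", "compare_groups", "NUCLEUS_LABEL"]

NUCLEUS_LABEL = 1


@dataclass
class CellGeometry:
    """One segmented cell: labeled mask plus physical pixel spacing."""

    mask: np.ndarray
    spacing: float = 1.0
    nucleus_label: int = NUCLEUS_LABEL

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2 or not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("mask must be a 2-D integer grid")
        if (self.mask < 0).any():
            raise ValueError("labels must be non-negative")

    @property
    def granule_labels(self) -> np.ndarray:
        labels = np.unique(self.mask)
        return labels[(labels != 0) & (labels != self.nucleus_label)]


_EDGE_SHIFTS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _exposed_edges(region: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """For each of the 4 directions, the pixels of `region` whose neighbor
    in that direction is outside the region (image border counts as outside).
    Returns (rows, cols) index pairs per direction."""
    out = []
    for dr, dc in _EDGE_SHIFTS:
        shifted = np.zeros_like(region)
        if dr == 1:
            shifted[:-1, :] = region[1:, :]
        elif dr == -1:
            shifted[1:, :] = region[:-1, :]
        elif dc == 1:
            shifted[:, :-1] = region[:, 1:]
        else:
            shifted[:, 1:] = region[:, :-1]
        edge = region & ~shifted
        out.append(np.nonzero(edge))
    return out


def measure_regions(mask: np.ndarray, spacing: float = 1.0) -> pd.DataFrame:
    """Area and perimeter of every labeled region, ordered by label.

    Area is pixel count x spacing^2; perimeter counts exposed pixel edges
    (4-neighborhood, image border exposed) x spacing.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels != 0]
    rows = []
    for lab in labels:
        region = mask == lab
        area = float(region.sum()) * spacing ** 2
        perim = float(sum(len(r) for r, _ in _exposed_edges(region))) * spacing
        rows.append((int(lab), area, perim))
    return pd.DataFrame(rows, columns=["label", "area", "perimeter"])


@dataclass
class ContactResult:
    """Per-granule contact measurements for one cell."""

    per_granule: pd.DataFrame  # label, area, perimeter, contact_length, ratio
    total_granule_area: float
    cell_ratio: float          # sum(contact) / total area, secondary summary
    empty: bool = False
    ratios: list[float] = field(default_factory=list)


def contact_ratio(cell: CellGeometry,
                  adjacency_distance: float = 1.0) -> ContactResult:
    """Score each granule's contact with the nucleus.

    A granule boundary edge counts as contact when the pixel just across
    it lies within ``adjacency_distance`` of the nucleus region (at the
    default of 1 pixel this means the neighboring pixel is nucleus).
    Each granule's ratio divides its contact length by the *total*
    granule area of the cell, so a cell's granules share a denominator.
    """
    mask = cell.mask
    if not (mask == cell.nucleus_label).any():
        raise ValueError("no nucleus region in mask")
    glabels = cell.granule_labels
    if glabels.size == 0:
        empty_frame = pd.DataFrame(columns=["label", "area", "perimeter",
                                            "contact_length", "ratio"])
        return ContactResult(per_granule=empty_frame, total_granule_area=0.0,
                             cell_ratio=float("nan"), empty=True)

    # distance (pixels) from every pixel to the nearest nucleus pixel
    dist = ndimage.distance_transform_edt(mask != cell.nucleus_label)
    measures = measure_regions(mask, spacing=cell.spacing)
    measures = measures[measures["label"].isin(glabels)].reset_index(drop=True)
    total_area = float(measures["area"].sum())

    contact_lengths = []
    for lab in measures["label"]:
        region = mask == lab
        contact = 0
        for (dr, dc), (rr, cc) in zip(_EDGE_SHIFTS, _exposed_edges(region)):
            nr, nc = rr + dr, cc + dc
            inside = (nr >= 0) & (nr < mask.shape[0]) \
                & (nc >= 0) & (nc < mask.shape[1])
            contact += int((dist[nr[inside], nc[inside]]
                            < adjacency_distance).sum())
        contact_lengths.append(contact * cell.spacing)
    measures["contact_length"] = contact_lengths
    measures["ratio"] = measures["contact_length"] / total_area
    return ContactResult(per_granule=measures, total_granule_area=total_area,
                         cell_ratio=float(measures["contact_length"].sum()
                                          / total_area),
                         ratios=[float(r) for r in measures["ratio"]])


def compare_groups(ratios_by_condition: dict[str, np.ndarray],
                   control: str = "control",
                   alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon rank-sum test of each condition's ratios against control.

    Conditions with fewer than 3 observations are flagged untestable
    (p = NaN).  Returns a frame indexed by condition with n, p and a
    significance flag at ``alpha``.
    """
    if control not in ratios_by_condition:
        raise ValueError(f"control condition {control!r} missing")
    ctrl = np.asarray(ratios_by_condition[control], dtype=float)
    rows = []
    for cond, vals in ratios_by_condition.items():
        if cond == control:
            continue
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3 or len(ctrl) < 3:
            rows.append((cond, len(vals), np.nan, False, False))
            continue
        p = float(stats.mannwhitneyu(vals, ctrl, alternative="two-sided").pvalue)
        rows.append((cond, len(vals), p, p < alpha, True))
    return pd.DataFrame(rows, columns=["condition", "n", "pvalue",
                                       "significant", "testable"]) \
        .set_index("condition")
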