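"""Tn5 cut-site extraction from paired-end ATAC fragments.

ATAC-seq reports where the Tn5 transposase inserted, but the transposase
binds as a dimer and duplicates 9 bp of target sequence, so the fragment
endpoints must be corrected to recover the actual insertion points: +5 bp
on the fragment start and -4 bp on the fragment end (0-based half-open
coordinates).  Each corrected cut site is then extended symmetrically by a
fixed number of bases (25 bp for browser-scale signal, giving 51-bp
windows; 5 bp for the PCA/SOM signal matrices) and accumulated into a
base-resolution coverage track.  Duplicate fragments are deliberately kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CutSiteTrack", "prepare_cutsites", "MITO_ALIASES"]

MITO_ALIASES = frozenset({"MT", "chrM", "M", "chrMT", "mito"})

# Tn5 dimer offset correction applied to fragment endpoints
TN5_SHIFT_START = 5
TN5_SHIFT_END = 4


@dataclass
class CutSiteTrack:
    """Base-resolution coverage of extended Tn5 cut sites.

    ``coverage`` maps chromosome name to an integer (or float once
    normalized) array of per-base signal.  ``library_size`` is the number
    of retained cut sites (two per retained fragment).
    """

    coverage: dict[str, np.ndarray]
    extension: int
    library_size: int
    n_fragments_retained: int
    n_fragments_skipped: int = 0
    n_fragments_filtered: int = 0
    normalized: bool = False
    cut_positions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def genome_size(self) -> int:
        return int(sum(len(v) for v in self.coverage.values()))

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.coverage.values()))

    def normalize(self) -> "CutSiteTrack":
        """Return a copy with coverage divided by library size."""
        cov = {c: v / self.library_size for c, v in self.coverage.items()}
        return CutSiteTrack(coverage=cov, extension=self.extension,
                            library_size=self.library_size,
                            n_fragments_retained=self.n_fragments_retained,
                            n_fragments_skipped=self.n_fragments_skipped,
                            n_fragments_filtered=self.n_fragments_filtered,
                            normalized=True, cut_positions=self.cut_positions)


def _is_mito(name: str) -> bool:
    return name in MITO_ALIASES


def cut_sites_for_fragment(start: int, end: int) -> tuple[int, int]:
    """Corrected Tn5 cut sites of one fragment: (start+5, end-4)."""
    return start + TN5_SHIFT_START, end - TN5_SHIFT_END


def prepare_cutsites(fragments: pd.DataFrame,
                     chrom_lengths: dict[str, int],
                     min_mapq: int = 10,
                     extension: int = 25,
                     exclude_mito: bool = True) -> CutSiteTrack:
    """Filter fragments, correct for the Tn5 offset and build a track.

    Parameters
    ----------
    fragments
        Columns ``chrom``, ``start``, ``end`` (0-based half-open), ``mapq``.
    chrom_lengths
        Chromosomes to keep, with their lengths.  Fragments on chromosomes
        absent from this map (unplaced contigs) are dropped; the
        mitochondrial chromosome is excluded by default even if listed.
    min_mapq
        Fragments below this mapping quality are dropped (default 10).
    extension
        Symmetric extension of each cut site; a cut site contributes a
        ``2 * extension + 1`` bp window of coverage.

    Notes
    -----
    Fragments whose corrected end does not exceed their corrected start
    (shorter than 10 bp) are skipped and counted.  Extension windows are
    clipped at chromosome boundaries.  No duplicate removal is performed.
    """
    keep_chroms = {c: int(l) for c, l in chrom_lengths.items()
                   if not (exclude_mito and _is_mito(c))}

    codes, uniques = pd.factorize(fragments["chrom"].astype(str))
    start = fragments["start"].to_numpy(dtype=np.int64)
    end = fragments["end"].to_numpy(dtype=np.int64)
    mapq = fragments["mapq"].to_numpy(dtype=np.int64)

    kept_code = np.array([u in keep_chroms for u in uniques])
    on_kept = kept_code[codes] if len(uniques) else np.zeros(0, bool)
    good_q = mapq >= min_mapq
    selected = on_kept & good_q
    n_filtered = int((~selected).sum())

    c1 = start + TN5_SHIFT_START
    c2 = end - TN5_SHIFT_END
    valid = c2 > c1
    n_skipped = int((selected & ~valid).sum())
    use = selected & valid

    coverage: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    n_retained = 0
    code_of = {u: i for i, u in enumerate(uniques)}
    for c, length in keep_chroms.items():
        if c in code_of:
            m = use & (codes == code_of[c])
        else:
            m = np.zeros(len(codes), dtype=bool)
        cuts = np.concatenate([c1[m], c2[m]])
        cuts = cuts[(cuts >= 0) & (cuts < length)]
        positions[c] = np.sort(cuts)
        point = np.bincount(cuts, minlength=length)
        if extension > 0 and cuts.size:
            # windowed sum of points: cumsum difference, O(length)
            cs = np.concatenate([np.zeros(extension + 1, dtype=np.int64),
                                 np.cumsum(point),
                                 np.full(extension,
                                         int(point.sum()), dtype=np.int64)])
            cov = cs[2 * extension + 1:] - cs[:length]
        else:
            cov = point
        coverage[c] = cov.astype(np.int32)  # per-base pileup stays small
        n_retained += int(m.sum())

    return CutSiteTrack(coverage=coverage, extension=extension,
                        library_size=2 * n_retained,
                        n_fragments_retained=n_retained,
                        n_fragments_skipped=n_skipped,
                        n_fragments_filtered=n_filtered,
                        cut_positions=positions)
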