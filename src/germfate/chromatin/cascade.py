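"""The candidate-enhancer filtering cascade.

Candidate enhancers are open-chromatin elements that are (i) reproducible
between replicates at 5% IDR, (ii) TSS-distal (no part of the element
within 500 bp of any transcript start), and (iii) at most 1 kb wide.
Survivors from all conditions are merged into a union (touching intervals
merge) and the width filter is applied once more to the merged elements.
Every step logs its survivor count per condition so the cascade can be
audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .idr import idr_fit

__all__ = ["ElementSet", "enhancer_cascade", "match_peaks", "merge_intervals"]


@dataclass
class ElementSet:
    """Merged candidate elements plus the per-step cascade log.

    ``elements`` has columns chrom, start, end, conditions (a sorted
    tuple of contributing condition names).  ``cascade_log`` is a list of
    (step, condition, surviving count) records in execution order.
    """

    elements: pd.DataFrame
    cascade_log: list[tuple[str, str, int]] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cascade_log,
                            columns=["step", "condition", "count"])


def match_peaks(rep1: pd.DataFrame, rep2: pd.DataFrame,
                return_unmatched: bool = False):
    """One-to-one overlap matching of peaks between two replicates.

    Peaks overlap when they share at least 1 bp.  Matching is greedy from
    the strongest replicate-1 peak down; among its overlapping,
    still-unmatched replicate-2 peaks the best-scoring one is taken.
    Returns a frame with the union span of each matched pair and both
    scores (columns chrom, start, end, score1, score2); with
    ``return_unmatched`` also the score arrays of peaks unique to each
    replicate.
    """
    rows = []
    un1, un2 = [], []
    rep2_by_chrom = dict(tuple(rep2.groupby("chrom", sort=False)))
    for chrom, g1 in rep1.groupby("chrom", sort=False):
        g2 = rep2_by_chrom.pop(chrom, None)
        if g2 is None:
            un1.extend(g1["score"].tolist())
            continue
        s2 = g2["start"].to_numpy()
        e2 = g2["end"].to_numpy()
        sc2 = g2["score"].to_numpy()
        taken = np.zeros(len(g2), dtype=bool)
        order = np.argsort(-g1["score"].to_numpy(), kind="stable")
        for i in order:
            p = g1.iloc[i]
            ov = (s2 < p["end"]) & (e2 > p["start"]) & ~taken
            if not ov.any():
                un1.append(float(p["score"]))
                continue
            cand = np.flatnonzero(ov)
            j = cand[np.argmax(sc2[cand])]
            taken[j] = True
            rows.append((chrom,
                         int(min(p["start"], s2[j])),
                         int(max(p["end"], e2[j])),
                         float(p["score"]), float(sc2[j])))
        un2.extend(sc2[~taken].tolist())
    for g2 in rep2_by_chrom.values():
        un2.extend(g2["score"].tolist())
    matched = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                          "score1", "score2"])
    if return_unmatched:
        return matched, np.asarray(un1), np.asarray(un2)
    return matched


def merge_intervals(df: pd.DataFrame, bookended: bool = True) -> pd.DataFrame:
    """Merge overlapping (and, by default, touching) intervals per chrom.

    Returns chrom, start, end plus, if a ``condition`` column is present,
    a ``conditions`` column holding the sorted tuple of contributors.
    """
    has_cond = "condition" in df.columns
    rows = []
    for chrom, g in df.sort_values(["chrom", "start"]).groupby("chrom",
                                                               sort=False):
        cur_s = cur_e = None
        conds: set = set()
        for r in g.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
                conds = {r.condition} if has_cond else set()
                continue
            joins = r.start <= cur_e if bookended else r.start < cur_e
            if joins:
                cur_e = max(cur_e, r.end)
                if has_cond:
                    conds.add(r.condition)
            else:
                rows.append((chrom, cur_s, cur_e, tuple(sorted(conds))))
                cur_s, cur_e = r.start, r.end
                conds = {r.condition} if has_cond else set()
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, tuple(sorted(conds))))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "conditions"])
    if not has_cond:
        out = out.drop(columns="conditions")
    return out


def _tss_distal(df: pd.DataFrame, tss: pd.DataFrame, exclusion: int) -> np.ndarray:
    """Mask of elements with no part within `exclusion` bp (inclusive) of a TSS."""
    keep = np.ones(len(df), dtype=bool)
    for i, r in enumerate(df.itertuples(index=False)):
        pos = tss.loc[tss["chrom"] == r.chrom, "pos"].to_numpy()
        if pos.size == 0:
            continue
        # distance from the interval [start, end) to the point
        d = np.where(pos < r.start, r.start - pos,
                     np.where(pos >= r.end, pos - (r.end - 1), 0))
        if (d <= exclusion).any():
            keep[i] = False
    return keep


def enhancer_cascade(peaksets: dict[str, list[pd.DataFrame]],
                     tss: pd.DataFrame,
                     idr_threshold: float = 0.05,
                     tss_exclusion: int = 500,
                     max_width: int = 1000,
                     min_peaks_for_idr: int = 20) -> ElementSet:
    """Run the full candidate-enhancer cascade.

    Parameters
    ----------
    peaksets
        Condition name -> [replicate-1 peaks, replicate-2 peaks]; each
        peak frame needs chrom, start, end, score columns.
    tss
        Transcript starts with chrom and pos columns.
    idr_threshold
        Global IDR cut for reproducibility (default 5%).
    tss_exclusion
        Drop elements any part of which lies within this many bp
        (inclusive) of a TSS.
    max_width
        Maximum element width, applied per condition and again after the
        union merge.
    min_peaks_for_idr
        Below this many matched pairs the copula mixture is not
        identifiable; all overlap-matched pairs are then kept as
        reproducible (logged as step ``idr`` all the same).
    """
    surviving = []
    log: list[tuple[str, str, int]] = []
    for cond, reps in peaksets.items():
        if len(reps) != 2:
            raise ValueError(f"condition {cond!r} needs exactly 2 replicates")
        matched, un1, un2 = match_peaks(reps[0], reps[1],
                                        return_unmatched=True)
        log.append(("matched", cond, len(matched)))
        n_total = len(matched) + len(un1) + len(un2)
        if len(matched) >= min_peaks_for_idr and len(un1) + len(un2) > 0:
            # the mixture needs an irreproducible component to identify:
            # peaks unique to one replicate enter with a floor pseudo
            # score in the other (the usual IDR convention), and only
            # matched pairs can pass
            floor1 = float(reps[0]["score"].min()) if len(reps[0]) else 0.0
            floor2 = float(reps[1]["score"].min()) if len(reps[1]) else 0.0
            s1 = np.concatenate([matched["score1"].to_numpy(), un1,
                                 np.full(len(un2), floor1 - 1.0)])
            s2 = np.concatenate([matched["score2"].to_numpy(),
                                 np.full(len(un1), floor2 - 1.0), un2])
            model = idr_fit(s1, s2)
            repro = matched[model.passing(idr_threshold)[:len(matched)]]
        else:
            # nothing irreproducible to discover (or too few peaks for
            # the copula fit): every overlap-matched pair is kept
            repro = matched
        log.append(("idr", cond, len(repro)))
        distal = repro[_tss_distal(repro, tss, tss_exclusion)]
        log.append(("tss_distance", cond, len(distal)))
        narrow = distal[(distal["end"] - distal["start"]) <= max_width]
        log.append(("width", cond, len(narrow)))
        surviving.append(narrow.assign(condition=cond))

    pooled = pd.concat(surviving, ignore_index=True) if surviving \
        else pd.DataFrame(columns=["chrom", "start", "end", "condition"])
    union = merge_intervals(pooled, bookended=True)
    log.append(("union", "all", len(union)))
    final = union[(union["end"] - union["start"]) <= max_width] \
        .reset_index(drop=True)
    log.append(("final_width", "all", len(final)))
    return ElementSet(elements=final, cascade_log=log)
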