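"""CpG methylation summaries from bisulfite coverage tables.

Input is the bismark coverage dialect (chrom, start, end, percent
methylated, count methylated, count unmethylated), one file or frame per
sample.  CpGs below a minimum coverage (default 6 reads, the extraction
cutoff used for RRBS) are dropped up front.  Region-level methylation is
the coverage-weighted mean fraction over the CpGs a region contains.
Per-CpG differential methylation between two groups pools replicate
counts within each group and applies a two-sided Fisher exact test to
the 2x2 methylated/unmethylated x group table, with BH correction; a CpG
is differential when q < 0.01 and the methylation difference is at least
25 percentage points, and the headline statistic is the fraction of
matched CpGs that are differential.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParseError

__all__ = ["read_bismark_cov", "load_filter_cpgs", "region_methylation",
           "differential_cpgs", "write_bismark_cov"]

BISMARK_COLUMNS = ["chrom", "start", "end", "percent", "meth", "unmeth"]


def read_bismark_cov(path) -> pd.DataFrame:
    """Parse a bismark-coverage-dialect file, reporting bad lines by number."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"expected 6 tab-separated fields, "
                                 f"got {len(parts)}", line=ln)
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             float(parts[3]), int(parts[4]), int(parts[5])))
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=ln) from exc
    return pd.DataFrame(rows, columns=BISMARK_COLUMNS)


def write_bismark_cov(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "percent" not in out.columns:
        cov = out["meth"] + out["unmeth"]
        out["percent"] = np.where(cov > 0, 100.0 * out["meth"] / cov, 0.0)
    out[BISMARK_COLUMNS].to_csv(path, sep="\t", header=False, index=False,
                                float_format="%.6g")


def load_filter_cpgs(source, min_coverage: int = 6,
                     percent_tolerance: float = 0.5) -> pd.DataFrame:
    """Load a CpG table and drop low-coverage sites.

    ``source`` is a path or an already-parsed DataFrame.  The percent
    column is recomputed from the counts; a discrepancy beyond
    ``percent_tolerance`` points triggers a warning (the counts win).
    """
    df = source.copy() if isinstance(source, pd.DataFrame) \
        else read_bismark_cov(source)
    cov = df["meth"] + df["unmeth"]
    df = df[cov >= min_coverage].copy()
    cov = df["meth"] + df["unmeth"]
    recomputed = 100.0 * df["meth"] / cov
    if "percent" in df.columns:
        off = (recomputed - df["percent"]).abs() > percent_tolerance
        if off.any():
            warnings.warn(f"{int(off.sum())} CpG(s) with percent field "
                          f"off by > {percent_tolerance} points; "
                          "recomputed from counts", stacklevel=2)
    df["percent"] = recomputed
    return df.reset_index(drop=True)


def region_methylation(cpgs: pd.DataFrame, regions: pd.DataFrame,
                       sample_col: str = "sample") -> pd.DataFrame:
    """Coverage-weighted mean methylation fraction per region per sample.

    ``regions`` needs chrom/start/end and an index of region ids.
    Regions without any covered CpG in a sample are NaN there; regions
    with no CpGs in any sample are dropped entirely.
    """
    has_sample = sample_col in cpgs.columns
    samples = cpgs[sample_col].unique() if has_sample else ["all"]
    out = pd.DataFrame(index=regions.index, columns=samples, dtype=float)
    for rid, reg in regions.iterrows():
        sel = cpgs[(cpgs["chrom"] == reg["chrom"])
                   & (cpgs["start"] >= reg["start"])
                   & (cpgs["start"] < reg["end"])]
        for s in samples:
            sub = sel[sel[sample_col] == s] if has_sample else sel
            cov = (sub["meth"] + sub["unmeth"]).sum()
            if cov > 0:
                out.loc[rid, s] = sub["meth"].sum() / cov
    return out.dropna(how="all")


@lru_cache(maxsize=100_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def differential_cpgs(group_a: pd.DataFrame, group_b: pd.DataFrame,
                      q_threshold: float = 0.01,
                      min_diff: float = 25.0) -> tuple[pd.DataFrame, float]:
    """Per-CpG Fisher exact test between two pooled groups.

    Replicate tables within each group are pooled by position before
    testing.  Returns the per-CpG table (difference in percentage
    points B - A, p, q, differential flag) and the differential fraction
    n_differential / n_matched.

    Raises
    ------
    ValueError
        If no CpG position is covered in both groups.
    """
    def pool(df):
        return df.groupby(["chrom", "start"], as_index=True)[["meth", "unmeth"]] \
            .sum()

    a = pool(group_a)
    b = pool(group_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no CpG matched by position across groups")
    a, b = a.loc[common], b.loc[common]

    pa = 100.0 * a["meth"] / (a["meth"] + a["unmeth"])
    pb = 100.0 * b["meth"] / (b["meth"] + b["unmeth"])
    diff = (pb - pa).to_numpy()
    pvals = np.array([
        _fisher_p(int(am), int(au), int(bm), int(bu))
        for am, au, bm, bu in zip(a["meth"], a["unmeth"], b["meth"], b["unmeth"])
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    flag = (qvals < q_threshold) & (np.abs(diff) >= min_diff)
    table = pd.DataFrame({"difference": diff, "pvalue": pvals, "qvalue": qvals,
                          "differential": flag}, index=common)
    return table, float(flag.mean())
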