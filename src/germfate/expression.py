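"""Count normalization, TPM, zygotic-gene classification, ERCC absolute
quantification and a simplified negative-binomial differential test.

The transcriptome side of the pipeline works on gene-level count tables
from FACS-sorted primordial germ cells (PGCs) and somatic cells sampled
across early zebrafish development.  Three small models live here:

* median-of-ratios size factors (the DESeq-style pseudo-reference), used
  to put libraries of different depth on a common scale;
* the zygotic-gene rule: a gene is called zygotic when it is essentially
  absent before genome activation (< 2 TPM at the first stage) and rises
  at the next stage;
* ERCC spike-in calibration: ordinary least squares of log10 RPKM on
  log10 known concentration, inverted to estimate absolute RNA amounts.

The differential test is a deliberately simple stand-in for a full
shrinkage-based GLM: a per-feature Wald test under a negative-binomial
model with a single moment-matched dispersion shared across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    InsufficientDataError,
    NoReferenceError,
    UndefinedTPMError,
)

__all__ = [
    "CountMatrix",
    "SizeFactors",
    "ErccFit",
    "DiffResult",
    "size_factors",
    "normalized_counts",
    "tpm",
    "rpkm",
    "classify_zygotic",
    "ercc_calibrate",
    "differential_counts",
]


@dataclass
class CountMatrix:
    """Integer feature x sample counts with feature lengths and sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, features as rows, samples as columns.
    lengths
        Feature lengths in bp, indexed like ``counts``.
    samples
        Per-sample metadata with at least ``cell_type``, ``stage`` and
        ``replicate`` columns, indexed by sample id.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every feature needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in ("cell_type", "stage", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)],
            self.lengths,
            self.samples.loc[list(sample_ids)],
        )


@dataclass
class SizeFactors:
    """Per-sample positive scale factors with geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")

    def __getitem__(self, sample):
        return self.factors[sample]


def size_factors(counts: CountMatrix | pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors against the per-feature geometric mean.

    Only features with a nonzero count in *every* sample contribute to the
    pseudo-reference; all samples are normalized regardless.  Factors are
    rescaled so that their geometric mean is exactly 1.

    Raises
    ------
    NoReferenceError
        If no feature is nonzero in every sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    usable = (x > 0).all(axis=1)
    if not usable.any():
        raise NoReferenceError(
            "no feature has nonzero counts in all samples; "
            "cannot build the geometric-mean reference"
        )
    logx = np.log(x[usable])
    ref = logx.mean(axis=1)  # log geometric mean per feature
    log_ratios = logx - ref[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return SizeFactors(pd.Series(factors, index=mat.columns, name="size_factor"))


def normalized_counts(counts: CountMatrix | pd.DataFrame,
                      factors: SizeFactors | None = None) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(mat)
    return mat / factors.factors


def tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million.  Each column sums to 1e6.

    Raises
    ------
    UndefinedTPMError
        If a sample has zero total counts.
    """
    rate = counts.counts.div(counts.lengths / 1e3, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise UndefinedTPMError(f"all-zero sample column(s): {bad}")
    return rate.div(totals, axis=1) * 1e6


def rpkm(counts: pd.DataFrame | pd.Series, lengths: pd.Series,
         total_reads: pd.Series | float | None = None):
    """Reads per kilobase per million mapped reads.

    ``total_reads`` defaults to the column sums of ``counts`` (i.e. the
    denominator includes every feature in the table, spike-ins included).
    """
    if total_reads is None:
        total_reads = counts.sum(axis=0) if isinstance(counts, pd.DataFrame) \
            else counts.sum()
    per_kb = counts.div(lengths / 1e3, axis=0) if isinstance(counts, pd.DataFrame) \
        else counts / (lengths / 1e3)
    return per_kb / (total_reads / 1e6)


def classify_zygotic(tpm_by_stage: pd.DataFrame, stage_order: list[str],
                     tpm_threshold: float = 2.0) -> pd.Series:
    """Classify genes as zygotic vs not_zygotic from a per-stage TPM table.

    A gene is zygotic when its TPM at the first (pre-activation) stage is
    strictly below ``tpm_threshold`` and its TPM strictly increases at the
    second stage.  Ties count as no increase.  Stages beyond the second are
    ignored.
    """
    if len(stage_order) < 2:
        raise ValueError("need at least two ordered stages")
    for s in stage_order[:2]:
        if s not in tpm_by_stage.columns:
            raise ValueError(f"stage {s!r} missing from TPM table")
    s1, s2 = stage_order[0], stage_order[1]
    zyg = (tpm_by_stage[s1] < tpm_threshold) & (tpm_by_stage[s2] > tpm_by_stage[s1])
    return zyg.map({True: "zygotic", False: "not_zygotic"}).rename("zygotic_class")


@dataclass
class ErccFit:
    """Log-log linear calibration of spike-in RPKM against concentration.

    Fitted as ``y = a + b X`` with ``X = log10(concentration, attomoles/uL)``
    and ``y = log10(RPKM)`` on spike-ins with RPKM >= the retention cutoff.
    """

    intercept: float
    slope: float
    n_used: int
    rpkm_cutoff: float = 1.0

    def predict_log_rpkm(self, concentration) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(concentration, float))

    def predict_concentration(self, rpkm_values) -> np.ndarray:
        """Invert the calibration: estimated attomoles/uL for observed RPKM."""
        y = np.log10(np.asarray(rpkm_values, dtype=float))
        return 10.0 ** ((y - self.intercept) / self.slope)


def ercc_calibrate(concentration, observed_rpkm,
                   rpkm_cutoff: float = 1.0) -> ErccFit:
    """OLS calibration of observed spike-in RPKM on known concentration.

    Spike-ins with RPKM below ``rpkm_cutoff`` are discarded before fitting.

    Raises
    ------
    InsufficientDataError
        If fewer than two spike-ins survive the cutoff.
    """
    conc = np.asarray(concentration, dtype=float)
    obs = np.asarray(observed_rpkm, dtype=float)
    if conc.shape != obs.shape:
        raise ValueError("concentration and rpkm must align")
    keep = obs >= rpkm_cutoff
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"only {int(keep.sum())} spike-in(s) with rpkm >= {rpkm_cutoff}"
        )
    x = np.log10(conc[keep])
    y = np.log10(obs[keep])
    design = np.column_stack([np.ones_like(x), x])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    return ErccFit(intercept=float(a), slope=float(b),
                   n_used=int(keep.sum()), rpkm_cutoff=rpkm_cutoff)


@dataclass
class DiffResult:
    """Per-feature differential statistics between two sample groups."""

    table: pd.DataFrame  # log2fc, pvalue, padj, mean_a, mean_b, significant
    lfc_threshold: float
    padj_threshold: float
    dispersion: float
    fold_enrichment_threshold: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _common_dispersion(norm: np.ndarray, groups: list[np.ndarray],
                       inv_sf_mean: float) -> float:
    """Moment-matched NB dispersion pooled across features.

    For normalized counts X = K/s with K ~ NB(mean q*s, var mu + a*mu^2),
    Var(X) = q/s + a*q^2, so the pooled within-group sample variance has
    expectation q*c + a*q^2 with c = mean(1/s).  The shared dispersion is
    the through-origin least-squares slope of (var - q*c) on q^2, which is
    robust to the per-feature noise that makes individual estimates
    useless at n of 2-3 per group.
    """
    var_parts = []
    dof = 0
    for g in groups:
        sub = norm[:, g]
        var_parts.append(sub.var(axis=1, ddof=1) * (len(g) - 1))
        dof += len(g) - 1
    pooled_var = np.sum(var_parts, axis=0) / dof
    q = np.mean([norm[:, g].mean(axis=1) for g in groups], axis=0)
    ok = q > 0
    resid = pooled_var[ok] - q[ok] * inv_sf_mean
    alpha = float(np.sum(resid * q[ok] ** 2) / np.sum(q[ok] ** 4))
    return max(alpha, 1e-8)


def differential_counts(counts: CountMatrix, group_a, group_b, *,
                        lfc_threshold: float = 1.0,
                        padj_threshold: float = 0.05,
                        pseudocount: float = 0.5,
                        dispersion: float | None = None) -> DiffResult:
    """Negative-binomial Wald test of group B against group A.

    Counts are normalized by median-of-ratios size factors computed on the
    union of the two groups; the fold change is
    ``log2((mean_b + pc) / (mean_a + pc))`` with pseudocount ``pc``; the
    Wald variance uses a single moment-based dispersion shared across
    features (pass ``dispersion`` to override); p values are adjusted by
    Benjamini-Hochberg.  A feature is significant when ``|log2fc|`` exceeds
    ``lfc_threshold`` and ``padj`` is below ``padj_threshold``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientDataError("need >= 2 samples per group")

    sub = counts.subset_samples(group_a + group_b)
    sf = size_factors(sub)
    s = sf.factors.to_numpy()
    norm = (sub.counts.to_numpy(dtype=float) / s)
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(group_a) + len(group_b))

    inv_s = 1.0 / s
    if dispersion is None:
        dispersion = _common_dispersion(norm, [ia, ib], float(inv_s.mean()))

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    def group_var(mean_q, idx):
        # Var(mean of K_j/s_j) with K_j ~ NB(q s_j, q s_j + a (q s_j)^2)
        q = np.maximum(mean_q, pseudocount)
        per_sample = q[:, None] * inv_s[None, idx] + dispersion * q[:, None] ** 2
        return per_sample.sum(axis=1) / len(idx) ** 2

    va = group_var(mean_a, ia)
    vb = group_var(mean_b, ib)
    # delta method onto the log2 scale
    ln2 = np.log(2.0)
    se = np.sqrt(va / np.maximum(mean_a + pseudocount, 1e-12) ** 2
                 + vb / np.maximum(mean_b + pseudocount, 1e-12) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvalue, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "significant": (np.abs(log2fc) > lfc_threshold)
            & (padj < padj_threshold),
        },
        index=sub.counts.index,
    )
    return DiffResult(table=table, lfc_threshold=lfc_threshold,
                      padj_threshold=padj_threshold, dispersion=float(dispersion))
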