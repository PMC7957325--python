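"""Readers and writers for the plain-text formats the pipeline speaks:
count TSVs, intron tables, BED6 fragment files (MAPQ in the score
column), narrowPeak, GTF gene models, and integer mask grids."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "write_counts", "read_counts", "write_samples", "read_samples",
    "write_introns", "read_introns",
    "write_fragments_bed", "read_fragments_bed",
    "write_narrowpeak", "read_narrowpeak",
    "read_gtf_models", "write_gtf_models",
    "write_mask", "read_mask",
]


def write_counts(cm: CountMatrix, path) -> None:
    """Counts TSV: feature, length, then one column per sample."""
    out = pd.concat([cm.lengths.rename("length"), cm.counts], axis=1)
    out.to_csv(path, sep="\t", index_label="feature")


def write_samples(cm: CountMatrix, path) -> None:
    cm.samples.to_csv(path, sep="\t", index_label="sample")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def read_counts(path, samples: pd.DataFrame | str | None = None) -> CountMatrix:
    """Read a counts TSV; sample metadata from a frame, a path, or parsed
    from ``celltype_stage_repN`` sample ids."""
    df = pd.read_csv(path, sep="\t", index_col="feature")
    lengths = df.pop("length")
    if isinstance(samples, (str, bytes)) or hasattr(samples, "__fspath__"):
        samples = read_samples(samples)
    if samples is None:
        samples = parse_sample_ids(df.columns)
    return CountMatrix(df, lengths, samples)


_SAMPLE_RE = re.compile(r"^(?P<cell_type>[^_]+)_(?P<stage>.+)_rep(?P<rep>\d+)$")


def parse_sample_ids(ids) -> pd.DataFrame:
    rows = []
    for sid in ids:
        m = _SAMPLE_RE.match(sid)
        if not m:
            raise ValueError(f"cannot parse sample id {sid!r}; provide a "
                             "sample metadata table")
        rows.append((sid, m["cell_type"], m["stage"], int(m["rep"])))
    return pd.DataFrame(rows, columns=["sample", "cell_type", "stage",
                                       "replicate"]).set_index("sample")


INTRON_COLUMNS = ["gene", "intron", "depth", "ss5", "ss3", "sample"]


def write_introns(df: pd.DataFrame, path) -> None:
    df[INTRON_COLUMNS].to_csv(path, sep="\t", index=False)


def read_introns(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})


def write_fragments_bed(frag: pd.DataFrame, path) -> None:
    """BED6 with the fragment's MAPQ in the score column."""
    out = pd.DataFrame({
        "chrom": frag["chrom"], "start": frag["start"], "end": frag["end"],
        "name": [f"frag_{i}" for i in range(len(frag))],
        "score": frag["mapq"], "strand": "+"})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand"],
                     dtype={"chrom": str})
    return pd.DataFrame({"chrom": df["chrom"], "start": df["start"],
                         "end": df["end"], "mapq": df["score"]})


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """ENCODE narrowPeak: summit goes into the 10th (peak offset) column."""
    out = pd.DataFrame({
        "chrom": peaks["chrom"], "start": peaks["start"], "end": peaks["end"],
        "name": [f"peak_{i}" for i in range(len(peaks))],
        "score": np.minimum(peaks["score"] * 10, 1000).astype(int),
        "strand": ".",
        "signalValue": peaks["fold_enrichment"],
        "pValue": peaks["score"],
        "qValue": -1,
        "peak": peaks["summit"] - peaks["start"]})
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format="%.6g")


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "signalValue", "pValue", "qValue",
                            "peak"],
                     dtype={"chrom": str})
    return pd.DataFrame({"chrom": df["chrom"], "start": df["start"],
                         "end": df["end"],
                         "summit": df["start"] + df["peak"],
                         "score": df["pValue"],
                         "fold_enrichment": df["signalValue"]})


_GTF_ATTR = re.compile(r'gene_id "([^"]+)"')


def read_gtf_models(path) -> dict[str, pd.DataFrame]:
    """Extract TSS and exon tables from a GTF.

    The TSS of a transcript/gene feature is its start for + strand and
    its end - 1 for - strand (GTF is 1-based inclusive; output is
    0-based).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "source", "feature", "start", "end",
                            "score", "strand", "frame", "attributes"],
                     dtype={"chrom": str})
    df["gene_id"] = df["attributes"].str.extract(_GTF_ATTR)
    exons = df[df["feature"] == "exon"]
    exons = pd.DataFrame({"chrom": exons["chrom"],
                          "start": exons["start"] - 1, "end": exons["end"],
                          "gene_id": exons["gene_id"]})
    tx = df[df["feature"].isin(["transcript", "gene"])]
    if tx.empty:  # derive transcript spans from exons
        tx = df[df["feature"] == "exon"].groupby("gene_id", as_index=False) \
            .agg(chrom=("chrom", "first"), start=("start", "min"),
                 end=("end", "max"), strand=("strand", "first"))
    pos = np.where(tx["strand"] == "-", tx["end"] - 1, tx["start"] - 1)
    tss = pd.DataFrame({"chrom": tx["chrom"].to_numpy(), "pos": pos,
                        "strand": tx["strand"].to_numpy(),
                        "gene_id": tx["gene_id"].to_numpy()}) \
        .drop_duplicates(ignore_index=True)
    return {"tss": tss, "exons": exons.reset_index(drop=True)}


def write_gtf_models(models: dict[str, pd.DataFrame], path) -> None:
    """Serialize synthetic gene models as a minimal GTF."""
    with open(path, "w") as fh:
        tss = models["tss"].set_index("gene_id")
        exons = models["exons"]
        for gid, g in exons.groupby("gene_id"):
            strand = tss.loc[gid, "strand"]
            start, end = int(g["start"].min()), int(g["end"].max())
            attrs = f'gene_id "{gid}";'
            fh.write(f"{g['chrom'].iloc[0]}\tgermfate\ttranscript\t"
                     f"{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")
            for r in g.itertuples(index=False):
                fh.write(f"{r.chrom}\tgermfate\texon\t{r.start + 1}\t{r.end}"
                         f"\t.\t{strand}\t.\t{attrs}\n")


def write_mask(mask: np.ndarray, path) -> None:
    """Integer grid as whitespace-separated text rows."""
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def read_mask(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int)
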