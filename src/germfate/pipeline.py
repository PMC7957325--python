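"""End-to-end driver: simulate the study design, run every analysis
stage on the synthetic outputs, write intermediates in their standard
formats, and summarize truth-recovery metrics in a structured report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, io
from .config import AnalysisParams, RunConfig
from .expression import (CountMatrix, classify_zygotic, differential_counts,
                         ercc_calibrate, rpkm, size_factors, tpm)
from .granules import compare_groups, contact_ratio
from .introns import gene_ir, ir_permutation_test
from .methylation import (differential_cpgs, load_filter_cpgs,
                          region_methylation, write_bismark_cov)
from .synthdata import (SimConfig, gen_atac, gen_expression, gen_gene_models,
                        gen_granule_masks, gen_introns, gen_methylation)

__all__ = ["run_end_to_end", "RunReport"]

log = logging.getLogger("germfate")

RunReport = dict  # serialized as JSON; see run_end_to_end


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_end_to_end(config: RunConfig | SimConfig | None = None,
                   outdir: str | Path | None = None,
                   seed: int | None = None) -> RunReport:
    """Run simulate -> expression -> intron retention -> chromatin ->
    methylation -> granules and return the report dictionary.

    A stage that raises marks itself failed in the report; stages that
    depend on it are skipped.  The same config and seed reproduce the
    report bit for bit.
    """
    if config is None:
        config = RunConfig()
    elif isinstance(config, SimConfig):
        config = RunConfig(simulation=config)
    sim = config.simulation
    ap = config.analysis
    if seed is not None:
        sim = SimConfig(**{**sim.__dict__, "seed": seed})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    report: RunReport = {
        "seed": sim.seed,
        "config": {
            "n_genes": sim.n_genes, "n_elements": sim.n_elements,
            "stages": list(sim.stages), "cell_types": list(sim.cell_types),
            "n_replicates": sim.n_replicates,
            "nb_dispersion": sim.nb_dispersion,
            "library_size": sim.library_size,
        },
        "constants": {
            "tpm_threshold": ap.tpm_threshold,
            "tss_exclusion_bp": ap.tss_exclusion,
            "max_element_width_bp": ap.max_element_width,
            "signal_window_bp": ap.signal_window,
            "idr_threshold": ap.idr_threshold,
            "n_permutations": ap.n_permutations,
            "lfc_threshold": ap.lfc_threshold,
            "padj_threshold": ap.padj_threshold,
            "fold_enrichment_threshold": ap.fold_enrichment_threshold,
            "min_cpg_coverage": ap.min_cpg_coverage,
        },
        "stages": {},
    }

    state: dict = {}
    failed = False
    for name, fn in [("simulate", _stage_simulate),
                     ("expression", _stage_expression),
                     ("intron_retention", _stage_ir),
                     ("chromatin", _stage_chromatin),
                     ("methylation", _stage_methylation),
                     ("granules", _stage_granules)]:
        if failed:
            report["stages"][name] = {"status": "skipped"}
            continue
        try:
            log.info("stage %s: start (seed=%d)", name, sim.seed)
            result = fn(sim, ap, state, outdir)
            report["stages"][name] = {"status": "ok", **_jsonable(result)}
        except Exception as exc:  # noqa: BLE001 - report and stop
            log.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            failed = True
    report["ok"] = all(s.get("status") == "ok"
                       for s in report["stages"].values())
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _stage_simulate(sim: SimConfig, ap: AnalysisParams, state: dict,
                    outdir: Path | None) -> dict:
    counts, truth = gen_expression(sim)
    introns = gen_introns(sim, truth)
    fragments, elements, truth = gen_atac(sim, truth)
    cpgs, regions, truth = gen_methylation(sim, truth)
    masks = gen_granule_masks(sim)
    models = gen_gene_models(sim)
    state.update(counts=counts, truth=truth, introns=introns,
                 fragments=fragments, elements=elements, cpgs=cpgs,
                 regions=regions, masks=masks, models=models)
    if outdir is not None:
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_samples(counts, outdir / "samples.tsv")
        io.write_introns(introns, outdir / "introns.tsv")
        frag_dir = outdir / "fragments"
        frag_dir.mkdir(exist_ok=True)
        for sid, frag in fragments.items():
            io.write_fragments_bed(frag, frag_dir / f"{sid}.bed")
        meth_dir = outdir / "methylation"
        meth_dir.mkdir(exist_ok=True)
        for sid, sub in cpgs.groupby("sample"):
            write_bismark_cov(sub, meth_dir / f"{sid}.cov")
        io.write_gtf_models(models, outdir / "gene_models.gtf")
        mask_dir = outdir / "masks"
        mask_dir.mkdir(exist_ok=True)
        for cond, cells in masks.items():
            for i, (cell, _exp) in enumerate(cells):
                io.write_mask(cell.mask, mask_dir / f"{cond}_{i:03d}.txt")
    return {"n_genes": sim.n_genes, "n_atac_samples": len(fragments),
            "n_elements": len(elements), "n_cpg_records": len(cpgs)}


def _stage_expression(sim: SimConfig, ap: AnalysisParams, state: dict,
                      outdir: Path | None) -> dict:
    counts = state["counts"]
    truth = state["truth"]
    sf = size_factors(counts)
    tpms = tpm(counts)

    pgc = counts.samples[counts.samples["cell_type"] == "PGC"]
    stage_tpm = pd.DataFrame({
        st: tpms[pgc.index[pgc["stage"] == st]].mean(axis=1)
        for st in sim.stages})
    calls = classify_zygotic(stage_tpm, list(sim.stages), ap.tpm_threshold)
    calls = calls.loc[truth.gene_class.index]
    is_zyg = truth.gene_class == "zygotic"
    called = calls == "zygotic"
    sensitivity = float(called[is_zyg].mean())
    fpr = float(called[~is_zyg].mean())

    # ERCC calibration on the first sample
    sample0 = counts.counts.columns[0]
    ercc_ids = [f for f in counts.features if f.startswith("ERCC-")]
    rp = rpkm(counts.counts[sample0], counts.lengths)
    fit = ercc_calibrate([sim.ercc_concentrations[e] for e in ercc_ids],
                         rp.loc[ercc_ids], ap.ercc_rpkm_cutoff)

    last = sim.stages[-1]
    meta = counts.samples
    ga = list(meta.index[(meta["cell_type"] == "soma") & (meta["stage"] == last)])
    gb = list(meta.index[(meta["cell_type"] == "PGC") & (meta["stage"] == last)])
    de = differential_counts(counts, ga, gb, lfc_threshold=ap.lfc_threshold,
                             padj_threshold=ap.padj_threshold)
    state.update(tpms=tpms, de=de)
    return {
        "size_factor_range": [float(sf.factors.min()), float(sf.factors.max())],
        "zygotic_sensitivity": sensitivity,
        "zygotic_false_positive_rate": fpr,
        "n_zygotic_called": int(called.sum()),
        "ercc_fit": {"intercept": fit.intercept, "slope": fit.slope,
                     "n_used": fit.n_used},
        "n_differential_genes": int(de.table["significant"].sum()),
    }


def _stage_ir(sim: SimConfig, ap: AnalysisParams, state: dict,
              outdir: Path | None) -> dict:
    introns = state["introns"]
    truth = state["truth"]
    pre_stage, post_stage = sim.stages[0], sim.stages[1]
    ir_pre = gene_ir(introns, sample=f"soma_{pre_stage}")
    ir_post = gene_ir(introns, sample=f"soma_{post_stage}")
    subgroup = truth.gene_class.index[truth.gene_class == "zygotic"]
    subgroup = pd.Index(subgroup).intersection(ir_pre.index) \
        .intersection(ir_post.index)
    res = ir_permutation_test(ir_pre, ir_post, subgroup,
                              n_perm=ap.n_permutations, seed=sim.seed)
    state["ir_result"] = res
    return {"observed_shift": res.observed, "pvalue": res.pvalue,
            "t_pvalue": res.t_pvalue,
            "null_interval": list(res.null_interval),
            "n_perm": res.n_perm}


def _stage_chromatin(sim: SimConfig, ap: AnalysisParams, state: dict,
                     outdir: Path | None) -> dict:
    fragments = state["fragments"]
    elements = state["elements"]
    models = state["models"]
    truth = state["truth"]
    lengths = sim.chrom_lengths

    # one sample in memory at a time: tracks are ~100 MB each at this
    # genome size, so per-sample processing keeps the footprint flat
    peaks: dict[str, pd.DataFrame] = {}
    for sid, frag in fragments.items():
        track = chromatin.prepare_cutsites(
            frag, lengths, min_mapq=ap.min_mapq,
            extension=ap.extension_browser)
        peaks[sid] = chromatin.call_peaks(
            track, effective_genome_size=None,
            window=ap.peak_window, p_cutoff=ap.peak_p_cutoff)
        if outdir is not None:
            peak_dir = outdir / "peaks"
            peak_dir.mkdir(exist_ok=True)
            io.write_narrowpeak(peaks[sid], peak_dir / f"{sid}.narrowPeak")
        del track

    # peak recovery of planted reproducible elements, per cell type
    recovery = {}
    for ct in sim.cell_types:
        cls = {"PGC": "pgc_open", "soma": "soma_open"}[ct]
        planted = elements[elements["element_class"].isin([cls, "shared"])]
        sids = [s for s in fragments if s.startswith(f"{ct}_")]
        hit = np.ones(len(planted), dtype=bool)
        for sid in sids:
            pk = peaks[sid]
            sample_hit = np.zeros(len(planted), dtype=bool)
            for i, el in enumerate(planted.itertuples(index=False)):
                sub = pk[(pk["chrom"] == el.chrom) & (pk["start"] < el.end)
                         & (pk["end"] > el.start)]
                sample_hit[i] = len(sub) > 0
            hit &= sample_hit
        recovery[ct] = float(hit.mean())

    peaksets = {}
    for ct in sim.cell_types:
        for st in sim.atac_stages:
            reps = [peaks[f"{ct}_{st}_rep{r}"]
                    for r in range(1, sim.n_replicates + 1)]
            peaksets[f"{ct}_{st}"] = reps[:2]
    cascade = chromatin.enhancer_cascade(
        peaksets, models["tss"], idr_threshold=ap.idr_threshold,
        tss_exclusion=ap.tss_exclusion, max_width=ap.max_element_width)
    if outdir is not None:
        cascade.log_frame().to_csv(outdir / "cascade_log.tsv", sep="\t",
                                   index=False)
        cascade.elements.assign(
            conditions=[",".join(c) for c in cascade.elements["conditions"]]
        ).to_csv(outdir / "candidate_enhancers.tsv", sep="\t", index=False)

    sm_parts = []
    ec_cols: dict[str, pd.Series] = {}
    for sid, frag in fragments.items():
        track5 = chromatin.prepare_cutsites(
            frag, lengths, min_mapq=ap.min_mapq, extension=ap.extension_som)
        sm_parts.append(chromatin.signal_matrix(
            cascade.elements, {sid: track5}, window=ap.signal_window))
        ec_cols[sid] = chromatin.element_counts(cascade.elements,
                                                {sid: track5})[sid]
        del track5
    sm = chromatin.SignalMatrix(
        values=pd.concat([p.values for p in sm_parts], axis=1),
        window=ap.signal_window, truncated=sm_parts[0].truncated)
    sml = chromatin.log_transform(sm)
    pca = chromatin.pca_embed(chromatin.center_columns(sml), n_components=2)
    som = chromatin.som_cluster(
        chromatin.center_rows(chromatin.center_columns(sml)),
        grid=ap.som_grid, epochs=ap.som_epochs, seed=sim.seed)

    # differential accessibility on the IDR-reproducible candidate
    # elements (irreproducible single-replicate peaks were removed by
    # the cascade, as in the real analysis order)
    ec = pd.DataFrame(ec_cols)
    truth_label = _overlap_labels(cascade.elements, elements)
    meta = pd.DataFrame(
        [(sid, *sid.split("_")[:2], int(sid.rsplit("rep", 1)[1]))
         for sid in ec.columns],
        columns=["sample", "cell_type", "stage", "replicate"]).set_index("sample")
    widths = (cascade.elements["end"] - cascade.elements["start"])
    cm = CountMatrix(ec, widths.rename("length"), meta)
    last = sim.atac_stages[-1]
    ga = [s for s in ec.columns if s.startswith(f"soma_{last}_")]
    gb = [s for s in ec.columns if s.startswith(f"PGC_{last}_")]
    fe = _element_fold_enrichment(ec, widths.to_numpy(), sim)
    da = chromatin.diff_accessibility(
        cm, ga, gb, fe, lfc_threshold=ap.lfc_threshold,
        padj_threshold=ap.padj_threshold,
        fe_threshold=ap.fold_enrichment_threshold)
    is_pgc = truth_label == "pgc_open"
    up_in_pgc = da.table["significant"] & (da.table["log2fc"] > 0)
    da_sens = float(up_in_pgc[is_pgc].mean()) if is_pgc.any() else float("nan")
    called = da.table["significant"]
    da_fdr = float((~truth_label[called]
                    .isin(["pgc_open", "soma_open"])).mean()) \
        if called.any() else 0.0

    ann = chromatin.annotate_elements(cascade.elements, models)
    state.update(cascade=cascade, som=som, pca=pca, annotated=ann)
    return {
        "peak_recovery": recovery,
        "cascade_log": [list(r) for r in cascade.cascade_log],
        "n_candidate_enhancers": len(cascade.elements),
        "pca_variance_explained": pca.variance_explained,
        "som_units_used": int(len(np.unique(som.assignment))),
        "som_grid": list(ap.som_grid),
        "diff_accessibility": {
            "n_significant": int(called.sum()),
            "pgc_open_sensitivity": da_sens,
            "false_discovery_rate": da_fdr,
        },
        "feature_fractions": ann["feature"].value_counts(normalize=True)
        .to_dict(),
    }


def _overlap_labels(candidates: pd.DataFrame,
                    planted: pd.DataFrame) -> pd.Series:
    """Label each candidate element by the planted element it overlaps
    ('background' when none)."""
    labels = []
    for r in candidates.itertuples(index=False):
        sub = planted[(planted["chrom"] == r.chrom)
                      & (planted["start"] < r.end)
                      & (planted["end"] > r.start)]
        labels.append(sub["element_class"].iloc[0] if len(sub)
                      else "background")
    return pd.Series(labels, index=candidates.index, name="truth")


def _element_fold_enrichment(ec: pd.DataFrame, widths: np.ndarray,
                             sim: SimConfig) -> pd.Series:
    """Max across samples of observed / genome-wide expected cut sites."""
    genome = sum(v for k, v in sim.chrom_lengths.items()
                 if k != sim.mito_name)
    expected = ec.sum(axis=0).to_numpy()[None, :] * widths[:, None] / genome
    fe = ec.to_numpy() / np.maximum(expected, 1e-12)
    return pd.Series(fe.max(axis=1), index=ec.index, name="fold_enrichment")


def _stage_methylation(sim: SimConfig, ap: AnalysisParams, state: dict,
                       outdir: Path | None) -> dict:
    cpgs = state["cpgs"]
    regions = state["regions"].set_index("region")
    filtered = load_filter_cpgs(cpgs, min_coverage=ap.min_cpg_coverage)
    last = sim.meth_stages[-1]
    grp = {ct: filtered[filtered["sample"].str.startswith(f"{ct}_{last}_")]
           for ct in sim.cell_types}
    table, frac = differential_cpgs(grp["PGC"], grp["soma"],
                                    q_threshold=ap.meth_q_threshold,
                                    min_diff=ap.meth_min_diff)
    enh = regions[regions["region_class"] == "enhancer_like"]
    rm = region_methylation(filtered, enh)
    soma_first = [c for c in rm.columns
                  if c.startswith(f"soma_{sim.meth_stages[0]}_")]
    soma_last = [c for c in rm.columns if c.startswith(f"soma_{last}_")]
    pgc_last = [c for c in rm.columns if c.startswith(f"PGC_{last}_")]
    return {
        "n_cpgs_filtered": int(len(cpgs) - len(filtered)),
        "n_cpgs_tested": int(len(table)),
        "n_differential": int(table["differential"].sum()),
        "differential_fraction_percent": 100.0 * frac,
        "enhancer_methylation": {
            "soma_first_stage": float(rm[soma_first].mean().mean()),
            "soma_last_stage": float(rm[soma_last].mean().mean()),
            "pgc_last_stage": float(rm[pgc_last].mean().mean()),
        },
    }


def _stage_granules(sim: SimConfig, ap: AnalysisParams, state: dict,
                    outdir: Path | None) -> dict:
    masks = state["masks"]
    ratios = {}
    for cond, cells in masks.items():
        vals = []
        for cell, _expected in cells:
            vals.extend(contact_ratio(cell).ratios)
        ratios[cond] = np.array(vals)
    control = "control" if "control" in ratios else next(iter(ratios))
    cmp_table = compare_groups(ratios, control=control)
    return {
        "mean_ratio_by_condition": {c: float(v.mean())
                                    for c, v in ratios.items()},
        "comparisons": {c: {"pvalue": float(r["pvalue"]),
                            "significant": bool(r["significant"])}
                        for c, r in cmp_table.iterrows()},
        "control": control,
    }
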