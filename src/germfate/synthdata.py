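"""Seeded synthetic datasets with the statistical structure of the study
design: two cell types (PGC, soma) x five developmental stages (256-cell,
high, dome, 10-somites, prim-5) x two replicates, with ground-truth labels
for every simulated record.

The generators emulate, at desk scale, the features the downstream
analyses are built to detect:

* transcript classes — maternal (decaying), zygotic (absent before
  genome activation, rising after), maternal-zygotic, germ-plasm
  stabilized (persisting in PGCs while decaying in soma after ZGA) and
  housekeeping — drawn as negative-binomial counts around class
  trajectories, with ERCC spike-ins appended at counts proportional to
  their known concentrations;
* per-intron depth and splice-site reads whose realized intron-retention
  ratio has expectation equal to the per-stage nascent fraction;
* ATAC fragments as uniform background plus enrichment at planted
  elements: cell-type-specific and shared elements reproduce across
  replicates, irreproducible-noise elements appear in one replicate only;
  a slice of fragments carries low mapping quality or sits on the
  mitochondrial chromosome so the upstream filters have something to do;
* CpG tables where enhancer-like regions demethylate across stages in
  soma only while PGCs stay hypermethylated, with binomial counts around
  the region trajectory and some CpGs below the coverage cutoff;
* labeled cell masks whose granule-nucleus contact geometry is
  axis-aligned, so the expected contact ratio is exact.

The synthetic genome is 25 numbered chromosomes plus one mitochondrial
contig, 1 Mb each by default — a scaled-down stand-in for the zebrafish
assembly.  A single integer seed determines every output bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError
from .expression import CountMatrix
from .granules import NUCLEUS_LABEL, CellGeometry

__all__ = ["SimConfig", "SimTruth", "default_ercc_catalogue",
           "gen_expression", "gen_introns", "gen_atac", "gen_methylation",
           "gen_granule_masks", "gen_gene_models"]

STAGES = ("256-cell", "high", "dome", "10-somites", "prim-5")
CELL_TYPES = ("PGC", "soma")
GENE_CLASSES = ("maternal", "zygotic", "maternal_zygotic",
                "germ_plasm_stabilized", "housekeeping")
ELEMENT_CLASSES = ("pgc_open", "soma_open", "shared", "irreproducible_noise")


def default_ercc_catalogue(n: int = 92) -> dict[str, float]:
    """Synthetic spike-in catalogue: concentrations (attomoles/uL) spanning
    six orders of magnitude log-uniformly, mirroring the real ERCC mix
    design.  Deterministic by construction."""
    conc = np.geomspace(1e-2, 1e4, n)
    return {f"ERCC-{i:04d}": float(c) for i, c in enumerate(conc, start=1)}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study design: five stages, two cell types, two
    replicates; counts are negative-binomial with variance
    mu + dispersion * mu^2 (dispersion shared across genes).
    """

    n_genes: int = 2000
    n_elements: int = 240
    stages: tuple[str, ...] = STAGES
    cell_types: tuple[str, ...] = CELL_TYPES
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    ercc_concentrations: dict[str, float] = field(
        default_factory=default_ercc_catalogue)
    seed: int = 0

    # synthetic genome
    n_chroms: int = 25
    chrom_length: int = 1_000_000
    mito_name: str = "MT"
    mito_length: int = 17_000

    # gene-class mixture
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "maternal": 0.35, "zygotic": 0.20, "maternal_zygotic": 0.25,
        "germ_plasm_stabilized": 0.05, "housekeeping": 0.15})

    # intron generator
    introns_per_gene: int = 3
    intron_coverage: float = 60.0

    # ATAC generator
    atac_stages: tuple[str, ...] = ("high", "prim-5")
    atac_background_fragments: int = 200_000
    atac_enrichment_fold: float = 10.0
    element_width: int = 400
    mito_fragment_fraction: float = 0.03
    low_mapq_fraction: float = 0.05

    # methylation generator: promoter-like regions sit at a low flat
    # level; enhancer-like regions stay at the start level in PGCs and
    # move linearly start -> end across the assayed stages in soma
    meth_stages: tuple[str, ...] = ("high", "dome", "prim-5")
    n_meth_regions: int = 200
    cpgs_per_region: int = 10
    meth_mean_coverage: float = 15.0
    meth_promoter_level: float = 0.05
    meth_enhancer_start: float = 0.8
    meth_enhancer_end: float = 0.2

    # granule generator: condition -> probability a granule is flush
    granule_conditions: dict[str, float] = field(default_factory=lambda: {
        "control": 0.7, "tdrd7_kd": 0.2})
    cells_per_condition: int = 30

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        if self.library_size <= 0:
            raise InvalidConfigError("library_size must be positive")
        if not self.stages:
            raise InvalidConfigError("stages must be non-empty")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if self.n_replicates < 1:
            raise InvalidConfigError("need >= 1 replicate")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError("class fractions must sum to 1")
        if self.n_elements * self.element_width * 4 > \
                self.n_chroms * self.chrom_length:
            raise InvalidConfigError("n_elements exceeds genome capacity")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        d = {str(i): self.chrom_length for i in range(1, self.n_chroms + 1)}
        d[self.mito_name] = self.mito_length
        return d

    def rng(self, *stream: int) -> np.random.Generator:
        """Child generator for an independent, named random stream."""
        return np.random.default_rng([self.seed, *stream])

    def sample_ids(self, cell_types=None, stages=None) -> list[tuple]:
        out = []
        for ct in (cell_types or self.cell_types):
            for st in (stages or self.stages):
                for r in range(1, self.n_replicates + 1):
                    out.append((f"{ct}_{st}_rep{r}", ct, st, r))
        return out


@dataclass
class SimTruth:
    """Ground-truth labels attached to a simulated dataset."""

    gene_class: pd.Series | None = None
    nascent_fraction: pd.DataFrame | None = None  # gene x stage
    expected_tpm: pd.DataFrame | None = None      # gene x sample
    element_class: pd.Series | None = None
    meth_trajectory: pd.DataFrame | None = None   # region x (cell_type, stage)
    granule_truth: dict | None = None             # condition -> expected ratios


# Relative expression multipliers per class across the five default
# stage indices, per cell type.  Germ-plasm transcripts decay in soma
# after ZGA (stage index >= 2) but persist in PGCs.
def _class_profile(cls: str, cell_type: str, n_stages: int) -> np.ndarray:
    ramps = {
        "maternal": [1.0, 0.6, 0.35, 0.15, 0.05],
        "maternal_zygotic": [1.0, 1.2, 1.2, 1.0, 1.0],
        "housekeeping": [1.0, 1.0, 1.0, 1.0, 1.0],
    }
    if cls == "zygotic":
        prof = np.array([1.0, 10.0, 20.0, 30.0, 30.0])
    elif cls == "germ_plasm_stabilized":
        if cell_type == "PGC":
            prof = np.array([1.0, 1.0, 1.0, 0.9, 0.8])
        else:
            prof = np.array([1.0, 1.0, 0.5, 0.1, 0.02])
    else:
        prof = np.array(ramps[cls])
    if n_stages == len(prof):
        return prof
    # resample the canonical 5-point trajectory onto another stage count
    xs = np.linspace(0, 1, len(prof))
    return np.interp(np.linspace(0, 1, n_stages), xs, prof)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, var = mu + a mu^2) via gamma-Poisson; Poisson when a = 0."""
    mean = np.maximum(mean, 0.0)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def gen_expression(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate the gene x sample count matrix with ERCC spike-ins.

    Gene classes are assigned by the configured fractions; expected TPM
    per sample follows the class trajectory (zygotic genes sit below
    2 TPM at the first stage and rise at the second); counts are NB draws
    around the expected fraction of the library.  Spike-in counts are
    Poisson around a mean proportional to concentration x length.
    """
    rng = config.rng(1)
    n = config.n_genes
    genes = [f"gene_{i:05d}" for i in range(1, n + 1)]

    counts_per_class = {c: int(round(f * n))
                        for c, f in config.class_fractions.items()}
    # fix rounding drift on the largest class
    drift = n - sum(counts_per_class.values())
    counts_per_class[max(counts_per_class, key=counts_per_class.get)] += drift
    labels = np.concatenate([np.repeat(c, k)
                             for c, k in counts_per_class.items()])
    rng.shuffle(labels)
    gene_class = pd.Series(labels, index=genes, name="gene_class")

    lengths = np.round(rng.lognormal(np.log(2000), 0.6, size=n)).astype(int)
    lengths = np.clip(lengths, 200, 50_000)

    # per-gene base level; zygotic genes are pinned in true TPM units
    # (every non-zygotic class has multiplier 1 at the first stage, so
    # the stage-1 library total is known up front and a stage-1 TPM
    # below 2 can be guaranteed by construction)
    base = rng.lognormal(np.log(300), 1.0, size=n)
    zyg = labels == "zygotic"
    stage1_total = base[~zyg].sum()
    base[zyg] = rng.uniform(0.1, 1.0, size=int(zyg.sum())) \
        * stage1_total / 1e6

    samples = config.sample_ids()
    n_stages = len(config.stages)
    profiles = {(c, ct): _class_profile(c, ct, n_stages)
                for c in GENE_CLASSES for ct in config.cell_types}
    stage_idx = {s: i for i, s in enumerate(config.stages)}

    expected_tpm = {}
    raw_counts = {}
    ercc_ids = list(config.ercc_concentrations)
    ercc_conc = np.array([config.ercc_concentrations[e] for e in ercc_ids])
    ercc_len = np.round(np.geomspace(250, 2000, len(ercc_ids))).astype(int) \
        if ercc_ids else np.array([], dtype=int)
    for sid, ct, st, rep in samples:
        mult = np.empty(n)
        for c in GENE_CLASSES:
            m = labels == c
            mult[m] = profiles[(c, ct)][stage_idx[st]]
        level = base * mult
        tpmv = level / level.sum() * 1e6
        expected_tpm[sid] = tpmv
        weight = tpmv * (lengths / 1e3)
        mean_counts = weight / weight.sum() * config.library_size
        raw_counts[sid] = _nb_draw(rng, mean_counts, config.nb_dispersion)

    count_df = pd.DataFrame(raw_counts, index=genes)
    if ercc_ids:
        # spike-ins: ~2% of the library, counts proportional to conc x length
        spike_weight = ercc_conc * ercc_len / 1e3
        spike_mean = spike_weight / spike_weight.sum() \
            * 0.02 * config.library_size
        spike_rows = {sid: rng.poisson(spike_mean) for sid, *_ in samples}
        count_df = pd.concat([count_df,
                              pd.DataFrame(spike_rows, index=ercc_ids)])
    length_s = pd.Series(np.concatenate([lengths, ercc_len]),
                         index=genes + ercc_ids, name="length")
    meta = pd.DataFrame([(sid, ct, st, rep) for sid, ct, st, rep in samples],
                        columns=["sample", "cell_type", "stage", "replicate"]) \
        .set_index("sample")

    # nascent fraction per gene x stage: zygotically transcribed classes
    # show elevated intron retention once transcription starts
    nf = np.zeros((n, n_stages))
    post = np.arange(n_stages) >= 1
    nf[np.isin(labels, ["zygotic", "germ_plasm_stabilized"])] = \
        np.where(post, 0.5, 0.02)
    nf[labels == "maternal_zygotic"] = np.where(post, 0.3, 0.02)
    nf[labels == "housekeeping"] = np.where(post, 0.15, 0.02)
    nf[labels == "maternal"] = 0.02
    nascent = pd.DataFrame(nf, index=genes, columns=list(config.stages))

    truth = SimTruth(gene_class=gene_class, nascent_fraction=nascent,
                     expected_tpm=pd.DataFrame(expected_tpm, index=genes))
    return CountMatrix(count_df, length_s, meta), truth


def gen_introns(config: SimConfig, truth: SimTruth,
                cell_type: str = "soma") -> pd.DataFrame:
    """Per-intron depth and splice-site reads for one cell type.

    For each gene, stage and intron a total read weight W ~ Poisson of
    the configured intron coverage is split binomially into intronic
    depth D (probability = the gene's nascent fraction at that stage)
    and spliced support S = W - D, with SS5 = S and SS3 a thinned copy,
    so E[D / (max(SS5, SS3) + D)] equals the nascent fraction.
    """
    if truth.nascent_fraction is None:
        raise ValueError("truth must come from gen_expression")
    rng = config.rng(2)
    genes = truth.nascent_fraction.index
    rows = []
    for st in config.stages:
        f = truth.nascent_fraction[st].to_numpy()
        sid = f"{cell_type}_{st}"
        for k in range(config.introns_per_gene):
            w = rng.poisson(config.intron_coverage, size=len(genes))
            d = rng.binomial(w, f)
            s = w - d
            ss3 = rng.binomial(s, 0.8)
            rows.append(pd.DataFrame({
                "gene": genes, "intron": k + 1, "depth": d.astype(float),
                "ss5": s, "ss3": ss3, "sample": sid}))
    return pd.concat(rows, ignore_index=True)


def gen_atac(config: SimConfig, truth: SimTruth | None = None
             ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SimTruth]:
    """Per-sample ATAC fragment tables plus the planted element catalogue.

    Background fragments are uniform over the numbered chromosomes; a
    configured fraction lands on the mitochondrial contig and another
    carries mapping quality below 10, so the upstream filters are
    exercised.  Planted elements receive extra fragments in the samples
    where their class is active: ``pgc_open``/``soma_open`` in both
    replicates of the matching cell type, ``shared`` everywhere, and
    ``irreproducible_noise`` in a single randomly chosen replicate.
    """
    rng = config.rng(3)
    if truth is None:
        truth = SimTruth()
    n_el = config.n_elements
    # place elements on a spaced grid so they never overlap
    pitch = config.element_width * 4
    per_chrom = config.chrom_length // pitch
    capacity = config.n_chroms * per_chrom
    if n_el > capacity:
        raise InvalidConfigError("n_elements exceeds genome capacity")
    slots = rng.choice(capacity, size=n_el, replace=False)
    chrom_ids = slots // per_chrom + 1
    starts = (slots % per_chrom) * pitch + pitch // 4
    class_cycle = np.array(ELEMENT_CLASSES)[
        rng.integers(0, len(ELEMENT_CLASSES), size=n_el)]
    elements = pd.DataFrame({
        "element": [f"el_{i:04d}" for i in range(1, n_el + 1)],
        "chrom": chrom_ids.astype(str),
        "start": starts,
        "end": starts + config.element_width,
        "element_class": class_cycle,
    }).set_index("element")
    truth.element_class = elements["element_class"]

    # which single replicate an irreproducible element shows up in
    noise_rep = pd.Series(rng.integers(1, config.n_replicates + 1, size=n_el),
                          index=elements.index)
    noise_ct = pd.Series(rng.choice(config.cell_types, size=n_el),
                         index=elements.index)

    bg_density = config.atac_background_fragments \
        / (config.n_chroms * config.chrom_length)
    frags_per_element = config.atac_enrichment_fold * bg_density \
        * config.element_width

    samples = {}
    for sid, ct, st, rep in config.sample_ids(stages=config.atac_stages):
        n_bg = config.atac_background_fragments
        n_mito = rng.binomial(n_bg, config.mito_fragment_fraction)
        n_nuc = n_bg - n_mito
        chrom = rng.integers(1, config.n_chroms + 1, size=n_nuc).astype(str)
        start = rng.integers(0, config.chrom_length - 500, size=n_nuc)
        length = rng.integers(50, 400, size=n_nuc)
        frames = [pd.DataFrame({"chrom": chrom, "start": start,
                                "end": start + length})]
        if n_mito:
            ms = rng.integers(0, config.mito_length - 500, size=n_mito)
            frames.append(pd.DataFrame({
                "chrom": config.mito_name, "start": ms,
                "end": ms + rng.integers(50, 400, size=n_mito)}))
        for el, row in elements.iterrows():
            cls = row["element_class"]
            active = (cls == "shared"
                      or (cls == "pgc_open" and ct == "PGC")
                      or (cls == "soma_open" and ct == "soma")
                      or (cls == "irreproducible_noise"
                          and rep == noise_rep[el] and ct == noise_ct[el]))
            if not active:
                continue
            k = rng.poisson(frags_per_element)
            if k == 0:
                continue
            fl = rng.integers(80, min(400, config.element_width + 100), size=k)
            centers = rng.integers(row["start"], row["end"], size=k)
            fs = np.maximum(centers - fl // 2, 0)
            frames.append(pd.DataFrame({"chrom": row["chrom"], "start": fs,
                                        "end": fs + fl}))
        frag = pd.concat(frames, ignore_index=True)
        mapq = rng.integers(20, 61, size=len(frag))
        low = rng.random(len(frag)) < config.low_mapq_fraction
        mapq[low] = rng.integers(0, 10, size=int(low.sum()))
        frag["mapq"] = mapq
        samples[sid] = frag.sample(frac=1.0, random_state=int(rng.integers(2**31))) \
            .reset_index(drop=True)
    return samples, elements.reset_index(), truth


def gen_methylation(config: SimConfig, truth: SimTruth | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Per-sample CpG tables with region-level methylation trajectories.

    Regions split into promoter-like (lowly methylated in both cell
    types at all stages) and enhancer-like (soma demethylates linearly
    across the assayed stages while PGCs stay hypermethylated).  Each
    CpG's methylated count is binomial around its region's trajectory
    with Poisson-distributed coverage, so some CpGs fall below the
    6-read cutoff.
    """
    rng = config.rng(4)
    if truth is None:
        truth = SimTruth()
    n_reg = config.n_meth_regions
    kinds = np.where(np.arange(n_reg) % 2 == 0, "promoter_like",
                     "enhancer_like")
    chrom = rng.integers(1, config.n_chroms + 1, size=n_reg).astype(str)
    start = rng.integers(0, config.chrom_length - 2000, size=n_reg)
    regions = pd.DataFrame({
        "region": [f"reg_{i:04d}" for i in range(1, n_reg + 1)],
        "chrom": chrom, "start": start, "end": start + 1000,
        "region_class": kinds}).set_index("region")

    stages = list(config.meth_stages)
    hi, lo = config.meth_enhancer_start, config.meth_enhancer_end
    traj = {}
    for ct in config.cell_types:
        for si, st in enumerate(stages):
            level = np.where(
                kinds == "promoter_like", config.meth_promoter_level,
                hi if ct == "PGC"
                else hi - (hi - lo) * si / max(len(stages) - 1, 1))
            traj[(ct, st)] = level
    trajectory = pd.DataFrame(traj, index=regions.index)
    trajectory.columns = pd.MultiIndex.from_tuples(trajectory.columns,
                                                   names=["cell_type", "stage"])
    truth.meth_trajectory = trajectory

    # CpG sites are a property of the region: the same positions are
    # surveyed in every sample, as in a real bisulfite assay
    site_map = {
        rid: np.sort(rng.choice(np.arange(reg["start"], reg["end"], 2),
                                size=config.cpgs_per_region, replace=False))
        for rid, reg in regions.iterrows()}

    rows = []
    for sid, ct, st, rep in config.sample_ids(stages=stages):
        for rid, reg in regions.iterrows():
            level = trajectory.loc[rid, (ct, st)]
            pos = site_map[rid]
            cov = rng.poisson(config.meth_mean_coverage,
                              size=config.cpgs_per_region)
            meth = rng.binomial(cov, level)
            rows.append(pd.DataFrame({
                "chrom": reg["chrom"], "start": pos, "end": pos + 1,
                "meth": meth, "unmeth": cov - meth,
                "sample": sid, "region": rid}))
    cpgs = pd.concat(rows, ignore_index=True)
    cov = cpgs["meth"] + cpgs["unmeth"]
    cpgs["percent"] = np.where(cov > 0, 100.0 * cpgs["meth"] / cov, 0.0)
    return cpgs, regions.reset_index(), truth


def gen_granule_masks(config: SimConfig
                      ) -> dict[str, list[tuple[CellGeometry, list[float]]]]:
    """Labeled cell masks with analytically known contact ratios.

    Each cell is a 96x96 grid with a rectangular nucleus; granules are
    axis-aligned squares placed either flush against a nucleus edge
    (probability = the condition's contact fraction) or detached by more
    than one pixel.  Because placement is axis-aligned, each flush
    granule's expected ratio is exactly side / total granule area, and a
    detached granule's is 0.
    """
    rng = config.rng(5)
    out: dict[str, list] = {}
    size = 96
    nuc = (34, 62, 34, 62)  # r0, r1, c0, c1 (half-open)
    for cond, contact_prob in config.granule_conditions.items():
        cells = []
        for _ in range(config.cells_per_condition):
            mask = np.zeros((size, size), dtype=np.int32)
            mask[nuc[0]:nuc[1], nuc[2]:nuc[3]] = NUCLEUS_LABEL
            n_gran = int(rng.integers(2, 6))
            sides = rng.integers(4, 11, size=n_gran)
            flush = rng.random(n_gran) < contact_prob
            expected: list[float] = []
            label = 2
            placed: list[tuple[int, int, int]] = []
            for s, fl in zip(sides, flush):
                for _attempt in range(200):
                    if fl:
                        edge = rng.integers(0, 4)
                        if edge == 0:    # above the nucleus
                            r0, c0 = nuc[0] - s, rng.integers(nuc[2],
                                                              nuc[3] - s + 1)
                        elif edge == 1:  # below
                            r0, c0 = nuc[1], rng.integers(nuc[2], nuc[3] - s + 1)
                        elif edge == 2:  # left
                            r0, c0 = rng.integers(nuc[0], nuc[1] - s + 1), \
                                nuc[2] - s
                        else:            # right
                            r0, c0 = rng.integers(nuc[0], nuc[1] - s + 1), nuc[1]
                    else:
                        r0 = rng.integers(2, size - s - 2)
                        c0 = rng.integers(2, size - s - 2)
                        # keep detached granules > 1 px from the nucleus
                        if (r0 + s >= nuc[0] - 2 and r0 <= nuc[1] + 1
                                and c0 + s >= nuc[2] - 2 and c0 <= nuc[3] + 1):
                            continue
                    if r0 < 0 or c0 < 0 or r0 + s > size or c0 + s > size:
                        continue
                    clash = any(not (r0 + s + 1 <= pr or pr + ps + 1 <= r0
                                     or c0 + s + 1 <= pc or pc + ps + 1 <= c0)
                                for pr, pc, ps in placed)
                    if clash:
                        continue
                    if (mask[r0:r0 + s, c0:c0 + s] != 0).any():
                        continue
                    mask[r0:r0 + s, c0:c0 + s] = label
                    placed.append((r0, c0, int(s)))
                    expected.append((int(s), bool(fl)))
                    label += 1
                    break
            total_area = float(sum(s * s for s, _ in expected))
            ratios = [s / total_area if fl else 0.0 for s, fl in expected]
            cells.append((CellGeometry(mask=mask), ratios))
        out[cond] = cells
    return out


def gen_gene_models(config: SimConfig, n_genes: int | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Synthetic TSS/exon gene models on the synthetic genome, for the
    TSS-distance filter and feature annotation."""
    rng = config.rng(6)
    n = n_genes or config.n_genes
    chrom = rng.integers(1, config.n_chroms + 1, size=n).astype(str)
    tss_pos = rng.integers(5_000, config.chrom_length - 50_000, size=n)
    strand = rng.choice(["+", "-"], size=n)
    gene_ids = [f"gene_{i:05d}" for i in range(1, n + 1)]
    tss = pd.DataFrame({"chrom": chrom, "pos": tss_pos, "strand": strand,
                        "gene_id": gene_ids})
    exon_rows = []
    for i in range(n):
        n_ex = rng.integers(2, 6)
        pos = tss_pos[i]
        for e in range(n_ex):
            ex_start = pos
            ex_end = ex_start + rng.integers(100, 300)
            exon_rows.append((chrom[i], ex_start, ex_end, gene_ids[i]))
            pos = ex_end + rng.integers(500, 3000)  # intron gap
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end",
                                             "gene_id"])
    return {"tss": tss, "exons": exons}
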