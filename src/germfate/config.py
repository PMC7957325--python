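"""Run configuration: simulation design plus analysis constants.

Every analysis constant of the pipeline is a named key with its default:
zygotic TPM threshold 2; differential thresholds |logFC| > 1, padj < 0.05,
fold enrichment > 4; IDR 0.05; TSS exclusion 500 bp; max element width
1000 bp; signal window 601 bp; cut-site extensions 25 bp (browser) and
5 bp (PCA/SOM); 10,000 permutations; CpG coverage cutoff 6.  Configs are
plain TOML with ``[simulation]`` and ``[analysis]`` tables.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .synthdata import SimConfig

__all__ = ["AnalysisParams", "RunConfig", "load_config"]


@dataclass
class AnalysisParams:
    tpm_threshold: float = 2.0
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    fold_enrichment_threshold: float = 4.0
    idr_threshold: float = 0.05
    tss_exclusion: int = 500
    max_element_width: int = 1000
    signal_window: int = 601
    extension_browser: int = 25
    extension_som: int = 5
    n_permutations: int = 10_000
    min_cpg_coverage: int = 6
    meth_q_threshold: float = 0.01
    meth_min_diff: float = 25.0
    som_grid: tuple[int, int] = (3, 3)
    som_epochs: int = 50
    peak_window: int = 300
    peak_p_cutoff: float = 1e-5
    ercc_rpkm_cutoff: float = 1.0
    min_mapq: int = 10


@dataclass
class RunConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)


def _build(cls, table: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(table)
    for key in ("stages", "cell_types", "atac_stages", "meth_stages",
                "som_grid"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a TOML run configuration; missing keys keep their defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(
        simulation=_build(SimConfig, data.get("simulation", {})),
        analysis=_build(AnalysisParams, data.get("analysis", {})),
    )
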