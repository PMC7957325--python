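"""The synthetic-data generators: seed determinism, the planted
statistical structure, and truth recovery by the downstream stages."""

import numpy as np
import pandas as pd
import pytest

from germfate.exceptions import InvalidConfigError
from germfate.expression import tpm
from germfate.granules import contact_ratio
from germfate.introns import gene_ir
from germfate.synthdata import (SimConfig, default_ercc_catalogue, gen_atac,
                                gen_expression, gen_gene_models,
                                gen_granule_masks, gen_introns,
                                gen_methylation)


class TestConfig:
    def test_default_stage_series(self):
        assert SimConfig().stages == ("256-cell", "high", "dome",
                                      "10-somites", "prim-5")

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0}, {"library_size": 0}, {"stages": ()},
        {"nb_dispersion": -1},
        {"n_elements": 10_000, "n_chroms": 2, "chrom_length": 100_000},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kwargs)

    def test_ercc_catalogue_spans_six_orders(self):
        conc = np.array(list(default_ercc_catalogue().values()))
        assert len(conc) == 92
        assert conc.max() / conc.min() == pytest.approx(1e6)


class TestGenExpression:
    def test_seed_determinism(self, small_config):
        a, _ = gen_expression(small_config)
        b, _ = gen_expression(small_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_different_seed_differs(self, small_config):
        a, _ = gen_expression(small_config)
        other = SimConfig(**{**small_config.__dict__, "seed": 99})
        b, _ = gen_expression(other)
        assert not a.counts.equals(b.counts)

    def test_zero_dispersion_is_poisson(self):
        # many replicate draws of the same means: variance tracks mean
        cfg = SimConfig(n_genes=300, nb_dispersion=0.0, seed=3,
                        stages=("s1",), cell_types=("PGC",),
                        n_replicates=60, ercc_concentrations={})
        cm, truth = gen_expression(cfg)
        counts = cm.counts.to_numpy(float)
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        deep = mean > 50
        ratio = var[deep] / mean[deep]
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_zygotic_genes_silent_then_rising(self, small_config):
        cm, truth = gen_expression(small_config)
        zyg = truth.gene_class == "zygotic"
        expected = truth.expected_tpm
        pgc1 = [c for c in expected.columns
                if c.startswith("PGC_256-cell")][0]
        pgc2 = [c for c in expected.columns if c.startswith("PGC_high")][0]
        assert (expected.loc[zyg[zyg].index, pgc1] < 2).all()
        assert (expected.loc[zyg[zyg].index, pgc2]
                > expected.loc[zyg[zyg].index, pgc1]).all()

    def test_germ_plasm_transcripts_persist_in_pgc_only(self, small_config):
        cm, truth = gen_expression(small_config)
        gps = truth.gene_class[truth.gene_class
                               == "germ_plasm_stabilized"].index
        t = tpm(cm)
        meta = cm.samples
        last = small_config.stages[-1]
        pgc = t[meta.index[(meta.cell_type == "PGC")
                           & (meta.stage == last)]].mean(axis=1)
        soma = t[meta.index[(meta.cell_type == "soma")
                            & (meta.stage == last)]].mean(axis=1)
        assert (pgc.loc[gps].mean() / soma.loc[gps].mean()) > 5

    def test_spikeins_proportional_to_concentration(self, small_config):
        cm, _ = gen_expression(small_config)
        ercc = [f for f in cm.features if f.startswith("ERCC-")]
        assert len(ercc) == 92
        conc = pd.Series(small_config.ercc_concentrations)
        counts = cm.counts.loc[ercc].iloc[:, 0]
        per_kb = counts / (cm.lengths.loc[ercc] / 1e3)
        deep = counts > 20
        ratio = per_kb[deep] / conc[deep]
        assert ratio.std() / ratio.mean() < 0.3

    def test_sample_labels_cover_design(self, small_config):
        cm, _ = gen_expression(small_config)
        assert set(cm.samples["stage"]) == set(small_config.stages)
        assert set(cm.samples["cell_type"]) == {"PGC", "soma"}
        assert len(cm.samples) == 2 * 5 * 2


class TestGenIntrons:
    def test_all_counts_non_negative(self, small_config):
        _, truth = gen_expression(small_config)
        table = gen_introns(small_config, truth)
        assert (table[["depth", "ss5", "ss3"]].to_numpy() >= 0).all()

    def test_zero_nascent_fraction_gives_zero_depth(self, small_config):
        _, truth = gen_expression(small_config)
        truth.nascent_fraction.iloc[:, :] = 0.0
        table = gen_introns(small_config, truth)
        assert (table["depth"] == 0).all()

    def test_realized_ir_matches_nascent_fraction(self, small_config):
        _, truth = gen_expression(small_config)
        truth.nascent_fraction.iloc[:, :] = 0.5
        table = gen_introns(small_config, truth)
        ir = gene_ir(table, sample=f"soma_{small_config.stages[1]}")
        assert 0.45 <= ir.mean() <= 0.55

    def test_pre_zga_ir_below_post_zga(self, small_config):
        _, truth = gen_expression(small_config)
        table = gen_introns(small_config, truth)
        pre = gene_ir(table, sample=f"soma_{small_config.stages[0]}")
        post = gene_ir(table, sample=f"soma_{small_config.stages[1]}")
        common = pre.index.intersection(post.index)
        assert post.loc[common].mean() > pre.loc[common].mean()

    def test_requires_truth(self, small_config):
        from germfate.synthdata import SimTruth
        with pytest.raises(ValueError):
            gen_introns(small_config, SimTruth())


@pytest.fixture(scope="module")
def atac(small_config):
    return gen_atac(small_config)


class TestGenAtac:

    def test_determinism(self, small_config, atac):
        frags, elements, _ = atac
        frags2, elements2, _ = gen_atac(small_config)
        sid = next(iter(frags))
        pd.testing.assert_frame_equal(frags[sid], frags2[sid])
        pd.testing.assert_frame_equal(elements, elements2)

    def test_fragment_fields_and_intervals(self, atac):
        frags, _, _ = atac
        for df in frags.values():
            assert {"chrom", "start", "end", "mapq"} <= set(df.columns)
            assert (df["start"] < df["end"]).all()
            assert (df["start"] >= 0).all()

    def test_mitochondrial_and_low_mapq_present(self, small_config, atac):
        frags, _, _ = atac
        df = next(iter(frags.values()))
        assert (df["chrom"] == small_config.mito_name).any()
        assert (df["mapq"] < 10).any()

    def test_element_classes_cover_catalogue(self, atac):
        _, elements, truth = atac
        assert set(elements["element_class"]) == {
            "pgc_open", "soma_open", "shared", "irreproducible_noise"}
        assert truth.element_class.notna().all()

    def test_capacity_error(self):
        with pytest.raises(InvalidConfigError):
            cfg = SimConfig(n_elements=300, n_chroms=1, chrom_length=400_000)
            gen_atac(cfg)


@pytest.fixture(scope="module")
def meth(small_config):
    return gen_methylation(small_config)


class TestGenMethylation:

    def test_low_coverage_cpgs_present(self, meth):
        cpgs, _, _ = meth
        cov = cpgs["meth"] + cpgs["unmeth"]
        assert (cov < 6).any()

    def test_zero_trajectory_zero_methylated(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__,
                           "meth_promoter_level": 0.0,
                           "meth_enhancer_start": 0.0,
                           "meth_enhancer_end": 0.0})
        cpgs, _, _ = gen_methylation(cfg)
        assert (cpgs["meth"] == 0).all()

    def test_soma_demethylates_enhancers_pgc_does_not(self, small_config,
                                                      meth):
        cpgs, regions, truth = meth
        traj = truth.meth_trajectory
        enh = regions.set_index("region")
        enh = enh[enh["region_class"] == "enhancer_like"].index
        first, last = small_config.meth_stages[0], small_config.meth_stages[-1]
        assert (traj.loc[enh, ("soma", last)]
                < traj.loc[enh, ("soma", first)]).all()
        assert (traj.loc[enh, ("PGC", last)]
                == traj.loc[enh, ("PGC", first)]).all()
        # realized counts follow the trajectory
        soma_last = cpgs[cpgs["sample"].str.startswith(f"soma_{last}_")
                         & cpgs["region"].isin(enh)]
        soma_first = cpgs[cpgs["sample"].str.startswith(f"soma_{first}_")
                          & cpgs["region"].isin(enh)]
        frac = lambda d: d["meth"].sum() / (d["meth"] + d["unmeth"]).sum()
        assert frac(soma_last) < frac(soma_first)


class TestGenGranuleMasks:
    def test_analytic_truth_matches_measurement(self, small_config):
        masks = gen_granule_masks(small_config)
        for cond, cells in masks.items():
            for cell, expected in cells[:6]:
                measured = contact_ratio(cell).ratios
                assert measured == pytest.approx(expected)

    def test_condition_shifts_contact(self, small_config):
        masks = gen_granule_masks(small_config)
        means = {c: np.mean([r for _, exp in cells for r in exp])
                 for c, cells in masks.items()}
        assert means["control"] > means["tdrd7_kd"]

    def test_determinism(self, small_config):
        a = gen_granule_masks(small_config)
        b = gen_granule_masks(small_config)
        np.testing.assert_array_equal(a["control"][0][0].mask,
                                      b["control"][0][0].mask)


class TestGenGeneModels:
    def test_models_are_consistent(self, small_config):
        models = gen_gene_models(small_config)
        assert (models["exons"]["start"] < models["exons"]["end"]).all()
        assert set(models["tss"]["gene_id"]) == \
            set(models["exons"]["gene_id"])
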