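"""Signal matrices, their transforms, PCA embedding, batch SOM and
feature annotation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from germfate.chromatin import (SignalMatrix, annotate_elements, call_peaks,
                                center_columns, center_rows, log_transform,
                                pca_embed, prepare_cutsites, signal_matrix,
                                som_cluster, tss_distance_ecdf)


def element_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestSignalMatrix:
    def test_single_cutsite_at_center_sums_to_window(self):
        # one cut site at the element center with 5-bp extension: an
        # 11-bp coverage patch inside the 601-bp window; the fragment's
        # other cut site lands outside the window
        frag = pd.DataFrame({"chrom": ["1"], "start": [4995], "end": [5804],
                             "mapq": [60]})
        # corrected cut sites: 5000 (in window) and 5800 (outside)
        track = prepare_cutsites(frag, {"1": 10_000}, extension=5)
        elements = element_frame([("1", 4800, 5200)])  # midpoint 5000
        sm = signal_matrix(elements, {"s": track}, normalize=False)
        assert sm.window == 601
        assert sm.values.iloc[0, 0] == 11

    def test_library_normalization_invariant_to_duplication(self, rng):
        start = rng.integers(100, 9000, 300)
        frag = pd.DataFrame({"chrom": "1", "start": start,
                             "end": start + 80, "mapq": 60})
        doubled = pd.concat([frag, frag], ignore_index=True)
        t1 = prepare_cutsites(frag, {"1": 10_000}, extension=5)
        t2 = prepare_cutsites(doubled, {"1": 10_000}, extension=5)
        elements = element_frame([("1", 2000, 2400), ("1", 6000, 6400)])
        a = signal_matrix(elements, {"s": t1})
        b = signal_matrix(elements, {"s": t2})
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_boundary_window_truncated_and_flagged(self):
        frag = pd.DataFrame({"chrom": ["1"], "start": [10], "end": [100],
                             "mapq": [60]})
        track = prepare_cutsites(frag, {"1": 10_000}, extension=5)
        sm = signal_matrix(element_frame([("1", 0, 100)]), {"s": track})
        assert sm.truncated[0]


class TestTransforms:
    def _matrix(self, rng):
        vals = pd.DataFrame(rng.random((40, 6)) * 1e-5,
                            columns=[f"s{i}" for i in range(6)])
        return SignalMatrix(values=vals, window=601)

    def test_centering_invariants(self, rng):
        sm = log_transform(self._matrix(rng))
        cc = center_columns(sm)
        assert np.abs(cc.values.mean(axis=0)).max() < 1e-9
        rr = center_rows(cc)
        assert np.abs(rr.values.mean(axis=1)).max() < 1e-9

    def test_precondition_enforced(self, rng):
        with pytest.raises(ValueError):
            pca_embed(self._matrix(rng))  # not log-transformed
        with pytest.raises(ValueError):
            som_cluster(log_transform(self._matrix(rng)))  # not centered


class TestPca:
    def _prepared(self, rng, vals=None):
        if vals is None:
            vals = rng.random((50, 6))
        sm = SignalMatrix(values=pd.DataFrame(
            vals, columns=[f"s{i}" for i in range(vals.shape[1])]),
            window=601)
        return center_columns(log_transform(sm))

    def test_duplicated_samples_identical_coordinates(self, rng):
        vals = rng.random((50, 4))
        vals[:, 3] = vals[:, 0]
        res = pca_embed(self._prepared(rng, vals), n_components=2)
        np.testing.assert_allclose(res.coordinates.iloc[0],
                                   res.coordinates.iloc[3], atol=1e-9)

    def test_variance_explained_properties(self, rng):
        res = pca_embed(self._prepared(rng), n_components=5)
        v = res.variance_explained
        assert v.sum() <= 1 + 1e-12
        assert (np.diff(v) <= 1e-12).all()

    def test_full_reconstruction(self, rng):
        sm = self._prepared(rng)
        res = pca_embed(sm, n_components=6)
        x = sm.values.to_numpy()
        x = x - x.mean(axis=0, keepdims=True)
        recon = res.components @ res.coordinates.to_numpy().T
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_rank_clipping_warns(self, rng):
        vals = np.tile(rng.random((30, 1)), (1, 4))
        with pytest.warns(UserWarning):
            res = pca_embed(self._prepared(rng, vals), n_components=4)
        assert res.coordinates.shape[1] < 4


def planted_pattern_matrix(seed, n_per=60, n_samples=8):
    """Three element groups: up in the first half of samples, up in the
    second half, and flat."""
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    rows, labels = [], []
    for kind in range(3):
        base = np.zeros(n_samples)
        if kind == 0:
            base[:half] = 2.0
        elif kind == 1:
            base[half:] = 2.0
        block = base + rng.normal(0, 0.3, (n_per, n_samples))
        rows.append(block)
        labels += [kind] * n_per
    vals = pd.DataFrame(np.vstack(rows),
                        columns=[f"s{i}" for i in range(n_samples)])
    sm = SignalMatrix(values=np.exp(vals) * 1e-6, window=601)
    return center_rows(center_columns(log_transform(sm))), np.array(labels)


class TestSom:
    def test_grid_defines_cluster_count(self):
        sm, _ = planted_pattern_matrix(0)
        fit = som_cluster(sm, grid=(3, 3), epochs=30, seed=1)
        assert fit.n_units == 9
        assert fit.codebook.shape == (9, 8)
        assert fit.assignment.max() < 9

    def test_planted_patterns_recovered(self):
        # the SOM refines the three planted patterns over its nine units;
        # agglomerating the codebook to three groups (the standard
        # two-level read-out) must recover the planted partition
        from sklearn.cluster import AgglomerativeClustering

        sm, labels = planted_pattern_matrix(2)
        fit = som_cluster(sm, grid=(3, 3), epochs=50, seed=3)
        unit_group = AgglomerativeClustering(n_clusters=3) \
            .fit_predict(fit.codebook)
        assert adjusted_rand_score(labels,
                                   unit_group[fit.assignment]) >= 0.8

    def test_quantization_error_decreases(self):
        sm, _ = planted_pattern_matrix(4)
        fit = som_cluster(sm, grid=(3, 3), epochs=50, seed=5)
        qe = fit.quantization_error
        assert qe[-1] <= qe[0]
        # after the first reorganization epoch (the wide neighborhood
        # pulls the random-row codebook toward the mean) the error is
        # non-increasing
        assert (np.diff(qe[1:]) <= 1e-6).all()

    def test_oversized_grid_raises(self):
        sm, _ = planted_pattern_matrix(6, n_per=2)
        with pytest.raises(ValueError):
            som_cluster(sm, grid=(5, 5), epochs=5, seed=0)

    def test_seed_determinism(self):
        sm, _ = planted_pattern_matrix(8)
        a = som_cluster(sm, grid=(3, 3), epochs=20, seed=9)
        b = som_cluster(sm, grid=(3, 3), epochs=20, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_allclose(a.codebook, b.codebook)


GENE_MODELS = {
    "tss": pd.DataFrame({"chrom": ["1", "1"], "pos": [50_000, 90_000],
                         "strand": ["+", "-"],
                         "gene_id": ["gA", "gB"]}),
    "exons": pd.DataFrame({
        "chrom": ["1", "1", "1"],
        "start": [50_000, 55_000, 85_000],
        "end": [50_500, 55_400, 90_000],
        "gene_id": ["gA", "gA", "gB"]}),
}


class TestAnnotateElements:
    def test_promoter_within_1kb(self):
        el = element_frame([("1", 48_800, 49_202)])  # midpoint 49_001
        out = annotate_elements(el, GENE_MODELS)
        assert out["feature"].iloc[0] == "promoter"
        assert out["tss_distance"].iloc[0] == -999

    def test_intron_beyond_promoter(self):
        el = element_frame([("1", 52_800, 53_200)])  # midpoint 53_000
        out = annotate_elements(el, GENE_MODELS)
        assert out["feature"].iloc[0] == "intron"

    def test_exon_precedence_over_intron(self):
        el = element_frame([("1", 55_100, 55_300)])
        out = annotate_elements(el, GENE_MODELS)
        assert out["feature"].iloc[0] == "exon"

    def test_intergenic_far_from_everything(self):
        el = element_frame([("1", 20_000, 20_400)])
        out = annotate_elements(el, GENE_MODELS)
        assert out["feature"].iloc[0] == "intergenic"

    def test_minus_strand_orients_signed_distance(self):
        el = element_frame([("1", 91_800, 92_202)])  # midpoint 92_001
        out = annotate_elements(el, GENE_MODELS)
        # downstream of gA in genome coords but upstream of gB (minus)
        assert out["tss_distance"].iloc[0] == -2001

    def test_empty_models_all_intergenic(self):
        el = element_frame([("1", 100, 200)])
        out = annotate_elements(el, {})
        assert out["feature"].iloc[0] == "intergenic"
        assert np.isinf(out["tss_distance"].iloc[0])

    def test_cumulative_distance_curve(self):
        el = element_frame([("1", s, s + 200) for s in
                            (10_000, 30_000, 48_000, 70_000)])
        out = annotate_elements(el, GENE_MODELS)
        curve = tss_distance_ecdf(out)
        frac = curve["cumulative_fraction"].to_numpy()
        assert (np.diff(frac) >= 0).all()
        assert frac[-1] == 1.0
        assert (np.diff(curve["distance"]) >= 0).all()
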