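"""Unit tests for count normalization, TPM, the zygotic-gene rule,
ERCC calibration and the NB differential test."""

import numpy as np
import pandas as pd
import pytest

from germfate.exceptions import (InsufficientDataError, NoReferenceError,
                                 UndefinedTPMError)
from germfate.expression import (classify_zygotic, differential_counts,
                                 ercc_calibrate, rpkm, size_factors, tpm)

from conftest import make_count_matrix


class TestSizeFactors:
    def test_identical_columns_are_unit(self):
        cm = make_count_matrix({"s1": [10, 30, 50], "s2": [10, 30, 50]})
        np.testing.assert_allclose(size_factors(cm).factors, [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        # geometric-mean reference per feature; ratios are 1/sqrt(2) and
        # sqrt(2) for every feature, so the medians are too
        cm = make_count_matrix({"s1": [10, 30, 50], "s2": [20, 60, 100]})
        np.testing.assert_allclose(size_factors(cm).factors,
                                   [0.70710678, 1.41421356], atol=1e-4)

    def test_zero_feature_excluded_from_reference_but_normalized(self):
        cm = make_count_matrix({"s1": [10, 0, 50], "s2": [20, 40, 100]})
        sf = size_factors(cm)
        np.testing.assert_allclose(sf.factors, [0.70710678, 1.41421356],
                                   atol=1e-4)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(1, 1000, size=(50, 6))
        cm = make_count_matrix({f"s{i}": counts[:, i] for i in range(6)})
        factors = size_factors(cm).factors
        assert abs(np.exp(np.mean(np.log(factors))) - 1.0) < 1e-9

    def test_scale_equivariance(self, rng):
        counts = rng.integers(1, 1000, size=(80, 3))
        cm = make_count_matrix({f"s{i}": counts[:, i] for i in range(3)})
        base = size_factors(cm).factors
        scaled = counts.astype(float).copy()
        scaled[:, 0] *= 4
        cm2 = make_count_matrix({f"s{i}": scaled[:, i] for i in range(3)})
        new = size_factors(cm2).factors
        # ratio of factors for sample 0 vs others changes by exactly 4
        np.testing.assert_allclose((new.iloc[0] / new.iloc[1])
                                   / (base.iloc[0] / base.iloc[1]),
                                   4.0, rtol=1e-9)

    def test_no_common_nonzero_feature_raises(self):
        cm = make_count_matrix({"s1": [10, 0], "s2": [0, 5]})
        with pytest.raises(NoReferenceError):
            size_factors(cm)


class TestTpm:
    def test_length_normalization(self):
        cm = make_count_matrix({"s": [100, 300]}, lengths=[1000, 3000])
        np.testing.assert_allclose(tpm(cm)["s"], [500000.0, 500000.0])

    def test_equal_lengths_proportional_to_counts(self):
        cm = make_count_matrix({"s": [10, 30]}, lengths=[500, 500])
        t = tpm(cm)["s"]
        np.testing.assert_allclose(t.iloc[1] / t.iloc[0], 3.0)

    def test_columns_sum_to_one_million(self, rng):
        counts = rng.integers(0, 500, size=(40, 4))
        counts[0] += 1  # keep every column nonzero
        cm = make_count_matrix({f"s{i}": counts[:, i] for i in range(4)},
                               lengths=rng.integers(200, 5000, 40))
        np.testing.assert_allclose(tpm(cm).sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_column_raises(self):
        cm = make_count_matrix({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(UndefinedTPMError):
            tpm(cm)


class TestClassifyZygotic:
    @pytest.mark.parametrize("t1, t2, expected", [
        (0.5, 10.0, "zygotic"),       # silent pre-activation, then rises
        (5.0, 10.0, "not_zygotic"),   # maternal contribution present
        (0.5, 0.4, "not_zygotic"),    # no increase
        (1.9, 1.9, "not_zygotic"),    # tie counts as no increase
        (2.0, 10.0, "not_zygotic"),   # threshold is strict
    ])
    def test_rule(self, t1, t2, expected):
        df = pd.DataFrame({"pre": [t1], "post": [t2], "later": [0.0]},
                          index=["g"])
        assert classify_zygotic(df, ["pre", "post", "later"])["g"] == expected

    def test_invariant_to_gene_order_and_later_stages(self, rng):
        df = pd.DataFrame({"pre": rng.uniform(0, 5, 30),
                           "post": rng.uniform(0, 20, 30),
                           "later": rng.uniform(0, 20, 30)},
                          index=[f"g{i}" for i in range(30)])
        a = classify_zygotic(df, ["pre", "post", "later"])
        shuffled = df.sample(frac=1.0, random_state=0)
        b = classify_zygotic(shuffled, ["pre", "post"])
        assert (a.loc[b.index] == b).all()

    def test_missing_stage_raises(self):
        df = pd.DataFrame({"pre": [1.0]})
        with pytest.raises(ValueError):
            classify_zygotic(df, ["pre", "post"])


class TestErccCalibrate:
    def test_exact_log_linear_recovery(self):
        conc = np.array([1.0, 10.0, 100.0, 1000.0])
        obs = 10 ** (2.0 + 0.5 * np.log10(conc))
        fit = ercc_calibrate(conc, obs)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        # inversion round-trips
        np.testing.assert_allclose(fit.predict_concentration(obs), conc,
                                   rtol=1e-10)

    def test_low_rpkm_excluded(self):
        conc = np.array([0.1, 1.0, 10.0, 100.0])
        obs = np.array([0.5, 2.0, 20.0, 200.0])
        fit = ercc_calibrate(conc, obs)
        assert fit.n_used == 3

    def test_matches_normal_equations_oracle(self, rng):
        conc = rng.uniform(1, 1e4, 50)
        obs = 10 ** (1.0 + 0.9 * np.log10(conc) + rng.normal(0, 0.1, 50))
        fit = ercc_calibrate(conc, obs)
        x = np.log10(conc)
        y = np.log10(obs)
        X = np.column_stack([np.ones_like(x), x])
        a, b = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(a, abs=1e-10)
        assert fit.slope == pytest.approx(b, abs=1e-10)

    def test_noise_recovery(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            conc = np.geomspace(1, 1e5, 50)
            obs = 10 ** (1.5 + 1.0 * np.log10(conc) + r.normal(0, 0.1, 50))
            fit = ercc_calibrate(conc, obs)
            hits += (abs(fit.intercept - 1.5) < 0.05
                     and abs(fit.slope - 1.0) < 0.05)
        assert hits >= 9

    def test_insufficient_points_raise(self):
        with pytest.raises(InsufficientDataError):
            ercc_calibrate([1.0, 10.0], [0.5, 0.2])


class TestRpkm:
    def test_definition(self):
        counts = pd.Series([100, 200], index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        out = rpkm(counts, lengths, total_reads=1e6)
        np.testing.assert_allclose(out, [100.0, 100.0])


class TestDifferentialCounts:
    def test_identical_groups_find_nothing(self, nb_counts):
        cm, ga, gb = nb_counts(300, 3, 0.05, seed=5)
        # compare a group against itself's distribution: split same draws
        res = differential_counts(cm, ga, gb)
        assert not res.table["significant"].any() or \
            res.table["significant"].mean() < 0.01

    def test_same_samples_zero_logfc(self):
        cm = make_count_matrix({"a1": [10, 20], "a2": [12, 18],
                                "b1": [10, 20], "b2": [12, 18]})
        res = differential_counts(cm, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        assert not res.table["significant"].any()

    def test_overlapping_groups_raise(self, nb_counts):
        cm, ga, gb = nb_counts(50, 3, 0.05)
        with pytest.raises(ValueError):
            differential_counts(cm, ga, ga)

    def test_planted_fold_changes_recovered(self, nb_counts):
        cm, ga, gb = nb_counts(1000, 3, 0.05, fold=4.0, n_planted=50, seed=3)
        res = differential_counts(cm, ga, gb)
        sig = res.table["significant"].to_numpy()
        assert sig[:50].mean() >= 0.8
        called = sig.sum()
        assert called == 0 or sig[50:].sum() / called <= 0.1
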