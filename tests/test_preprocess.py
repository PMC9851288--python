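import numpy as np
import pandas as pd
import pytest

from bulkcraft.matrixio import ExpressionMatrix, MatrixIOError
from bulkcraft.preprocess import (
    NoiseResult,
    NormalisationSpec,
    apply_noise_removal,
    detect_noise_threshold,
    median_of_ratios_factors,
    normalise,
    tmm_factors,
)

from oracles import naive_tmm_factors


class TestNoiseDetection:
    def test_threshold_brackets_noise_signal_boundary(self, noise_fixture):
        """Uniform sub-10 counts vs perfectly correlated >=100 features: the
        detected threshold must fall between the two regimes."""
        nr = detect_noise_threshold(noise_fixture, window_size=40, step=5,
                                    similarity_threshold=0.25)
        assert 10 <= nr.threshold <= 100

    def test_identical_samples_give_smallest_window_mean(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 500, size=60).astype(float)
        data = pd.DataFrame({f"s{j}": col for j in range(3)},
                            index=[f"g{i}" for i in range(60)])
        m = ExpressionMatrix(data)
        nr = detect_noise_threshold(m, window_size=10, step=5)
        assert nr.threshold == pytest.approx(min(a for a, _ in nr.window_stats))
        assert all(c == pytest.approx(1.0) for _, c in nr.window_stats)

    def test_window_stats_ordered_and_bounded(self, noise_fixture):
        nr = detect_noise_threshold(noise_fixture, window_size=40, step=5)
        abundances = [a for a, _ in nr.window_stats]
        assert abundances == sorted(abundances)
        assert all(-1 - 1e-12 <= c <= 1 + 1e-12 for _, c in nr.window_stats)

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.5, -0.1])
    def test_similarity_threshold_validated(self, noise_fixture, bad):
        with pytest.raises(MatrixIOError):
            detect_noise_threshold(noise_fixture, similarity_threshold=bad)

    def test_window_larger_than_matrix_rejected(self, tiny_matrix):
        with pytest.raises(MatrixIOError, match="window_size"):
            detect_noise_threshold(tiny_matrix, window_size=10)

    def test_permutation_invariance(self, noise_fixture):
        nr = detect_noise_threshold(noise_fixture, window_size=40, step=5)
        rng = np.random.default_rng(9)
        data = noise_fixture.data
        shuffled = data.iloc[rng.permutation(len(data)), rng.permutation(data.shape[1])]
        nr2 = detect_noise_threshold(ExpressionMatrix(shuffled), window_size=40, step=5)
        assert nr2.threshold == pytest.approx(nr.threshold)


class TestNoiseRemoval:
    def _matrix(self, rows, ids=None):
        ids = ids or [f"g{i}" for i in range(len(rows))]
        return ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=["s1", "s2"]))

    def test_drop_keeps_features_above_threshold(self):
        m = self._matrix([[5.0, 5.0], [50.0, 50.0]])
        out = apply_noise_removal(m, NoiseResult(threshold=10.0))
        assert out.feature_ids == ["g1"]
        assert out.state == "denoised"

    def test_zero_threshold_is_identity(self, tiny_matrix):
        out = apply_noise_removal(tiny_matrix, NoiseResult(threshold=0.0))
        np.testing.assert_array_equal(out.values, tiny_matrix.values)
        assert out.state == "denoised"

    def test_floor_mode(self):
        m = self._matrix([[2.0, 12.0]])
        out = apply_noise_removal(m, NoiseResult(threshold=10.0), mode="floor")
        np.testing.assert_array_equal(out.values, [[10.0, 12.0]])

    def test_floor_drops_features_left_constant(self):
        m = self._matrix([[2.0, 3.0], [2.0, 12.0]])
        out = apply_noise_removal(m, NoiseResult(threshold=10.0), mode="floor")
        assert out.feature_ids == ["g1"]

    def test_degenerate_threshold_errors(self, tiny_matrix):
        with pytest.raises(MatrixIOError, match="manual"):
            apply_noise_removal(tiny_matrix, NoiseResult(threshold=np.inf))


class TestNormalisation:
    def test_rpm_small_example(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [10.0, 90.0], "s2": [90.0, 10.0]},
                                          index=["g1", "g2"]), state="denoised")
        out = normalise(m, "rpm")
        np.testing.assert_allclose(out.values, [[1e5, 9e5], [9e5, 1e5]])
        assert out.state == "normalised"

    def test_rpm_column_sums(self, six_sample_matrix):
        out = normalise(six_sample_matrix.with_data(six_sample_matrix.data, "denoised"), "rpm")
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_quantile_small_example(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                                          index=list("abc")), state="denoised")
        out = normalise(m, "quantile")
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_quantile_sorted_columns_identical(self):
        # continuous values: tie-free, so every column maps exactly onto the
        # mean order statistics
        rng = np.random.default_rng(21)
        data = pd.DataFrame(rng.random((50, 6)) * 1e3,
                            index=[f"g{i:02d}" for i in range(50)],
                            columns=[f"s{j}" for j in range(6)])
        out = normalise(ExpressionMatrix(data, state="denoised"), "quantile")
        cols = np.sort(out.values, axis=0)
        for j in range(1, cols.shape[1]):
            np.testing.assert_allclose(cols[:, j], cols[:, 0], atol=1e-12)

    def test_quantile_ties_get_mean_reference(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]},
                                          index=list("abc")), state="denoised")
        out = normalise(m, "quantile")
        ref = np.sort(m.values, axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        # tied pair in s1 shares the mean of the two lowest reference values
        np.testing.assert_allclose(out.data["s1"].to_numpy(),
                                   [(ref[0] + ref[1]) / 2, (ref[0] + ref[1]) / 2, ref[2]])

    def test_median_column_medians_are_one(self, six_sample_matrix):
        out = normalise(six_sample_matrix.with_data(six_sample_matrix.data, "denoised"), "median")
        np.testing.assert_array_equal(np.median(out.values, axis=0), 1.0)

    def test_median_zero_median_advises_denoising(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0, 0.0, 5.0], "s2": [1.0, 2.0, 3.0]},
                                          index=list("abc")), state="denoised")
        with pytest.raises(MatrixIOError, match="denoise"):
            normalise(m, "median")

    def test_median_of_ratios_doubled_column(self):
        rng = np.random.default_rng(4)
        a = rng.integers(10, 1000, size=30).astype(float)
        m = ExpressionMatrix(pd.DataFrame({"s1": a, "s2": 2 * a},
                                          index=[f"g{i}" for i in range(30)]),
                             state="denoised")
        f = median_of_ratios_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [2 ** -0.5, 2 ** 0.5], atol=1e-12)

    def test_factor_methods_identical_columns_give_one(self):
        col = np.arange(1.0, 21.0)
        m = ExpressionMatrix(pd.DataFrame({"s1": col, "s2": col},
                                          index=[f"g{i}" for i in range(20)]),
                             state="denoised")
        np.testing.assert_allclose(median_of_ratios_factors(m).to_numpy(), 1.0, atol=1e-12)
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), 1.0, atol=1e-12)

    def test_factor_methods_sample_relabelling_permutes_factors(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.integers(1, 2000, size=(40, 4)).astype(float),
                            index=[f"g{i}" for i in range(40)],
                            columns=["s1", "s2", "s3", "s4"])
        m = ExpressionMatrix(data, state="denoised")
        perm = ["s3", "s1", "s4", "s2"]
        mp = ExpressionMatrix(data[perm], state="denoised")
        for fn in (median_of_ratios_factors, tmm_factors):
            f, fp = fn(m), fn(mp)
            np.testing.assert_allclose(fp.to_numpy(), f.loc[perm].to_numpy(), rtol=1e-12)

    def test_tmm_matches_naive_oracle(self):
        """20-gene fixture: the TMM factors equal an independent step-by-step
        transcription of the trim-and-weight formula."""
        rng = np.random.default_rng(17)
        counts = rng.integers(1, 5000, size=(20, 4)).astype(float)
        counts[:, 1] *= 3  # deliberately unbalanced library
        m = ExpressionMatrix(pd.DataFrame(counts, index=[f"g{i:02d}" for i in range(20)],
                                          columns=list("abcd")), state="denoised")
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), naive_tmm_factors(counts),
                                   atol=1e-10)

    def test_tmm_normalised_values_follow_factors(self):
        rng = np.random.default_rng(18)
        counts = rng.integers(1, 3000, size=(25, 3)).astype(float)
        m = ExpressionMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(25)],
                                          columns=list("xyz")), state="denoised")
        out, f = normalise(m, "tmm", return_factors=True)
        lib = counts.sum(axis=0)
        np.testing.assert_allclose(out.values, counts / (lib * f.to_numpy()), rtol=1e-12)
        assert f.prod() == pytest.approx(1.0)

    def test_all_zero_column_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 2.0]},
                                          index=["g1", "g2"]), state="denoised")
        with pytest.raises(MatrixIOError, match="s1"):
            normalise(m, "rpm")

    def test_unknown_method_rejected(self):
        with pytest.raises(MatrixIOError):
            NormalisationSpec("tpm")

    def test_raw_matrix_warns(self, tiny_matrix):
        with pytest.warns(UserWarning, match="denoising"):
            normalise(tiny_matrix, "rpm")
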