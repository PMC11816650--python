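import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subtype_awa import (
    DataValidationError,
    OmicsKind,
    PreprocessConfig,
    dedup_copy_number,
    filter_methylation,
    impute_and_standardize,
    preprocess_expression,
    preprocess_matrix,
    preprocess_proteomics,
)
from conftest import mk_matrix


class TestDedupCopyNumber:
    def test_identical_columns_keep_first(self):
        m = mk_matrix(OmicsKind.COPY_NUMBER, [[1, 1], [2, 2]])
        out = dedup_copy_number(m)
        assert out.feature_ids == ["f1"]

    def test_all_distinct_identity(self):
        m = mk_matrix(OmicsKind.COPY_NUMBER, [[1, 2, 3], [4, 5, 6]])
        out = dedup_copy_number(m)
        assert out.feature_ids == m.feature_ids
        np.testing.assert_array_equal(out.values, m.values)

    def test_two_duplicate_groups(self):
        # features 2 and 4 identical; features 3 and 5 identical -> keep 1,2,3
        cols = np.array([[0, 1, 2, 1, 2], [9, 8, 7, 8, 7]], dtype=float)
        out = dedup_copy_number(mk_matrix(OmicsKind.COPY_NUMBER, cols))
        assert out.feature_ids == ["f1", "f2", "f3"]

    def test_nan_patterns_compare_equal(self):
        cols = np.array([[np.nan, np.nan, 1], [2, 2, 2]])
        out = dedup_copy_number(mk_matrix(OmicsKind.COPY_NUMBER, cols))
        assert out.feature_ids == ["f1", "f3"]


class TestFilterMethylation:
    def test_boundary_inclusive(self):
        m = mk_matrix(OmicsKind.METHYLATION, [[0.3, 0.1], [0.3, 0.1]])
        out = filter_methylation(m)
        assert out.feature_ids == ["f1"]  # mean 0.3 kept, 0.1 removed

    def test_mean_over_nonmissing(self):
        m = mk_matrix(OmicsKind.METHYLATION, [[0.2], [0.5]])
        assert filter_methylation(m).n_features == 1  # mean 0.35 >= 0.3

    def test_all_missing_probe_dropped_with_warning(self, caplog):
        m = mk_matrix(OmicsKind.METHYLATION, [[np.nan, 0.5], [np.nan, 0.5]])
        with caplog.at_level(logging.WARNING, logger="subtype_awa"):
            out = filter_methylation(m)
        assert out.feature_ids == ["f2"]
        assert any("all-missing" in msg for msg in caplog.messages)


class TestPreprocessExpression:
    def test_log_offset_maps_zero_to_zero(self):
        m = mk_matrix(OmicsKind.MRNA, [[0.0], [3.0]])
        out = preprocess_expression(m, PreprocessConfig(mad_quantile=0.0))
        assert out.values[0, 0] == 0.0
        assert out.values[1, 0] == 2.0  # log2(3+1)

    def test_negative_value_rejected(self):
        m = mk_matrix(OmicsKind.MRNA, [[-1.0], [2.0]])
        with pytest.raises(DataValidationError, match="negative"):
            preprocess_expression(m)

    def test_constant_feature_removed_by_variance_step(self):
        m = mk_matrix(OmicsKind.MRNA, [[7.0, 1.0], [7.0, 2.0]])
        out = preprocess_expression(m, PreprocessConfig(mad_quantile=0.0, variance_threshold=0.0))
        assert out.feature_ids == ["f2"]

    def test_mad_filter_removes_lowest_half(self):
        # on the log2 scale, features get MADs {0, 0.1, 2, 3}: 4 samples with
        # pattern (-1,-1,1,1)*c around a base level have MAD c after log2
        base = 8.0
        pattern = np.array([-1.0, -1.0, 1.0, 1.0])
        mads = [0.0, 0.1, 2.0, 3.0]
        logged = np.column_stack([base + pattern * c for c in mads])
        m = mk_matrix(OmicsKind.MRNA, np.exp2(logged) - 1.0)
        out = preprocess_expression(m, PreprocessConfig(mad_quantile=0.5))
        assert out.feature_ids == ["f3", "f4"]

    def test_mad_not_variance_drives_low_information_removal(self):
        # f1 has the lowest MAD (0) but by far the highest variance (one
        # outlier sample): the MAD step must be what removes it
        logged = np.array([
            [5.0, 4.0, 4.0],
            [5.0, 5.0, 4.5],
            [5.0, 6.0, 5.5],
            [5.0, 4.0, 6.0],
            [25.0, 6.0, 5.0],
        ])  # per-feature MADs: 0, 1, 0.5
        m = mk_matrix(OmicsKind.MRNA, np.exp2(logged) - 1.0)
        out = preprocess_expression(m, PreprocessConfig(mad_quantile=1 / 3))
        assert out.feature_ids == ["f2", "f3"]


class TestPreprocessProteomics:
    def test_missingness_threshold_strict(self):
        vals = np.array([
        # f1: 3/4 missing (dropped); f2: 2/4 missing (kept)
            [np.nan, np.nan],
            [np.nan, np.nan],
            [np.nan, 1.0],
            [4.0, 2.0],
        ])
        out = preprocess_proteomics(
            mk_matrix(OmicsKind.PROTEOMICS, vals), PreprocessConfig(mad_quantile=0.0)
        )
        assert out.feature_ids == ["f2"]

    def test_median_normalization(self):
        vals = np.array([[1.0, 3.0, 5.0], [2.0, 4.0, 6.0]])
        out = preprocess_proteomics(
            mk_matrix(OmicsKind.PROTEOMICS, vals), PreprocessConfig(mad_quantile=0.0)
        )
        np.testing.assert_allclose(out.values[0], [-2.0, 0.0, 2.0])
        np.testing.assert_allclose(out.values[1], [-2.0, 0.0, 2.0])

    def test_missing_imputed_with_feature_mean(self):
        vals = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        out = preprocess_proteomics(
            mk_matrix(OmicsKind.PROTEOMICS, vals), PreprocessConfig(mad_quantile=0.0)
        )
        assert not np.isnan(out.values).any()


class TestImputeAndStandardize:
    def test_sample_mean_imputation(self):
        m = mk_matrix(OmicsKind.MRNA, [[1.0, np.nan, 3.0], [2.0, 5.0, 2.0]])
        # row mean of sample 1 is (1+3)/2 = 2 -> imputed before scaling;
        # feature f2 becomes (2, 5) -> standardized to (-1, 1)
        out = impute_and_standardize(m)
        np.testing.assert_allclose(out.values[:, 1], [-1.0, 1.0])

    def test_constant_feature_zeroed_with_warning(self, caplog):
        m = mk_matrix(OmicsKind.MRNA, [[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        with caplog.at_level(logging.WARNING, logger="subtype_awa"):
            out = impute_and_standardize(m)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0, 0.0])
        assert any("constant" in msg for msg in caplog.messages)

    def test_two_point_feature(self):
        m = mk_matrix(OmicsKind.MRNA, [[1.0], [3.0]])
        out = impute_and_standardize(m)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])  # population SD = 1

    def test_all_missing_sample_rejected(self):
        m = mk_matrix(OmicsKind.MRNA, [[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(DataValidationError, match="s1"):
            impute_and_standardize(m)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(1, 6), st.integers(0, 10_000))
    def test_output_mean_zero_variance_one(self, n, p, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n, p))
        vals[rng.random((n, p)) < 0.2] = np.nan
        vals[:, 0] = np.where(np.isnan(vals[:, 0]), np.nan, 1.0)  # maybe-constant col
        if np.isnan(vals).all(axis=1).any():
            vals[:, -1] = 1.0
        out = impute_and_standardize(mk_matrix(OmicsKind.MRNA, vals))
        means = out.values.mean(axis=0)
        var = out.values.var(axis=0)
        assert np.all(np.abs(means) < 1e-10)
        for j in range(p):
            assert var[j] == pytest.approx(1.0) or var[j] == 0.0


class TestPipelineInvariants:
    @pytest.mark.parametrize("kind,builder", [
        (OmicsKind.COPY_NUMBER, lambda rng, n, p: rng.normal(size=(n, p))),
        (OmicsKind.METHYLATION, lambda rng, n, p: rng.random((n, p))),
        (OmicsKind.MRNA, lambda rng, n, p: rng.exponential(5.0, size=(n, p))),
        (OmicsKind.PROTEOMICS, lambda rng, n, p: rng.normal(size=(n, p))),
    ])
    def test_sample_order_preserved_and_deterministic(self, kind, builder):
        rng = np.random.default_rng(3)
        vals = builder(rng, 6, 10)
        vals[rng.random(vals.shape) < 0.1] = np.nan
        if kind is OmicsKind.MRNA:
            vals = np.abs(np.nan_to_num(vals, nan=np.nan))
        m = mk_matrix(kind, vals)
        out1 = preprocess_matrix(m, PreprocessConfig())
        out2 = preprocess_matrix(m, PreprocessConfig())
        assert out1.sample_ids == m.sample_ids
        np.testing.assert_array_equal(out1.values, out2.values)  # byte-identical
        assert set(out1.feature_ids) <= set(m.feature_ids)
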