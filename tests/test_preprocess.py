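import numpy as np
import pytest

from proteoscreen import (
    IntensityMatrix,
    filter_missing_features,
    impute_minimum,
    normalize,
    read_matrix,
    read_maxquant,
)
from proteoscreen.preprocess import MatrixFormatError, write_matrix


def make_matrix(values, mask=None, log=True):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    return IntensityMatrix(values, mask,
                           [f"P{i}" for i in range(values.shape[0])],
                           [f"S{i}" for i in range(values.shape[1])],
                           log_transformed=log)


class TestReadMaxquant:
    def test_filters_decoy_and_contaminant_rows(self, maxquant_file):
        m = read_maxquant(maxquant_file, "LFQ intensity")
        assert m.n_features == 3 and m.n_samples == 2
        assert m.feature_ids == ["PG1", "PG4", "PG5"]
        assert m.sample_ids == ["A", "B"]

    def test_zero_intensity_becomes_missing(self, maxquant_file):
        m = read_maxquant(maxquant_file, "LFQ intensity")
        i = m.feature_ids.index("PG4")
        assert m.missing_mask[i, m.sample_ids.index("A")]
        assert not m.missing_mask[i, m.sample_ids.index("B")]

    def test_intensity_prefix_does_not_capture_lfq_columns(self, maxquant_file):
        m = read_maxquant(maxquant_file, "Intensity")
        assert m.sample_ids == ["A", "B"]
        assert m.values[m.feature_ids.index("PG1"), 0] == 1100

    def test_missing_prefix_raises_naming_it(self, maxquant_file):
        with pytest.raises(MatrixFormatError, match="iBAQ"):
            read_maxquant(maxquant_file, "iBAQ")


class TestReadMatrix:
    def test_empty_cell_is_missing(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\tS1\tS2\nP1\t1.5\t2.5\nP2\t\t4.0\nP3\t5.0\t6.0\n")
        m = read_matrix(str(p))
        assert m.missing_mask.sum() == 1
        assert m.missing_mask[1, 0]
        assert m.values[0, 1] == 2.5

    def test_orientation_involution(self, tmp_path):
        p1 = tmp_path / "rows.tsv"
        p1.write_text("feature\tS1\tS2\nP1\t1\t2\nP2\t3\t4\n")
        p2 = tmp_path / "cols.tsv"
        p2.write_text("sample\tP1\tP2\nS1\t1\t3\nS2\t2\t4\n")
        a = read_matrix(str(p1), "features_in_rows")
        b = read_matrix(str(p2), "samples_in_rows")
        np.testing.assert_array_equal(a.values, b.values)
        assert a.sample_ids == b.sample_ids

    def test_duplicate_sample_label_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("feature\tS1\tS1\nP1\t1\t2\n")
        with pytest.raises(MatrixFormatError, match="duplicate"):
            read_matrix(str(p))

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("feature\tS1\nP1\t1.0\nP2\toops\n")
        with pytest.raises(MatrixFormatError, match="P2"):
            read_matrix(str(p))

    def test_round_trip_through_write_matrix(self, small_matrix, tmp_path):
        p = tmp_path / "rt.tsv"
        write_matrix(small_matrix, str(p))
        back = read_matrix(str(p))
        np.testing.assert_array_equal(back.missing_mask, small_matrix.missing_mask)
        obs = ~back.missing_mask
        np.testing.assert_allclose(back.values[obs], small_matrix.values[obs])


class TestFilterMissing:
    def test_strictly_above_threshold_removed(self):
        vals = np.ones((2, 5))
        mask = np.zeros((2, 5), dtype=bool)
        mask[0, :4] = True  # 0.8 missing
        m = filter_missing_features(make_matrix(np.where(mask, np.nan, vals), mask),
                                    0.75)
        assert m.feature_ids == ["P1"]

    def test_exactly_at_threshold_kept(self):
        vals = np.ones((1, 4))
        mask = np.array([[True, True, True, False]])  # exactly 0.75
        m = filter_missing_features(make_matrix(np.where(mask, np.nan, vals), mask),
                                    0.75)
        assert m.n_features == 1

    def test_fully_observed_identity(self, small_matrix):
        full = impute_minimum(small_matrix)
        out = filter_missing_features(full, 0.75)
        np.testing.assert_array_equal(out.values, full.values)
        assert out.sample_ids == full.sample_ids


class TestImputeMinimum:
    def test_stated_rule(self):
        m = make_matrix([[1, np.nan], [3, 4]])
        out = impute_minimum(m)
        np.testing.assert_array_equal(out.values, [[1, 1], [3, 4]])
        assert not out.has_missing

    def test_no_missing_is_identity(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        out = impute_minimum(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_minimum_preserved_and_observed_unchanged(self, synthetic_dataset):
        m = synthetic_dataset.matrix
        out = impute_minimum(m)
        assert out.values.min() == m.observed_values().min()
        obs = ~m.missing_mask
        np.testing.assert_array_equal(out.values[obs], m.values[obs])

    def test_all_missing_rejected(self):
        vals = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            impute_minimum(make_matrix(vals))


class TestNormalize:
    def test_quantile_hand_computed(self):
        # samples (2,4,6) and (3,5,9): k-th order-statistic means (2.5, 4.5, 7.5)
        m = make_matrix(np.array([[2.0, 3.0], [4.0, 5.0], [6.0, 9.0]]))
        out = normalize(m, "quantile")
        np.testing.assert_allclose(out.values,
                                   [[2.5, 2.5], [4.5, 4.5], [7.5, 7.5]])

    def test_quantile_equalizes_sorted_multisets(self):
        # tie-free (complete, continuous) matrix: the defining property holds exactly
        from proteoscreen import generate
        m = generate(30, 150, 0.0, missing_frac=0.0, seed=2).matrix
        out = normalize(m, "quantile")
        ref = np.sort(out.values[:, 0])
        for j in range(1, out.n_samples):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)

    def test_quantile_idempotent(self):
        from proteoscreen import generate
        m = generate(30, 150, 0.0, missing_frac=0.0, seed=2).matrix
        once = normalize(m, "quantile")
        twice = normalize(once, "quantile")
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_quantile_tie_handling(self):
        # tied values within a sample share the mean of their quantile means
        m = make_matrix(np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]]))
        out = normalize(m, "quantile")
        col0 = out.values[:, 0]
        assert col0[0] == col0[1]

    def test_none_is_identity(self, small_matrix):
        full = impute_minimum(small_matrix)
        out = normalize(full, "none")
        np.testing.assert_array_equal(out.values, full.values)

    def test_standardize_moments(self, synthetic_dataset):
        m = impute_minimum(synthetic_dataset.matrix)
        out = normalize(m, "standardize")
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        assert np.abs(out.values.std(axis=1) - 1).max() < 1e-10

    def test_standardize_constant_feature_warns_to_zero(self):
        m = make_matrix(np.array([[2.0, 2.0, 2.0], [1.0, 5.0, 3.0]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = normalize(m, "standardize")
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_loess_removes_systematic_sample_trend(self):
        rng = np.random.default_rng(3)
        base = rng.normal(25, 2, size=(300, 1))
        vals = np.repeat(base, 6, axis=1) + rng.normal(0, 0.05, size=(300, 6))
        vals[:, 0] += 1.5  # one sample shifted off the reference profile
        m = make_matrix(vals)
        out = normalize(m, "loess")
        medians = np.median(out.values, axis=0)
        assert np.abs(medians - medians.mean()).max() < 0.2

    def test_unknown_method_lists_valid_names(self, small_matrix):
        with pytest.raises(ValueError, match="quantile"):
            normalize(impute_minimum(small_matrix), "bogus")

    def test_requires_complete_matrix(self, small_matrix):
        with pytest.raises(ValueError, match="impute"):
            normalize(small_matrix, "quantile")


def test_pipeline_deterministic(synthetic_dataset):
    from proteoscreen.preprocess import preprocess_pipeline
    a = preprocess_pipeline(synthetic_dataset.matrix.copy())
    b = preprocess_pipeline(synthetic_dataset.matrix.copy())
    np.testing.assert_array_equal(a.values, b.values)
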