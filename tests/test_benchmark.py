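import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from proteoscreen import (
    DetectorConfig,
    IntensityMatrix,
    curate_clean,
    detection_point,
    evaluate_config,
    generate,
    make_groups,
    mann_kendall,
    select_models,
    shuffle_features,
)
from proteoscreen.benchmark import (
    DEFAULT_PROPORTIONS,
    BenchmarkResult,
    run_benchmark,
)


def mk_oracle(values):
    """O(n^2) pair-loop Mann-Kendall with tie-corrected variance."""
    v = np.asarray(values, float)
    n = len(v)
    S = sum(np.sign(v[j] - v[i]) for i in range(n) for j in range(i + 1, n))
    _, counts = np.unique(v, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5)
           - sum(t * (t - 1) * (2 * t + 5) for t in counts)) / 18
    if S == 0 or var <= 0:
        return int(S), var, 0.0, 1.0
    Z = (S - np.sign(S)) / np.sqrt(var)
    return int(S), var, float(Z), float(min(1.0, 2 * norm.sf(abs(Z))))


class TestMannKendall:
    def test_strictly_increasing(self):
        res = mann_kendall(np.arange(10))
        assert res.S == 45 and res.var_S == 125
        assert res.Z == pytest.approx(3.9355, abs=1e-4)
        assert res.p_value == pytest.approx(8.3e-5, abs=2e-5)

    def test_strictly_decreasing(self):
        res = mann_kendall([5, 4, 3, 2, 1])
        assert res.S == -10
        assert res.Z == pytest.approx(-2.2045, abs=1e-4)
        assert res.p_value == pytest.approx(0.0275, abs=1e-3)

    def test_constant_sequence(self):
        res = mann_kendall([2.0] * 6)
        assert res.S == 0 and res.p_value == 1.0 and res.Z == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0])

    @given(st.lists(st.sampled_from([1.0, 2.0, 3.0]), min_size=3, max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seq):
        res = mann_kendall(seq)
        S, var, Z, p = mk_oracle(seq)
        assert res.S == S
        assert res.var_S == pytest.approx(var, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reversal_negates_s(self, seq):
        assert mann_kendall(seq).S == -mann_kendall(seq[::-1]).S


class TestDetectionPoint:
    def test_early_drop_then_flat(self):
        # Seq1 trends (p ~ 0.038); Seq2 is stable (p ~ 0.175)
        cvs = [0.50, 0.30] + [0.02] * 8
        assert detection_point(cvs) == pytest.approx(0.2)

    def test_all_constant_stable_from_start(self):
        assert detection_point([0.1] * 10) == pytest.approx(0.1)

    def test_strictly_decreasing_curve(self):
        cvs = np.linspace(1.0, 0.1, 10)
        dp = detection_point(cvs)
        # oracle: suffixes of length >= 5 trend significantly; the 4-point
        # suffix starting at 70% has S=-6, Z=-1.698, p=0.089 -> first stable
        assert dp == pytest.approx(0.7)
        for start, expected_p in [(0, 8.1e-7), (5, 0.0275), (6, 0.089)]:
            assert (mk_oracle(cvs[start:])[3] < 0.05) == (expected_p < 0.05)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            detection_point([0.1] * 7)


def bench_result(cid, dp, acc=0.95):
    r = BenchmarkResult(cid, "KNN", None)
    r.detection_point = dp
    r.accuracy_at_dp = acc
    return r


class TestSelectModels:
    def test_published_distribution_shape(self):
        # detection-point counts 6,49,36,6,2,2,2,0,0 over 10%..90%
        counts = [6, 49, 36, 6, 2, 2, 2, 0, 0]
        results = []
        i = 0
        for dp, c in zip(DEFAULT_PROPORTIONS, counts):
            for _ in range(c):
                results.append(bench_result(f"cfg{i}", dp))
                i += 1
        summary = select_models(results)
        assert summary.balance_point == pytest.approx(0.2)
        assert summary.criterion == pytest.approx(0.3)
        assert len(summary.selected_ids) == 91
        table = summary.detection_point_counts
        assert table["n_detection_points"].tolist() == counts

    def test_stated_rule_small_case(self):
        results = [bench_result("a", 0.1), bench_result("b", 0.2),
                   bench_result("c", 0.2), bench_result("d", 0.4)]
        summary = select_models(results)
        assert summary.balance_point == pytest.approx(0.2)
        assert summary.criterion == pytest.approx(0.3)
        assert summary.selected_ids == ["a", "b", "c"]

    def test_criterion_capped_at_last_node(self):
        summary = select_models([bench_result("a", 0.9)])
        assert summary.balance_point == pytest.approx(0.9)
        assert summary.criterion == pytest.approx(1.0)
        assert summary.selected_ids == ["a"]

    def test_accuracy_gate_is_strict(self):
        results = [bench_result("a", 0.2, acc=0.90)]  # not strictly above
        assert select_models(results).selected_ids == []

    def test_monotone_in_threshold(self):
        results = [bench_result(f"c{i}", 0.2, acc=0.85 + 0.01 * i)
                   for i in range(10)]
        loose = set(select_models(results, accuracy_threshold=0.88).selected_ids)
        tight = set(select_models(results, accuracy_threshold=0.92).selected_ids)
        assert tight <= loose

    def test_no_detection_points_warns_empty(self):
        with pytest.warns(UserWarning, match="detection point"):
            summary = select_models([bench_result("a", None)])
        assert summary.selected_ids == []


class TestGroupsAndShuffle:
    def test_group_sizes_302_into_10(self):
        groups = make_groups([f"S{i}" for i in range(302)], k=10, seed=0)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [30] * 8 + [31] * 2

    def test_singleton_groups(self):
        groups = make_groups([f"S{i}" for i in range(10)], k=10, seed=1)
        assert all(len(g) == 1 for g in groups)

    def test_partition_disjoint_exhaustive_seeded(self):
        ids = [f"S{i}" for i in range(47)]
        g1 = make_groups(ids, k=5, seed=3)
        g2 = make_groups(ids, k=5, seed=3)
        assert g1 == g2
        flat = [s for g in g1 for s in g]
        assert sorted(flat) == sorted(ids)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_groups(["a", "b"], k=3)

    def test_shuffle_zero_proportion_is_identity(self, small_matrix):
        full = small_matrix
        out, truth = shuffle_features(full, [full.sample_ids[0]], 0.0, seed=1)
        np.testing.assert_array_equal(
            np.nan_to_num(out.values), np.nan_to_num(full.values))
        assert truth.sum() == 1

    def test_shuffle_preserves_value_multiset(self, synthetic_dataset):
        m = synthetic_dataset.matrix
        target = m.sample_ids[0]
        out, truth = shuffle_features(m, [target], 1.0, seed=2)
        j = m.sample_ids.index(target)
        np.testing.assert_allclose(
            np.sort(np.nan_to_num(out.values[:, j])),
            np.sort(np.nan_to_num(m.values[:, j])))
        assert not np.array_equal(out.values[:, j], m.values[:, j])

    def test_shuffle_leaves_non_targets_untouched(self, synthetic_dataset):
        m = synthetic_dataset.matrix
        out, _ = shuffle_features(m, [m.sample_ids[0]], 0.5, seed=3)
        other = slice(1, None)
        np.testing.assert_array_equal(
            np.nan_to_num(out.values[:, other]),
            np.nan_to_num(m.values[:, other]))

    def test_shuffle_count_rounding(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6451, 3))
        m = IntensityMatrix(vals, np.zeros_like(vals, dtype=bool),
                            [f"P{i}" for i in range(6451)], ["A", "B", "C"],
                            log_transformed=True)
        out, _ = shuffle_features(m, ["A"], 0.3, seed=1)
        changed = (out.values[:, 0] != m.values[:, 0]).sum()
        # round(0.3 * 6451) = 1935 features drawn; a permuted subset can keep
        # a handful of fixed points
        assert changed <= 1935
        assert changed > 1800


class TestCurateClean:
    def test_degraded_sample_removed(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(25, 1, size=(200, 25))
        mask = np.zeros_like(vals, dtype=bool)
        mask[:180, 0] = True  # 90% missing: Grubbs outlier on id counts
        vals = np.where(mask, np.nan, vals)
        m = IntensityMatrix(vals, mask, [f"P{i}" for i in range(200)],
                            [f"S{i}" for i in range(25)], log_transformed=True)
        clean = curate_clean(m)
        assert "S0" not in clean.sample_ids
        assert clean.n_samples == 24

    def test_homogeneous_matrix_untouched(self):
        # Grubbs screens operate at alpha=0.05, so an occasional flag on
        # homogeneous data is expected; this seed's cohort is clean
        ds = generate(30, 100, 0.0, missing_frac=0.0, seed=9)
        clean = curate_clean(ds.matrix)
        assert clean.sample_ids == ds.matrix.sample_ids

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(25, 1, size=(200, 25))
        mask = np.zeros_like(vals, dtype=bool)
        mask[:180, 0] = True
        vals = np.where(mask, np.nan, vals)
        m = IntensityMatrix(vals, mask, [f"P{i}" for i in range(200)],
                            [f"S{i}" for i in range(25)], log_transformed=True)
        once = curate_clean(m)
        twice = curate_clean(once)
        assert twice.sample_ids == once.sample_ids


@pytest.fixture(scope="module")
def clean():
    from proteoscreen.preprocess import preprocess_pipeline
    return preprocess_pipeline(generate(40, 120, 0.0, missing_frac=0.05,
                                        seed=4).matrix)


class TestEvaluateConfig:
    def test_grid_shape(self, clean):
        cfg = DetectorConfig("c", "KNN", {"n_neighbors": 5, "metric": "euclidean"})
        groups = make_groups(list(clean.sample_ids), k=2, seed=0)
        grid = evaluate_config(cfg, clean, groups, proportions=(0.5, 1.0),
                               repeats=2, seed=0)
        assert grid.shape == (2, 2, 2)
        assert np.isfinite(grid).all()
        assert ((grid >= 0) & (grid <= 1)).all()

    def test_full_shuffle_easy_to_detect(self, clean):
        cfg = DetectorConfig("c", "KNN", {"n_neighbors": 5, "metric": "euclidean"})
        groups = make_groups(list(clean.sample_ids), k=8, seed=0)
        grid = evaluate_config(cfg, clean, groups[:2], proportions=(1.0,),
                               repeats=3, seed=0)
        assert grid.mean() >= 0.95

    def test_zero_proportion_bounded_by_contamination(self, clean):
        cfg = DetectorConfig("c", "KNN", {"n_neighbors": 5, "metric": "euclidean"})
        groups = make_groups(list(clean.sample_ids), k=4, seed=0)
        grid = evaluate_config(cfg, clean, groups[:1], proportions=(0.0,),
                               repeats=2, seed=0)
        n = clean.n_samples
        frac = len(groups[0]) / n
        assert (grid <= (n - np.floor(frac * n) + 1) / n).all()

    def test_infeasible_config_returns_none(self, clean):
        cfg = DetectorConfig("c", "KNN", {"n_neighbors": 200, "metric": "euclidean"})
        groups = make_groups(list(clean.sample_ids), k=2, seed=0)
        assert evaluate_config(cfg, clean, groups, proportions=(0.5,),
                               repeats=1, seed=0) is None


def test_run_benchmark_smoke_summary(tiny_registry):
    from proteoscreen.preprocess import preprocess_pipeline
    clean = preprocess_pipeline(generate(30, 100, 0.0, missing_frac=0.05,
                                         seed=5).matrix)
    results, summary = run_benchmark(clean, tiny_registry, n_groups=2,
                                     proportions=DEFAULT_PROPORTIONS,
                                     repeats=2, seed=0)
    assert len(results) == len(tiny_registry)
    table = summary.detection_point_counts
    assert table["proportion"].tolist() == list(DEFAULT_PROPORTIONS[:-1])
    assert (table["n_detection_points"] >= 0).all()
    for r in results:
        assert r.cv is not None and (r.cv >= 0).all()
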