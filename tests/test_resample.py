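import numpy as np
import pytest

from csbboost import (
    ClassSubset,
    LabeledDataset,
    QuotaError,
    ResampleConfig,
    compute_weights,
    fit_resample,
    imbalance_ratio,
    plan_oversampling,
    plan_undersampling,
    resample_with_assignments,
    smote_within_cluster,
    split_classes,
    undersample,
)
from csbboost.resample import ORIGIN_MAJORITY, ORIGIN_SYNTHETIC

from conftest import make_imbalanced


def _dataset_with_counts(n_major, n_minor, seed=0):
    return make_imbalanced(n_major, n_minor, seed=seed)


class TestSplitClasses:
    def test_case_study_counts(self):
        ds = _dataset_with_counts(695, 55)
        split = split_classes(ds)
        assert split.majority.class_total == 695
        assert split.minority.class_total == 55
        assert not split.tied

    def test_exact_tie_flags_noop(self):
        split = split_classes(_dataset_with_counts(25, 25))
        assert split.tied
        assert split.majority.class_total == 25

    def test_single_class_raises(self):
        ds = LabeledDataset(np.zeros((5, 2)), np.ones(5, int))
        with pytest.raises(ValueError):
            split_classes(ds)


class TestWeights:
    def test_exact_division(self):
        np.testing.assert_allclose(
            compute_weights([10, 30, 60], 100), [0.1, 0.3, 0.6]
        )

    def test_case_minority_weights(self):
        np.testing.assert_allclose(compute_weights([44, 11], 55), [0.8, 0.2])

    def test_single_cluster_normalises(self):
        np.testing.assert_allclose(compute_weights([7], 7), [1.0])

    def test_inconsistent_total_raises(self):
        with pytest.raises(ValueError):
            compute_weights([10, 10], 30)
        with pytest.raises(ValueError):
            compute_weights([10], 0)


class TestPlans:
    def test_printed_majority_quotas(self):
        plan = plan_undersampling([0.128, 0.791, 0.080], [89, 550, 56], 750)
        assert plan.quotas.tolist() == [48, 296, 30]

    def test_symmetric_halves(self):
        plan = plan_undersampling([0.5, 0.5], [60, 60], 100)
        assert plan.quotas.tolist() == [25, 25]

    def test_exact_weights_match_integer_arithmetic_oracle(self):
        sizes = [89, 550, 56]
        w = compute_weights(sizes, 695)
        plan = plan_undersampling(w, sizes, 750)
        oracle = [o * 750 // (2 * 695) for o in sizes]  # floor(O_i * N / (2 N_ma))
        assert plan.quotas.tolist() == oracle == [48, 296, 30]
        assert plan.total == 374

    def test_quota_exceeding_cluster_raises(self):
        with pytest.raises(QuotaError):
            plan_undersampling([0.5, 0.5], [10, 200], 300)

    def test_printed_minority_quotas(self):
        plan = plan_oversampling([0.8, 0.2], [44, 11], 750)
        assert plan.quotas.tolist() == [256, 64]

    def test_cluster_already_at_quota(self):
        plan = plan_oversampling([1.0], [50], 100)
        assert plan.quotas.tolist() == [0]

    def test_negative_quota_clamped(self):
        plan = plan_oversampling([0.9, 0.1], [40, 20], 100)
        assert plan.quotas.tolist() == [5, 0]

    def test_weight_normalisation_enforced(self):
        with pytest.raises(ValueError):
            plan_undersampling([0.6, 0.6], [10, 10], 20)

    def test_no_majority_inflation_on_random_instances(self, rng):
        # s_i <= O_i whenever the class holds at least half the training set
        for _ in range(100):
            C = int(rng.integers(1, 6))
            sizes = rng.integers(1, 200, size=C)
            n_ma = int(sizes.sum())
            n_mi = int(rng.integers(1, n_ma + 1))
            w = compute_weights(sizes, n_ma)
            plan = plan_undersampling(w, sizes, n_ma + n_mi)
            assert (plan.quotas <= sizes).all()
            assert abs(w.sum() - 1.0) < 1e-12


class TestUndersample:
    def _subset(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        assignments = np.concatenate(
            [np.full(s, c) for c, s in enumerate(sizes)]
        )
        rows = rng.normal(size=(int(sum(sizes)), 2))
        subset = ClassSubset(rows, "majority", int(sum(sizes)))
        subset.set_assignments(assignments)
        return subset

    def test_quota_equal_size_is_identity(self):
        subset = self._subset([5, 7])
        plan = plan_undersampling(compute_weights([5, 7], 12), [5, 7], 24)
        kept = undersample(subset, plan, seed=1)
        assert kept.tolist() == list(range(12))

    def test_zero_quota_cluster_contributes_nothing(self):
        subset = self._subset([40, 3])
        plan = plan_undersampling([0.95, 0.05], [40, 3], 20)
        assert plan.quotas.tolist() == [9, 0]
        kept = undersample(subset, plan, seed=2)
        assert np.all(subset.assignments[kept] == 0)

    def test_wrong_mode_plan_rejected(self):
        subset = self._subset([40, 3])
        plan = plan_oversampling([0.5, 0.5], [40, 3], 4)
        with pytest.raises(ValueError):
            undersample(subset, plan, seed=0)

    def test_case_study_per_cluster_counts(self):
        sizes = [89, 550, 56]
        subset = self._subset(sizes)
        plan = plan_undersampling(compute_weights(sizes, 695), sizes, 750)
        kept = undersample(subset, plan, seed=3)
        assert kept.size == 374
        counts = np.bincount(subset.assignments[kept], minlength=3)
        assert counts.tolist() == [48, 296, 30]

    def test_deterministic_per_seed(self):
        sizes = [30, 20]
        subset = self._subset(sizes)
        plan = plan_undersampling(compute_weights(sizes, 50), sizes, 60)
        a = undersample(subset, plan, seed=9)
        b = undersample(subset, plan, seed=9)
        np.testing.assert_array_equal(a, b)


class TestSmote:
    def test_two_points_interpolate_on_segment(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        res = smote_within_cluster(pts, 10, k_neighbors=1, seed=0)
        np.testing.assert_allclose(res.points[:, 0], res.points[:, 1], atol=1e-12)
        assert np.all(res.points >= 0.0) and np.all(res.points <= 1.0)

    def test_zero_requested_returns_empty(self):
        res = smote_within_cluster(np.zeros((4, 2)), 0, seed=0)
        assert res.points.shape == (0, 2)

    def test_synthetic_points_are_convex_combinations_of_parents(self, rng):
        pts = rng.normal(size=(20, 3))
        res = smote_within_cluster(pts, 50, k_neighbors=5, seed=4)
        a, b = pts[res.parent_a], pts[res.parent_b]
        recon = a + res.u[:, None] * (b - a)
        np.testing.assert_allclose(res.points, recon, atol=1e-9)
        assert np.all(res.u >= 0) and np.all(res.u < 1)

    def test_neighbours_limited_to_k_nearest(self, rng):
        pts = rng.normal(size=(12, 2))
        res = smote_within_cluster(pts, 200, k_neighbors=3, seed=5)
        from scipy.spatial.distance import cdist
        D = cdist(pts, pts)
        np.fill_diagonal(D, np.inf)
        nearest3 = np.argsort(D, axis=1)[:, :3]
        for x, z in zip(res.parent_a, res.parent_b):
            assert z in nearest3[x]

    def test_lone_point_copied(self):
        res = smote_within_cluster(np.array([[2.0, 3.0]]), 4, seed=0)
        np.testing.assert_allclose(res.points, np.tile([2.0, 3.0], (4, 1)))

    def test_negative_request_raises(self):
        with pytest.raises(ValueError):
            smote_within_cluster(np.zeros((2, 2)), -1, seed=0)


class TestFitResample:
    def _injected_case(self, seed=0):
        rng = np.random.default_rng(seed)
        maj_sizes, min_sizes = [89, 550, 56], [44, 11]
        maj_assign = np.concatenate([np.full(s, c) for c, s in enumerate(maj_sizes)])
        min_assign = np.concatenate([np.full(s, c) for c, s in enumerate(min_sizes)])
        maj_rows = rng.normal(size=(695, 2))
        min_rows = rng.normal(5.0, 1.0, size=(55, 2))
        train = LabeledDataset(
            np.vstack([maj_rows, min_rows]),
            np.concatenate([np.zeros(695, int), np.ones(55, int)]),
        )
        majority = ClassSubset(maj_rows, "majority", 695)
        majority.set_assignments(maj_assign)
        minority = ClassSubset(min_rows, "minority", 55)
        minority.set_assignments(min_assign)
        return train, majority, minority

    def test_injected_case_assignments_reproduce_balanced_counts(self):
        train, majority, minority = self._injected_case()
        balanced, report = resample_with_assignments(
            train, majority, minority, ResampleConfig(seed=1, k_neighbors=5), 3, 2
        )
        assert report.majority_out == 374
        assert report.minority_out == 375
        n0, n1 = balanced.dataset.class_counts()
        assert (n0, n1) == (374, 375)
        counts = balanced.counts()
        assert counts[ORIGIN_MAJORITY] == 374
        assert counts[ORIGIN_SYNTHETIC] == 320

    def test_balanced_input_is_noop(self):
        ds = _dataset_with_counts(30, 30)
        balanced, report = fit_resample(ds, ResampleConfig(seed=0))
        assert report.noop
        np.testing.assert_array_equal(balanced.dataset.features, ds.features)
        np.testing.assert_array_equal(balanced.dataset.labels, ds.labels)

    def test_degenerate_minority_passes_through(self):
        ds = _dataset_with_counts(40, 1)
        balanced, report = fit_resample(ds, ResampleConfig(seed=0))
        assert report.noop
        assert balanced.dataset.n == 41

    def test_ir9_dataset_balances_to_unit_ratio(self):
        ds = _dataset_with_counts(540, 60, seed=8)
        balanced, report = fit_resample(ds, ResampleConfig(seed=2, k_max=4))
        n0, n1 = balanced.dataset.class_counts()
        assert 0.95 <= imbalance_ratio(max(n0, n1), min(n0, n1)) <= 1.05

    def test_seed_determinism_bit_identical(self):
        ds = _dataset_with_counts(180, 20, seed=5)
        cfg = ResampleConfig(seed=11, k_max=3)
        a, _ = fit_resample(ds, cfg)
        b, _ = fit_resample(ds, cfg)
        np.testing.assert_array_equal(a.dataset.features, b.dataset.features)
        np.testing.assert_array_equal(a.dataset.labels, b.dataset.labels)
        np.testing.assert_array_equal(a.origin, b.origin)

    def test_conservation_and_report_consistency(self):
        ds = _dataset_with_counts(300, 40, seed=6)
        balanced, report = fit_resample(ds, ResampleConfig(seed=4, k_max=3))
        assert report.majority_out == report.majority_plan.total
        assert report.minority_out == (
            sum(report.minority_cluster_sizes) + report.minority_plan.total
        )
        assert sum(balanced.counts().values()) == balanced.dataset.n
        # no synthetic row tagged as majority
        synth = balanced.origin == ORIGIN_SYNTHETIC
        assert np.all(balanced.dataset.labels[synth] == 1)
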