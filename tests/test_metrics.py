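import numpy as np
import pytest

from brainuad.metrics import (
    MetricError,
    auprc,
    dice,
    dice_dataset,
    dice_subjects,
    evaluate_segmentation,
    label_slices,
    pr_curve,
    relative_improvement,
    score_slices,
)


def brute_force_dice(pred, truth):
    x = {i for i, v in enumerate(np.asarray(pred).ravel()) if v}
    y = {i for i, v in enumerate(np.asarray(truth).ravel()) if v}
    if not x and not y:
        return 1.0
    return 2 * len(x & y) / (len(x) + len(y))


def brute_force_auprc(scores, labels):
    """Exhaustive sweep over every unique score as a threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pts = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        pts.append((tp / labels.sum(), tp / (tp + fp)))
    area, prev_r = 0.0, 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return 100.0 * area


class TestDice:
    def test_printed_formula_cases(self):
        ones = np.ones(5, np.uint8)
        assert dice(ones, ones) == 1.0
        assert dice(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0
        # |X|=2, |Y|=3, |X∩Y|=2 -> 2*2/(2+3)
        assert dice(np.array([1, 1, 0, 0]), np.array([1, 1, 1, 0])) == 0.8

    def test_both_empty_convention(self):
        assert dice(np.zeros(4), np.zeros(4)) == 1.0

    def test_symmetric_and_matches_set_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 500))
            a = (rng.random(n) < 0.3).astype(np.uint8)
            b = (rng.random(n) < 0.3).astype(np.uint8)
            d = dice(a, b)
            assert d == dice(b, a)
            assert d == pytest.approx(brute_force_dice(a, b), abs=0)
            assert 0.0 <= d <= 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(MetricError):
            dice(np.array([0.5, 1.0]), np.array([1, 0]))


class TestDatasetDice:
    def test_singleton_reduces_to_plain_dice(self, rng):
        a = (rng.random(50) < 0.4).astype(np.uint8)
        b = (rng.random(50) < 0.4).astype(np.uint8)
        assert dice_dataset([a], [b]) == pytest.approx(100 * dice(a, b))

    def test_pooled_is_not_the_mean_of_subject_scores(self):
        """Pooling concatenates the prediction/truth sets and applies the
        formula once; with subjects of unequal set sizes this differs from
        the mean of per-subject scores."""
        p1 = t1 = np.array([1, 1, 1, 0, 0, 0], np.uint8)     # dice 1.0, |X|=3
        p2 = np.array([1, 0, 0, 0, 0, 0], np.uint8)
        t2 = np.array([0, 1, 0, 0, 0, 0], np.uint8)          # dice 0.0, |X|=1
        pooled = dice_dataset([p1, p2], [t1, t2])
        # pooled: |X∩Y| = 3, |X| = 4, |Y| = 4  ->  2*3/(4+4)
        assert pooled == pytest.approx(100 * 2 * 3 / (4 + 4))
        mean_s, _, _ = dice_subjects([p1, p2], [t1, t2])
        assert mean_s == pytest.approx(50.0)
        assert pooled != mean_s

    def test_order_invariant(self, rng):
        preds = [(rng.random(30) < 0.3).astype(np.uint8) for _ in range(4)]
        truths = [(rng.random(30) < 0.3).astype(np.uint8) for _ in range(4)]
        assert dice_dataset(preds, truths) == dice_dataset(preds[::-1], truths[::-1])

    def test_empty_list_rejected(self):
        with pytest.raises(MetricError):
            dice_dataset([], [])


class TestSubjectDice:
    def test_identical_subjects_have_zero_std(self, rng):
        a = (rng.random(20) < 0.5).astype(np.uint8)
        mean, std, scores = dice_subjects([a, a], [a, a])
        assert mean == 100.0 and std == 0.0

    def test_population_std_of_extremes(self):
        ones = np.ones(4, np.uint8)
        zeros = np.zeros(4, np.uint8)
        mean, std, scores = dice_subjects([ones, zeros], [ones, ones])
        assert scores == [100.0, 0.0]
        assert mean == 50.0 and std == 50.0  # population, not sample, std

    def test_reported_mean_equals_mean_of_scores(self, rng):
        preds = [(rng.random(40) < 0.4).astype(np.uint8) for _ in range(6)]
        truths = [(rng.random(40) < 0.4).astype(np.uint8) for _ in range(6)]
        mean, _, scores = dice_subjects(preds, truths)
        assert mean == pytest.approx(np.mean(scores), abs=1e-9)


class TestAUPRC:
    def test_perfect_separation_scores_100(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auprc(scores, labels) == pytest.approx(100.0)

    def test_constant_scores_give_prevalence(self):
        scores = np.full(100, 0.5)
        labels = np.r_[np.ones(30), np.zeros(70)].astype(int)
        assert auprc(scores, labels) == pytest.approx(30.0)

    def test_matches_exhaustive_threshold_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 500))
            scores = rng.random(n)
            if rng.random() < 0.3:  # force ties sometimes
                scores = np.round(scores, 1)
            labels = (rng.random(n) < rng.uniform(0.1, 0.6)).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            assert auprc(scores, labels) == pytest.approx(
                brute_force_auprc(scores, labels), abs=1e-9)

    def test_matches_sklearn_average_precision(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores = rng.random(200)
            labels = (rng.random(200) < 0.25).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            ref = 100 * sklearn_metrics.average_precision_score(labels, scores)
            assert auprc(scores, labels) == pytest.approx(ref, abs=1e-9)

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            pr_curve(np.array([0.1, 0.2]), np.array([0, 0]))


class TestSliceLabels:
    def test_empty_annotation_all_normal(self):
        assert label_slices(np.zeros((4, 4, 6))).sum() == 0

    def test_single_voxel_marks_exactly_its_slice(self):
        ann = np.zeros((4, 4, 6), np.uint8)
        ann[1, 2, 3] = 1
        labels = label_slices(ann)
        assert labels.shape == (6,)
        assert labels.sum() == 1 and labels[3] == 1

    def test_label_count_equals_axial_extent(self):
        assert label_slices(np.zeros((64, 64, 64))).shape == (64,)


class TestSliceScores:
    def test_perfect_reconstruction_scores_zero(self, rng):
        x = rng.random((8, 8, 8))
        mask = np.ones_like(x, bool)
        assert np.all(score_slices(x, x, mask) == 0.0)

    def test_error_confined_to_one_slice(self, rng):
        x = rng.random((8, 8, 8))
        x_hat = x.copy()
        x_hat[:, :, 5] += 0.3
        s = score_slices(x, x_hat, np.ones_like(x, bool))
        assert s[5] > 0 and np.all(np.delete(s, 5) == 0.0)

    def test_linearity_in_the_residual(self, rng):
        x = rng.random((8, 8, 8))
        delta = rng.random((8, 8, 8)) * 0.1
        mask = np.ones_like(x, bool)
        s1 = score_slices(x, x + delta, mask)
        s2 = score_slices(x, x + 2 * delta, mask)
        assert np.allclose(s2, 2 * s1)

    def test_maskless_slices_score_zero(self, rng):
        x = rng.random((4, 4, 4))
        mask = np.zeros_like(x, bool)
        mask[:, :, 0] = True
        s = score_slices(x, np.zeros_like(x), mask)
        assert np.all(s[1:] == 0.0)


class TestRelativeImprovement:
    def test_no_change_is_zero(self):
        assert relative_improvement(10.0, 10.0) == 0.0

    def test_reported_improvements_from_table_cells(self):
        # tumor data set: 2D baseline 26.80 vs best 3D cube-noise 30.10
        assert relative_improvement(26.80, 30.10) == 12.31
        # stroke data set: 24.72 vs 32.68
        assert relative_improvement(24.72, 32.68) == 32.20

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(MetricError):
            relative_improvement(0.0, 10.0)


class TestReport:
    def test_report_assembles_all_fields(self, rng):
        truths = [(rng.random((6, 6, 6)) < 0.2).astype(np.uint8) for _ in range(3)]
        preds = truths  # perfect prediction
        residuals = [t + 0.1 * rng.random(t.shape) for t in truths]
        rep = evaluate_segmentation(preds, truths, residuals=residuals)
        assert rep.dice_dataset == 100.0
        assert rep.dice_subject_mean == 100.0 and rep.dice_subject_std == 0.0
        assert 0.0 < rep.auprc_voxel <= 100.0
        assert rep.n_subjects == 3
        assert "dice_dataset" in rep.to_json()
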