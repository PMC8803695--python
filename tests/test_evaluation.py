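import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from petstage.errors import ConfigurationError, UndefinedMetricError
from petstage.evaluation import (
    ClassifiedCandidate,
    ConfusionMatrix,
    average_precision,
    bootstrap_ci,
    detection_counts_to_percents,
    location_accuracy,
    merge_confusion,
    paired_z_test,
    pooled_detection_metrics,
    stage_agreement,
)
from petstage.segmentation import Finding
from tests.oracles import average_precision_bruteforce


class TestAveragePrecision:
    def test_perfect_ranking_is_100(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 100.0

    def test_six_point_toy_set_matches_bruteforce(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        labels = [1, 0, 1, 1, 0, 0]
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_bruteforce(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_random_small_sets_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        scores = rng.permutation(n) / n  # distinct scores
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            labels[0] = 1
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_bruteforce(scores, labels), abs=1e-9
        )

    def test_tied_scores_grouped_into_one_threshold(self):
        # all scores equal -> single threshold, AP = prevalence
        assert average_precision([0.5] * 4, [1, 0, 0, 1]) == pytest.approx(50.0)

    def test_chance_level_equals_prevalence(self):
        aps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = (rng.random(1000) < 0.1).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.random(1000)
            aps.append(average_precision(scores, labels))
        assert np.mean(aps) == pytest.approx(10.0, abs=3.0)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        assert average_precision(scores, labels) == pytest.approx(
            100.0 * average_precision_score(labels, scores), abs=1e-9
        )

    def test_no_positives_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([0.5, 0.4], [0, 0])


def _finding(fid, voxels, shape=(8, 8, 8), suv=5.0):
    voxels = np.asarray(voxels)
    return Finding(finding_id=fid, voxels=voxels, grid_shape=shape, suv_max=suv,
                   suv_max_voxel=tuple(voxels[0]), volume_ml=len(voxels) * 0.027)


class TestDetectionMetrics:
    def test_pooled_counts_reproduce_published_percentages(self):
        recall, ppv = detection_counts_to_percents(tp=159, fp=79, fn=37)
        assert round(recall, 1) == 81.1
        assert round(ppv, 1) == 66.8

    def test_matching_by_suvmax_containment(self):
        expert = _finding("e1", [[2, 2, 2], [2, 2, 3]])
        hit = ClassifiedCandidate("s1", _finding("c1", [[2, 2, 2]]), 0.9)
        miss = ClassifiedCandidate("s1", _finding("c2", [[6, 6, 6]]), 0.8)
        low = ClassifiedCandidate("s1", _finding("c3", [[2, 2, 3]]), 0.2)
        rep = pooled_detection_metrics([hit, miss, low], [("s1", expert)])
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 0)
        assert rep.recall == pytest.approx(100.0)
        assert rep.ppv == pytest.approx(50.0)

    def test_overlap_rule_matches_any_shared_voxel(self):
        expert = _finding("e1", [[2, 2, 2], [2, 2, 3]])
        # SUVmax voxel outside the mask, but one voxel overlaps
        cand = _finding("c1", [[4, 4, 4], [2, 2, 3]])
        cc = ClassifiedCandidate("s1", cand, 0.9)
        by_suvmax = pooled_detection_metrics([cc], [("s1", expert)],
                                             match_rule="suvmax")
        by_overlap = pooled_detection_metrics([cc], [("s1", expert)],
                                              match_rule="overlap")
        assert (by_suvmax.tp, by_suvmax.fp) == (0, 1)
        assert (by_overlap.tp, by_overlap.fp) == (1, 0)

    def test_double_match_counts_expert_finding_once(self):
        expert = _finding("e1", [[2, 2, 2], [2, 2, 3]])
        c1 = ClassifiedCandidate("s1", _finding("c1", [[2, 2, 2]]), 0.9)
        c2 = ClassifiedCandidate("s1", _finding("c2", [[2, 2, 3]]), 0.8)
        rep = pooled_detection_metrics([c1, c2], [("s1", expert)])
        assert rep.tp + rep.fn == 1  # one expert finding total

    def test_empty_subject_is_all_zero(self):
        rep = pooled_detection_metrics([], [])
        assert (rep.tp, rep.fp, rep.fn) == (0, 0, 0)

    def test_per_subject_recall_conventions(self):
        expert = _finding("e1", [[2, 2, 2]])
        cand_fp = ClassifiedCandidate("clean", _finding("c9", [[5, 5, 5]]), 0.9)
        rep = pooled_detection_metrics(
            [cand_fp, ClassifiedCandidate("pos", _finding("c1", [[2, 2, 2]]), 0.9)],
            [("pos", expert)],
        )
        per = rep.per_subject
        # subject without expert positives but with a prediction: excluded
        assert np.isnan(per.loc["clean", "recall"])
        assert per.loc["pos", "recall"] == pytest.approx(100.0)
        # emitted percentages always recomputable from emitted counts
        recall, ppv = detection_counts_to_percents(rep.tp, rep.fp, rep.fn)
        assert abs(recall - rep.recall) < 0.1 and abs(ppv - rep.ppv) < 0.1

    def test_subject_without_findings_and_without_predictions_gets_recall_100(self):
        rep = pooled_detection_metrics(
            [ClassifiedCandidate("clean", _finding("c0", [[1, 1, 1]]), 0.1)], []
        )
        assert rep.per_subject.loc["clean", "recall"] == pytest.approx(100.0)

    def test_duplicate_expert_ids_rejected(self):
        e = _finding("e1", [[1, 1, 1]])
        with pytest.raises(ConfigurationError):
            pooled_detection_metrics([], [("s1", e), ("s1", e)])


class TestBootstrap:
    def test_constant_metric_has_zero_width(self):
        lo, hi, reps = bootstrap_ci(lambda subs: 42.0, list(range(10)), b=100, seed=0)
        assert lo == hi == 42.0
        assert np.all(reps == 42.0)

    def test_same_seed_reproduces_interval(self):
        data = list(np.random.default_rng(0).normal(10, 2, 30))
        f = lambda subs: float(np.mean(subs))
        a = bootstrap_ci(f, data, b=200, seed=5)
        b = bootstrap_ci(f, data, b=200, seed=5)
        assert a[:2] == b[:2]
        np.testing.assert_array_equal(a[2], b[2])

    def test_undefined_replicates_are_redrawn(self):
        calls = {"n": 0}

        def sometimes_undefined(subs):
            calls["n"] += 1
            if sum(subs) % 7 == 0:
                raise UndefinedMetricError("boom")
            return float(np.mean(subs))

        lo, hi, reps = bootstrap_ci(sometimes_undefined, [1, 2, 3, 4], b=50, seed=1)
        assert len(reps) == 50
        assert calls["n"] >= 50

    def test_percentile_interval_covers_true_mean(self):
        # 95% interval for the mean of 30 Gaussian subjects: empirical
        # coverage over simulation repetitions stays near nominal
        cover = 0
        reps = 250
        for sim in range(reps):
            rng = np.random.default_rng(1000 + sim)
            data = list(rng.normal(50.0, 10.0, 30))
            lo, hi, _ = bootstrap_ci(lambda s: float(np.mean(s)), data, b=200,
                                     seed=sim)
            cover += lo <= 50.0 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.03)

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            bootstrap_ci(lambda s: 0.0, [1], b=10, seed=0)

    def test_replicate_mean_converges_to_point_estimate(self):
        data = list(np.random.default_rng(3).normal(20, 5, 40))
        point = float(np.mean(data))
        _, _, reps = bootstrap_ci(lambda s: float(np.mean(s)), data, b=20000, seed=2)
        assert np.mean(reps) == pytest.approx(point, rel=0.01)


class TestPairedZTest:
    def test_identical_replicates_give_p_one(self):
        a = np.arange(10.0)
        z, p_raw, p_bonf = paired_z_test(a, a.copy())
        assert p_raw == 1.0 and p_bonf == 1.0

    def test_constant_positive_difference_gives_p_zero(self):
        a = np.arange(10.0) + 3.0
        z, p_raw, _ = paired_z_test(a, np.arange(10.0))
        assert p_raw == 0.0 and z == np.inf

    def test_matches_closed_form_for_gaussian_shift(self):
        rng = np.random.default_rng(0)
        shift, sd = 1.5, 2.0
        d = rng.normal(shift, sd, 200_000)
        b = rng.normal(0, 0.0, 200_000)
        z, p_raw, _ = paired_z_test(b + d, b)
        p_true = float(2 * norm.sf(shift / sd))
        assert p_raw == pytest.approx(p_true, abs=0.01)

    def test_bonferroni_scales_and_caps(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.2, 1.0, 500)
        b = rng.normal(0.0, 1.0, 500)
        z, p_raw, p_bonf = paired_z_test(a, b, n_comparisons=5)
        assert p_bonf == pytest.approx(min(1.0, 5 * p_raw))


class TestStageAgreement:
    def test_identity_matrix_is_100(self):
        cm = ConfusionMatrix(labels=["a", "b", "c"], counts=np.eye(3, dtype=int) * 4)
        assert stage_agreement(cm)[0] == 100

    def test_row_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 9, (4, 4))
        labels = ["a", "b", "c", "d"]
        cm = ConfusionMatrix(labels=labels, counts=counts)
        perm = [2, 0, 3, 1]
        cm_p = ConfusionMatrix(labels=[labels[i] for i in perm],
                               counts=counts[np.ix_(perm, perm)])
        assert stage_agreement(cm)[1] == pytest.approx(stage_agreement(cm_p)[1])

    def test_merge_map_must_reference_known_labels(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.eye(2, dtype=int))
        with pytest.raises(ConfigurationError):
            merge_confusion(cm, {"zzz": "a"})

    def test_merging_pools_rows_and_columns(self):
        cm = ConfusionMatrix(
            labels=["x", "y", "z"],
            counts=np.array([[2, 1, 0], [1, 3, 0], [0, 0, 4]]),
        )
        merged = merge_confusion(cm, {"x": "xy", "y": "xy"})
        assert merged.labels == ["xy", "z"]
        np.testing.assert_array_equal(merged.counts, [[7, 0], [0, 4]])

    def test_from_pairs_counts_rows_as_truth(self):
        cm = ConfusionMatrix.from_pairs(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])


class TestLocationAccuracy:
    def test_all_correct_is_100(self):
        assert location_accuracy(["a", "b"], ["a", "b"]) == 100.0

    def test_half_correct_is_50(self):
        pred = ["a"] * 5 + ["b"] * 5
        true = ["a"] * 5 + ["c"] * 5
        assert location_accuracy(pred, true) == 50.0

    def test_suspicious_only_scope(self):
        pred = ["a", "b", "c"]
        true = ["a", "x", "c"]
        flags = [True, True, False]
        assert location_accuracy(pred, true, flags, scope="suspicious_only") == 50.0

    def test_known_corruption_rate_recovers_accuracy(self):
        rng = np.random.default_rng(4)
        true = list(rng.choice(["a", "b", "c"], 2000))
        q = 0.3
        pred = [
            ("wrong" if rng.random() < q else t) for t in true
        ]
        acc = location_accuracy(pred, true)
        assert acc == pytest.approx(100 * (1 - q), abs=3.0)

    def test_empty_scope_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            location_accuracy([], [])
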