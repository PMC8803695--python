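import numpy as np
import pytest

from petstage.cnn_model import ModelConfig, build_model
from petstage.errors import ConfigurationError
from petstage.io_volumes import Subject
from petstage.segmentation import Finding
from petstage.training import (
    SamplingConfig,
    TrainConfig,
    collect_location_classes,
    sample_epoch,
    stratified_folds,
    train,
)
from tests.conftest import make_volume


def _dummy_finding(fid, label, location="unlabeled"):
    return Finding(finding_id=fid, voxels=np.array([[0, 0, 0]]),
                   grid_shape=(2, 2, 2), suv_max=2.0, suv_max_voxel=(0, 0, 0),
                   volume_ml=0.027, label_suspicious=label,
                   label_location=location)


def _dummy_subject(sid, n_nonsusp, n_susp, locations=()):
    findings = [_dummy_finding(f"n{i}", "nonsuspicious") for i in range(n_nonsusp)]
    findings += [
        _dummy_finding(f"s{i}", "suspicious",
                       locations[i % len(locations)] if locations else "unlabeled")
        for i in range(n_susp)
    ]
    vol = make_volume(np.zeros((2, 2, 2)))
    return Subject(subject_id=sid, tracer="PSMA", volume=vol, findings=findings)


class TestSampleEpoch:
    def test_balanced_draw_respects_binary_caps(self):
        subj = _dummy_subject("a", n_nonsusp=100, n_susp=50)
        cfg = SamplingConfig(mode="balanced", epoch_seed=1)
        picked = sample_epoch([subj], cfg, epoch_index=0)
        ids = [fid for _, fid in picked]
        assert sum(fid.startswith("n") for fid in ids) <= 32
        assert sum(fid.startswith("s") for fid in ids) <= 32

    def test_caps_never_exceeded_over_many_epochs(self):
        subjects = [
            _dummy_subject("a", 80, 50, locations=["bone", "kidney"]),
            _dummy_subject("b", 40, 10, locations=["liver"]),
        ]
        cfg = SamplingConfig(mode="balanced", epoch_seed=3)
        for epoch in range(100):
            picked = sample_epoch(subjects, cfg, epoch_index=epoch)
            for s in subjects:
                ids = [fid for sid, fid in picked if sid == s.subject_id]
                assert len(ids) == len(set(ids))  # without replacement
                n = sum(fid.startswith("n") for fid in ids)
                k = sum(fid.startswith("s") for fid in ids)
                assert n <= 32 and k <= 32

    def test_small_subject_fully_selected(self):
        subj = _dummy_subject("a", 1, 2, locations=["bone"])
        picked = sample_epoch([subj], SamplingConfig(mode="balanced"), 0)
        assert len(picked) == 3

    def test_same_seed_and_epoch_reproduce_selection(self):
        subj = _dummy_subject("a", 100, 50)
        cfg = SamplingConfig(mode="balanced", epoch_seed=9)
        a = sample_epoch([subj], cfg, 4)
        b = sample_epoch([subj], cfg, 4)
        assert a == b
        c = sample_epoch([subj], cfg, 5)
        assert a != c

    def test_location_caps_add_class_coverage(self):
        locs = ["bone"] * 40
        subj = _dummy_subject("a", 0, 40, locations=locs)
        cfg = SamplingConfig(mode="balanced")
        picked = sample_epoch([subj], cfg, 0)
        # binary cap is hard; location top-up never breaches it
        assert len(picked) == 32

    def test_sequential_returns_every_finding_once(self):
        subjects = [_dummy_subject("a", 5, 3), _dummy_subject("b", 2, 0)]
        picked = sample_epoch(subjects, SamplingConfig(mode="sequential"), 0)
        assert len(picked) == 10
        assert len(set(picked)) == 10

    def test_sequential_count_at_least_balanced_count(self):
        subjects = [_dummy_subject("a", 90, 40), _dummy_subject("b", 10, 5)]
        seq = sample_epoch(subjects, SamplingConfig(mode="sequential"), 0)
        bal = sample_epoch(subjects, SamplingConfig(mode="balanced"), 0)
        assert len(bal) <= len(seq)


class TestStratifiedFolds:
    @staticmethod
    def _cohort(n):
        return [
            _dummy_subject(f"s{i}", 2, i % 2, locations=["bone"])
            for i in range(n)
        ]

    def test_every_subject_in_exactly_one_fold(self):
        subjects = self._cohort(8)
        folds = stratified_folds(subjects, k=4, seed=0)
        all_ids = [s.subject_id for fold in folds for s in fold]
        assert sorted(all_ids) == sorted(s.subject_id for s in subjects)
        assert len(folds) == 4

    def test_same_seed_reproduces_folds(self):
        subjects = self._cohort(9)
        a = stratified_folds(subjects, k=3, seed=5)
        b = stratified_folds(subjects, k=3, seed=5)
        assert [[s.subject_id for s in f] for f in a] == [
            [s.subject_id for s in f] for f in b
        ]

    def test_stratification_spreads_positive_subjects(self):
        subjects = self._cohort(8)  # 4 with suspicious findings
        folds = stratified_folds(subjects, k=4, seed=1)
        per_fold = [
            sum(any(f.label_suspicious == "suspicious" for f in s.findings)
                for s in fold)
            for fold in folds
        ]
        assert max(per_fold) - min(per_fold) <= 1

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_folds(self._cohort(3), k=4)


class TestTrainStrategies:
    def test_strategy_requirements_enforced(self):
        with pytest.raises(ConfigurationError):
            train(TrainConfig(strategy="I", epochs=1), psma_subjects=[])
        with pytest.raises(ConfigurationError):
            train(TrainConfig(strategy="VI", epochs=1),
                  psma_subjects=[_dummy_subject("a", 1, 1, ["bone"])])
        with pytest.raises(ConfigurationError):
            train(TrainConfig(strategy="V", epochs=1),
                  psma_subjects=[_dummy_subject("a", 1, 1, ["bone"])],
                  init_model=None)

    def test_zero_epoch_finetune_is_identity(self, phantom_subject):
        subject, _ = phantom_subject
        classes = collect_location_classes([subject])
        cfg = ModelConfig(n_location_classes=len(classes), conv_blocks=2,
                          base_filters=2, fc_width=8, pool_first=True)
        pretrained = build_model(cfg, seed=11, location_classes=classes)
        model, _ = train(
            TrainConfig(strategy="V", epochs=0, seed=0),
            psma_subjects=[subject], init_model=pretrained,
            location_classes=classes,
        )
        for k in pretrained.params:
            np.testing.assert_array_equal(model.params[k], pretrained.params[k])
        assert model is not pretrained  # fine-tuning never mutates the checkpoint

    def test_one_epoch_training_runs_and_records_history(self, phantom_subject):
        subject, _ = phantom_subject
        classes = collect_location_classes([subject])
        cfg = ModelConfig(n_location_classes=len(classes), conv_blocks=2,
                          base_filters=2, fc_width=8, pool_first=True)
        model, hist = train(
            TrainConfig(strategy="III", epochs=1, seed=3),
            psma_subjects=[subject], model_cfg=cfg, location_classes=classes,
        )
        assert list(hist.columns) == ["epoch", "n_examples", "loss"]
        assert hist["n_examples"].iloc[0] == len(subject.findings)
        assert np.isfinite(hist["loss"].iloc[0])

    def test_same_seed_reproduces_training(self, phantom_subject):
        subject, _ = phantom_subject
        classes = collect_location_classes([subject])
        cfg = ModelConfig(n_location_classes=len(classes), conv_blocks=2,
                          base_filters=2, fc_width=8, pool_first=True)
        runs = []
        for _ in range(2):
            model, _ = train(
                TrainConfig(strategy="III", epochs=1, seed=21),
                psma_subjects=[subject], model_cfg=cfg,
                location_classes=classes,
            )
            runs.append(model)
        for k in runs[0].params:
            np.testing.assert_array_equal(runs[0].params[k], runs[1].params[k])


def test_dual_tracer_model_learns_contradictory_labels_via_tracer_bit():
    """Identical image patterns with tracer-dependent labels are separable
    only through the tracer bit; the location head stays tracer-invariant."""
    from petstage.nn import Adam

    cfg = ModelConfig(n_location_classes=2, conv_blocks=2, base_filters=2,
                      fc_width=8, input_channels=2, input_size=8,
                      dual_tracer=True)
    model = build_model(cfg, seed=0)
    rng = np.random.default_rng(0)
    x_single = rng.random((4, 2, 8, 8), dtype=np.float32)
    x = np.concatenate([x_single, x_single])
    t = np.array([0.0] * 4 + [1.0] * 4)
    y_s = np.array([0.0] * 4 + [1.0] * 4)  # label flips with the tracer
    y_l = np.array([0, 1, 0, 1] * 2)
    opt = Adam(model.params, lr=3e-3)
    for _ in range(300):
        _, grads, _ = model.loss_and_grads(x, t, y_s, y_l)
        opt.step(grads)
    p0, probs0 = model.predict_batch(x_single, np.zeros(4))
    p1, probs1 = model.predict_batch(x_single, np.ones(4))
    assert np.all(p0 < 0.5) and np.all(p1 >= 0.5)
    np.testing.assert_array_equal(probs0, probs1)


def test_collect_location_classes_requires_two():
    with pytest.raises(ConfigurationError):
        collect_location_classes([_dummy_subject("a", 3, 1, ["bone"])])
    classes = collect_location_classes(
        [_dummy_subject("a", 3, 2, ["bone", "liver"])]
    )
    assert classes == ["bone", "liver"]


def test_strategy_vi_with_constant_tracer_bit_matches_relabeled_cohort():
    """Forcing the tracer bit constant in combined training is equivalent to
    training on the pooled cohort with every subject tagged as that tracer:
    identical parameters under identical seeds."""
    from dataclasses import replace as dc_replace

    from petstage.phantom import PhantomConfig, generate_subject

    psma, _ = generate_subject(
        PhantomConfig(tracer="PSMA", lesion_counts={"bone": 1}, seed=61)
    )
    fdg, _ = generate_subject(
        PhantomConfig(tracer="FDG", lesion_counts={"bone": 1}, seed=62)
    )
    classes = collect_location_classes([psma, fdg])
    model_cfg = ModelConfig(n_location_classes=len(classes), conv_blocks=2,
                            base_filters=2, fc_width=8, dual_tracer=True,
                            pool_first=True)
    cfg = TrainConfig(strategy="VI", epochs=1, seed=5, force_tracer=0.0)
    forced, hist_a = train(cfg, psma_subjects=[psma], fdg_subjects=[fdg],
                           model_cfg=model_cfg, location_classes=classes)
    # same data, but the FDG subject relabeled so its data-driven bit is 0
    fdg_as_psma = Subject(subject_id=fdg.subject_id, tracer="PSMA",
                          volume=fdg.volume, findings=fdg.findings,
                          group=fdg.group)
    cfg_b = TrainConfig(strategy="VI", epochs=1, seed=5)
    relabeled, hist_b = train(cfg_b, psma_subjects=[psma],
                              fdg_subjects=[fdg_as_psma],
                              model_cfg=model_cfg, location_classes=classes)
    assert hist_a["loss"].tolist() == hist_b["loss"].tolist()
    for k in forced.params:
        np.testing.assert_array_equal(forced.params[k], relabeled.params[k])


def test_crossvalidate_partitions_and_pools_predictions():
    from petstage.phantom import generate_cohort
    from petstage.training import crossvalidate

    cohort, _ = generate_cohort(4, tracer="PSMA", seed=71)
    subjects = [s for s, _ in cohort]
    model_cfg = ModelConfig(
        n_location_classes=len(collect_location_classes(subjects)),
        conv_blocks=2, base_filters=2, fc_width=8, pool_first=True,
    )
    cfg = TrainConfig(strategy="II", epochs=1, seed=2)
    fold_metrics, pooled, table = crossvalidate(subjects, cfg, k=2,
                                                model_cfg=model_cfg)
    assert len(fold_metrics) == 2
    # every labeled finding predicted exactly once across folds
    n_labeled = sum(
        1 for s in subjects for f in s.findings
        if f.label_suspicious in ("suspicious", "nonsuspicious")
    )
    assert len(table) == n_labeled
    assert set(table["subject_id"]) == {s.subject_id for s in subjects}
    assert pooled["n_findings"] == n_labeled
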