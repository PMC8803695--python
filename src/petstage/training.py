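"""Training strategies for the uptake classifier.

Six strategies are supported, forming an ablation ladder:

I    sequential sampling of every training finding, no augmentation;
II   balanced sampling — per subject and epoch at most 32 nonsuspicious and
     32 suspicious findings for the suspicious task plus at most 4 findings
     per anatomical location class, the union forming the epoch set;
III  II plus random affine augmentation of every drawn example;
IV   III applied to the FDG dataset with a single 90/10 subject-level
     train/validation split;
V    transfer learning — fine-tune (all weights) a model pretrained on FDG
     (IV) on the PSMA data with strategy III;
VI   combined dual-tracer training — strategy III over the union of both
     tracers' subjects with the dual-tracer model, the tracer bit taken
     from each subject's tracer tag.

Losses: binary cross-entropy (suspicious head) plus categorical
cross-entropy (location head), summed 1:1 by default; the location loss is
masked to zero for findings without an anatomical label (auto-generated
nonsuspicious regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from petstage.cnn_model import ModelConfig, MultiTaskCnn, TRACER_BIT, build_model
from petstage.errors import ConfigurationError
from petstage.io_volumes import Subject
from petstage.mpr_features import augment_affine, extract_mpr
from petstage.nn import Adam
from petstage.evaluation import average_precision, location_accuracy

logger = logging.getLogger(__name__)

STRATEGIES = ("I", "II", "III", "IV", "V", "VI")


@dataclass
class SamplingConfig:
    mode: str = "balanced"
    max_physiological_per_subject: int = 32
    max_suspicious_per_subject: int = 32
    max_per_location_class_per_subject: int = 4
    epoch_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "balanced"):
            raise ConfigurationError(f"unknown sampling mode {self.mode!r}")
        for name in (
            "max_physiological_per_subject",
            "max_suspicious_per_subject",
            "max_per_location_class_per_subject",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class TrainConfig:
    strategy: str = "III"
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    fdg_split_fraction: float = 0.9
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)
    bce_pos_weight: float = 1.0  # positive-class weight against imbalance
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    force_tracer: float | None = None  # ablation: constant tracer bit

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.fdg_split_fraction < 1:
            raise ConfigurationError("fdg_split_fraction must be in (0, 1)")


def _training_findings(subject: Subject):
    return [
        f for f in subject.findings
        if f.label_suspicious in ("suspicious", "nonsuspicious")
    ]


def sample_epoch(
    subjects: list[Subject],
    cfg: SamplingConfig,
    epoch_index: int = 0,
) -> list[tuple[str, str]]:
    """Select the (subject_id, finding_id) pairs for one epoch.

    Sequential mode returns every training finding once in subject/finding
    order.  Balanced mode draws, per subject, without replacement: up to 32
    nonsuspicious and 32 suspicious findings (suspicious task) and up to 4
    findings per labeled location class (location task); the union of the
    draws forms the epoch set.  Reproducible given (epoch_seed,
    epoch_index).
    """
    out: list[tuple[str, str]] = []
    if cfg.mode == "sequential":
        for s in subjects:
            fs = _training_findings(s)
            if not fs:
                logger.info("subject %s has no training findings", s.subject_id)
            out.extend((s.subject_id, f.finding_id) for f in fs)
        return out

    rng = np.random.default_rng([cfg.epoch_seed & 0x7FFFFFFF, epoch_index])
    for s in subjects:
        fs = _training_findings(s)
        if not fs:
            logger.info("subject %s has no training findings", s.subject_id)
            continue
        susp = [f.finding_id for f in fs if f.label_suspicious == "suspicious"]
        nons = [f.finding_id for f in fs if f.label_suspicious == "nonsuspicious"]
        is_susp = {f.finding_id: f.label_suspicious == "suspicious" for f in fs}
        chosen: set[str] = set()
        for pool, cap in (
            (nons, cfg.max_physiological_per_subject),
            (susp, cfg.max_suspicious_per_subject),
        ):
            if len(pool) <= cap:
                chosen.update(pool)
            else:
                chosen.update(rng.choice(pool, size=cap, replace=False))
        # top up location-class coverage without breaching the binary caps
        by_class: dict[str, list[str]] = {}
        for f in fs:
            if f.label_location != "unlabeled":
                by_class.setdefault(f.label_location, []).append(f.finding_id)
        counts = {
            True: sum(1 for fid in chosen if is_susp[fid]),
            False: sum(1 for fid in chosen if not is_susp[fid]),
        }
        caps = {True: cfg.max_suspicious_per_subject,
                False: cfg.max_physiological_per_subject}
        for cls in sorted(by_class):
            pool = by_class[cls]
            have = sum(1 for fid in pool if fid in chosen)
            want = cfg.max_per_location_class_per_subject - have
            if want <= 0:
                continue
            extra = [fid for fid in pool if fid not in chosen]
            if len(extra) > want:
                extra = list(rng.choice(extra, size=want, replace=False))
            for fid in extra:
                if counts[is_susp[fid]] < caps[is_susp[fid]]:
                    chosen.add(fid)
                    counts[is_susp[fid]] += 1
        order = {f.finding_id: i for i, f in enumerate(fs)}
        out.extend((s.subject_id, fid) for fid in sorted(chosen, key=order.__getitem__))
    return out


# -- dataset assembly ---------------------------------------------------------

def collect_location_classes(subjects: list[Subject]) -> list[str]:
    """Sorted union of location labels present in the subjects' findings."""
    classes = sorted(
        {
            f.label_location
            for s in subjects
            for f in s.findings
            if f.label_location != "unlabeled"
        }
    )
    if len(classes) < 2:
        raise ConfigurationError("need at least two location classes to train")
    return classes


class _ExampleIndex:
    """Finding lookup plus (optionally cached) MPR extraction."""

    def __init__(self, subjects, location_classes, augment, cache=True):
        self.subjects = {s.subject_id: s for s in subjects}
        self.findings = {
            (s.subject_id, f.finding_id): f for s in subjects for f in s.findings
        }
        self.class_index = {c: i for i, c in enumerate(location_classes)}
        self.augment = augment
        self._cache: dict | None = {} if (cache and not augment) else None

    def example(self, key, rng):
        subject = self.subjects[key[0]]
        finding = self.findings[key]
        if self._cache is not None and key in self._cache:
            x = self._cache[key]
        else:
            if self.augment:
                stack = augment_affine(subject.volume, finding.suv_max_voxel, rng)
            else:
                stack = extract_mpr(subject.volume, finding.suv_max_voxel)
            x = stack.as_network_input()
            if self._cache is not None:
                self._cache[key] = x
        y_susp = 1.0 if finding.label_suspicious == "suspicious" else 0.0
        y_loc = self.class_index.get(finding.label_location, -1)
        return x, y_susp, y_loc, TRACER_BIT[subject.tracer]


def _split_subjects(subjects, fraction, rng):
    idx = rng.permutation(len(subjects))
    n_train = max(1, int(round(fraction * len(subjects))))
    n_train = min(n_train, len(subjects) - 1) if len(subjects) > 1 else n_train
    train = [subjects[i] for i in idx[:n_train]]
    val = [subjects[i] for i in idx[n_train:]]
    return train, val


def _run_training(
    model: MultiTaskCnn,
    subjects: list[Subject],
    cfg: TrainConfig,
    sampling_mode: str,
    augment: bool,
) -> pd.DataFrame:
    sampling = replace(cfg.sampling, mode=sampling_mode, epoch_seed=cfg.seed)
    index = _ExampleIndex(
        subjects, model.location_classes, augment=augment, cache=not augment
    )
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xA5])
    history = []
    for epoch in range(cfg.epochs):
        pairs = sample_epoch(subjects, sampling, epoch)
        perm = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), cfg.batch_size):
            batch = [pairs[i] for i in perm[start : start + cfg.batch_size]]
            xs, ys, yl, tb = zip(*(index.example(k, rng) for k in batch))
            x = np.stack(xs)
            tracer = None
            if model.cfg.dual_tracer:
                tracer = (
                    np.full(len(batch), cfg.force_tracer)
                    if cfg.force_tracer is not None
                    else np.asarray(tb)
                )
            loss, grads, _ = model.loss_and_grads(
                x, tracer, np.asarray(ys), np.asarray(yl),
                loss_weights=cfg.loss_weights, pos_weight=cfg.bce_pos_weight,
                rng=rng,
            )
            opt.step(grads)
            losses.append(loss)
        history.append(
            {"epoch": epoch, "n_examples": len(pairs),
             "loss": float(np.mean(losses)) if losses else float("nan")}
        )
    return pd.DataFrame(history)


def predict_findings(
    model: MultiTaskCnn,
    subjects: list[Subject],
    batch_size: int = 64,
) -> pd.DataFrame:
    """Classify every labeled finding of the subjects (no augmentation).

    Returns one row per finding with the true labels, ``p_suspicious`` and
    the predicted location class.
    """
    classes = model.location_classes
    rows = []
    batch_x, meta = [], []

    def flush():
        if not batch_x:
            return
        x = np.stack(batch_x)
        tracer = (
            np.asarray([m["tracer_bit"] for m in meta])
            if model.cfg.dual_tracer
            else None
        )
        p_susp, probs = model.predict_batch(x, tracer)
        for i, m in enumerate(meta):
            rows.append(
                {
                    "subject_id": m["subject_id"],
                    "finding_id": m["finding_id"],
                    "label_suspicious": m["label_suspicious"],
                    "label_location": m["label_location"],
                    "p_suspicious": float(p_susp[i]),
                    "pred_location": classes[int(np.argmax(probs[i]))],
                }
            )
        batch_x.clear()
        meta.clear()

    for s in subjects:
        for f in s.findings:
            if f.label_suspicious not in ("suspicious", "nonsuspicious"):
                continue
            batch_x.append(extract_mpr(s.volume, f.suv_max_voxel).as_network_input())
            meta.append(
                {
                    "subject_id": s.subject_id,
                    "finding_id": f.finding_id,
                    "label_suspicious": f.label_suspicious,
                    "label_location": f.label_location,
                    "tracer_bit": TRACER_BIT[s.tracer],
                }
            )
            if len(batch_x) >= batch_size:
                flush()
    flush()
    return pd.DataFrame(rows)


def evaluate_pooled(pred: pd.DataFrame) -> dict:
    """Pooled AP and location accuracies from a predict_findings table."""
    y = (pred["label_suspicious"] == "suspicious").astype(int).to_numpy()
    out = {"n_findings": int(len(pred))}
    out["ap"] = average_precision(pred["p_suspicious"].to_numpy(), y) if y.sum() else None
    labeled = pred[pred["label_location"] != "unlabeled"]
    if len(labeled):
        out["accuracy_all"] = location_accuracy(
            labeled["pred_location"], labeled["label_location"]
        )
        susp = labeled[labeled["label_suspicious"] == "suspicious"]
        if len(susp):
            out["accuracy_suspicious"] = location_accuracy(
                susp["pred_location"], susp["label_location"]
            )
    return out


def train(
    cfg: TrainConfig,
    psma_subjects: list[Subject] | None = None,
    fdg_subjects: list[Subject] | None = None,
    model_cfg: ModelConfig | None = None,
    init_model: MultiTaskCnn | None = None,
    location_classes: list[str] | None = None,
):
    """Train a model with one of strategies I-VI.

    Returns (model, history).  Strategy IV ignores ``psma_subjects`` and
    splits the FDG subjects 90/10 at subject level (validation metrics are
    appended to the history attrs); V requires ``init_model`` (the IV
    checkpoint); VI requires both datasets and a dual-tracer model config.
    """
    strategy = cfg.strategy
    if strategy in ("I", "II", "III", "V"):
        if not psma_subjects:
            raise ConfigurationError(f"strategy {strategy} requires PSMA subjects")
        data = list(psma_subjects)
    elif strategy == "IV":
        if not fdg_subjects:
            raise ConfigurationError("strategy IV requires FDG subjects")
        data = list(fdg_subjects)
    else:  # VI
        if not psma_subjects or not fdg_subjects:
            raise ConfigurationError("strategy VI requires both tracers' datasets")
        data = list(psma_subjects) + list(fdg_subjects)

    if location_classes is None:
        location_classes = collect_location_classes(data)

    val_subjects: list[Subject] = []
    if strategy == "IV":
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x51])
        data, val_subjects = _split_subjects(data, cfg.fdg_split_fraction, rng)

    if strategy == "V":
        if init_model is None:
            raise ConfigurationError("strategy V requires a pretrained model (IV)")
        model = init_model.clone()
        if model.location_classes is None:
            model.location_classes = location_classes
    else:
        if model_cfg is None:
            model_cfg = ModelConfig(
                n_location_classes=len(location_classes),
                dual_tracer=(strategy == "VI"),
            )
        if strategy == "VI" and not model_cfg.dual_tracer:
            raise ConfigurationError("strategy VI requires dual_tracer=True")
        model = build_model(model_cfg, seed=cfg.seed, location_classes=location_classes)

    mode = "sequential" if strategy == "I" else "balanced"
    augment = strategy in ("III", "IV", "V", "VI")
    history = _run_training(model, data, cfg, mode, augment)

    if val_subjects:
        history.attrs["validation"] = evaluate_pooled(
            predict_findings(model, val_subjects)
        )
    return model, history


def stratified_folds(subjects: list[Subject], k: int, seed: int = 0,
                     strata: dict | None = None) -> list[list[Subject]]:
    """Subject-level folds, stratified on a per-subject label.

    ``strata`` maps subject_id to a stratification label (e.g. the true
    stage); by default subjects are stratified on whether they carry any
    suspicious finding.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(subjects) < k:
        raise ConfigurationError(f"{len(subjects)} subjects < {k} folds")
    if strata is None:
        strata = {
            s.subject_id: any(
                f.label_suspicious == "suspicious" for f in s.findings
            )
            for s in subjects
        }
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xCF])
    folds: list[list[Subject]] = [[] for _ in range(k)]
    slot = 0
    for label in sorted({str(strata[s.subject_id]) for s in subjects}):
        group = [s for s in subjects if str(strata[s.subject_id]) == label]
        order = rng.permutation(len(group))
        for i in order:
            folds[slot % k].append(group[i])
            slot += 1
    return folds


def crossvalidate(
    subjects: list[Subject],
    cfg: TrainConfig,
    k: int = 4,
    model_cfg: ModelConfig | None = None,
    fdg_subjects: list[Subject] | None = None,
    init_model: MultiTaskCnn | None = None,
    strata: dict | None = None,
):
    """k-fold subject-level cross-validation of one training strategy.

    Trains on k-1 folds, predicts the held-out fold, and pools predictions
    across folds.  Returns (per-fold metric dicts, pooled metric dict,
    pooled prediction table).
    """
    location_classes = collect_location_classes(subjects)
    folds = stratified_folds(subjects, k, seed=cfg.seed, strata=strata)
    fold_metrics = []
    pooled_tables = []
    for i, holdout in enumerate(folds):
        train_set = [s for j, f in enumerate(folds) if j != i for s in f]
        model, _ = train(
            cfg,
            psma_subjects=train_set,
            fdg_subjects=fdg_subjects,
            model_cfg=model_cfg,
            init_model=init_model,
            location_classes=location_classes,
        )
        pred = predict_findings(model, holdout)
        pred["fold"] = i
        pooled_tables.append(pred)
        fold_metrics.append(evaluate_pooled(pred))
    pooled = pd.concat(pooled_tables, ignore_index=True)
    return fold_metrics, evaluate_pooled(pooled), pooled
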