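"""Evaluation statistics for uptake classification and staging.

Implements the full metric set used to assess the pipeline: average
precision (area under the step-wise precision-recall curve), pooled and
per-subject detection metrics (TP/FP/FN, recall, PPV), anatomical-location
accuracies, subject-level percentile bootstrap confidence intervals,
two-sided paired z-tests on bootstrap replicates with Bonferroni
correction, confusion matrices and percent agreement for stage
comparisons.

Reporting conventions: percentages are carried unrounded internally;
detection/accuracy percentages are conventionally printed with one decimal
and agreement percentages as integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from petstage.errors import ConfigurationError, UndefinedMetricError

logger = logging.getLogger(__name__)


# -- average precision --------------------------------------------------------

def average_precision(scores, labels) -> float:
    """Area under the precision-recall curve, as a percent.

    AP = sum_k (R_k - R_{k-1}) P_k over descending-score thresholds, with
    tied scores grouped into a single threshold (step-wise interpolation,
    no smoothing).  Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).reshape(-1).astype(np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("average precision undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score group
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision) * 100.0)


# -- detection metrics --------------------------------------------------------

@dataclass
class ClassifiedCandidate:
    """One candidate region with its classification, for evaluation."""

    subject_id: str
    finding: object  # segmentation.Finding
    p_suspicious: float
    location: str = "unlabeled"


@dataclass
class MetricReport:
    """Pooled metrics with counts, per-subject table, optional CIs.

    Percent metrics are on the 0-100 scale; ``per_subject`` is a DataFrame
    with one row per subject, ``summary`` its row-wise summary statistics
    (average, min, Q1, median, Q3, max; NaN-aware), ``ci`` maps metric name
    to a (low, high) 95% interval when bootstrapping was run.
    """

    ap: float | None
    recall: float
    ppv: float
    tp: int
    fp: int
    fn: int
    accuracy_suspicious: float | None = None
    accuracy_all: float | None = None
    per_subject: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    ci: dict = field(default_factory=dict)


def _match_counts(cands, experts, match_rule, threshold):
    """TP/FP/FN for one subject's candidates vs expert-suspicious findings.

    A suspicious-classified candidate matches an expert finding if its
    SUVmax voxel lies in the expert mask ('suvmax'), or if the masks share
    any voxel ('overlap').  TP counts matched expert findings (a double
    match counts once); FP counts suspicious candidates matching nothing;
    FN counts unmatched expert findings, so TP + FN equals the number of
    expert-suspicious findings.
    """
    expert_sets = [
        set(map(tuple, f.voxels.tolist())) for f in experts
    ]
    matched = [False] * len(experts)
    fp = 0
    for cand in cands:
        if cand.p_suspicious < threshold:
            continue
        hit = False
        if match_rule == "suvmax":
            probe = tuple(cand.finding.suv_max_voxel)
            for i, es in enumerate(expert_sets):
                if probe in es:
                    matched[i] = True
                    hit = True
        elif match_rule == "overlap":
            cand_set = set(map(tuple, cand.finding.voxels.tolist()))
            for i, es in enumerate(expert_sets):
                if cand_set & es:
                    matched[i] = True
                    hit = True
        else:
            raise ConfigurationError(f"unknown match_rule {match_rule!r}")
        if not hit:
            fp += 1
    tp = sum(matched)
    fn = len(experts) - tp
    return tp, fp, fn


def detection_counts_to_percents(tp: int, fp: int, fn: int):
    """(recall, ppv) percents from pooled counts; NaN where undefined."""
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return recall, ppv


_SUMMARY_ROWS = ("average", "min", "q1", "median", "q3", "max")


def _summarize(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        v = df[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            out[col] = [np.nan] * 6
            continue
        out[col] = [
            float(np.mean(v)),
            float(np.min(v)),
            float(np.percentile(v, 25)),
            float(np.median(v)),
            float(np.percentile(v, 75)),
            float(np.max(v)),
        ]
    return pd.DataFrame(out, index=list(_SUMMARY_ROWS))


def pooled_detection_metrics(
    predictions: list[ClassifiedCandidate],
    expert_findings: list[tuple[str, object]],
    match_rule: str = "suvmax",
    threshold: float = 0.5,
) -> MetricReport:
    """Pooled and per-subject detection metrics.

    ``expert_findings`` is a list of (subject_id, Finding) for
    expert-suspicious findings.  Per-subject recall for subjects without
    expert positives is 100 by convention only when the subject also has no
    suspicious predictions, and undefined (excluded from the summary)
    otherwise.  AP is computed over all candidates pooled, against
    matched/unmatched as the binary label.
    """
    ids = [f"{sid}/{f.finding_id}" for sid, f in expert_findings]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate expert finding ids")
    subjects = sorted(
        {c.subject_id for c in predictions} | {sid for sid, _ in expert_findings}
    )
    by_subj_c: dict[str, list] = {s: [] for s in subjects}
    by_subj_e: dict[str, list] = {s: [] for s in subjects}
    for c in predictions:
        by_subj_c[c.subject_id].append(c)
    for sid, f in expert_findings:
        by_subj_e[sid].append(f)

    rows = []
    tp = fp = fn = 0
    ap_scores, ap_labels = [], []
    for sid in subjects:
        cands, experts = by_subj_c[sid], by_subj_e[sid]
        t, f_, n_ = _match_counts(cands, experts, match_rule, threshold)
        tp, fp, fn = tp + t, fp + f_, fn + n_
        n_pred = sum(1 for c in cands if c.p_suspicious >= threshold)
        if experts:
            rec = 100.0 * t / len(experts)
        else:
            rec = 100.0 if n_pred == 0 else float("nan")
        ppv_s = 100.0 * t / n_pred if n_pred > 0 else float("nan")
        rows.append(
            {"subject_id": sid, "tp": t, "fp": f_, "fn": n_,
             "recall": rec, "ppv": ppv_s}
        )
        # candidate-level scores for AP: label = matches an expert finding
        for c in cands:
            hit = _match_counts(
                [ClassifiedCandidate(sid, c.finding, 1.0, c.location)],
                experts, match_rule, 0.5,
            )[0]
            ap_scores.append(c.p_suspicious)
            ap_labels.append(1 if hit else 0)

    recall, ppv = detection_counts_to_percents(tp, fp, fn)
    try:
        ap = average_precision(ap_scores, ap_labels) if ap_scores else None
    except UndefinedMetricError:
        ap = None
    columns = ["subject_id", "tp", "fp", "fn", "recall", "ppv"]
    per_subject = pd.DataFrame(rows, columns=columns).set_index("subject_id")
    return MetricReport(
        ap=ap, recall=recall, ppv=ppv, tp=tp, fp=fp, fn=fn,
        per_subject=per_subject,
        summary=_summarize(per_subject[["recall", "ppv", "tp", "fp", "fn"]]),
    )


def location_accuracy(predicted_labels, expert_labels, suspicious_flags=None,
                      scope: str = "all") -> float:
    """Percent of expert-labeled findings with the correct predicted class.

    Aligned sequences; ``scope='suspicious_only'`` restricts to findings
    the experts labeled suspicious (``suspicious_flags`` required then).
    """
    pred = list(predicted_labels)
    true = list(expert_labels)
    if len(pred) != len(true):
        raise ValueError("prediction and label sequences differ in length")
    if scope == "suspicious_only":
        if suspicious_flags is None:
            raise ConfigurationError("suspicious_flags required for suspicious_only")
        keep = [i for i, s in enumerate(suspicious_flags) if s]
        pred = [pred[i] for i in keep]
        true = [true[i] for i in keep]
    elif scope != "all":
        raise ConfigurationError(f"unknown scope {scope!r}")
    if not true:
        raise UndefinedMetricError("location accuracy undefined on empty scope")
    correct = sum(1 for p, t in zip(pred, true) if p == t)
    return 100.0 * correct / len(true)


# -- bootstrap and tests ------------------------------------------------------

def bootstrap_ci(metric_fn, subjects: list, b: int = 2000, seed: int = 0,
                 max_redraws: int = 10_000):
    """Subject-level percentile bootstrap 95% CI.

    ``metric_fn`` maps a list of per-subject data items to a scalar;
    resamples the subject list with replacement ``b`` times.  Replicates on
    which the metric is undefined (raises UndefinedMetricError) are redrawn
    (count logged).  Returns (low, high, replicates).
    """
    if len(subjects) < 2:
        raise ConfigurationError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    n = len(subjects)
    reps = np.empty(b, dtype=np.float64)
    redraws = 0
    i = 0
    while i < b:
        idx = rng.integers(0, n, size=n)
        try:
            reps[i] = metric_fn([subjects[j] for j in idx])
        except UndefinedMetricError:
            redraws += 1
            if redraws > max_redraws:
                raise UndefinedMetricError(
                    "metric undefined on too many bootstrap replicates"
                )
            continue
        i += 1
    if redraws:
        logger.info("bootstrap: %d replicates redrawn (metric undefined)", redraws)
    low, high = np.percentile(reps, [2.5, 97.5])
    return float(low), float(high), reps


def paired_z_test(replicates_a, replicates_b, n_comparisons: int = 1):
    """Two-sided paired z-test on matched bootstrap replicates.

    z = mean(d)/sd(d) for d = a - b; p_raw = 2(1 - Phi(|z|)); Bonferroni
    multiplies by ``n_comparisons`` (capped at 1).  Degenerate cases:
    sd = 0 with mean = 0 gives p = 1; sd = 0 with mean != 0 gives p = 0.
    """
    a = np.asarray(replicates_a, dtype=np.float64).reshape(-1)
    b = np.asarray(replicates_b, dtype=np.float64).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length (paired)")
    d = a - b
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, 1.0
        logger.warning("paired_z_test: constant nonzero difference (degenerate)")
        return float(np.inf) if mean > 0 else float(-np.inf), 0.0, 0.0
    z = mean / sd
    p_raw = float(2.0 * norm.sf(abs(z)))
    return z, p_raw, min(1.0, p_raw * n_comparisons)


# -- confusion matrices and agreement -----------------------------------------

@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = annotation (truth), columns = prediction."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(cls, true_labels, pred_labels, labels) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(true_labels, pred_labels):
            counts[index[t], index[p]] += 1
        return cls(labels=list(labels), counts=counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def merge_confusion(cm: ConfusionMatrix, merge: dict) -> ConfusionMatrix:
    """Merge categories per ``merge`` (old label -> merged label).

    The map must cover a partition: every label maps somewhere (labels
    absent from the map keep their own name).
    """
    new_of = {lab: merge.get(lab, lab) for lab in cm.labels}
    new_labels = list(dict.fromkeys(new_of[lab] for lab in cm.labels))
    for old in merge:
        if old not in cm.labels:
            raise ConfigurationError(f"merge map references unknown label {old!r}")
    index = {lab: i for i, lab in enumerate(new_labels)}
    counts = np.zeros((len(new_labels), len(new_labels)), dtype=np.int64)
    for i, ri in enumerate(cm.labels):
        for j, cj in enumerate(cm.labels):
            counts[index[new_of[ri]], index[new_of[cj]]] += cm.counts[i, j]
    return ConfusionMatrix(labels=new_labels, counts=counts)


def stage_agreement(cm: ConfusionMatrix, merge: dict | None = None):
    """Percent agreement (trace / total) after optional category merging.

    Returns (rounded integer percent, unrounded percent).
    """
    if merge:
        cm = merge_confusion(cm, merge)
    total = int(cm.counts.sum())
    if total == 0:
        raise UndefinedMetricError("agreement undefined on an empty matrix")
    pct = 100.0 * float(np.trace(cm.counts)) / total
    return int(round(pct)), pct
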