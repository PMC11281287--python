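"""Test-set evaluation: AUC-ROC, support-weighted precision/recall/F1,
percentile-bootstrap confidence intervals, per-plant majority voting and
mean ± SD spectral signatures.

All point metrics come from scikit-learn; AUC uses the rank (Mann–Whitney)
formulation so ties count one half. Confidence intervals are 95% percentile
bootstrap with 1000 paired resamples; resamples on which a metric is undefined
(single-class draws for AUC) are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from .containers import HyperCube


def auc_roc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative
    (ties counted 0.5). Raises on single-class input."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC-ROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def weighted_prf(labels, predictions) -> tuple[float, float, float]:
    """Per-class precision/recall/F1 averaged with weights equal to class
    support; zero-division cells are defined as 0."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same length")
    p, r, f1, _ = precision_recall_fscore_support(
        labels, predictions, labels=[0, 1], average="weighted", zero_division=0)
    return float(p), float(r), float(f1)


def bootstrap_ci(labels, scores, metric_fn, n_resamples: int = 1000,
                 alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """(2.5th, 97.5th) percentile interval of ``metric_fn(labels, scores)``
    over paired resamples with replacement."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n = len(labels)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 samples")
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric_fn(labels[idx], scores[idx]))
        except ValueError:
            skipped += 1
    if not values:
        raise ValueError("metric undefined on every bootstrap resample")
    if skipped:
        warnings.warn(f"{skipped}/{n_resamples} bootstrap resamples skipped "
                      "(metric undefined)", stacklevel=2)
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class PlantVote:
    """Majority-vote aggregation of tile predictions for one plant."""

    identifier: str
    n_samples: int
    n_predicted_deficient: int
    plant_label: int
    mean_score: float
    true_label: int | None = None


def majority_vote(identifiers, predictions, scores, true_labels=None) -> list[PlantVote]:
    """Aggregate tile-level predictions to one label per plant.

    The plant is labelled water-deficient iff strictly more tiles are
    predicted deficient than not; an exact tie is broken by the mean
    continuous score versus 0.5 (label 0 when the mean is exactly 0.5).
    The plant-level continuous score is the mean of its tile scores.
    """
    identifiers = np.asarray(identifiers)
    predictions = np.asarray(predictions)
    scores = np.asarray(scores)
    votes = []
    for ident in sorted(set(identifiers.tolist())):
        sel = identifiers == ident
        n = int(sel.sum())
        n_pos = int(predictions[sel].sum())
        mean_score = float(scores[sel].mean())
        if n_pos * 2 > n:
            label = 1
        elif n_pos * 2 < n:
            label = 0
        else:
            label = 1 if mean_score > 0.5 else 0
        true = None
        if true_labels is not None:
            tl = np.asarray(true_labels)[sel]
            true = int(tl[0])
        votes.append(PlantVote(str(ident), n, n_pos, label, mean_score, true))
    return votes


def spectral_signature(cubes, masks) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD of reflectance over plant (mask-true) pixels,
    pooled across the given cubes."""
    chunks = []
    for cube, mask in zip(cubes, masks):
        values = cube.values if isinstance(cube, HyperCube) else np.asarray(cube)
        mask = np.asarray(mask, dtype=bool)
        if mask.any():
            chunks.append(values[:, mask])
    if not chunks:
        raise ValueError("no plant pixels in any cube")
    pixels = np.concatenate(chunks, axis=1)
    return pixels.mean(axis=1), pixels.std(axis=1)


@dataclass
class MetricRow:
    """Metrics (with 95% CIs) for one imaging session or the pooled set."""

    group: str
    n_per_class: dict
    auc_roc: float | None = None
    auc_ci: tuple | None = None
    f1: float = 0.0
    f1_ci: tuple = (0.0, 0.0)
    precision: float = 0.0
    precision_ci: tuple = (0.0, 0.0)
    recall: float = 0.0
    recall_ci: tuple = (0.0, 0.0)


@dataclass
class MetricsReport:
    """Sample-level per-session rows plus a pooled row, and the plant-level
    majority-vote summary."""

    rows: list
    plant_votes: list = field(default_factory=list)
    plant_auc: float | None = None
    plant_auc_ci: tuple | None = None
    plant_f1: float | None = None
    plant_f1_ci: tuple | None = None
    plant_sensitivity: float | None = None
    plant_specificity: float | None = None

    @property
    def pooled(self) -> MetricRow:
        return next(r for r in self.rows if r.group == "pooled")

    def session_rows(self) -> list:
        return [r for r in self.rows if r.group != "pooled"]


def _metric_row(group, labels, scores, threshold, n_resamples, seed) -> MetricRow:
    preds = (scores >= threshold).astype(int)
    prec, rec, f1 = weighted_prf(labels, preds)
    row = MetricRow(
        group=str(group),
        n_per_class={"C": int((labels == 0).sum()), "D": int((labels == 1).sum())},
        f1=f1, precision=prec, recall=rec)
    prf_fns = {
        "f1": lambda l, s: weighted_prf(l, (s >= threshold).astype(int))[2],
        "precision": lambda l, s: weighted_prf(l, (s >= threshold).astype(int))[0],
        "recall": lambda l, s: weighted_prf(l, (s >= threshold).astype(int))[1],
    }
    for name, fn in prf_fns.items():
        setattr(row, f"{name}_ci",
                bootstrap_ci(labels, scores, fn, n_resamples, seed=seed))
    if len(np.unique(labels)) < 2:
        warnings.warn(f"group {group!r} has a single class; AUC omitted",
                      stacklevel=2)
    else:
        row.auc_roc = auc_roc(labels, scores)
        row.auc_ci = bootstrap_ci(labels, scores, auc_roc, n_resamples, seed=seed)
    return row


def evaluate_scores(labels, scores, sessions, identifiers,
                    threshold: float = 0.5, n_resamples: int = 1000,
                    seed: int = 0) -> MetricsReport:
    """Build the full report from precomputed tile scores.

    One row per imaging session present plus a pooled row; plant-level metrics
    from majority voting (plant score = mean tile score; sensitivity = recall
    of the deficient class, specificity = recall of the control class).
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    sessions = np.asarray(sessions)
    identifiers = np.asarray(identifiers)
    rows = []
    for s in sorted(set(sessions.tolist())):
        sel = sessions == s
        rows.append(_metric_row(s, labels[sel], scores[sel], threshold,
                                n_resamples, seed))
    rows.append(_metric_row("pooled", labels, scores, threshold, n_resamples, seed))
    report = MetricsReport(rows=rows)

    preds = (scores >= threshold).astype(int)
    votes = majority_vote(identifiers, preds, scores, true_labels=labels)
    report.plant_votes = votes
    p_true = np.array([v.true_label for v in votes])
    p_pred = np.array([v.plant_label for v in votes])
    p_score = np.array([v.mean_score for v in votes])
    if len(votes) >= 2 and len(np.unique(p_true)) == 2:
        report.plant_auc = auc_roc(p_true, p_score)
        report.plant_auc_ci = bootstrap_ci(p_true, p_score, auc_roc,
                                           n_resamples, seed=seed)
        _, _, report.plant_f1 = weighted_prf(p_true, p_pred)
        report.plant_f1_ci = bootstrap_ci(
            p_true, p_score,
            lambda l, s: weighted_prf(l, (s >= 0.5).astype(int))[2],
            n_resamples, seed=seed)
        pos, neg = p_true == 1, p_true == 0
        report.plant_sensitivity = float((p_pred[pos] == 1).mean())
        report.plant_specificity = float((p_pred[neg] == 0).mean())
    return report


def evaluate(model, test_set, threshold: float = 0.5, n_resamples: int = 1000,
             seed: int = 0) -> MetricsReport:
    """Score a test set with a trained model and build the metrics report."""
    from .training import predict_scores

    if not test_set:
        raise ValueError("test set is empty")
    scores = predict_scores(model, test_set)
    labels = np.array([s.label for s in test_set])
    sessions = np.array([s.imaging for s in test_set])
    identifiers = np.array([s.identifier for s in test_set])
    return evaluate_scores(labels, scores, sessions, identifiers,
                           threshold=threshold, n_resamples=n_resamples, seed=seed)
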