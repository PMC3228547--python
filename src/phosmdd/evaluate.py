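"""Evaluation harness: metrics, five-fold CV with threshold calibration,
and the repeated balanced independent test.

Thresholds are picked on a small integer grid of bit scores (default -20
to 0).  For each candidate t, a window scoring strictly above t is a
positive call; the chosen t maximises accuracy, ties broken first by the
most balanced sensitivity/specificity, then by the larger t (favouring
specificity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .balance import select_representatives
from .fragments import PeptideFragment
from .mdd import MotifCluster
from .profiles import ProfileModel, pooled_background, score_windows, train_profile

logger = logging.getLogger(__name__)

DEFAULT_GRID = range(-20, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Precision, sensitivity, specificity, accuracy; None where undefined."""

    precision: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Pre = TP/(TP+FP), Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/all.

    A metric whose denominator is zero is reported as ``None`` rather
    than coerced to 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return MetricsReport(
        precision=ratio(counts.TP, counts.TP + counts.FP),
        sensitivity=ratio(counts.TP, counts.TP + counts.FN),
        specificity=ratio(counts.TN, counts.TN + counts.FP),
        accuracy=ratio(counts.TP + counts.TN, counts.total),
    )


def make_folds(items: Sequence, k: int = 5, seed: int = 0) -> list[list]:
    """Shuffle and split into k folds whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(items) < k:
        raise ValueError(f"cannot split {len(items)} items into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return [[items[int(i)] for i in part] for part in np.array_split(order, k)]


def _counts_at(scores_pos: np.ndarray, scores_neg: np.ndarray, t: float) -> ConfusionCounts:
    tp = int((scores_pos > t).sum())
    fp = int((scores_neg > t).sum())
    return ConfusionCounts(TP=tp, FP=fp, TN=len(scores_neg) - fp, FN=len(scores_pos) - tp)


def select_threshold(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    grid: Sequence[int] = DEFAULT_GRID,
) -> int:
    """Grid-search the bit-score cutoff maximising accuracy.

    Ties break towards the smallest |Sn - Sp| and then towards the larger
    threshold.  Sensitivity is non-increasing and specificity
    non-decreasing along the grid by construction; this is asserted on
    every call as a cheap self-check.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    sp_arr = np.asarray(scores_pos, dtype=float)
    sn_arr = np.asarray(scores_neg, dtype=float)
    if sp_arr.size == 0 or sn_arr.size == 0:
        raise ValueError("both score sets must be non-empty")
    best_t, best_key = None, None
    prev_sn, prev_sp = math.inf, -math.inf
    for t in sorted(grid):
        c = _counts_at(sp_arr, sn_arr, t)
        m = compute_metrics(c)
        assert m.sensitivity <= prev_sn + 1e-12 and m.specificity >= prev_sp - 1e-12
        prev_sn, prev_sp = m.sensitivity, m.specificity
        key = (m.accuracy, -abs(m.sensitivity - m.specificity), t)
        if best_key is None or key > best_key:
            best_t, best_key = t, key
    return best_t


def _mean_metrics(reports: Sequence[MetricsReport]) -> tuple[MetricsReport, dict[str, int]]:
    """Mean per metric across reports, excluding undefined values."""
    means: dict[str, float | None] = {}
    excluded: dict[str, int] = {}
    for name in ("precision", "sensitivity", "specificity", "accuracy"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        excluded[name] = len(reports) - len(vals)
        means[name] = float(np.mean(vals)) if vals else None
    return MetricsReport(**means), excluded


@dataclass
class ClusterCVResult:
    cluster_id: str
    threshold_bits: int
    fold_metrics: list[MetricsReport]
    mean_metrics: MetricsReport
    n_members: int


@dataclass
class CVReport:
    """Per-cluster CV outcomes plus the macro-average over clusters."""

    per_cluster: list[ClusterCVResult]
    macro_average: MetricsReport
    k: int
    seed: int
    skipped_clusters: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_cluster:
            rows.append(
                {"cluster": r.cluster_id, "n": r.n_members,
                 "threshold_bits": r.threshold_bits, **r.mean_metrics.as_dict()}
            )
        rows.append({"cluster": "Average", "n": sum(r.n_members for r in self.per_cluster),
                     "threshold_bits": None, **self.macro_average.as_dict()})
        return pd.DataFrame(rows)


def cross_validate(
    clusters: Sequence[MotifCluster],
    negatives: Sequence[PeptideFragment],
    k: int = 5,
    grid: Sequence[int] = DEFAULT_GRID,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> CVReport:
    """Five-fold cross-validation with per-cluster threshold calibration.

    Folds are built per cluster so every fold sees every motif.  Within a
    fold, the profile trains on the other folds' positives; the threshold
    is chosen on training-fold scores (positives vs an equal-size seeded
    negative sample) and evaluated on the held-out positives against a
    fresh seeded negative sample of matching size.  The reported cluster
    threshold is the modal choice across folds (ties towards the larger
    value).  Clusters smaller than k are skipped with a warning.
    """
    if background is None:
        pool = [f for c in clusters for f in c.members] + list(negatives)
        background = pooled_background(pool)
    neg_windows = [f.window for f in negatives]
    results: list[ClusterCVResult] = []
    skipped: list[str] = []
    for ci, cluster in enumerate(clusters):
        if len(cluster.members) < k:
            logger.warning("cluster %s has %d < %d members; skipped",
                           cluster.id, len(cluster.members), k)
            skipped.append(cluster.id)
            continue
        rng = np.random.default_rng((seed, ci))
        folds = make_folds(cluster.members, k, seed=int(rng.integers(2**31)))
        fold_metrics: list[MetricsReport] = []
        thresholds: list[int] = []
        for fi in range(k):
            held_out = folds[fi]
            training = [f for fj, fold in enumerate(folds) if fj != fi for f in fold]
            model = train_profile(training, pseudocount=pseudocount,
                                  background=background, cluster_id=cluster.id)
            train_scores = score_windows(model, [f.window for f in training])
            n_cal = min(len(training), len(neg_windows))
            cal_idx = rng.choice(len(neg_windows), size=n_cal, replace=False)
            cal_scores = score_windows(model, [neg_windows[int(i)] for i in cal_idx])
            t = select_threshold(train_scores, cal_scores, grid)
            thresholds.append(t)
            val_scores = score_windows(model, [f.window for f in held_out])
            n_val = min(len(held_out), len(neg_windows))
            val_idx = rng.choice(len(neg_windows), size=n_val, replace=False)
            val_neg = score_windows(model, [neg_windows[int(i)] for i in val_idx])
            fold_metrics.append(compute_metrics(_counts_at(val_scores, val_neg, t)))
        mean, _ = _mean_metrics(fold_metrics)
        counts = {t: thresholds.count(t) for t in set(thresholds)}
        chosen = max(counts, key=lambda t: (counts[t], t))
        results.append(
            ClusterCVResult(cluster_id=cluster.id, threshold_bits=chosen,
                            fold_metrics=fold_metrics, mean_metrics=mean,
                            n_members=len(cluster.members))
        )
    macro, _ = _mean_metrics([r.mean_metrics for r in results]) if results else (
        MetricsReport(None, None, None, None), {})
    return CVReport(per_cluster=results, macro_average=macro, k=k, seed=seed,
                    skipped_clusters=skipped)


def train_models(
    clusters: Sequence[MotifCluster],
    negatives: Sequence[PeptideFragment],
    k: int = 5,
    grid: Sequence[int] = DEFAULT_GRID,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> tuple[list[ProfileModel], CVReport]:
    """Train one final profile per cluster with its CV-calibrated threshold."""
    if background is None:
        pool = [f for c in clusters for f in c.members] + list(negatives)
        background = pooled_background(pool)
    report = cross_validate(clusters, negatives, k=k, grid=grid, seed=seed,
                            pseudocount=pseudocount, background=background)
    thresholds = {r.cluster_id: r.threshold_bits for r in report.per_cluster}
    models: list[ProfileModel] = []
    for cluster in clusters:
        if cluster.id not in thresholds:
            continue
        model = train_profile(cluster, pseudocount=pseudocount,
                              background=background, cluster_id=cluster.id)
        model.threshold_bits = thresholds[cluster.id]
        models.append(model)
    return models, report


@dataclass
class IndependentTestReport:
    per_repeat: list[MetricsReport]
    mean: MetricsReport
    sd: dict[str, float | None]
    repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"repeat": i, **m.as_dict()} for i, m in enumerate(self.per_repeat)]
        rows.append({"repeat": "mean", **self.mean.as_dict()})
        rows.append({"repeat": "sd", **self.sd})
        return pd.DataFrame(rows)


def independent_test(
    models: Sequence[ProfileModel],
    positives: Sequence[PeptideFragment],
    negatives_pool: Sequence[PeptideFragment],
    repeats: int = 10,
    seed: int = 0,
) -> IndependentTestReport:
    """Repeated balanced test with the at-least-one-model positive rule.

    Each repeat balances the negative pool down to the positive count by
    medoid selection (seed + repeat index), then classifies every test
    fragment: positive if any model scores it above that model's
    threshold.  Results are aggregated per repeat; mean and standard
    deviation are reported across repeats.
    """
    from .predict import classify_window

    if len(negatives_pool) < len(positives):
        raise ValueError("negative pool smaller than positive set")
    per_repeat: list[MetricsReport] = []
    for r in range(repeats):
        bal = select_representatives(negatives_pool, K=len(positives), seed=seed + r)
        tp = sum(classify_window(models, f.window)[0] for f in positives)
        fp = sum(classify_window(models, f.window)[0] for f in bal.selected)
        counts = ConfusionCounts(TP=tp, FP=fp,
                                 TN=len(bal.selected) - fp, FN=len(positives) - tp)
        per_repeat.append(compute_metrics(counts))
    mean, _ = _mean_metrics(per_repeat)
    sd: dict[str, float | None] = {}
    for name in ("precision", "sensitivity", "specificity", "accuracy"):
        vals = [getattr(m, name) for m in per_repeat if getattr(m, name) is not None]
        sd[name] = float(np.std(vals)) if vals else None
    return IndependentTestReport(per_repeat=per_repeat, mean=mean, sd=sd,
                                 repeats=repeats, seed=seed)
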