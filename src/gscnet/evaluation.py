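"""Confusion accounting, accuracy/sensitivity/specificity, AUC, ablations.

Positive means CGI present.  Metrics with an empty denominator (no positives
for sensitivity, no negatives for specificity, single-class truth for AUC)
are reported as ``None`` — an explicit undefined marker, never silently 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import GSCNet, ModelConfig, build_model
from .synthetic import Cohort

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "auc",
    "evaluate_model",
    "run_ablation",
    "ABLATION_VARIANTS",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    auc: Optional[float]
    counts: ConfusionCounts
    threshold: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "threshold": self.threshold,
        }


def _check_labels(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(int)


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Tally confusion counts; positive = CGI present."""
    pred = _check_labels(predicted, "predicted")
    true = _check_labels(truth, "truth")
    if len(pred) != len(true):
        raise ValueError(
            f"length mismatch: {len(pred)} predictions vs {len(true)} truths"
        )
    if len(pred) == 0:
        raise ValueError("need at least one prediction")
    return ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Exact rational accuracy, sensitivity and specificity.

    acc = (TP+TN)/(TP+TN+FP+FN); sens = TP/(TP+FN); spec = TN/(TN+FP).
    A zero denominator yields ``None``.
    """

    def ratio(num: int, den: int) -> Optional[float]:
        return float(Fraction(num, den)) if den > 0 else None

    acc = ratio(counts.tp + counts.tn, counts.total)
    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    return acc, sens, spec


def auc(scores: Sequence[float], truth: Sequence[int]) -> Optional[float]:
    """Probability a random positive outranks a random negative, ties 1/2.

    Computed from midranks (Mann-Whitney), equivalent to trapezoidal ROC
    integration.  ``None`` when the truth is single-class.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels(truth, "truth")
    if len(s) != len(y):
        raise ValueError("scores and truth must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # midranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_model(
    model: GSCNet,
    cohort: Cohort,
    threshold: float = 0.5,
    batch_size: int = 32,
) -> MetricsReport:
    """Score every patient (eval mode, no augmentation) and report metrics."""
    antrum, body, cardia = cohort.image_batches()
    truth = cohort.labels
    was_training = model.training
    model.eval()
    try:
        scores = []
        for start in range(0, len(cohort), batch_size):
            sl = slice(start, start + batch_size)
            outputs = model.forward(antrum[sl], body[sl], cardia[sl])
            scores.append(outputs.final.data[:, 1])
        scores = np.concatenate(scores)
    finally:
        model.train(was_training)
    predicted = (scores >= threshold).astype(int)  # ties resolve positive
    counts = confusion(predicted, truth)
    acc, sens, spec = metrics(counts)
    return MetricsReport(acc, sens, spec, auc(scores, truth), counts, threshold)


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

#: variant tag -> (ModelConfig overrides, TrainConfig overrides)
ABLATION_VARIANTS: dict[str, tuple[dict, dict]] = {
    "full": ({}, {}),
    "-SFF": ({"use_sff": False}, {}),  # single large-field-of-view branch
    "-CA": ({"use_ca": False}, {}),  # channel attention -> identity
    "-SC": ({"use_sc": False}, {}),  # one head on f^ABC, single loss
    "-labc": ({}, {"use_loss_abc": False}),  # drop the third correlation loss
}


def run_ablation(
    train_cohort: Cohort,
    test_cohort: Cohort,
    variants: Sequence[str],
    model_cfg: ModelConfig,
    train_cfg,
    seeds: Sequence[int] = (0,),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Train each variant under identical data and seeds; one metrics row per
    (variant, seed) pair.

    Variant tags: ``full``, ``-SFF``, ``-CA``, ``-SC``, ``-labc``.
    """
    from .training import train as _train  # deferred: avoids import cycle

    for tag in variants:
        if tag not in ABLATION_VARIANTS:
            raise ValueError(
                f"unknown variant {tag!r}; choose from {sorted(ABLATION_VARIANTS)}"
            )
    rows = []
    for tag in variants:
        model_over, train_over = ABLATION_VARIANTS[tag]
        for seed in seeds:
            cfg_v = dataclasses.replace(model_cfg, **model_over)
            tcfg_v = dataclasses.replace(train_cfg, **train_over, seed=int(seed))
            model = build_model(cfg_v, seed=int(seed))
            model, _ = _train(model, train_cohort, tcfg_v)
            report = evaluate_model(model, test_cohort, threshold=threshold)
            rows.append(
                {
                    "variant": tag,
                    "seed": int(seed),
                    "accuracy": report.accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "auc": report.auc,
                }
            )
    return pd.DataFrame(rows)
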