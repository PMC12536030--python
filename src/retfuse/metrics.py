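"""Evaluation metrics: Top-k accuracy, MRR, ECE and the multiclass Brier score.

Ranking metrics use 1-based ranks in the descending sort of each predicted
distribution, ties broken by label order (the same deterministic convention
used throughout the package), so MRR lies in (0, 1] and Top-k is monotone
non-decreasing in k.

ECE bins each case by its confidence — defined as the top-1 predicted
probability — into M equal-width bins over [0, 1], half-open [m/M, (m+1)/M)
with the last bin closed, and sums the bin-weighted absolute gaps between
empirical accuracy and mean confidence:

    ECE = Σ_m |B_m|/N · |acc(B_m) − conf(B_m)|

The Brier score is the mean over cases of the full-vector squared error
against the one-hot truth, Σ_c (p_c − 1{y=c})², with no ÷2 convention; its
algebraic range is [0, 2] for multiclass predictions.

All metrics are point estimates; no interval estimation is provided.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core import DEFAULT_LABEL_SET, LabelSet, ProbVector

__all__ = [
    "EvaluationConfig",
    "top_k_accuracy",
    "mean_reciprocal_rank",
    "expected_calibration_error",
    "brier_score",
    "rank_of_truth",
    "evaluate",
]


class EvaluationConfig(BaseModel):
    """Which k values to report and how many ECE bins to use."""

    model_config = ConfigDict(frozen=True)

    k_values: tuple[int, ...] = (1, 3)
    ece_bins: int = Field(default=10, ge=1)

    @field_validator("k_values")
    @classmethod
    def _check_k(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if not v or any(k < 1 for k in v):
            raise ValueError("k values must be positive")
        return v


def _check_lengths(
    predictions: Sequence[ProbVector], truths: Sequence[str], label_set: LabelSet
) -> None:
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions but {len(truths)} truths"
        )
    if not predictions:
        raise ValueError("no cases to evaluate")
    for t in truths:
        if t not in label_set:
            raise ValueError(f"truth label {t!r} not in the label set")


def rank_of_truth(p: ProbVector, truth: str, label_set: LabelSet = DEFAULT_LABEL_SET) -> int:
    """1-based rank of the true label in the descending sort of ``p``.

    A class outranks the truth if its probability is strictly higher, or
    equal with a lower label index (the deterministic tie-break).
    """
    arr = p.as_array()
    t = label_set.index(truth)
    ahead = sum(
        1
        for i in range(arr.size)
        if arr[i] > arr[t] or (arr[i] == arr[t] and i < t)
    )
    return ahead + 1


def top_k_accuracy(
    predictions: Sequence[ProbVector],
    truths: Sequence[str],
    k: int,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> float:
    """Fraction of cases whose truth is among the k top-ranked classes."""
    _check_lengths(predictions, truths, label_set)
    if not 1 <= k <= label_set.size:
        raise ValueError(f"k must be in [1, {label_set.size}], got {k}")
    hits = sum(
        rank_of_truth(p, t, label_set) <= k for p, t in zip(predictions, truths)
    )
    return hits / len(truths)


def mean_reciprocal_rank(
    predictions: Sequence[ProbVector],
    truths: Sequence[str],
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> float:
    """Mean of 1/rank(true label) over cases (1-based ranks)."""
    _check_lengths(predictions, truths, label_set)
    return float(
        np.mean([1.0 / rank_of_truth(p, t, label_set) for p, t in zip(predictions, truths)])
    )


def expected_calibration_error(
    predictions: Sequence[ProbVector],
    truths: Sequence[str],
    M: int = 10,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> float:
    """Bin-weighted |accuracy − confidence| gap over M equal-width bins.

    Confidence of a case is its top-1 predicted probability; a case counts
    as correct when its top-1 class (first index on ties) equals the truth.
    Empty bins contribute 0.
    """
    _check_lengths(predictions, truths, label_set)
    if M < 1:
        raise ValueError(f"need at least one bin, got {M}")
    n = len(truths)
    conf = np.empty(n)
    correct = np.empty(n)
    for i, (p, t) in enumerate(zip(predictions, truths)):
        arr = p.as_array()
        top = int(np.argmax(arr))
        conf[i] = arr[top]
        correct[i] = 1.0 if label_set.labels[top] == t else 0.0
    # half-open bins [m/M, (m+1)/M); confidence 1.0 folds into the last bin
    bins = np.minimum((conf * M).astype(int), M - 1)
    ece = 0.0
    for m in range(M):
        mask = bins == m
        if not mask.any():
            continue
        ece += (mask.sum() / n) * abs(correct[mask].mean() - conf[mask].mean())
    return float(ece)


def brier_score(
    predictions: Sequence[ProbVector],
    truths: Sequence[str],
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> float:
    """Mean full-vector squared error against the one-hot truth."""
    _check_lengths(predictions, truths, label_set)
    total = 0.0
    for p, t in zip(predictions, truths):
        onehot = np.zeros(label_set.size)
        onehot[label_set.index(t)] = 1.0
        total += float(np.sum((p.as_array() - onehot) ** 2))
    return total / len(truths)


def evaluate(
    predictions: Sequence[ProbVector],
    truths: Sequence[str],
    cfg: EvaluationConfig = EvaluationConfig(),
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> dict:
    """Full metric block for one method: top-k per k, MRR, ECE, Brier, n."""
    for k in cfg.k_values:
        if k > label_set.size:
            raise ValueError(f"k={k} exceeds the label set size {label_set.size}")
    return {
        "top_k": {
            k: top_k_accuracy(predictions, truths, k, label_set)
            for k in cfg.k_values
        },
        "mrr": mean_reciprocal_rank(predictions, truths, label_set),
        "ece": expected_calibration_error(predictions, truths, cfg.ece_bins, label_set),
        "brier": brier_score(predictions, truths, label_set),
        "n": len(truths),
    }
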