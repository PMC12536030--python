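"""Seeded dataset partitioning and per-submodel reliability estimation.

Labeled cases are split — with a fixed random seed, so every partition is
reproducible — into three disjoint, exhaustive subsets:

* a small **calibration** subset (default 20 cases) used *solely* to
  estimate each submodel's reliability;
* a **development** portion for internal tuning;
* a held-out **test** set for final reporting.

Reliability α_i of submodel i is its top-1 match rate on the calibration
subset: the fraction of calibration cases where the submodel's
highest-probability class equals the ground-truth label (argmax ties broken
deterministically by label order). α is therefore always a multiple of
1/n_calibration and lives in [0, 1]. Reliability is never computed on
development or test cases; when the calibration partition is supplied,
outputs from outside it are rejected outright.

The default split is unstratified uniform shuffling: class counts in the
intended corpora are moderately balanced, so stratification is optional
behavior, not the default.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core import DEFAULT_LABEL_SET, CaseRecord, LabelSet, SubmodelOutput, argmax_label

__all__ = [
    "SplitConfig",
    "DatasetSplit",
    "ReliabilityProfile",
    "split_dataset",
    "estimate_reliability",
]


class SplitConfig(BaseModel):
    """Seeded three-way split parameters.

    ``calibration_size`` cases go to the calibration subset (default 20);
    ``round(test_fraction * n)`` cases to test (default fraction 0.3, which
    on a 200-case corpus yields the 20 / 120 / 60 partition); the remainder
    to development.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    calibration_size: int = Field(default=20, gt=0)
    test_fraction: float = Field(default=0.3, gt=0.0, lt=1.0)


class DatasetSplit(BaseModel):
    """Disjoint, exhaustive calibration / development / test partitions."""

    model_config = ConfigDict(frozen=True)

    calibration: tuple[CaseRecord, ...]
    development: tuple[CaseRecord, ...]
    test: tuple[CaseRecord, ...]
    provenance: dict[str, int | float] = {}

    def calibration_ids(self) -> frozenset[str]:
        return frozenset(c.case_id for c in self.calibration)


class ReliabilityProfile(BaseModel):
    """Per-submodel reliability α estimated on the calibration subset.

    Every α is a top-1 match rate on ``n_calibration`` cases, hence a
    multiple of ``1/n_calibration`` in [0, 1]. ``provenance`` records the
    split seed and sizes the estimate came from.
    """

    model_config = ConfigDict(frozen=True)

    alpha: dict[str, float]
    n_calibration: int = Field(gt=0)
    provenance: dict[str, int | float] = {}

    @field_validator("alpha")
    @classmethod
    def _check_alpha(cls, v: dict[str, float]) -> dict[str, float]:
        for sid, a in v.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"reliability for {sid!r} out of [0, 1]: {a!r}")
        return v


def split_dataset(
    cases: Sequence[CaseRecord],
    cfg: SplitConfig,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> DatasetSplit:
    """Partition labeled cases into calibration / development / test.

    Deterministic for a given seed (a single seeded permutation assigns the
    first ``calibration_size`` shuffled cases to calibration and the last
    ``round(test_fraction * n)`` to test). Every case must carry a label
    from the active label set.
    """
    unlabeled = [c.case_id for c in cases if c.label is None]
    if unlabeled:
        raise ValueError(f"cannot split unlabeled cases: {unlabeled[:5]}")
    bad = [c.case_id for c in cases if c.label not in label_set]
    if bad:
        raise ValueError(f"cases with labels outside the label set: {bad[:5]}")
    n = len(cases)
    n_test = int(round(cfg.test_fraction * n))
    if cfg.calibration_size >= n:
        raise ValueError(
            f"calibration_size {cfg.calibration_size} must be < number of cases {n}"
        )
    if n_test < 1 or cfg.calibration_size + n_test >= n:
        raise ValueError(
            f"split of {n} cases leaves no development cases "
            f"(calibration {cfg.calibration_size}, test {n_test})"
        )
    perm = np.random.default_rng(cfg.seed).permutation(n)
    shuffled = [cases[int(i)] for i in perm]
    calibration = tuple(shuffled[: cfg.calibration_size])
    test = tuple(shuffled[n - n_test :])
    development = tuple(shuffled[cfg.calibration_size : n - n_test])
    return DatasetSplit(
        calibration=calibration,
        development=development,
        test=test,
        provenance={
            "seed": cfg.seed,
            "calibration_size": cfg.calibration_size,
            "test_fraction": cfg.test_fraction,
            "n_total": n,
        },
    )


def estimate_reliability(
    outputs_by_submodel: Mapping[str, Sequence[SubmodelOutput]],
    truths: Mapping[str, str],
    calibration_ids: Optional[Iterable[str]] = None,
    label_set: LabelSet = DEFAULT_LABEL_SET,
    provenance: Optional[dict[str, int | float]] = None,
) -> ReliabilityProfile:
    """Estimate α_i = top-1 match rate for each submodel on calibration cases.

    ``truths`` maps every calibration case id to its ground-truth label.
    Each submodel must supply exactly one output per calibration case;
    a missing output raises, naming the submodel and the case — reliability
    is never silently imputed. When ``calibration_ids`` is given, any output
    for a case outside that partition raises (leakage guard).
    """
    if not truths:
        raise ValueError("no calibration truths supplied")
    cal_ids = frozenset(calibration_ids) if calibration_ids is not None else None
    if cal_ids is not None:
        outside = sorted(set(truths) - cal_ids)
        if outside:
            raise ValueError(
                f"truths reference cases outside the calibration partition: {outside[:5]}"
            )
    n = len(truths)
    alpha: dict[str, float] = {}
    for sid, outputs in outputs_by_submodel.items():
        by_case: dict[str, SubmodelOutput] = {}
        for out in outputs:
            if cal_ids is not None and out.case_id not in cal_ids:
                raise ValueError(
                    f"submodel {sid!r} supplied an output for case "
                    f"{out.case_id!r} outside the calibration partition"
                )
            if out.case_id in by_case:
                raise ValueError(
                    f"submodel {sid!r} has duplicate outputs for case {out.case_id!r}"
                )
            by_case[out.case_id] = out
        hits = 0
        for case_id, truth in truths.items():
            if case_id not in by_case:
                raise ValueError(
                    f"submodel {sid!r} is missing an output for calibration "
                    f"case {case_id!r}"
                )
            if argmax_label(by_case[case_id].probs, label_set) == truth:
                hits += 1
        alpha[sid] = hits / n
    return ReliabilityProfile(
        alpha=alpha, n_calibration=n, provenance=dict(provenance or {})
    )
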