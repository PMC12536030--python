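"""Core domain types and probability-vector arithmetic.

The package models five-way retinal differential diagnosis over the ordered
label set {NoDR, MildDR, SevereDR, Glaucoma, AMD} (no / mild / severe
diabetic retinopathy, glaucoma, age-related macular degeneration). Every
submodel — a language model queried per disease candidate, or an image
classifier — emits a probability vector aligned to this order; downstream
fusion, calibration and evaluation all share the types defined here.

Conventions fixed in this module and relied on everywhere else:

* probability vectors must sum to 1 within ``PROB_SUM_TOL`` (1e-9); vectors
  arriving from files are rejected when they fail this, vectors produced by
  internal floating-point arithmetic are renormalized with a warning;
* argmax ties are broken by the lowest label index, so reliability
  estimates and rankings are deterministic;
* an all-zero score vector normalizes to the uniform distribution and emits
  a :class:`DegenerateInputWarning` instead of raising — a fusion step can
  legitimately produce all-zero scores (e.g. every submodel exactly uniform)
  and the system must still return a distribution.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "PROB_SUM_TOL",
    "DEFAULT_LABELS",
    "DEFAULT_LABEL_SET",
    "DegenerateInputWarning",
    "LabelSet",
    "ProbVector",
    "CaseRecord",
    "SubmodelOutput",
    "FusedDiagnosis",
    "normalize",
    "argmax_label",
]

#: Tolerance on |sum(p) - 1| at validation boundaries.
PROB_SUM_TOL = 1e-9

#: The ordered five-way retinal label set.
DEFAULT_LABELS: tuple[str, ...] = ("NoDR", "MildDR", "SevereDR", "Glaucoma", "AMD")


class DegenerateInputWarning(UserWarning):
    """A zero-sum score vector fell back to the uniform distribution."""


class LabelSet(BaseModel):
    """An ordered, duplicate-free set of class names.

    The order is semantic: it defines vector alignment and the deterministic
    tie-break (lowest index wins) used by :func:`argmax_label` and by all
    ranking code.
    """

    model_config = ConfigDict(frozen=True)

    labels: tuple[str, ...] = DEFAULT_LABELS

    @field_validator("labels")
    @classmethod
    def _check_labels(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) < 2:
            raise ValueError("a label set needs at least two classes")
        if len(set(v)) != len(v):
            raise ValueError("labels must be unique")
        return v

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValueError(
                f"unknown label {label!r}; expected one of {list(self.labels)}"
            ) from None

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self) -> Iterator[str]:  # type: ignore[override]
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


DEFAULT_LABEL_SET = LabelSet()


class ProbVector(BaseModel):
    """A probability distribution aligned to a :class:`LabelSet` order.

    Entries are dimensionless, nonnegative and sum to 1 within
    ``PROB_SUM_TOL``.
    """

    model_config = ConfigDict(frozen=True)

    probs: tuple[float, ...]

    @field_validator("probs", mode="before")
    @classmethod
    def _coerce(cls, v: Sequence[float]) -> tuple[float, ...]:
        return tuple(float(x) for x in v)

    @field_validator("probs")
    @classmethod
    def _check_probs(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        arr = np.asarray(v, dtype=float)
        if arr.size < 2:
            raise ValueError("a probability vector needs at least two entries")
        if not np.all(np.isfinite(arr)):
            raise ValueError("probabilities must be finite")
        if np.any(arr < 0):
            raise ValueError("probabilities must be nonnegative")
        total = float(arr.sum())
        if abs(total - 1.0) > PROB_SUM_TOL:
            raise ValueError(
                f"probabilities sum to {total!r}, expected 1 within {PROB_SUM_TOL}"
            )
        return v

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def __len__(self) -> int:
        return len(self.probs)

    def __getitem__(self, i: int) -> float:
        return self.probs[i]


def _from_float_arithmetic(arr: np.ndarray) -> ProbVector:
    """Build a ProbVector from internally computed values.

    Values off by more than the validation tolerance (but still a sane
    distribution) are renormalized with a warning rather than rejected:
    rejection is the policy for *external* inputs only.
    """
    total = float(arr.sum())
    if abs(total - 1.0) > PROB_SUM_TOL:
        warnings.warn(
            f"renormalizing internally produced vector (sum={total!r})",
            DegenerateInputWarning,
            stacklevel=3,
        )
        arr = arr / total
    else:
        arr = arr / total  # snap exactly to sum 1
    return ProbVector(probs=tuple(float(x) for x in arr))


def normalize(
    raw_scores: Sequence[float] | np.ndarray,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> ProbVector:
    """Normalize nonnegative scores into a probability vector.

    The output is proportional to the input when the input sum is positive.
    An all-zero input maps to the uniform distribution with a
    :class:`DegenerateInputWarning` — see the module docstring for why this
    is not an error.

    Raises
    ------
    ValueError
        If any entry is negative or non-finite, or the length does not match
        the label set.
    """
    arr = np.asarray(raw_scores, dtype=float)
    if arr.ndim != 1 or arr.size != label_set.size:
        raise ValueError(
            f"expected {label_set.size} scores, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    if np.any(arr < 0):
        raise ValueError("scores must be nonnegative")
    total = arr.sum()
    if total == 0.0:
        warnings.warn(
            "all scores are zero; falling back to the uniform distribution",
            DegenerateInputWarning,
            stacklevel=2,
        )
        arr = np.full(label_set.size, 1.0 / label_set.size)
    else:
        arr = arr / total
    return ProbVector(probs=tuple(float(x) for x in arr))


def argmax_label(p: ProbVector, label_set: LabelSet = DEFAULT_LABEL_SET) -> str:
    """Label with the highest probability; ties go to the lowest index."""
    if len(p) != label_set.size:
        raise ValueError(
            f"vector length {len(p)} does not match label set size {label_set.size}"
        )
    return label_set.labels[int(np.argmax(p.as_array()))]


class CaseRecord(BaseModel):
    """One patient case: identifier, narrative and/or image evidence, label.

    ``image_probs`` is a precomputed five-way distribution from an image
    classifier branch (the classifier itself is outside this package); it is
    folded into fusion as just another submodel. At least one of
    ``text`` / ``image_probs`` must be present. Label membership in the
    active label set is enforced at I/O and split boundaries.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str
    text: Optional[str] = None
    image_probs: Optional[ProbVector] = None
    label: Optional[str] = None

    @field_validator("image_probs", mode="before")
    @classmethod
    def _coerce_probs(cls, v):
        if isinstance(v, (list, tuple)):
            return {"probs": v}
        return v

    @model_validator(mode="after")
    def _check_evidence(self) -> "CaseRecord":
        if self.text is None and self.image_probs is None:
            raise ValueError(
                f"case {self.case_id!r} carries neither text nor image evidence"
            )
        return self


class SubmodelOutput(BaseModel):
    """One submodel's five-way distribution for one case.

    ``response_lengths`` optionally records the per-candidate response
    lengths that induced ``probs`` through the pseudo-loss transform (text
    submodels only), one nonnegative integer per class in label-set order.
    """

    model_config = ConfigDict(frozen=True)

    submodel_id: str
    case_id: str
    probs: ProbVector
    modality: Literal["text", "image"] = "text"
    response_lengths: Optional[tuple[int, ...]] = None

    @field_validator("probs", mode="before")
    @classmethod
    def _coerce_probs(cls, v):
        if isinstance(v, (list, tuple)):
            return {"probs": v}
        return v

    @model_validator(mode="after")
    def _check_lengths(self) -> "SubmodelOutput":
        if self.response_lengths is not None:
            if len(self.response_lengths) != len(self.probs):
                raise ValueError(
                    "response_lengths must have one entry per class "
                    f"({len(self.probs)}), got {len(self.response_lengths)}"
                )
            if any(n < 0 for n in self.response_lengths):
                raise ValueError("response lengths must be nonnegative")
        return self


class FusedDiagnosis(BaseModel):
    """A fused five-way distribution with ranked hypotheses and diagnostics.

    ``per_submodel_weight`` holds each contributing submodel's effective
    fusion weight (≥ 0, dimensionless); ``per_submodel_entropy`` its Shannon
    entropy in nats, bounded by ln(size). Both are retained for audit.
    """

    model_config = ConfigDict(frozen=True)

    probs: ProbVector
    ranking: tuple[str, ...]
    per_submodel_weight: dict[str, float]
    per_submodel_entropy: dict[str, float]
    contributing: tuple[str, ...]

    @model_validator(mode="after")
    def _check(self) -> "FusedDiagnosis":
        if sorted(self.ranking) != sorted(set(self.ranking)):
            raise ValueError("ranking must not repeat labels")
        if len(self.ranking) != len(self.probs):
            raise ValueError("ranking must cover every class")
        h_max = float(np.log(len(self.probs)))
        for sid, h in self.per_submodel_entropy.items():
            if not (-1e-12 <= h <= h_max + 1e-9):
                raise ValueError(
                    f"entropy for {sid!r} out of [0, ln(size)]: {h!r}"
                )
        for sid, w in self.per_submodel_weight.items():
            if w < 0:
                raise ValueError(f"negative weight for {sid!r}: {w!r}")
        return self
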