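"""Fusion of submodel distributions: rank baseline and reliability+entropy.

Two strategies combine the per-submodel five-way distributions for a case
into a single fused distribution:

**Rank-based baseline ("1/r").** Each submodel ranks the classes by
descending probability (ties by label order); the class at 0-based rank r
accrues a fractional weight 1/(r+1), so the top class of every submodel
contributes 1, the runner-up 1/2, and so on down the harmonic sequence.
Accumulated scores are normalized. Submodel quality is deliberately
ignored — this is the transparent reference method.

**Reliability-plus-entropy aggregator.** Each submodel i carries a
reliability α_i (its top-1 match rate on the disjoint calibration subset)
and an entropy penalty: with H_i the Shannon entropy of its distribution in
nats and H_max = ln(size) (ln 5 for the five-way task), its effective weight
is

    w_i = α_i · (1 − H_i / H_max)

and the fused score of class d is Score(d) = Σ_i w_i · p_i(d), normalized
over d. Submodels that are both reliable and low-entropy contribute more;
near-uniform (maximally uncertain) distributions are driven to weight zero.
Normalizing the scores over classes is algebraically identical to first
renormalizing the weights to sum to 1.

**Missing evidence is neutral.** Fusion runs over the set of submodels
actually available for a case; an absent submodel (most often the image
branch) is simply excluded and the remaining weights renormalize through
the final normalization step. Fusing with a submodel absent therefore
equals fusing the remaining subset exactly.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import entropy as _scipy_entropy

from .calibration import ReliabilityProfile
from .core import (
    DEFAULT_LABEL_SET,
    CaseRecord,
    FusedDiagnosis,
    LabelSet,
    ProbVector,
    SubmodelOutput,
    normalize,
)

__all__ = [
    "FusionMethod",
    "FusionInputs",
    "NoEvidenceError",
    "shannon_entropy",
    "rank_fusion",
    "reliability_entropy_fusion",
    "fuse_case",
]

FusionMethod = Literal["rank", "reliability_entropy"]


class NoEvidenceError(ValueError):
    """No submodel output is available for a case; fusion cannot proceed."""


class FusionInputs(BaseModel):
    """The available submodel outputs for one case, plus reliabilities.

    ``reliabilities`` is consulted only by the reliability-plus-entropy
    method; the rank baseline ignores it.
    """

    model_config = ConfigDict(frozen=True)

    outputs: tuple[SubmodelOutput, ...]
    reliabilities: Optional[ReliabilityProfile] = None

    @model_validator(mode="after")
    def _check(self) -> "FusionInputs":
        if not self.outputs:
            raise ValueError("fusion needs at least one submodel output")
        case_ids = {o.case_id for o in self.outputs}
        if len(case_ids) > 1:
            raise ValueError(f"outputs mix multiple cases: {sorted(case_ids)}")
        sids = [o.submodel_id for o in self.outputs]
        if len(set(sids)) != len(sids):
            raise ValueError(f"duplicate submodel ids in fusion inputs: {sids}")
        return self


def shannon_entropy(p: ProbVector | Sequence[float] | np.ndarray) -> float:
    """Shannon entropy −Σ p·ln p in nats, with 0·ln 0 := 0.

    Bounded by [0, ln(size)]; the upper bound H_max = ln(size) is attained
    by the uniform distribution.
    """
    arr = p.as_array() if isinstance(p, ProbVector) else np.asarray(p, dtype=float)
    return float(_scipy_entropy(arr))


def _ranks_desc(p: np.ndarray) -> list[int]:
    """Class indices sorted by descending probability, ties by label order."""
    return sorted(range(p.size), key=lambda i: (-p[i], i))


def _ranking(fused: ProbVector, label_set: LabelSet) -> tuple[str, ...]:
    order = _ranks_desc(fused.as_array())
    return tuple(label_set.labels[i] for i in order)


def _as_inputs(inputs: FusionInputs | Sequence[SubmodelOutput]) -> FusionInputs:
    if isinstance(inputs, FusionInputs):
        return inputs
    return FusionInputs(outputs=tuple(inputs))


def rank_fusion(
    inputs: FusionInputs | Sequence[SubmodelOutput],
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> FusedDiagnosis:
    """Rank-based baseline: class at 0-based rank r accrues 1/(r+1)."""
    inp = _as_inputs(inputs)
    scores = np.zeros(label_set.size)
    entropies: dict[str, float] = {}
    for out in inp.outputs:
        p = out.probs.as_array()
        if p.size != label_set.size:
            raise ValueError(
                f"output from {out.submodel_id!r} has {p.size} classes, "
                f"label set has {label_set.size}"
            )
        for r, idx in enumerate(_ranks_desc(p)):
            scores[idx] += 1.0 / (r + 1)
        entropies[out.submodel_id] = shannon_entropy(p)
    fused = normalize(scores, label_set)
    return FusedDiagnosis(
        probs=fused,
        ranking=_ranking(fused, label_set),
        per_submodel_weight={o.submodel_id: 1.0 for o in inp.outputs},
        per_submodel_entropy=entropies,
        contributing=tuple(sorted(o.submodel_id for o in inp.outputs)),
    )


def reliability_entropy_fusion(
    inputs: FusionInputs | Sequence[SubmodelOutput],
    reliabilities: Optional[ReliabilityProfile] = None,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> FusedDiagnosis:
    """Reliability-plus-entropy aggregator.

    Score(d) = Σ_i α_i · p_i(d) · (1 − H_i/H_max), normalized over d.
    Submodels with α = 0 are retained at weight zero (their diagnostics stay
    visible). If every weight vanishes — e.g. all submodels exactly
    uniform — the fused output falls back to uniform with a warning.

    Raises
    ------
    KeyError
        If a submodel has no reliability entry, naming the submodel.
    """
    inp = _as_inputs(inputs)
    profile = reliabilities if reliabilities is not None else inp.reliabilities
    if profile is None:
        raise KeyError("reliability_entropy fusion requires a ReliabilityProfile")
    h_max = float(np.log(label_set.size))
    scores = np.zeros(label_set.size)
    weights: dict[str, float] = {}
    entropies: dict[str, float] = {}
    for out in inp.outputs:
        if out.submodel_id not in profile.alpha:
            raise KeyError(
                f"no reliability entry for submodel {out.submodel_id!r}"
            )
        p = out.probs.as_array()
        if p.size != label_set.size:
            raise ValueError(
                f"output from {out.submodel_id!r} has {p.size} classes, "
                f"label set has {label_set.size}"
            )
        h = shannon_entropy(p)
        # fp roundoff can push H a hair past H_max; the weight floor keeps it ≥ 0
        w = max(profile.alpha[out.submodel_id] * (1.0 - h / h_max), 0.0)
        weights[out.submodel_id] = w
        entropies[out.submodel_id] = min(h, h_max)
        scores += w * p
    fused = normalize(scores, label_set)
    return FusedDiagnosis(
        probs=fused,
        ranking=_ranking(fused, label_set),
        per_submodel_weight=weights,
        per_submodel_entropy=entropies,
        contributing=tuple(sorted(o.submodel_id for o in inp.outputs)),
    )


def fuse_case(
    case: CaseRecord,
    outputs: Sequence[SubmodelOutput],
    method: FusionMethod = "reliability_entropy",
    reliabilities: Optional[ReliabilityProfile] = None,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> FusedDiagnosis:
    """Fuse whatever submodel outputs exist for ``case`` with ``method``.

    Outputs for other cases are filtered out; an absent submodel (e.g. no
    image branch for this case) is simply excluded, which leaves the fusion
    of the remaining submodels unchanged. Zero available outputs raise
    :class:`NoEvidenceError` rather than returning a silent uniform.
    """
    available = tuple(o for o in outputs if o.case_id == case.case_id)
    if not available:
        raise NoEvidenceError(
            f"case {case.case_id!r}: no submodel outputs available to fuse"
        )
    inp = FusionInputs(outputs=available, reliabilities=reliabilities)
    if method == "rank":
        return rank_fusion(inp, label_set)
    if method == "reliability_entropy":
        return reliability_entropy_fusion(inp, reliabilities, label_set)
    raise ValueError(f"unknown fusion method {method!r}")
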