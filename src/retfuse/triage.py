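"""Threshold-based mapping from a fused distribution to a triage action.

A fused five-way distribution is mapped to one of four tiers —
``referral > monitoring > screening > none`` — by comparing per-class fused
probabilities against three strictly increasing thresholds. The highest
tier whose threshold is met by any eligible class wins; within a tier, the
triggering class is the one with the highest probability (label order on
ties). The distribution itself is always passed through unmodified
alongside the action, so downstream consumers see the preserved
uncertainty, never just the committed tier.

The default thresholds (0.15 / 0.35 / 0.60) are documented, non-clinical
placeholders: the mapping is an application-aligned decision support, not a
validated clinical endpoint, and every number here is configuration. By
default the no-disease class ``NoDR`` is exempt from triggering any tier,
and only the sight-threatening classes {SevereDR, Glaucoma, AMD} can
trigger a referral.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import DEFAULT_LABEL_SET, FusedDiagnosis, LabelSet, ProbVector

__all__ = ["TriageAction", "TriagePolicy", "TriageDecision", "map_to_action"]

TriageAction = Literal["none", "screening", "monitoring", "referral"]

#: Tier precedence, strongest first.
_TIERS: tuple[TriageAction, ...] = ("referral", "monitoring", "screening")


class TriagePolicy(BaseModel):
    """Strictly increasing action thresholds plus class eligibility rules."""

    model_config = ConfigDict(frozen=True)

    screening_min: float = Field(default=0.15, ge=0.0, le=1.0)
    monitoring_min: float = Field(default=0.35, ge=0.0, le=1.0)
    referral_min: float = Field(default=0.60, ge=0.0, le=1.0)
    referral_classes: frozenset[str] = frozenset({"SevereDR", "Glaucoma", "AMD"})
    exempt_classes: frozenset[str] = frozenset({"NoDR"})

    @model_validator(mode="after")
    def _check_order(self) -> "TriagePolicy":
        if not (self.screening_min < self.monitoring_min < self.referral_min):
            raise ValueError(
                "thresholds must be strictly increasing: "
                f"screening {self.screening_min} < monitoring {self.monitoring_min} "
                f"< referral {self.referral_min}"
            )
        return self

    def threshold(self, tier: TriageAction) -> float:
        return {
            "screening": self.screening_min,
            "monitoring": self.monitoring_min,
            "referral": self.referral_min,
        }[tier]


class TriageDecision(BaseModel):
    """Chosen tier, the class/probability that triggered it, and the full
    (unmodified) fused distribution for audit."""

    model_config = ConfigDict(frozen=True)

    action: TriageAction
    trigger_label: Optional[str] = None
    trigger_probability: Optional[float] = None
    probs: ProbVector


def map_to_action(
    diag: FusedDiagnosis,
    policy: TriagePolicy = TriagePolicy(),
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> TriageDecision:
    """Map a fused diagnosis to the highest triage tier its probabilities meet.

    Referral eligibility is restricted to ``policy.referral_classes``;
    monitoring and screening consider every non-exempt class. Classes in
    ``policy.exempt_classes`` never trigger any tier.
    """
    arr = diag.probs.as_array()
    if arr.size != label_set.size:
        raise ValueError(
            f"distribution has {arr.size} classes, label set has {label_set.size}"
        )
    for tier in _TIERS:
        if tier == "referral":
            eligible = policy.referral_classes - policy.exempt_classes
        else:
            eligible = set(label_set.labels) - policy.exempt_classes
        cut = policy.threshold(tier)
        hits = [
            (label_set.labels[i], float(arr[i]))
            for i in range(arr.size)
            if label_set.labels[i] in eligible and arr[i] >= cut
        ]
        if hits:
            # highest probability wins; label (index) order breaks exact ties
            best = max(hits, key=lambda lp: (lp[1], -label_set.index(lp[0])))
            return TriageDecision(
                action=tier,
                trigger_label=best[0],
                trigger_probability=best[1],
                probs=diag.probs,
            )
    return TriageDecision(action="none", probs=diag.probs)
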