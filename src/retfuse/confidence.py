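"""Pseudo-loss confidence scoring: response lengths → a five-way distribution.

Language-model submodels are queried once per disease candidate and do not
declare probabilities. Instead, a heuristic surrogate converts the length of
each per-candidate response into an unnormalized confidence:

    pseudo_loss(d) = len(response_d) / length_divisor      (divisor 10.0)
    confidence(d)  = 1 / (pseudo_loss(d) + epsilon)

followed by normalization across the candidates, so *shorter* responses
receive *higher* probability. This is a relative-reactivity heuristic, not a
calibrated probability estimator; it is kept exactly as stated so the rest
of the pipeline (reliability estimation, fusion, calibration metrics) can be
studied on top of it.

``epsilon`` guards the zero-length response (confidence 1/epsilon, finite);
lengths are counted in characters by default, with a token mode available
for sensitivity analysis.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .core import DEFAULT_LABEL_SET, LabelSet, ProbVector, normalize

__all__ = [
    "ConfidenceConfig",
    "DEFAULT_CONFIDENCE_CONFIG",
    "pseudo_loss",
    "confidence",
    "lengths_to_distribution",
]


class ConfidenceConfig(BaseModel):
    """Parameters of the pseudo-loss transform.

    epsilon
        Additive guard in the reciprocal, > 0. Default 1e-9: small enough
        not to distort any realistic length, large enough to keep
        zero-length responses finite.
    length_divisor
        The constant dividing the raw length. Default 10.0.
    length_unit
        Bookkeeping only — records whether lengths were counted in
        characters (default) or tokens.
    """

    model_config = ConfigDict(frozen=True)

    epsilon: float = Field(default=1e-9, gt=0)
    length_divisor: float = Field(default=10.0, gt=0)
    length_unit: Literal["characters", "tokens"] = "characters"


DEFAULT_CONFIDENCE_CONFIG = ConfidenceConfig()


def _check_length(length: int) -> int:
    if not float(length).is_integer() or isinstance(length, bool):
        raise ValueError(f"length must be an integer, got {length!r}")
    length = int(length)
    if length < 0:
        raise ValueError(f"length must be nonnegative, got {length}")
    return length


def pseudo_loss(length: int, cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG) -> float:
    """Surrogate loss of one candidate response: ``length / length_divisor``."""
    return _check_length(length) / cfg.length_divisor


def confidence(length: int, cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG) -> float:
    """Unnormalized confidence ``1 / (pseudo_loss + epsilon)``.

    Strictly decreasing in ``length``; finite (``1/epsilon``) at length 0.
    """
    return 1.0 / (pseudo_loss(length, cfg) + cfg.epsilon)


def lengths_to_distribution(
    lengths: Sequence[int],
    cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> ProbVector:
    """Per-candidate response lengths → a submodel probability vector.

    One length per class, in label-set order. Confidences are computed per
    candidate and normalized; shorter responses map to higher probability.
    """
    if len(lengths) != label_set.size:
        raise ValueError(
            f"expected {label_set.size} lengths (one per class), got {len(lengths)}"
        )
    conf = np.array([confidence(n, cfg) for n in lengths], dtype=float)
    return normalize(conf, label_set)
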