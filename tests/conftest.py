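"""Shared fixtures and hypothesis configuration for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retfuse import (
    DEFAULT_LABEL_SET,
    ProbVector,
    ReliabilityProfile,
    SubmodelOutput,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def label_set():
    return DEFAULT_LABEL_SET


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_prob_vector(rng: np.random.Generator, size: int = 5) -> ProbVector:
    return ProbVector(probs=tuple(rng.dirichlet(np.ones(size))))


def random_fusion_instance(
    rng: np.random.Generator, n_submodels: int, case_id: str = "case-x"
) -> tuple[list[SubmodelOutput], ReliabilityProfile]:
    """Random submodel outputs for one case plus random reliabilities."""
    outputs = [
        SubmodelOutput(
            submodel_id=f"sub-{j}",
            case_id=case_id,
            probs=random_prob_vector(rng),
        )
        for j in range(n_submodels)
    ]
    profile = ReliabilityProfile(
        alpha={f"sub-{j}": float(rng.uniform(0, 1)) for j in range(n_submodels)},
        n_calibration=20,
    )
    return outputs, profile


@pytest.fixture
def two_submodel_case():
    """The hand-computed two-submodel reliability+entropy scenario."""
    a = SubmodelOutput(
        submodel_id="A",
        case_id="c1",
        probs=ProbVector(probs=(0.7, 0.1, 0.1, 0.05, 0.05)),
    )
    b = SubmodelOutput(
        submodel_id="B",
        case_id="c1",
        probs=ProbVector(probs=(0.1, 0.6, 0.1, 0.1, 0.1)),
    )
    profile = ReliabilityProfile(alpha={"A": 0.6, "B": 0.3}, n_calibration=20)
    return a, b, profile
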