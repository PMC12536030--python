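"""Synthetic ensemble simulator: labeled cases plus submodel outputs.

The study regime this package targets — a ~200-case five-way retinal corpus
scored by half a dozen language-model submodels of heterogeneous quality
(top-1 accuracy roughly 0.22–0.56), plus an image branch covering only a
minority of cases — cannot be reproduced offline. This module generates
that regime synthetically so every downstream stage (pseudo-loss scoring,
calibration, fusion, evaluation, triage) is testable end to end with full
control over the ground truth.

Per covered case, a submodel's output is drawn as follows: the emitted
distribution's mode equals the true label with probability
``target_accuracy`` and is otherwise uniform over the remaining classes
(no confusion structure is assumed by default). A symmetric Dirichlet(1)
draw u supplies the off-mode shape; its largest coordinate is swapped into
the mode position and the vector sharpened toward the mode:

    p = (u + κ·e_mode) / (1 + κ)

so the argmax is the chosen mode for any κ > 0 and the emitted entropy
falls as the sharpness κ rises. Text submodels additionally emit integer
per-candidate response lengths that induce their distribution through the
pseudo-loss transform (``distribution_to_lengths`` inverts it), so the
length-based scoring path is exercised end to end; image submodels emit
probabilities directly.

All randomness flows from the single scenario seed through independent
per-submodel substreams keyed by submodel id, so adding or removing a
submodel never perturbs the draws of the others.

Generated narratives are label-free placeholder stubs: synthetic text must
never leak the ground-truth label to anything that might parse it.
"""

from __future__ import annotations

import zlib
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .confidence import (
    DEFAULT_CONFIDENCE_CONFIG,
    ConfidenceConfig,
    lengths_to_distribution,
)
from .core import (
    DEFAULT_LABEL_SET,
    CaseRecord,
    LabelSet,
    ProbVector,
    SubmodelOutput,
)

__all__ = [
    "SubmodelSpec",
    "EnsembleScenario",
    "generate_cases",
    "generate_submodel_outputs",
    "generate_ensemble",
    "distribution_to_lengths",
    "study_scenario",
    "STUDY_ACCURACIES",
]

#: Heterogeneous-quality regime for the six text submodels: calibration-style
#: top-1 accuracies spanning the weak-to-strong range the method is built for.
STUDY_ACCURACIES: tuple[float, ...] = (0.45, 0.60, 0.35, 0.30, 0.30, 0.40)

#: Matching heterogeneous sharpness regime (moderate κ around 1): stronger
#: submodels are modeled as more decisive, so emitted entropy carries signal
#: about quality — the condition the entropy penalty is designed for.
STUDY_SHARPNESS: tuple[float, ...] = (1.2, 2.0, 0.8, 0.6, 0.6, 1.0)


class SubmodelSpec(BaseModel):
    """Behavioral knobs of one simulated submodel.

    target_accuracy
        Probability that the emitted distribution's argmax equals the true
        label, in [0, 1].
    sharpness
        Concentration κ > 0 of emitted distributions toward their mode;
        higher κ → lower entropy. 1.0 is a moderate setting (mode mass
        ≥ 0.5, entropy typically around 1.0–1.2 nats on five classes).
    coverage
        Fraction of cases for which this submodel emits an output at all;
        models the minority-coverage image branch (text submodels default
        to full coverage).
    """

    model_config = ConfigDict(frozen=True)

    submodel_id: str
    target_accuracy: float = Field(ge=0.0, le=1.0)
    sharpness: float = Field(default=1.0, gt=0.0)
    modality: str = "text"
    coverage: float = Field(default=1.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_modality(self) -> "SubmodelSpec":
        if self.modality not in ("text", "image"):
            raise ValueError(f"modality must be text or image, got {self.modality!r}")
        return self


class EnsembleScenario(BaseModel):
    """A full simulated study: cases, class mix, submodels, one seed."""

    model_config = ConfigDict(frozen=True)

    n_cases: int = Field(gt=0)
    submodels: tuple[SubmodelSpec, ...]
    seed: int
    class_weights: Optional[ProbVector] = None  # None → uniform

    @model_validator(mode="after")
    def _check(self) -> "EnsembleScenario":
        sids = [s.submodel_id for s in self.submodels]
        if len(set(sids)) != len(sids):
            raise ValueError(f"duplicate submodel ids: {sids}")
        return self


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator keyed by (seed, name); stable across runs."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def generate_cases(
    scenario: EnsembleScenario, label_set: LabelSet = DEFAULT_LABEL_SET
) -> list[CaseRecord]:
    """Draw ``n_cases`` labeled cases with labels from ``class_weights``.

    Narratives are label-free stubs; reproducible for a given seed.
    """
    if scenario.class_weights is not None:
        weights = scenario.class_weights.as_array()
        if weights.size != label_set.size:
            raise ValueError(
                f"class_weights has {weights.size} entries, label set has "
                f"{label_set.size}"
            )
    else:
        weights = np.full(label_set.size, 1.0 / label_set.size)
    rng = _substream(scenario.seed, "cases")
    idx = rng.choice(label_set.size, size=scenario.n_cases, p=weights)
    cases = []
    for i, j in enumerate(idx):
        case_id = f"case-{i:04d}"
        cases.append(
            CaseRecord(
                case_id=case_id,
                text=f"synthetic ophthalmic narrative for {case_id} (details withheld)",
                label=label_set.labels[int(j)],
            )
        )
    return cases


def _draw_distribution(
    rng: np.random.Generator, mode: int, kappa: float, size: int
) -> np.ndarray:
    u = rng.dirichlet(np.ones(size))
    top = int(np.argmax(u))
    if top != mode:
        u[top], u[mode] = u[mode], u[top]
    p = u.copy()
    p[mode] += kappa
    return p / (1.0 + kappa)


def generate_submodel_outputs(
    cases: Sequence[CaseRecord],
    spec: SubmodelSpec,
    seed: int,
    cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> list[SubmodelOutput]:
    """Simulate one submodel over the cases (uncovered cases emit nothing).

    Text submodels emit response lengths whose pseudo-loss transform
    reproduces the drawn distribution (the stored ``probs`` are recomputed
    from those lengths, so both fields stay exactly consistent); image
    submodels emit probabilities directly.
    """
    rng = _substream(seed, spec.submodel_id)
    k = label_set.size
    outputs: list[SubmodelOutput] = []
    for case in cases:
        if rng.random() >= spec.coverage:
            continue
        if case.label is None:
            raise ValueError(f"case {case.case_id!r} has no label to simulate from")
        true_idx = label_set.index(case.label)
        if rng.random() < spec.target_accuracy:
            mode = true_idx
        else:
            others = [i for i in range(k) if i != true_idx]
            mode = int(rng.choice(others))
        p = _draw_distribution(rng, mode, spec.sharpness, k)
        if spec.modality == "text":
            lengths = distribution_to_lengths(p, cfg, label_set=label_set)
            outputs.append(
                SubmodelOutput(
                    submodel_id=spec.submodel_id,
                    case_id=case.case_id,
                    probs=lengths_to_distribution(lengths, cfg, label_set),
                    modality="text",
                    response_lengths=tuple(lengths),
                )
            )
        else:
            outputs.append(
                SubmodelOutput(
                    submodel_id=spec.submodel_id,
                    case_id=case.case_id,
                    probs=ProbVector(probs=tuple(float(x) for x in p / p.sum())),
                    modality="image",
                )
            )
    return outputs


def generate_ensemble(
    scenario: EnsembleScenario,
    cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> tuple[list[CaseRecord], list[SubmodelOutput]]:
    """Cases plus the pooled outputs of every submodel in the scenario."""
    cases = generate_cases(scenario, label_set)
    outputs: list[SubmodelOutput] = []
    for spec in scenario.submodels:
        outputs.extend(
            generate_submodel_outputs(cases, spec, scenario.seed, cfg, label_set)
        )
    return cases, outputs


def distribution_to_lengths(
    p: ProbVector | Sequence[float] | np.ndarray,
    cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG,
    scale: float = 100.0,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> list[int]:
    """Integer response lengths whose pseudo-loss transform approximates ``p``.

    Inverts the length → confidence → normalize chain: confidence is (up to
    the negligible ε term) proportional to 1/length, so lengths are taken
    proportional to 1/p and rounded, ``length_i = round(scale / p_i)``.
    ``scale`` sets the granularity; at the default 100 the rounding error
    keeps the round-trip total-variation distance well below 0.02 whenever
    all entries are ≥ 0.05. All entries of ``p`` must be strictly positive —
    probability zero would require an infinite response.
    """
    arr = p.as_array() if isinstance(p, ProbVector) else np.asarray(p, dtype=float)
    if arr.size != label_set.size:
        raise ValueError(
            f"expected {label_set.size} probabilities, got {arr.size}"
        )
    if np.any(arr <= 0):
        raise ValueError(
            "cannot invert a zero probability: no finite response length reaches it"
        )
    lengths = np.rint(scale / arr).astype(int)
    return [int(max(n, 1)) for n in lengths]


def study_scenario(
    seed: int,
    n_cases: int = 200,
    sharpness: Optional[float] = None,
    include_image: bool = False,
) -> EnsembleScenario:
    """The default study regime: six heterogeneous text submodels.

    Target accuracies follow :data:`STUDY_ACCURACIES` (0.30–0.60, i.e. a
    weak-to-strong LLM ensemble) and per-submodel sharpness follows
    :data:`STUDY_SHARPNESS` unless a single ``sharpness`` override is
    given; class mix is uniform over the five labels; ``include_image``
    adds a sharper image-classifier branch covering ~30% of cases (most
    records in the emulated corpora are text-only).
    """
    kappas = (
        STUDY_SHARPNESS if sharpness is None else (sharpness,) * len(STUDY_ACCURACIES)
    )
    submodels = [
        SubmodelSpec(
            submodel_id=f"llm-{chr(ord('a') + i)}",
            target_accuracy=acc,
            sharpness=kappa,
            modality="text",
        )
        for i, (acc, kappa) in enumerate(zip(STUDY_ACCURACIES, kappas))
    ]
    if include_image:
        submodels.append(
            SubmodelSpec(
                submodel_id="image-cnn",
                target_accuracy=0.50,
                sharpness=2.0,
                modality="image",
                coverage=0.3,
            )
        )
    return EnsembleScenario(n_cases=n_cases, submodels=tuple(submodels), seed=seed)
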