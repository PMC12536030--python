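"""End-to-end orchestration: simulate → split → calibrate → fuse → evaluate.

The stages mirror how the method is used on real data: labeled cases are
partitioned with a fixed seed; per-submodel reliabilities are estimated on
the calibration subset only; fused diagnoses are produced for the held-out
test cases by each configured fusion method; and the evaluation report
carries one metric row per single submodel plus one per fusion method,
alongside the reliability block and provenance (config hash, seed,
timestamp).

A case's precomputed image-evidence distribution, when present, is folded
in as one more submodel (id ``"image"``) — the fusion layer makes no
distinction between modalities beyond the per-submodel reliability it
already tracks. Submodels that cover only part of the corpus (typically
the image branch) are calibrated on the calibration cases they actually
cover and evaluated on the test cases they cover; their absence from a
case's fusion changes nothing except the removal of that evidence source.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .calibration import (
    DatasetSplit,
    ReliabilityProfile,
    estimate_reliability,
    split_dataset,
)
from .core import CaseRecord, FusedDiagnosis, LabelSet, SubmodelOutput
from .fusion import FusionMethod, fuse_case
from .io import RunConfig, config_hash
from .metrics import evaluate
from .simulate import generate_ensemble
from .triage import TriageDecision, map_to_action

__all__ = [
    "METHOD_LABELS",
    "RunArtifacts",
    "image_outputs_from_cases",
    "group_by_submodel",
    "calibrate_submodels",
    "fuse_cases",
    "evaluate_methods",
    "run_study",
    "write_split_assignment",
    "read_split_assignment",
]

#: Report row names for the fusion methods.
METHOD_LABELS: dict[str, str] = {
    "rank": "baseline (1/r)",
    "reliability_entropy": "reliability-plus-entropy",
}


class RunArtifacts(BaseModel):
    """Everything one pipeline run produced, for serialization or inspection."""

    model_config = ConfigDict(frozen=True)

    cases: tuple[CaseRecord, ...]
    outputs: tuple[SubmodelOutput, ...]
    split: DatasetSplit
    reliability: ReliabilityProfile
    fused: dict[str, tuple[tuple[str, FusedDiagnosis, Optional[TriageDecision]], ...]]
    report: dict


def image_outputs_from_cases(
    cases: Sequence[CaseRecord], submodel_id: str = "image"
) -> list[SubmodelOutput]:
    """Precomputed per-case image distributions as an image-branch submodel."""
    return [
        SubmodelOutput(
            submodel_id=submodel_id,
            case_id=c.case_id,
            probs=c.image_probs,
            modality="image",
        )
        for c in cases
        if c.image_probs is not None
    ]


def group_by_submodel(
    outputs: Sequence[SubmodelOutput],
) -> dict[str, list[SubmodelOutput]]:
    grouped: dict[str, list[SubmodelOutput]] = {}
    for o in outputs:
        grouped.setdefault(o.submodel_id, []).append(o)
    return grouped


def calibrate_submodels(
    split: DatasetSplit,
    outputs: Sequence[SubmodelOutput],
    label_set: LabelSet,
) -> ReliabilityProfile:
    """Reliability per submodel on the calibration cases it covers.

    Full-coverage submodels are required to cover every calibration case;
    partial-coverage submodels (the image branch) are scored on their
    covered subset, whose size is recorded in the provenance.
    """
    cal_ids = split.calibration_ids()
    truths = {c.case_id: c.label for c in split.calibration}
    grouped = group_by_submodel(
        [o for o in outputs if o.case_id in cal_ids]
    )
    alpha: dict[str, float] = {}
    per_submodel_n: dict[str, int] = {}
    for sid, outs in grouped.items():
        covered = {o.case_id for o in outs}
        sub_truths = {cid: lab for cid, lab in truths.items() if cid in covered}
        if not sub_truths:
            raise ValueError(
                f"submodel {sid!r} covers no calibration case; "
                "cannot estimate its reliability"
            )
        profile = estimate_reliability(
            {sid: outs}, sub_truths, calibration_ids=cal_ids, label_set=label_set
        )
        alpha[sid] = profile.alpha[sid]
        per_submodel_n[sid] = len(sub_truths)
    provenance: dict = dict(split.provenance)
    provenance.update({f"n_calibration[{s}]": n for s, n in per_submodel_n.items()})
    return ReliabilityProfile(
        alpha=alpha,
        n_calibration=len(split.calibration),
        provenance=provenance,
    )


def fuse_cases(
    cases: Sequence[CaseRecord],
    outputs: Sequence[SubmodelOutput],
    method: FusionMethod,
    reliabilities: Optional[ReliabilityProfile],
    config: RunConfig,
    with_triage: bool = True,
) -> list[tuple[str, FusedDiagnosis, Optional[TriageDecision]]]:
    """Fuse every case with ``method``; optionally attach a triage action."""
    by_case: dict[str, list[SubmodelOutput]] = {}
    for o in outputs:
        by_case.setdefault(o.case_id, []).append(o)
    results = []
    for case in cases:
        diag = fuse_case(
            case,
            by_case.get(case.case_id, []),
            method=method,
            reliabilities=reliabilities,
            label_set=config.label_set,
        )
        decision = (
            map_to_action(diag, config.triage, config.label_set) if with_triage else None
        )
        results.append((case.case_id, diag, decision))
    return results


def evaluate_methods(
    split: DatasetSplit,
    outputs: Sequence[SubmodelOutput],
    reliabilities: ReliabilityProfile,
    config: RunConfig,
) -> tuple[dict, dict[str, tuple[tuple[str, FusedDiagnosis, Optional[TriageDecision]], ...]]]:
    """Per-method metric rows on the test split, plus the fused artifacts.

    Rows: one per single submodel (on the test cases it covers) and one per
    configured fusion method (on all test cases).
    """
    label_set = config.label_set
    truth = {c.case_id: c.label for c in split.test}
    test_ids = set(truth)
    results: dict = {}

    for sid, outs in sorted(group_by_submodel(outputs).items()):
        covered = [o for o in outs if o.case_id in test_ids]
        if not covered:
            continue
        preds = [o.probs for o in covered]
        truths = [truth[o.case_id] for o in covered]
        results[sid] = evaluate(preds, truths, config.evaluation, label_set)

    fused_artifacts: dict = {}
    for method in config.fusion_methods:
        fused = fuse_cases(
            split.test,
            [o for o in outputs if o.case_id in test_ids],
            method,  # type: ignore[arg-type]
            reliabilities,
            config,
        )
        fused_artifacts[method] = tuple(fused)
        preds = [diag.probs for _, diag, _ in fused]
        truths = [truth[cid] for cid, _, _ in fused]
        results[METHOD_LABELS.get(method, method)] = evaluate(
            preds, truths, config.evaluation, label_set
        )
    return results, fused_artifacts


def run_study(
    config: RunConfig,
    seed: Optional[int] = None,
    timestamp: Optional[str] = None,
) -> RunArtifacts:
    """Run the whole pipeline from a configuration with a simulation scenario.

    ``seed`` overrides every embedded seed; ``timestamp`` is recorded in the
    report provenance (pass a fixed string for byte-reproducible reports).
    """
    if seed is not None:
        config = config.with_seed(seed)
    if config.scenario is None:
        raise ValueError("run_study needs a simulation scenario in the config")
    cases, outputs = generate_ensemble(
        config.scenario, config.confidence, config.label_set
    )
    outputs = list(outputs) + image_outputs_from_cases(cases)
    split = split_dataset(cases, config.split, config.label_set)
    reliability = calibrate_submodels(split, outputs, config.label_set)
    results, fused = evaluate_methods(split, outputs, reliability, config)
    triage_counts: dict[str, dict[str, int]] = {}
    for method, rows in fused.items():
        counts: dict[str, int] = {}
        for _, _, decision in rows:
            if decision is not None:
                counts[decision.action] = counts.get(decision.action, 0) + 1
        triage_counts[METHOD_LABELS.get(method, method)] = counts
    report = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "timestamp": timestamp if timestamp is not None else "unset",
            "n_cases": len(cases),
            "split": dict(split.provenance),
        },
        "reliability": {
            "alpha": dict(sorted(reliability.alpha.items())),
            "n_calibration": reliability.n_calibration,
        },
        "results": results,
        "triage": triage_counts,
    }
    return RunArtifacts(
        cases=tuple(cases),
        outputs=tuple(outputs),
        split=split,
        reliability=reliability,
        fused=fused,
        report=report,
    )


def write_split_assignment(split: DatasetSplit, path: Path | str) -> None:
    """Persist the partition assignment as a two-column CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "partition"])
        for name in ("calibration", "development", "test"):
            for case in getattr(split, name):
                writer.writerow([case.case_id, name])


def read_split_assignment(
    path: Path | str, cases: Sequence[CaseRecord]
) -> DatasetSplit:
    """Rebuild a DatasetSplit from an assignment CSV plus the case list."""
    by_id = {c.case_id: c for c in cases}
    parts: dict[str, list[CaseRecord]] = {
        "calibration": [],
        "development": [],
        "test": [],
    }
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cid, part = row["case_id"], row["partition"]
            if part not in parts:
                raise ValueError(f"{path}: unknown partition {part!r}")
            if cid not in by_id:
                raise ValueError(f"{path}: unknown case_id {cid!r}")
            parts[part].append(by_id[cid])
    return DatasetSplit(
        calibration=tuple(parts["calibration"]),
        development=tuple(parts["development"]),
        test=tuple(parts["test"]),
    )
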