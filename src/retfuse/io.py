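"""JSONL/JSON/CSV readers and writers, run configuration, provenance.

File formats
------------
Cases (JSONL, one object per line)::

    {"case_id": "case-0001", "text": "...", "image_probs": [..5..]|null,
     "label": "AMD"|null}

Submodel outputs (JSONL)::

    {"case_id": "...", "submodel_id": "...", "modality": "text"|"image",
     "probs": [..5..]|null, "response_lengths": [..5..]|null}

At least one of ``probs`` / ``response_lengths`` must be present; when only
lengths are given, the probabilities are computed on read through the
pseudo-loss transform. Duplicate (case_id, submodel_id) pairs are rejected.

Malformed rows are reported with their line numbers; in strict mode (the
default) any invalid row aborts the read, otherwise invalid rows are
skipped with a logged warning. Probabilities are serialized at full double
precision so a write/read round trip is lossless; CSV report exports round
for display only.

Every report embeds the configuration hash, the seed, and a timestamp; the
timestamp is injectable so that reruns from the same (config, seed) can be
made byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .calibration import ReliabilityProfile, SplitConfig
from .confidence import DEFAULT_CONFIDENCE_CONFIG, ConfidenceConfig, lengths_to_distribution
from .core import (
    DEFAULT_LABEL_SET,
    CaseRecord,
    FusedDiagnosis,
    LabelSet,
    SubmodelOutput,
)
from .metrics import EvaluationConfig
from .simulate import EnsembleScenario
from .triage import TriageDecision, TriagePolicy

__all__ = [
    "JsonlError",
    "RunConfig",
    "load_config",
    "config_hash",
    "read_cases",
    "write_cases",
    "read_submodel_outputs",
    "write_submodel_outputs",
    "read_reliability_profile",
    "write_reliability_profile",
    "write_fused",
    "write_report",
    "report_to_csv",
]

logger = logging.getLogger("retfuse")


class JsonlError(ValueError):
    """One or more invalid JSONL rows; carries (line number, message) pairs."""

    def __init__(self, path: Path | str, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        suffix = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{path}: {lines}{suffix}")


class RunConfig(BaseModel):
    """Everything a pipeline run needs, in one validated document."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    label_set: LabelSet = DEFAULT_LABEL_SET
    scenario: Optional[EnsembleScenario] = None
    split: SplitConfig = SplitConfig(seed=0)
    confidence: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG
    evaluation: EvaluationConfig = EvaluationConfig()
    triage: TriagePolicy = TriagePolicy()
    fusion_methods: tuple[str, ...] = ("rank", "reliability_entropy")
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "RunConfig":
        """A copy with every embedded seed replaced by ``seed``."""
        update: dict[str, Any] = {
            "seed": seed,
            "split": self.split.model_copy(update={"seed": seed}),
        }
        if self.scenario is not None:
            update["scenario"] = self.scenario.model_copy(update={"seed": seed})
        return self.model_copy(update=update)


def load_config(path: Path | str) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of the configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _read_jsonl(path: Path | str, strict: bool) -> tuple[list[tuple[int, dict]], list[tuple[int, str]]]:
    rows: list[tuple[int, dict]] = []
    errors: list[tuple[int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise ValueError("row is not a JSON object")
                rows.append((ln, obj))
            except ValueError as exc:
                errors.append((ln, f"malformed JSON: {exc}"))
    if errors and strict:
        raise JsonlError(path, errors)
    return rows, errors


def _finish(path: Path | str, errors: list[tuple[int, str]], strict: bool) -> None:
    if not errors:
        return
    if strict:
        raise JsonlError(path, errors)
    for ln, msg in errors:
        logger.warning("%s: skipping line %d: %s", path, ln, msg)


def read_cases(
    path: Path | str,
    strict: bool = True,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> list[CaseRecord]:
    """Read case records, validating labels and probability sums per line."""
    rows, errors = _read_jsonl(path, strict)
    cases: list[CaseRecord] = []
    seen: set[str] = set()
    for ln, obj in rows:
        try:
            case = CaseRecord.model_validate(obj)
            if case.label is not None and case.label not in label_set:
                raise ValueError(
                    f"label {case.label!r} not in label set {list(label_set.labels)} "
                    "(labels are exact strings)"
                )
            if case.image_probs is not None and len(case.image_probs) != label_set.size:
                raise ValueError("image_probs length does not match the label set")
            if case.case_id in seen:
                raise ValueError(f"duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)
            cases.append(case)
        except (ValidationError, ValueError) as exc:
            errors.append((ln, str(exc)))
    _finish(path, errors, strict)
    return cases


def write_cases(cases: Sequence[CaseRecord], path: Path | str) -> None:
    with open(path, "w") as fh:
        for c in cases:
            fh.write(
                json.dumps(
                    {
                        "case_id": c.case_id,
                        "text": c.text,
                        "image_probs": list(c.image_probs.probs) if c.image_probs else None,
                        "label": c.label,
                    }
                )
                + "\n"
            )


def read_submodel_outputs(
    path: Path | str,
    strict: bool = True,
    cfg: ConfidenceConfig = DEFAULT_CONFIDENCE_CONFIG,
    label_set: LabelSet = DEFAULT_LABEL_SET,
) -> list[SubmodelOutput]:
    """Read submodel outputs; rows with only response lengths get their
    probabilities computed through the pseudo-loss transform."""
    rows, errors = _read_jsonl(path, strict)
    outputs: list[SubmodelOutput] = []
    seen: set[tuple[str, str]] = set()
    for ln, obj in rows:
        try:
            probs = obj.get("probs")
            lengths = obj.get("response_lengths")
            if probs is None and lengths is None:
                raise ValueError("row has neither probs nor response_lengths")
            if probs is None:
                probs = list(lengths_to_distribution(lengths, cfg, label_set).probs)
            out = SubmodelOutput.model_validate({**obj, "probs": {"probs": probs}})
            if len(out.probs) != label_set.size:
                raise ValueError("probs length does not match the label set")
            key = (out.case_id, out.submodel_id)
            if key in seen:
                raise ValueError(f"duplicate (case_id, submodel_id) pair {key!r}")
            seen.add(key)
            outputs.append(out)
        except (ValidationError, ValueError) as exc:
            errors.append((ln, str(exc)))
    _finish(path, errors, strict)
    return outputs


def write_submodel_outputs(outputs: Sequence[SubmodelOutput], path: Path | str) -> None:
    with open(path, "w") as fh:
        for o in outputs:
            fh.write(
                json.dumps(
                    {
                        "case_id": o.case_id,
                        "submodel_id": o.submodel_id,
                        "modality": o.modality,
                        "probs": list(o.probs.probs),
                        "response_lengths": list(o.response_lengths)
                        if o.response_lengths is not None
                        else None,
                    }
                )
                + "\n"
            )


def read_reliability_profile(path: Path | str) -> ReliabilityProfile:
    with open(path) as fh:
        return ReliabilityProfile.model_validate(json.load(fh))


def write_reliability_profile(profile: ReliabilityProfile, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(profile.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")


def write_fused(
    fused: Sequence[tuple[str, FusedDiagnosis, Optional[TriageDecision]]],
    path: Path | str,
) -> None:
    """Write per-case fused diagnoses (+ optional triage actions) as JSONL."""
    with open(path, "w") as fh:
        for case_id, diag, decision in fused:
            row: dict[str, Any] = {
                "case_id": case_id,
                "probs": list(diag.probs.probs),
                "ranking": list(diag.ranking),
                "per_submodel_weight": diag.per_submodel_weight,
                "per_submodel_entropy": diag.per_submodel_entropy,
                "contributing": list(diag.contributing),
            }
            if decision is not None:
                row["triage"] = {
                    "action": decision.action,
                    "trigger_label": decision.trigger_label,
                    "trigger_probability": decision.trigger_probability,
                }
            fh.write(json.dumps(row) + "\n")


def write_report(report: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_to_csv(report: dict, path: Path | str, decimals: int = 4) -> None:
    """Flatten the per-method metric block into a CSV table (display only)."""
    methods = report.get("results", {})
    k_values = sorted(
        {int(k) for block in methods.values() for k in block.get("top_k", {})}
    )
    header = ["method"] + [f"top_{k}" for k in k_values] + ["mrr", "ece", "brier", "n"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for name, block in methods.items():
            row: list[Any] = [name]
            for k in k_values:
                v = block.get("top_k", {}).get(k, block.get("top_k", {}).get(str(k)))
                row.append("" if v is None else round(v, decimals))
            for key in ("mrr", "ece", "brier"):
                row.append(round(block[key], decimals))
            row.append(block["n"])
            writer.writerow(row)
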