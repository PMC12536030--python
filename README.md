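# retfuse

Uncertainty-aware fusion of heterogeneous diagnostic submodels for five-way
retinal differential diagnosis.

## The problem

Clinical screening pipelines increasingly ensemble several imperfect
classifiers — in this setting, a handful of large language models queried
over clinical narratives, plus an optional image-classifier branch — each
emitting a probability vector over the retinal label set
C = {NoDR, MildDR, SevereDR, Glaucoma, AMD}. Committing to any single
model's top label discards both the disagreement between models and each
model's own uncertainty. `retfuse` implements the fusion layer that keeps
both: it estimates how trustworthy each submodel is, damps the ones that
are guessing, and returns a full fused distribution with ranked hypotheses,
suitable for downstream triage rather than a single committed label.

It is a library for methodologists and tool builders evaluating ensemble
fusion and calibration; it performs no model queries itself and ships a
synthetic ensemble simulator so the whole method runs offline.

## The method

**Pseudo-loss scoring.** A text submodel is prompted once per candidate
disease d; the length of its response acts as a surrogate loss,
ℓ(d) = len(response_d)/10, and conf(d) = 1/(ℓ(d)+ε) normalized over the
five candidates yields that submodel's distribution (shorter reply ⇒
higher probability). This is a relative-reactivity heuristic, not a
calibrated estimator — which is exactly why the calibration metrics below
are part of the package.

**Reliability.** On a disjoint calibration subset (20 labeled cases by
default) each submodel i receives α_i = its top-1 match rate against
ground truth.

**Reliability-plus-entropy fusion.** With H_i the Shannon entropy of
submodel i's distribution (nats) and H_max = ln 5,

    Score(d) = Σ_i α_i · p_i(d) · (1 − H_i / H_max),

normalized over d. Reliable, decisive submodels dominate; a submodel
emitting near-uniform noise contributes nothing. A **rank-based baseline**
(class at 0-based rank r accrues 1/(r+1) per submodel) serves as the
quality-blind reference. Submodels absent for a case (typically the image
branch) are simply excluded; fusion over the remaining set is unchanged.

**Evaluation.** Top-k accuracy, mean reciprocal rank, expected calibration
error (M equal-width confidence bins) and the multiclass Brier score, all
as point estimates on a held-out test split. A configurable threshold layer
maps fused distributions to screening / monitoring / referral actions while
passing the full distribution through for audit.

## Worked example

```python
from retfuse import study_scenario
from retfuse.io import RunConfig
from retfuse.pipeline import run_study

cfg = RunConfig(seed=0, scenario=study_scenario(seed=0))
artifacts = run_study(cfg)
```

`examples/simulate_calibrate_evaluate.py` prints, for seed 0 (200 synthetic
cases, six text submodels with target accuracies 0.30–0.60, 20/120/60
split):

```
test-set results (60 cases):
method                      top-1  top-3    mrr    ece  brier
llm-a                      0.6167 0.7833 0.7333 0.1397 0.6049
llm-b                      0.5667 0.8000 0.7144 0.2531 0.7217
llm-c                      0.3333 0.7833 0.5647 0.3498 0.9332
llm-d                      0.3167 0.6833 0.5442 0.3491 0.9714
llm-e                      0.2833 0.6500 0.5019 0.3597 0.9818
llm-f                      0.3667 0.6667 0.5647 0.3532 0.9447
baseline (1/r)             0.6000 0.8833 0.7469 0.3125 0.6890
reliability-plus-entropy   0.6500 0.9333 0.7881 0.2437 0.5415
```

The fused row beats every single submodel and the rank baseline on top-1
accuracy and Brier score: weighting by calibration reliability and damping
high-entropy submodels pools the ensemble's complementary errors. The other
examples (`pseudo_loss_scoring.py`, `fuse_two_submodels.py`,
`triage_actions.py`) each walk through one capability the same way.

A thin CLI mirrors the pipeline stages on JSONL/CSV artifacts:

```bash
retfuse run-all --config run.yaml --seed 7 --out outputs/
# or stagewise: retfuse simulate | calibrate | fuse | evaluate
```

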