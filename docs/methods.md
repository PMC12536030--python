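# Methods

## Setting and model

A case x carries a free-text narrative and/or a precomputed image-evidence
distribution, plus (for labeled corpora) a ground-truth label from the
ordered five-class set C = {NoDR, MildDR, SevereDR, Glaucoma, AMD}. Each
submodel i emits a probability vector p_i(·|x) over C. The package's job is
to (a) obtain those vectors from raw per-candidate response lengths where
needed, (b) estimate per-submodel reliability on a disjoint calibration
subset, (c) fuse the available vectors per case, and (d) evaluate ranking
and calibration quality of each submodel and fusion method.

### Pseudo-loss confidence scoring

For candidate disease d, ℓ(d) = len(response_d)/10.0 and
conf(d) = 1/(ℓ(d)+ε), normalized across the five candidates. Assumptions
worth making explicit:

* the transform is monotone — shorter replies always score higher — so it
  captures *relative* reactivity only; absolute probabilities inherit no
  calibration guarantee, which is why ECE/Brier are first-class outputs;
* ε (default 1e-9, dimensionless like ℓ) exists solely to keep a
  zero-length reply finite (conf = 1/ε); it is orders of magnitude below
  any realistic ℓ and never visibly distorts a distribution;
* lengths are counted in characters by default; a token mode is provided as
  configuration for sensitivity analysis, because the choice of unit is a
  genuine free parameter of the heuristic.

### Reliability and splitting

Cases are partitioned by one seeded uniform permutation into
calibration / development / test. Defaults: 20 calibration cases and a 0.3
test fraction, i.e. 20/120/60 on a 200-case corpus. Splitting is
unstratified by default — the intended corpora are moderately class
balanced, and an unstratified single permutation keeps the provenance
trivial (seed + sizes reproduce the partition bytewise).

α_i is the top-1 match rate of submodel i on the calibration cases, hence a
multiple of 1/20 by default with a standard error around 0.11 at α ≈ 0.5 —
small-sample noise in α is an inherent property of the 20-case budget, not
an implementation artifact, and the parameter-recovery tests bound it by
the exact binomial interval rather than pretending it away. Reliability is
never computed outside the calibration partition; the estimator rejects
out-of-partition outputs outright. A partial-coverage submodel (the image
branch) is calibrated on the calibration cases it covers; the covered count
is recorded in the profile provenance.

### Fusion

Rank baseline: per submodel, classes are ranked by descending probability
(ties by label order); 0-based rank r accrues weight 1/(r+1); accumulated
scores are normalized. The top class therefore receives 1, matching the
"1/r" name under 1-based positions.

Reliability-plus-entropy: w_i = α_i(1 − H_i/H_max) with H_i in nats and
H_max = ln 5; Score(d) = Σ_i w_i p_i(d), normalized over d. Normalizing
scores over classes is algebraically the same as renormalizing weights to
sum to one, and the test suite asserts that identity numerically. α = 0
submodels are kept at weight zero rather than dropped so that their
entropy/weight diagnostics remain in the audit trail.

Missing evidence: fusion runs over the submodels present for the case; an
absent submodel is excluded before any weight is computed, so the result is
bit-identical to fusing the reduced set. Zero available submodels is an
explicit error — a silent uniform would be indistinguishable from maximal
model uncertainty downstream.

### Numerical conventions

* Probability vectors must sum to 1 within 1e-9 at I/O boundaries
  (rejected otherwise); internally produced vectors are renormalized, with
  a warning if they drift beyond the tolerance.
* All argmax/ranking ties break to the lowest label index. The tie rule is
  a package convention chosen for reproducibility; nothing in the method
  itself prescribes one.
* An all-zero score vector (every submodel exactly uniform under the
  entropy penalty) maps to the uniform distribution with a
  `DegenerateInputWarning` rather than raising: the pipeline must still
  return a distribution for every case.
* Entropies are clamped into [0, ln 5] against last-ulp floating-point
  excursions; weights are floored at 0.

### Metrics

Top-k and MRR use 1-based ranks under the same tie-break. ECE bins cases
by top-1 probability into M = 10 equal-width bins, half-open with the last
bin closed, empty bins contributing zero; confidence = top-1 probability is
the standard convention and is stated here because other conventions
(e.g. per-class binning) exist. Brier is the full-vector multiclass form
Σ_c (p_c − 1{y=c})², range [0, 2], with no ÷2. Everything is a point
estimate; interval estimation is deliberately out of scope at these sample
sizes.

## The synthetic ensemble

The simulator reproduces the *regime* the method is designed for, not any
real corpus: n_cases labeled cases (default 200, uniform class mix),
scored by submodels of chosen accuracy and sharpness. Per covered case the
emitted mode equals the truth with probability `target_accuracy`, else is
uniform over the other four classes; a symmetric Dirichlet(1) draw with its
maximum swapped into the mode position, sharpened as
p = (u + κ·e_mode)/(1+κ), supplies the distribution. The swap guarantees
the argmax is the drawn mode for every κ > 0, so realized accuracy is
exactly binomial around the target. Text submodels emit integer response
lengths (length ∝ 1/p at granularity 100) and store the distribution
recomputed from those lengths, keeping the pseudo-loss path exercised end
to end; the rounding stays below 0.02 total variation for entries ≥ 0.05.

The default study scenario uses six text submodels with target accuracies
(0.45, 0.60, 0.35, 0.30, 0.30, 0.40) — a weak-to-strong ensemble spanning
roughly 0.22–0.56 realized test accuracy — and heterogeneous moderate
sharpness κ = (1.2, 2.0, 0.8, 0.6, 0.6, 1.0), coupled so that stronger
submodels are more decisive. The coupling is the realistic case for the
entropy penalty: confidence that carries information about competence.
An optional image branch (accuracy 0.5, κ 2.0) covers 30% of cases,
mirroring corpora where only a minority of records include usable images.
All randomness derives from one scenario seed through independent
per-submodel substreams keyed by submodel id, so adding a submodel never
perturbs the others' draws.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: correlated errors between submodels (errors
here are independent given the truth; real LLMs share failure modes, which
shrinks ensemble gains), class-dependent confusion structure (an optional
confusion hook is out of scope by default), narrative-driven behavior of
any kind (texts are label-free stubs), and drift between calibration and
test conditions.

## Triage mapping

Thresholds default to 0.15 (screening) / 0.35 (monitoring) / 0.60
(referral); they are documented, arbitrary, non-clinical defaults — the
mapping is an application-aligned decision support, and every number is
configuration. NoDR is exempt from triggering any tier (a no-disease
hypothesis should not generate an action), and only {SevereDR, Glaucoma,
AMD} can trigger referral. The fused distribution is always passed through
unmodified with the action.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the study scenario at
n_cases = 200 with a 20/120/60 split, 10 seeds for across-seed summaries,
1000 random instances for fusion-oracle equivalence and missing-modality
neutrality, and 2000-case draws for rate-recovery checks — sizes chosen so
every stochastic check sits comfortably inside exact binomial 99% bounds
while the whole suite stays fast on one CPU.

## Known limitations

* The pseudo-loss surrogate is a heuristic; nothing here makes it a
  calibrated probability model, and no recalibration (temperature scaling
  etc.) is applied — reliability α is the only quality signal.
* α from 20 cases is noisy (±~0.2 at 99% confidence); fused performance
  inherits that noise across seeds.
* The rank baseline uses all five candidates per submodel; no truncated
  variant is implemented.
* Label sets other than the default five-way set are supported by the core
  arithmetic but not by the triage defaults, which name specific classes.
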