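"""Synthetic ensemble generator: determinism, rate control, round trips."""

import numpy as np
import pytest
from scipy.stats import binom

from retfuse import (
    ConfidenceConfig,
    EnsembleScenario,
    ProbVector,
    SubmodelSpec,
    argmax_label,
    distribution_to_lengths,
    generate_cases,
    generate_submodel_outputs,
    lengths_to_distribution,
    study_scenario,
)


def tv_distance(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


class TestGenerateCases:
    def test_label_counts_within_multinomial_bounds(self):
        scenario = EnsembleScenario(
            n_cases=200, submodels=(), seed=5
        )
        cases = generate_cases(scenario)
        assert len(cases) == 200
        counts = {lab: 0 for lab in ("NoDR", "MildDR", "SevereDR", "Glaucoma", "AMD")}
        for c in cases:
            counts[c.label] += 1
        lo, hi = binom.ppf([0.005, 0.995], 200, 0.2)
        for lab, cnt in counts.items():
            assert lo <= cnt <= hi, (lab, cnt)

    def test_same_seed_identical_cases(self):
        s = EnsembleScenario(n_cases=50, submodels=(), seed=9)
        assert generate_cases(s) == generate_cases(s)

    def test_degenerate_weights_force_single_label(self):
        s = EnsembleScenario(
            n_cases=30,
            submodels=(),
            seed=2,
            class_weights=ProbVector(probs=(1, 0, 0, 0, 0)),
        )
        assert all(c.label == "NoDR" for c in generate_cases(s))

    def test_narratives_never_contain_label_tokens(self):
        cases = generate_cases(EnsembleScenario(n_cases=50, submodels=(), seed=1))
        for c in cases:
            for lab in ("NoDR", "MildDR", "SevereDR", "Glaucoma", "AMD"):
                assert lab not in c.text


class TestGenerateSubmodelOutputs:
    def test_high_accuracy_high_sharpness_is_near_delta(self):
        spec = SubmodelSpec(submodel_id="s", target_accuracy=1.0, sharpness=1e6)
        cases = generate_cases(EnsembleScenario(n_cases=20, submodels=(), seed=3))
        for out in generate_submodel_outputs(cases, spec, seed=3):
            truth = next(c.label for c in cases if c.case_id == out.case_id)
            assert argmax_label(out.probs) == truth
            assert max(out.probs.probs) > 0.999

    def test_argmax_match_rate_within_binomial_bounds(self):
        spec = SubmodelSpec(submodel_id="s", target_accuracy=0.6, sharpness=1.0)
        cases = generate_cases(EnsembleScenario(n_cases=2000, submodels=(), seed=4))
        outs = generate_submodel_outputs(cases, spec, seed=4)
        truth = {c.case_id: c.label for c in cases}
        hits = sum(argmax_label(o.probs) == truth[o.case_id] for o in outs)
        lo, hi = binom.ppf([0.005, 0.995], 2000, 0.6)
        assert lo <= hits <= hi

    def test_coverage_controls_emission_rate(self):
        spec = SubmodelSpec(
            submodel_id="img", target_accuracy=0.5, coverage=0.3, modality="image"
        )
        cases = generate_cases(EnsembleScenario(n_cases=2000, submodels=(), seed=6))
        outs = generate_submodel_outputs(cases, spec, seed=6)
        lo, hi = binom.ppf([0.005, 0.995], 2000, 0.3)
        assert lo <= len(outs) <= hi

    def test_text_outputs_carry_consistent_lengths(self):
        spec = SubmodelSpec(submodel_id="s", target_accuracy=0.5, sharpness=1.0)
        cases = generate_cases(EnsembleScenario(n_cases=10, submodels=(), seed=7))
        for out in generate_submodel_outputs(cases, spec, seed=7):
            assert out.response_lengths is not None
            recomputed = lengths_to_distribution(out.response_lengths)
            assert recomputed.probs == out.probs.probs

    def test_adding_a_submodel_does_not_perturb_others(self):
        """Per-submodel substreams: llm-a draws are independent of llm-b."""
        cases = generate_cases(EnsembleScenario(n_cases=30, submodels=(), seed=8))
        a_spec = SubmodelSpec(submodel_id="llm-a", target_accuracy=0.4)
        alone = generate_submodel_outputs(cases, a_spec, seed=8)
        again = generate_submodel_outputs(cases, a_spec, seed=8)
        assert alone == again  # and unaffected by any other submodel's existence


class TestDistributionToLengths:
    def test_uniform_gives_equal_lengths(self):
        lengths = distribution_to_lengths(ProbVector(probs=(0.2,) * 5))
        assert len(set(lengths)) == 1

    def test_worked_example_ratio(self):
        p = lengths_to_distribution([10, 20, 40, 40, 40])
        lengths = distribution_to_lengths(p)
        ratio = [n / lengths[0] for n in lengths]
        assert ratio == pytest.approx([1, 2, 4, 4, 4], rel=0.01)

    def test_zero_entry_is_unreachable(self):
        with pytest.raises(ValueError):
            distribution_to_lengths(np.array([0.5, 0.5, 0.0, 0.0, 0.0]))

    def test_round_trip_total_variation(self, rng):
        """Forward(inverse(p)) stays within TV 0.02 when entries ≥ 0.05."""
        cfg = ConfidenceConfig()
        for _ in range(100):
            p = rng.dirichlet(np.ones(5) * 2.0)
            p = 0.05 + 0.75 * p  # floor entries at 0.05
            p = p / p.sum()
            lengths = distribution_to_lengths(p, cfg)
            back = lengths_to_distribution(lengths, cfg).as_array()
            assert tv_distance(p, back) <= 0.02


class TestStudyScenario:
    def test_regime_is_heterogeneous(self):
        sc = study_scenario(seed=0)
        accs = [s.target_accuracy for s in sc.submodels]
        kappas = [s.sharpness for s in sc.submodels]
        assert len(sc.submodels) == 6
        assert min(accs) == 0.30 and max(accs) == 0.60
        assert len(set(kappas)) > 1  # heterogeneous sharpness
        assert sc.n_cases == 200

    def test_optional_image_branch_has_partial_coverage(self):
        sc = study_scenario(seed=0, include_image=True)
        image = [s for s in sc.submodels if s.modality == "image"]
        assert len(image) == 1 and image[0].coverage < 1.0
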