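"""Fusion methods against loop-based reference implementations and invariants."""

import math
import warnings

import numpy as np
import pytest

from retfuse import (
    CaseRecord,
    DegenerateInputWarning,
    FusionInputs,
    NoEvidenceError,
    ProbVector,
    ReliabilityProfile,
    SubmodelOutput,
    fuse_case,
    rank_fusion,
    reliability_entropy_fusion,
    shannon_entropy,
)
from conftest import random_fusion_instance, random_prob_vector


def oracle_rank_fusion(dists: list[list[float]]) -> list[float]:
    """Naive reference: accumulate 1/(rank+1) per submodel, then normalize."""
    k = len(dists[0])
    scores = [0.0] * k
    for p in dists:
        order = sorted(range(k), key=lambda i: (-p[i], i))
        for r, idx in enumerate(order):
            scores[idx] += 1.0 / (r + 1)
    total = sum(scores)
    return [s / total for s in scores]


def oracle_reliability_entropy(
    dists: list[list[float]], alphas: list[float]
) -> list[float]:
    """Naive reference for Score(d) = Σ α·p(d)·(1 − H/H_max), normalized."""
    k = len(dists[0])
    h_max = math.log(k)
    scores = [0.0] * k
    for p, a in zip(dists, alphas):
        h = -sum(x * math.log(x) for x in p if x > 0)
        w = a * (1.0 - h / h_max)
        for d in range(k):
            scores[d] += w * p[d]
    total = sum(scores)
    if total == 0:
        return [1.0 / k] * k
    return [s / total for s in scores]


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((1, 0, 0, 0, 0), 0.0),
            ((0.2,) * 5, math.log(5)),
            # −(0.7·ln0.7 + 2·0.1·ln0.1 + 2·0.05·ln0.05), term-by-term
            ((0.7, 0.1, 0.1, 0.05, 0.05), 1.0097627067),
        ],
    )
    def test_values(self, probs, expected):
        assert shannon_entropy(ProbVector(probs=probs)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_bounded_by_ln_size(self, rng):
        for _ in range(100):
            h = shannon_entropy(random_prob_vector(rng))
            assert 0.0 <= h <= math.log(5) + 1e-12


def _out(sid, probs, case_id="c1"):
    return SubmodelOutput(submodel_id=sid, case_id=case_id, probs=ProbVector(probs=probs))


class TestRankFusion:
    def test_single_submodel_gives_harmonic_profile(self):
        diag = rank_fusion([_out("s", (0.5, 0.25, 0.12, 0.08, 0.05))])
        h5 = 137 / 60
        expected = [1 / (r + 1) / h5 for r in range(5)]
        assert diag.probs.as_array() == pytest.approx(expected, abs=1e-12)

    def test_swapped_top_two_tie_exactly(self):
        a = _out("a", (0.5, 0.3, 0.1, 0.06, 0.04))
        b = _out("b", (0.3, 0.5, 0.1, 0.06, 0.04))
        fused = rank_fusion([a, b]).probs.as_array()
        assert fused[0] == pytest.approx(fused[1], abs=1e-12)

    def test_identical_rankings_reduce_to_single_profile(self):
        a = _out("a", (0.5, 0.25, 0.12, 0.08, 0.05))
        b = _out("b", (0.4, 0.3, 0.15, 0.1, 0.05))  # same ranking
        single = rank_fusion([a]).probs.as_array()
        double = rank_fusion([a, b]).probs.as_array()
        assert double == pytest.approx(single, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            FusionInputs(outputs=())

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            outputs, _ = random_fusion_instance(rng, int(rng.integers(1, 7)))
            got = rank_fusion(outputs).probs.as_array()
            want = oracle_rank_fusion([list(o.probs.probs) for o in outputs])
            assert got == pytest.approx(want, abs=1e-12)


class TestReliabilityEntropyFusion:
    def test_single_submodel_weight_cancels(self, rng):
        p = random_prob_vector(rng)
        out = SubmodelOutput(submodel_id="s", case_id="c1", probs=p)
        prof = ReliabilityProfile(alpha={"s": 0.35}, n_calibration=20)
        fused = reliability_entropy_fusion([out], prof)
        assert fused.probs.as_array() == pytest.approx(p.as_array(), abs=1e-12)

    def test_uniform_submodel_contributes_nothing(self, rng):
        p = ProbVector(probs=(0.6, 0.2, 0.1, 0.05, 0.05))
        sharp = _out("sharp", p.probs)
        flat = _out("flat", (0.2,) * 5)
        prof = ReliabilityProfile(alpha={"sharp": 0.5, "flat": 0.9}, n_calibration=20)
        fused = reliability_entropy_fusion([sharp, flat], prof)
        assert fused.probs.as_array() == pytest.approx(p.as_array(), abs=1e-12)
        assert fused.per_submodel_weight["flat"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_submodel_example(self, two_submodel_case):
        a, b, profile = two_submodel_case
        fused = reliability_entropy_fusion([a, b], profile)
        assert fused.probs.as_array() == pytest.approx(
            [0.5551, 0.2208, 0.1000, 0.0621, 0.0621], abs=1e-3
        )
        assert fused.ranking[0] == "NoDR"

    def test_missing_reliability_names_submodel(self, two_submodel_case):
        a, b, _ = two_submodel_case
        prof = ReliabilityProfile(alpha={"A": 0.6}, n_calibration=20)
        with pytest.raises(KeyError, match="'B'"):
            reliability_entropy_fusion([a, b], prof)

    def test_all_uniform_falls_back_to_uniform_with_warning(self):
        outs = [_out(s, (0.2,) * 5) for s in ("a", "b")]
        prof = ReliabilityProfile(alpha={"a": 0.5, "b": 0.5}, n_calibration=20)
        with pytest.warns(DegenerateInputWarning):
            fused = reliability_entropy_fusion(outs, prof)
        assert fused.probs.as_array() == pytest.approx([0.2] * 5)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            outputs, profile = random_fusion_instance(rng, int(rng.integers(1, 7)))
            got = reliability_entropy_fusion(outputs, profile).probs.as_array()
            want = oracle_reliability_entropy(
                [list(o.probs.probs) for o in outputs],
                [profile.alpha[o.submodel_id] for o in outputs],
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_score_normalization_equals_weight_renormalization(self, rng):
        """Dividing scores by Σ_d Score(d) ≡ renormalizing weights to sum 1."""
        for _ in range(50):
            outputs, profile = random_fusion_instance(rng, 4)
            fused = reliability_entropy_fusion(outputs, profile)
            ws = np.array([fused.per_submodel_weight[o.submodel_id] for o in outputs])
            if ws.sum() == 0:
                continue
            ps = np.array([o.probs.as_array() for o in outputs])
            via_weights = (ws / ws.sum()) @ ps
            assert fused.probs.as_array() == pytest.approx(via_weights, abs=1e-12)

    def test_reliability_monotonicity(self):
        """Raising one submodel's α (equal entropies) raises its top class."""
        a = _out("a", (0.6, 0.2, 0.1, 0.05, 0.05))
        b = _out("b", (0.2, 0.6, 0.05, 0.1, 0.05))  # permutation → same entropy
        lo = reliability_entropy_fusion(
            [a, b], ReliabilityProfile(alpha={"a": 0.3, "b": 0.5}, n_calibration=20)
        )
        hi = reliability_entropy_fusion(
            [a, b], ReliabilityProfile(alpha={"a": 0.6, "b": 0.5}, n_calibration=20)
        )
        assert hi.probs[0] >= lo.probs[0]

    def test_entropy_monotonicity(self):
        """A strictly flatter distribution (same argmax) gets a lower weight."""
        sharp = _out("x", (0.7, 0.1, 0.1, 0.05, 0.05))
        flat = _out("x", (0.4, 0.15, 0.15, 0.15, 0.15))
        prof = ReliabilityProfile(alpha={"x": 0.8, "o": 0.5}, n_calibration=20)
        other = _out("o", (0.1, 0.6, 0.1, 0.1, 0.1))
        w_sharp = reliability_entropy_fusion([sharp, other], prof).per_submodel_weight["x"]
        w_flat = reliability_entropy_fusion([flat, other], prof).per_submodel_weight["x"]
        assert w_flat < w_sharp

    def test_label_permutation_equivariance(self, rng):
        for _ in range(25):
            outputs, profile = random_fusion_instance(rng, 3)
            perm = rng.permutation(5)
            permuted = [
                SubmodelOutput(
                    submodel_id=o.submodel_id,
                    case_id=o.case_id,
                    probs=ProbVector(probs=tuple(o.probs.as_array()[perm])),
                )
                for o in outputs
            ]
            base = reliability_entropy_fusion(outputs, profile).probs.as_array()
            moved = reliability_entropy_fusion(permuted, profile).probs.as_array()
            assert moved == pytest.approx(base[perm], abs=1e-12)


class TestFuseCase:
    def _case(self):
        return CaseRecord(case_id="c1", text="t", label="AMD")

    def test_submodel_order_is_irrelevant(self, rng):
        outputs, profile = random_fusion_instance(rng, 5, case_id="c1")
        case = self._case()
        for method in ("rank", "reliability_entropy"):
            a = fuse_case(case, outputs, method, profile).probs.as_array()
            b = fuse_case(case, outputs[::-1], method, profile).probs.as_array()
            assert a == pytest.approx(b, abs=1e-15)

    def test_absent_submodel_is_excluded_exactly(self, rng):
        """Fusing with the image branch missing equals fusing text alone."""
        outputs, profile = random_fusion_instance(rng, 4, case_id="c1")
        image = SubmodelOutput(
            submodel_id="image",
            case_id="OTHER-case",
            probs=random_prob_vector(rng),
            modality="image",
        )
        profile = ReliabilityProfile(
            alpha={**profile.alpha, "image": 0.5}, n_calibration=20
        )
        case = self._case()
        with_absent = fuse_case(case, outputs + [image], "reliability_entropy", profile)
        text_only = fuse_case(case, outputs, "reliability_entropy", profile)
        assert with_absent.probs.as_array() == pytest.approx(
            text_only.probs.as_array(), abs=0
        )
        assert "image" not in with_absent.contributing

    def test_consensus_delta_is_preserved(self):
        delta = (0.0, 0.0, 1.0, 0.0, 0.0)
        outs = [_out(s, delta) for s in ("a", "b", "c")]
        prof = ReliabilityProfile(
            alpha={"a": 0.4, "b": 0.5, "c": 0.6}, n_calibration=20
        )
        case = self._case()
        for method in ("rank", "reliability_entropy"):
            fused = fuse_case(case, outs, method, prof)
            assert fused.ranking[0] == "SevereDR"
            if method == "reliability_entropy":
                assert fused.probs.as_array() == pytest.approx(delta, abs=1e-12)

    def test_no_evidence_is_an_error_not_uniform(self):
        with pytest.raises(NoEvidenceError):
            fuse_case(self._case(), [], "rank", None)

    def test_both_methods_return_valid_distributions(self, rng):
        case = self._case()
        for _ in range(50):
            outputs, profile = random_fusion_instance(
                rng, int(rng.integers(1, 7)), case_id="c1"
            )
            for method in ("rank", "reliability_entropy"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DegenerateInputWarning)
                    fused = fuse_case(case, outputs, method, profile)
                arr = fused.probs.as_array()
                assert arr.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(arr >= 0)
                assert sorted(fused.ranking) == sorted(
                    ("NoDR", "MildDR", "SevereDR", "Glaucoma", "AMD")
                )
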