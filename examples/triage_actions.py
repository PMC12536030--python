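"""Map fused distributions to triage tiers (screening/monitoring/referral).

Thresholds are configurable, non-clinical defaults (0.15 / 0.35 / 0.60);
the no-disease class NoDR never triggers a tier, and only sight-threatening
classes (SevereDR, Glaucoma, AMD) can trigger a referral. The full fused
distribution always rides along with the action.
"""

from retfuse import (
    ProbVector,
    ReliabilityProfile,
    SubmodelOutput,
    TriagePolicy,
    map_to_action,
    reliability_entropy_fusion,
)

profile = ReliabilityProfile(alpha={"A": 0.6, "B": 0.3}, n_calibration=20)
policy = TriagePolicy()

scenarios = {
    "glaucoma consensus": [(0.05, 0.05, 0.1, 0.75, 0.05), (0.1, 0.1, 0.1, 0.6, 0.1)],
    "mild ambiguity": [(0.7, 0.1, 0.1, 0.05, 0.05), (0.1, 0.6, 0.1, 0.1, 0.1)],
    "amd progression risk": [(0.2, 0.15, 0.15, 0.1, 0.4), (0.25, 0.1, 0.1, 0.15, 0.4)],
}

for name, (pa, pb) in scenarios.items():
    fused = reliability_entropy_fusion(
        [
            SubmodelOutput(submodel_id="A", case_id="c", probs=ProbVector(probs=pa)),
            SubmodelOutput(submodel_id="B", case_id="c", probs=ProbVector(probs=pb)),
        ],
        profile,
    )
    decision = map_to_action(fused, policy)
    trigger = (
        f"{decision.trigger_label} at {decision.trigger_probability:.3f}"
        if decision.trigger_label
        else "nothing"
    )
    print(f"{name:<22} -> {decision.action:<10} (triggered by {trigger})")

# A dominant Glaucoma probability crosses the referral threshold; the mild
# NoDR-vs-MildDR case only reaches screening (NoDR is exempt); an AMD
# probability in the middle band lands on monitoring.
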