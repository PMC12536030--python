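"""Turn per-candidate response lengths into a five-way distribution.

A language model is queried once per disease candidate; the length of each
reply acts as a pseudo-loss (shorter = more confident). Here one simulated
query produced replies of 10, 20, 40, 40 and 40 characters.
"""

from retfuse import DEFAULT_LABELS, confidence, lengths_to_distribution, pseudo_loss

lengths = [10, 20, 40, 40, 40]
pv = lengths_to_distribution(lengths)

print("candidate  length  pseudo-loss  confidence  probability")
for label, n, p in zip(DEFAULT_LABELS, lengths, pv.probs):
    print(f"{label:<10} {n:>6} {pseudo_loss(n):>11.2f} {confidence(n):>11.4f} {p:>12.4f}")

# The 10-character reply earns twice the probability of the 20-character one
# and four times that of each 40-character one: probability is proportional
# to the reciprocal response length (up to the epsilon guard).
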