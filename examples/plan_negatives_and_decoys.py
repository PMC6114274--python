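"""Sizing the negative training set and generating decoy sequences.

For each domain the gathering-threshold training wants roughly as many
negative points as positive ones.  The planner sizes the effort; the
decoy generators (2-mer shuffle, reversal, order-3 Markov model) supply
the candidate sequences.
"""

import numpy as np

from cladescan.training_set import (
    fit_markov3,
    generate_simple_decoys,
    plan_negative_generation,
)

plan = plan_negative_generation(n_pos=100, n_simple_negs=10)
print(f"positives: 100 -> required negatives: {plan.required}")
print(f"cheap decoys supplied 10 -> Markov deficit: {plan.deficit}")
print(f"Markov decoys to draw at the expected SCM acceptance rate: {plan.decoy_budget}")
# required = ceil(half the positives); the deficit is what the Markov
# generator must still harvest; the budget divides it by the expected
# acceptance rate (5 per 10,000 decoys for consensus models).

rng = np.random.default_rng(0)
seed_seq = "MKVLIWAADECCHHKKWWYYMKVLIWAADE"
shuffled, reversed_ = generate_simple_decoys(seed_seq, rng)
print("\nSEED sequence:", seed_seq)
print("2-mer shuffle:", shuffled)
print("reversal:     ", reversed_)

markov = fit_markov3([seed_seq], W=1.0)
print("\norder-3 Markov decoy:", markov.sample(30, rng))
print(f"(emission over {markov.emission.size} 4-tuples, sums to {markov.emission.sum():.6f})")
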