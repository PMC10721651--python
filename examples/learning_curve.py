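"""Estimate the learning-completion trial of a synthetic mapping session.

Generates a session whose Bernoulli learner jumps from chance (1/3) to 95%
correct at trial 16, runs the binomial moving-average change-point rule
(5-trial windows, p_null = 0.45, all-correct criterion), and splits the
session into learning and post-learning blocks.
"""

import numpy as np

from pfcpop import behavior, synthetic
from pfcpop.synthetic import LearnerConfig, SyntheticConfig

cfg = SyntheticConfig(
    n_units_bw=4, n_units_nw=2, n_trials=100, seed=7,
    learner=LearnerConfig(p_pre=1 / 3, p_post=0.95, change_trial=16),
)
session, truth = synthetic.generate_session(cfg)

result = behavior.session_learning_trial(session)
learning, post = behavior.split_blocks(session.trials["trial_id"].to_numpy(), result.k)

print(f"true change trial        : {truth.change_trial}")
print(f"estimated learning trial : {result.k}")
print(f"learning block           : {len(learning)} trials")
print(f"post-learning block      : {len(post)} trials")
print(f"first window performances: {np.round(result.p_k[:12], 2)}")

# The estimated k should trail the true change point by a couple of trials:
# the rule needs a full all-correct 5-trial window before it can fire, so a
# lag of 0-4 trials is the expected behavior, not an error.
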