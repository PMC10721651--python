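"""Omega-squared selectivity time course for a selective population.

Generates a population with static association selectivity, computes the
balanced omega-squared time course (150 ms bins, 15 ms steps) and its
label-shuffle null, and reports the population onset latency against the
99.9th-percentile pointwise threshold.
"""

import numpy as np

from pfcpop import selectivity, session_io, synthetic
from pfcpop.synthetic import SyntheticConfig

cfg = SyntheticConfig(
    n_units_bw=40, n_units_nw=20, rate_bw=4.0, rate_nw=6.0, n_trials=96,
    seed=5, selectivity_profile="static", effect_size=2.5,
)
session, _ = synthetic.generate_session(cfg)

tensor = session_io.bin_spikes(session, "is_onset", (-0.5, 1.0), 150, 15)
usable = session_io.usable_trial_mask(session)
labels = session_io.condition_labels(session, "association_id")[usable]
sub = session_io.BinnedRateTensor(
    counts=tensor.counts[:, usable, :], width_ms=150, step_ms=15,
    align="is_onset", t0_s=-0.5, unit_ids=tensor.unit_ids,
    trial_ids=tensor.trial_ids[usable], valid=tensor.valid[usable],
)

rng = np.random.default_rng(0)
series = selectivity.omega_timecourse(sub, labels, rng=rng)
null = selectivity.omega_null_stack(sub, labels, iterations=500, rng=rng)
pop = series.omega.mean(axis=0)

fix = series.bin_centers_s < 0.0
print(f"population omega^2, fixation  : {pop[fix].mean():+.4f}")
print(f"population omega^2, IS period : {pop[~fix].mean():+.4f}")
latency = selectivity.onset_latency(pop, null, series.bin_centers_s)
print(f"population onset latency      : {1000 * latency:.0f} ms after IS onset")

# Fixation-period omega^2 hovers near zero (the variable is not yet shown);
# it rises through the IS period, and the onset latency marks the first bin
# whose population selectivity beats the shuffle null.
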