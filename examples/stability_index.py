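"""Static-bin classification and the stability index.

Runs the full stability pipeline on a static-coding and a transient-coding
population: cross-temporal decoding with a label-shuffle null, static
classification of off-diagonal bins (null-difference 99.9th percentile,
above-chance and Bonferroni-corrected diagonal gates), and the smoothed
per-bin stability index.
"""

import numpy as np

from pfcpop import session_io, stability, synthetic
from pfcpop.stability import masked_index_values
from pfcpop.synthetic import SyntheticConfig

for profile in ("static", "transient"):
    cfg = SyntheticConfig(
        n_units_bw=80, n_units_nw=0, rate_bw=6.0, n_trials=150, seed=13,
        selectivity_profile=profile, effect_size=3.5, transient_window=(0.0, 0.5),
    )
    session, _ = synthetic.generate_session(cfg)
    tensor = session_io.bin_spikes(session, "is_onset", (0.0, 1.0), 50, 50)
    usable = session_io.usable_trial_mask(session)
    labels = session_io.condition_labels(session, "association_id")[usable]
    series, static, ctm, _ = stability.compute_stability(
        tensor.counts[:, usable, :].astype(float), labels,
        runs=3, shuffles=500, rng=np.random.default_rng(2),
        bin_centers_s=tensor.bin_centers_s,
    )
    vals = masked_index_values(series, fill=0.0)
    late = series.bin_centers_s >= 0.5
    print(f"{profile:9s}: static bins {int(static.static.sum())}/380, "
          f"index early {vals[~late].mean():.2f}, late {vals[late].mean():.2f}, "
          f"masked bins {int(series.masked.sum())}/20")

# The static population is classified static across nearly the whole
# matrix (index near 1 everywhere). The transient population codes only
# the first 500 ms: its late diagonal is not significantly above chance,
# so the late index is undefined (reported as 0 here) and the early index
# reflects generalization only within the transient window.
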