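"""Classify synthetic units into broad/narrow waveform classes.

Generates 400 mean waveforms whose trough-to-peak durations follow a
two-Gaussian mixture (narrow 0.18 ms, broad 0.42 ms), then runs the full
classification pipeline: QC, cubic interpolation to 2.5 µs, trough-to-peak
measurement, Hartigan dip test, 1- vs 2-component Gaussian mixture with
AIC/BIC, and the 10:1 posterior-ratio cutoffs.
"""

import numpy as np

from pfcpop import cell_types, synthetic
from pfcpop.synthetic import SyntheticConfig

cfg = SyntheticConfig(n_units_bw=240, n_units_nw=160, seed=3)
waveforms, truth = synthetic.generate_waveforms(cfg)

table, model, dip = cell_types.classify_units(
    waveforms, n_boot=2000, rng=np.random.default_rng(0)
)

print(f"dip statistic            : {dip.statistic:.4f}")
print(f"dip p (uniform null)     : {dip.p_original:.4f}")
print(f"dip p (Gaussian null)    : {dip.p_calibrated:.4f}")
print(f"AIC 1 vs 2 components    : {model.aic_1:.1f} vs {model.aic_2:.1f}")
print(f"BIC 1 vs 2 components    : {model.bic_1:.1f} vs {model.bic_2:.1f}")
print(f"cutoffs (ms)             : {model.cutoff_low_ms:.3f} / {model.cutoff_high_ms:.3f}")
print(table["label"].value_counts().to_string())

merged = table.merge(truth.units[["unit_id", "cell_class"]], on="unit_id")
classified = merged[merged["label"].isin(["NW", "BW"])]
agree = (classified["label"] == classified["cell_class"]).mean()
print(f"ground-truth agreement   : {100 * agree:.1f}% of classified units")

# A small dip p-value and lower AIC/BIC for two components confirm the
# bimodal duration distribution; units between the cutoffs stay NC
# (unclassified) rather than being forced into a class.
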