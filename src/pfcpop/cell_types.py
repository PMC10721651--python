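"""Waveform-based cell-type classification and baseline firing metrics.

Units are classified into broad-waveform (BW, putative pyramidal cells),
narrow-waveform (NW, putative interneurons) and not-classified (NC) from
the trough-to-peak duration of their mean extracellular waveform:

1. the mean waveform is cleaned by dropping spikes exceeding 3 SD of the
   initial average at any sample;
2. amplitude QC removes axon-like traces (post-peak larger than the main
   trough, or pre-peak more than 20% above it);
3. the 25 µs trace is cubic-interpolated to 2.5 µs, normalized to a -1
   trough and the trough-to-argmax distance measured;
4. bimodality of the pooled trough-to-peak distribution is tested with the
   Hartigan dip test (uniform-reference Monte Carlo, plus a calibrated
   variant using a fitted-Gaussian reference);
5. 1- vs 2-component Gaussian mixtures are compared by AIC/BIC and two
   cutoffs placed where one component's posterior is at least 10 times the
   other's; durations between the cutoffs are left unclassified.

Baseline firing metrics (rate, Fano factor of trial spike counts, CV of
interspike intervals) are computed from the fixation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.mixture import GaussianMixture

from pfcpop._dip import dip_null_distribution, dip_statistic, mc_p_value

INTERP_FACTOR = 10  # 25 us -> 2.5 us


@dataclass
class WaveformRecord:
    """Mean waveform in raw and interpolated sampling, trough-aligned."""

    unit_id: str
    raw: np.ndarray
    raw_dt_us: float
    interpolated: np.ndarray
    interp_dt_us: float
    trough_index: int  # index into the interpolated trace
    qc_pass: bool
    qc_reason: str | None


@dataclass
class MixtureModel:
    """1- vs 2-component Gaussian mixture fit on trough-to-peak durations."""

    means: np.ndarray          # 2-component means, narrow first
    sds: np.ndarray
    weights: np.ndarray
    aic_1: float
    aic_2: float
    bic_1: float
    bic_2: float
    cutoff_low_ms: float
    cutoff_high_ms: float
    ratio: float

    @property
    def prefers_two_components(self) -> bool:
        return self.aic_2 < self.aic_1 and self.bic_2 < self.bic_1

    def posterior_narrow(self, x) -> np.ndarray:
        from scipy.stats import norm

        x = np.atleast_1d(np.asarray(x, dtype=float))
        dens = self.weights[:, None] * norm.pdf(x[None, :], self.means[:, None], self.sds[:, None])
        return dens[0] / dens.sum(axis=0)


@dataclass
class DipResult:
    statistic: float
    p_original: float
    p_calibrated: float


@dataclass
class FiringMetrics:
    rate: float
    fano: float | None
    cv: float | None
    n_trials: int


def clean_waveform(spike_waveforms: np.ndarray, sd_threshold: float = 3.0
                   ) -> tuple[np.ndarray, float]:
    """Recompute a mean waveform keeping spikes within 3 SD of the initial
    average at every sample point.

    ``spike_waveforms`` is (n_spikes, n_samples); same-unit recording blocks
    should be merged into one sample before calling. Returns the cleaned
    mean and the fraction of spikes rejected. Raises if every spike is
    rejected.
    """
    w = np.asarray(spike_waveforms, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need at least 2 spike waveforms (n_spikes, n_samples)")
    mean0 = w.mean(axis=0)
    sd0 = w.std(axis=0, ddof=1)
    sd0 = np.where(sd0 == 0, np.inf, sd0)
    keep = (np.abs(w - mean0) <= sd_threshold * sd0).all(axis=1)
    if not keep.any():
        raise ValueError("all spike waveforms rejected by the 3 SD rule")
    frac_rejected = 1.0 - keep.mean()
    return w[keep].mean(axis=0), float(frac_rejected)


def _extrema(trace: np.ndarray) -> tuple[int, float, float, float]:
    """(trough index, |trough|, |post-trough peak|, |pre-trough peak|)."""
    trough = int(np.argmin(trace))
    trough_amp = abs(trace[trough])
    post = trace[trough + 1:]
    post_amp = float(post.max()) if len(post) else -np.inf
    pre = trace[:trough]
    pre_amp = float(pre.max()) if len(pre) else 0.0
    return trough, trough_amp, post_amp, pre_amp


def qc_exclude(trace: np.ndarray, pre_peak_factor: float = 1.2) -> tuple[bool, str | None]:
    """Amplitude QC: (keep, reason-if-dropped).

    Drops axon-like traces whose main trough is smaller than the following
    peak, or whose preceding peak exceeds the trough by more than 20%.
    """
    trough, trough_amp, post_amp, pre_amp = _extrema(np.asarray(trace, dtype=float))
    if trough == len(trace) - 1 or post_amp <= 0:
        return False, "no peak"
    if trough_amp < post_amp:
        return False, "trough smaller than post-peak"
    if pre_amp > pre_peak_factor * trough_amp:
        return False, "pre-peak exceeds trough by more than 20%"
    return True, None


def interpolate_waveform(raw: np.ndarray, raw_dt_us: float = 25.0,
                         factor: int = INTERP_FACTOR) -> np.ndarray:
    """Cubic interpolation of the mean waveform (25 us -> 2.5 us by default)."""
    raw = np.asarray(raw, dtype=float)
    t = np.arange(len(raw)) * raw_dt_us
    fine_t = np.arange((len(raw) - 1) * factor + 1) * (raw_dt_us / factor)
    return CubicSpline(t, raw)(fine_t)


def make_waveform_record(unit_id: str, raw: np.ndarray, raw_dt_us: float = 25.0
                         ) -> WaveformRecord:
    """Interpolate, normalize to a -1 trough and QC one mean waveform."""
    keep, reason = qc_exclude(raw)
    interp = interpolate_waveform(raw, raw_dt_us)
    trough_amp = abs(interp.min())
    if trough_amp > 0:
        interp = interp / trough_amp  # trough value -1 after normalization
    trough_idx = int(np.argmin(interp))
    return WaveformRecord(
        unit_id=unit_id,
        raw=np.asarray(raw, dtype=float),
        raw_dt_us=raw_dt_us,
        interpolated=interp,
        interp_dt_us=raw_dt_us / INTERP_FACTOR,
        trough_index=trough_idx,
        qc_pass=keep,
        qc_reason=reason,
    )


def measure_trough_to_peak(record: WaveformRecord) -> tuple[float, bool]:
    """Trough-to-peak duration in ms on the interpolated trace.

    Duration = (argmax after the trough - trough index) x interpolation
    step. When the post-trough segment is monotone the global maximum after
    the trough is used; a maximum at the trace end is flagged (second
    return value True).
    """
    if not record.qc_pass:
        raise ValueError(f"unit {record.unit_id} failed QC ({record.qc_reason})")
    trace = record.interpolated
    trough = record.trough_index
    post = trace[trough:]
    peak_rel = int(np.argmax(post))
    at_end = peak_rel == len(post) - 1
    return peak_rel * record.interp_dt_us / 1000.0, at_end


def waveform_table_records(waveforms: pd.DataFrame, raw_dt_us: float = 25.0
                           ) -> list[WaveformRecord]:
    """Build records from a long-format waveforms table (one row per sample)."""
    records = []
    for unit_id, g in waveforms.groupby("unit_id", sort=True):
        raw = g.sort_values("sample_idx")["mean_v"].to_numpy()
        records.append(make_waveform_record(str(unit_id), raw, raw_dt_us))
    return records


def test_bimodality(
    t2p_ms: np.ndarray,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
) -> DipResult:
    """Hartigan dip test of the trough-to-peak distribution.

    ``p_original`` uses the classical uniform-sample Monte-Carlo reference.
    ``p_calibrated`` recalibrates the reference against the best-fitting
    single Gaussian (MLE mean/SD of the data), which is more sensitive when
    the null of interest is a unimodal bell shape rather than a flat
    density. A constant sample returns p = 1 by convention.
    """
    x = np.asarray(t2p_ms, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 values for the dip test")
    if np.ptp(x) == 0:
        return DipResult(statistic=0.5 / len(x), p_original=1.0, p_calibrated=1.0)
    if rng is None:
        rng = np.random.default_rng(0)
    d = dip_statistic(x)
    null_uniform = dip_null_distribution(len(x), n_boot, rng)
    p_orig = mc_p_value(d, null_uniform)
    mu, sd = x.mean(), x.std(ddof=0)
    null_gauss = np.empty(n_boot)
    for b in range(n_boot):
        null_gauss[b] = dip_statistic(rng.normal(mu, sd, len(x)))
    null_gauss.sort()
    p_cal = mc_p_value(d, null_gauss)
    return DipResult(statistic=d, p_original=p_orig, p_calibrated=p_cal)


def fit_mixture_and_cutoffs(
    t2p_ms: np.ndarray,
    ratio: float = 10.0,
    grid_step_ms: float = 0.001,
    random_state: int = 0,
) -> MixtureModel:
    """Fit 1- and 2-component Gaussian mixtures and place the NW/BW cutoffs.

    The narrow component is the smaller-mean component by definition. The
    first cutoff is the largest duration where the narrow posterior is at
    least ``ratio`` times the broad posterior, the second the smallest
    duration where the broad posterior dominates by the same factor; both
    are searched on a 1 µs grid over the data range.
    """
    x = np.asarray(t2p_ms, dtype=float).reshape(-1, 1)
    if len(x) < 4:
        raise ValueError("too few durations for a mixture fit")
    gm1 = GaussianMixture(1, random_state=random_state).fit(x)
    gm2 = GaussianMixture(2, n_init=5, random_state=random_state, tol=1e-6,
                          max_iter=500).fit(x)
    if not gm2.converged_:
        raise RuntimeError("2-component EM did not converge")
    means = gm2.means_.ravel()
    sds = np.sqrt(gm2.covariances_.ravel())
    weights = gm2.weights_.ravel()
    order = np.argsort(means)  # narrow first
    means, sds, weights = means[order], sds[order], weights[order]
    if np.isclose(means[0], means[1]):
        raise RuntimeError("degenerate mixture: equal component means")

    model = MixtureModel(
        means=means, sds=sds, weights=weights,
        aic_1=gm1.aic(x), aic_2=gm2.aic(x),
        bic_1=gm1.bic(x), bic_2=gm2.bic(x),
        cutoff_low_ms=np.nan, cutoff_high_ms=np.nan, ratio=ratio,
    )
    grid = np.arange(x.min(), x.max() + grid_step_ms, grid_step_ms)
    post_nw = model.posterior_narrow(grid)
    post_bw = 1.0 - post_nw
    nw_dominates = post_nw >= ratio * post_bw
    bw_dominates = post_bw >= ratio * post_nw
    if not nw_dominates.any() or not bw_dominates.any():
        raise RuntimeError("posterior ratio criterion not attainable on the data range")
    model.cutoff_low_ms = float(grid[nw_dominates][-1])
    model.cutoff_high_ms = float(grid[bw_dominates][0])
    if not model.cutoff_low_ms < model.cutoff_high_ms:
        raise RuntimeError("cutoffs are not ordered; mixture fit is degenerate")
    return model


def assign_cell_types(t2p_ms: np.ndarray, cutoff_low_ms: float, cutoff_high_ms: float
                      ) -> np.ndarray:
    """NW at or below the low cutoff, BW at or above the high cutoff, NC between."""
    if not cutoff_low_ms < cutoff_high_ms:
        raise ValueError("cutoff_low must be below cutoff_high")
    x = np.asarray(t2p_ms, dtype=float)
    labels = np.full(len(x), "NC", dtype=object)
    labels[x <= cutoff_low_ms] = "NW"
    labels[x >= cutoff_high_ms] = "BW"
    return labels


def classify_units(
    waveforms: pd.DataFrame,
    raw_dt_us: float = 25.0,
    ratio: float = 10.0,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
    curated_mask: dict | None = None,
) -> tuple[pd.DataFrame, MixtureModel, DipResult]:
    """Full classification pipeline on a waveforms table.

    ``curated_mask`` optionally maps unit_id -> bool for the manual-curation
    step (an input flag, not re-implemented). Returns a per-unit table
    (unit_id, t2p_ms, qc_pass, label, posterior_nw), the mixture model and
    the dip test result. Units failing QC or curation get label
    ``excluded``.
    """
    records = waveform_table_records(waveforms, raw_dt_us)
    rows = []
    for rec in records:
        curated = curated_mask.get(rec.unit_id, True) if curated_mask else True
        if not (rec.qc_pass and curated):
            rows.append((rec.unit_id, np.nan, False, "excluded"))
            continue
        t2p, _ = measure_trough_to_peak(rec)
        rows.append((rec.unit_id, t2p, True, None))
    table = pd.DataFrame(rows, columns=["unit_id", "t2p_ms", "qc_pass", "label"])
    ok = table["qc_pass"].to_numpy()
    t2p = table.loc[ok, "t2p_ms"].to_numpy()
    dip = test_bimodality(t2p, n_boot=n_boot, rng=rng)
    model = fit_mixture_and_cutoffs(t2p, ratio=ratio)
    table.loc[ok, "label"] = assign_cell_types(t2p, model.cutoff_low_ms, model.cutoff_high_ms)
    table["posterior_nw"] = np.nan
    table.loc[ok, "posterior_nw"] = model.posterior_narrow(t2p)
    return table, model, dip


def firing_metrics(
    spike_times_by_trial: list[np.ndarray],
    epoch: tuple[float, float] = (0.0, 1.0),
    min_trials: int = 30,
) -> FiringMetrics:
    """Baseline firing metrics over an epoch (default: fixation, 0-1 s).

    rate = total spikes / total epoch time; Fano factor = across-trial
    spike count variance / mean (sample variance, ddof=1); CV = SD/mean of
    interspike intervals pooled within trials (no across-trial intervals).
    Fano is None for silent units; CV is None when fewer than 2 ISIs exist.
    """
    if len(spike_times_by_trial) < min_trials:
        raise ValueError(
            f"{len(spike_times_by_trial)} trials < required minimum {min_trials}"
        )
    t0, t1 = epoch
    counts = []
    isis = []
    for spikes in spike_times_by_trial:
        s = np.asarray(spikes, dtype=float)
        s = s[(s >= t0) & (s < t1)]
        counts.append(len(s))
        if len(s) >= 2:
            isis.append(np.diff(np.sort(s)))
    counts = np.asarray(counts, dtype=float)
    total_time = (t1 - t0) * len(counts)
    rate = counts.sum() / total_time
    mean_count = counts.mean()
    fano = float(counts.var(ddof=1) / mean_count) if mean_count > 0 else None
    if isis:
        pooled = np.concatenate(isis)
        cv = float(pooled.std(ddof=1) / pooled.mean()) if len(pooled) >= 2 else None
    else:
        cv = None
    return FiringMetrics(rate=float(rate), fano=fano, cv=cv, n_trials=len(counts))
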