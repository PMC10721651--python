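"""Synthetic session generator with known ground truth.

Emulates the recorded sessions end to end: a trial timeline with a 1 s
fixation epoch and an instruction-stimulus (IS) period of 1/1.5/2 s drawn
pseudorandomly, three 3-level task variables (stimulus, response target,
stimulus-response association) under three task rules (strategy, novelmap,
fammap), Bernoulli step learners with a change-point, two waveform classes
with bimodal trough-to-peak durations realized as sampled voltage traces,
and unit firing with configurable static / transient / preference-switching
selectivity profiles at cell-type-specific rates.

All randomness flows from a single master seed split into named streams
(waveforms, spikes, behavior, session), so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pfcpop.session_io import IS_DURATIONS, RESPONSE_TARGETS, Session

_STREAMS = {"waveforms": 0, "spikes": 1, "behavior": 2, "session": 3}

RAW_DT_US = 25.0
FINE_DT_US = 2.5
N_RAW_SAMPLES = 64           # 1.6 ms trace
TROUGH_RAW_INDEX = 16        # trough fixed at 0.4 ms

STIMULI = ("s1", "s2", "s3")
ASSOCIATIONS = ("a1", "a2", "a3")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named child RNG split deterministically from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class LearnerConfig:
    """Bernoulli step learner: P(correct) jumps from p_pre to p_post at change_trial (1-based)."""

    p_pre: float = 1.0 / 3.0
    p_post: float = 0.95
    change_trial: int = 16

    def validate(self, n_trials: int) -> None:
        for name, p in (("p_pre", self.p_pre), ("p_post", self.p_post)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 1 <= self.change_trial <= n_trials:
            raise ValueError("change_trial must be within 1..n_trials")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic session.

    Rates are mean baseline firing rates in spikes/s (the broad/narrow
    defaults mirror typical pyramidal vs interneuron baselines); trough-to-
    peak means/SDs are in ms and must keep the narrow mean below the broad
    mean. ``effect_size`` multiplies the preferred condition's IS-period
    rate; 1 means no modulation.
    """

    n_units_bw: int = 40
    n_units_nw: int = 15
    rate_bw: float = 2.1
    rate_nw: float = 5.1
    t2p_bw_mean: float = 0.42
    t2p_bw_sd: float = 0.07
    t2p_nw_mean: float = 0.18
    t2p_nw_sd: float = 0.04
    selectivity_profile: str = "static"
    effect_size: float = 2.0
    n_trials: int = 100
    task: str = "novelmap"
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    seed: int = 0
    # profile geometry, relative to IS onset (s)
    transient_window: tuple[float, float] = (0.0, 0.5)
    switch_time: float = 0.5
    # renewal process: 1.0 = Poisson; >1 more regular, <1 more irregular
    gamma_shape: float = 1.0
    rate_dispersion: float = 4.0  # gamma shape of the across-unit rate distribution
    contamination_fraction: float = 0.0
    selective_variable: str | None = None

    def validate(self) -> None:
        if self.n_units_bw < 0 or self.n_units_nw < 0:
            raise ValueError("unit counts must be non-negative")
        if self.rate_bw <= 0 or self.rate_nw <= 0:
            raise ValueError("baseline rates must be positive")
        if self.t2p_nw_mean >= self.t2p_bw_mean:
            raise ValueError(
                "narrow t2p mean must be below broad t2p mean "
                f"(got NW {self.t2p_nw_mean} >= BW {self.t2p_bw_mean})"
            )
        if min(self.t2p_bw_mean, self.t2p_nw_mean) <= 0:
            raise ValueError("t2p means must be positive")
        if self.selectivity_profile not in ("none", "static", "transient", "switching"):
            raise ValueError(f"unknown selectivity profile {self.selectivity_profile!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0 (multiplicative)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.task not in ("strategy", "novelmap", "fammap"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        self.learner.validate(self.n_trials)

    @property
    def n_units(self) -> int:
        return self.n_units_bw + self.n_units_nw

    def variable(self) -> str:
        if self.selective_variable is not None:
            return self.selective_variable
        return "stimulus_id" if self.task == "strategy" else "association_id"


@dataclass
class GroundTruth:
    """Per-unit generative truth plus the session's behavioral change point."""

    units: pd.DataFrame  # unit_id, cell_class, t2p_ms, profile, preferred, preferred_post, rate_base
    change_trial: int
    variable: str


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def _waveform_trace(t2p_ms: float, fine_t_ms: np.ndarray, trough_ms: float,
                    peak_amp: float = 0.45, pre_amp: float = 0.12) -> np.ndarray:
    """Difference-of-Gaussians bump train with extrema ``t2p_ms`` apart.

    The post-trough peak centre is adjusted by fixed-point iteration so the
    measured trough-to-argmax distance matches the drawn duration despite
    tail overlap between the bumps; bump widths shrink with the duration so
    both extrema survive the overlap for narrow spikes.
    """
    trough_w = min(0.08, max(0.03, 0.35 * t2p_ms))
    peak_w = min(0.15, max(0.04, 0.45 * t2p_ms))
    pre_w = 0.10
    c = trough_ms + t2p_ms
    trough_part = -np.exp(-0.5 * ((fine_t_ms - trough_ms) / trough_w) ** 2)
    pre_part = pre_amp * np.exp(-0.5 * ((fine_t_ms - (trough_ms - 0.25)) / pre_w) ** 2)

    def build(center):
        return trough_part + pre_part + peak_amp * np.exp(
            -0.5 * ((fine_t_ms - center) / peak_w) ** 2
        )

    for _ in range(12):
        v = build(c)
        trough_idx = int(np.argmin(v))
        peak_idx = trough_idx + int(np.argmax(v[trough_idx:]))
        err = t2p_ms - (fine_t_ms[peak_idx] - fine_t_ms[trough_idx])
        if abs(err) < FINE_DT_US / 1000.0 / 4:
            break
        c += err
    return build(c)


def _draw_t2p(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Truncated-normal draws kept within the physically sensible range."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < 0.07) | (out > 1.1)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < 0.07) | (out > 1.1)
    return out


def generate_waveforms(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Sampled mean-voltage traces (25 µs resolution) for every unit.

    Returns a long-format waveform table (unit_id, sample_idx, mean_v, sd_v)
    and the ground truth with each unit's class and drawn trough-to-peak
    duration. With ``contamination_fraction`` zero every trace passes the
    amplitude QC rules by construction; contaminated units get an axon-like
    post-peak larger than the trough.
    """
    config.validate()
    rng = stream_rng(config.seed, "waveforms")
    classes = ["BW"] * config.n_units_bw + ["NW"] * config.n_units_nw
    t2p = np.concatenate(
        [
            _draw_t2p(rng, config.t2p_bw_mean, config.t2p_bw_sd, config.n_units_bw),
            _draw_t2p(rng, config.t2p_nw_mean, config.t2p_nw_sd, config.n_units_nw),
        ]
    )
    fine_t_ms = np.arange(0, N_RAW_SAMPLES * RAW_DT_US, FINE_DT_US) / 1000.0
    trough_ms = TROUGH_RAW_INDEX * RAW_DT_US / 1000.0
    raw_idx = np.arange(N_RAW_SAMPLES) * int(RAW_DT_US / FINE_DT_US)

    n = len(classes)
    contaminated = rng.random(n) < config.contamination_fraction
    rows = []
    truth_rows = []
    for i in range(n):
        unit_id = f"u{i:04d}"
        peak_amp = 1.25 if contaminated[i] else 0.45
        trace = _waveform_trace(t2p[i], fine_t_ms, trough_ms, peak_amp=peak_amp)
        amp = rng.lognormal(mean=0.0, sigma=0.25)
        raw = trace[raw_idx] * amp
        sd_v = np.full(N_RAW_SAMPLES, 0.03 * amp)
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": unit_id,
                    "sample_idx": np.arange(N_RAW_SAMPLES),
                    "mean_v": raw,
                    "sd_v": sd_v,
                }
            )
        )
        truth_rows.append((unit_id, classes[i], t2p[i], bool(contaminated[i])))
    waveforms = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["unit_id", "sample_idx", "mean_v", "sd_v"])
    )
    truth = pd.DataFrame(
        truth_rows, columns=["unit_id", "cell_class", "t2p_ms", "contaminated"]
    )
    gt = GroundTruth(units=truth, change_trial=config.learner.change_trial, variable=config.variable())
    return waveforms, gt


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def generate_behavior_sequence(
    learner: LearnerConfig, n_trials: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Binary correctness sequence: Bernoulli(p_pre) before the change trial,
    Bernoulli(p_post) from the change trial (1-based) onward."""
    if isinstance(rng, (int, np.integer)):
        rng = stream_rng(int(rng), "behavior")
    learner.validate(n_trials)
    trial = np.arange(1, n_trials + 1)
    p = np.where(trial < learner.change_trial, learner.p_pre, learner.p_post)
    return (rng.random(n_trials) < p).astype(int)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _renewal_times(rng: np.random.Generator, segments, gamma_shape: float) -> np.ndarray:
    """Event times of a (gamma-)renewal process with piecewise-constant rate.

    Uses time rescaling: unit-mean gamma interarrivals are accumulated in
    rescaled time and mapped back through the inverse cumulative intensity.
    ``gamma_shape=1`` is homogeneous Poisson within each segment.
    """
    t_edges = [segments[0][0]]
    lam_edges = [0.0]
    for (a, b, rate) in segments:
        if rate < 0:
            raise ValueError("negative firing rate in segment")
        t_edges.append(b)
        lam_edges.append(lam_edges[-1] + rate * (b - a))
    total = lam_edges[-1]
    if total <= 0:
        return np.empty(0)
    n_draw = int(total + 4.0 * np.sqrt(total) + 10)
    if gamma_shape == 1.0:
        inter = rng.exponential(1.0, size=n_draw)
    else:
        inter = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_draw)
    s = np.cumsum(inter)
    while s[-1] < total:  # pragma: no cover - rare top-up
        extra = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_draw)
        s = np.concatenate([s, s[-1] + np.cumsum(extra)])
    s = s[s < total]
    return np.interp(s, lam_edges, t_edges)


def _rate_segments(
    base: float,
    effect: float,
    profile: str,
    preferred: bool,
    preferred_post: bool,
    is_onset: float,
    is_dur: float,
    t_end: float,
    transient_window: tuple[float, float],
    switch_time: float,
):
    """Piecewise-constant rate over one trial, on the fixation-onset clock."""
    mod = base * effect
    segs = [(0.0, is_onset, base)]
    is_end = is_onset + is_dur
    if profile == "none":
        segs.append((is_onset, is_end, base))
    elif profile == "static":
        segs.append((is_onset, is_end, mod if preferred else base))
    elif profile == "transient":
        w0 = min(is_onset + transient_window[0], is_end)
        w1 = min(is_onset + transient_window[1], is_end)
        segs.append((is_onset, w0, base))
        segs.append((w0, w1, mod if preferred else base))
        segs.append((w1, is_end, base))
    elif profile == "switching":
        sw = min(is_onset + switch_time, is_end)
        segs.append((is_onset, sw, mod if preferred else base))
        segs.append((sw, is_end, mod if preferred_post else base))
    else:  # pragma: no cover
        raise ValueError(profile)
    segs.append((is_end, t_end, base))
    return [(a, b, r) for (a, b, r) in segs if b > a]


def generate_spike_trains(
    config: SyntheticConfig,
    trial_table: pd.DataFrame,
    unit_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spike table (unit_id, trial_id, t_s) for all units over all trials.

    Each unit fires as a renewal process whose IS-period rate is
    ``baseline * effect_size`` on trials of its preferred condition, with the
    modulation window set by the selectivity profile (whole IS period for
    ``static``, a sub-window for ``transient``, and a preference swap at
    ``switch_time`` for ``switching``).
    """
    if rng is None:
        rng = stream_rng(config.seed, "spikes")
    variable = config.variable()
    labels = trial_table[variable].to_numpy()
    is_onsets = (trial_table["is_onset_s"] - trial_table["fixation_onset_s"]).to_numpy()
    is_durs = trial_table["is_duration_s"].to_numpy()
    t_ends = (trial_table["go_s"] - trial_table["fixation_onset_s"]).to_numpy() + 0.5

    rows_unit, rows_trial, rows_t = [], [], []
    for _, u in unit_truth.iterrows():
        for k, trial_id in enumerate(trial_table["trial_id"].to_numpy()):
            segs = _rate_segments(
                base=u["rate_base"],
                effect=config.effect_size,
                profile=u["profile"],
                preferred=labels[k] == u["preferred"],
                preferred_post=labels[k] == u["preferred_post"],
                is_onset=is_onsets[k],
                is_dur=is_durs[k],
                t_end=t_ends[k],
                transient_window=config.transient_window,
                switch_time=config.switch_time,
            )
            times = _renewal_times(rng, segs, config.gamma_shape)
            rows_unit.extend([u["unit_id"]] * len(times))
            rows_trial.extend([trial_id] * len(times))
            rows_t.append(times)
    t_s = np.concatenate(rows_t) if rows_t else np.empty(0)
    return pd.DataFrame({"unit_id": rows_unit, "trial_id": rows_trial, "t_s": t_s})


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def _strategy_conditions(rng: np.random.Generator, n_trials: int):
    """Stimulus/response sequences under the repeat-stay / change-shift rule.

    A repeat trial re-presents the previous IS and requires the same target;
    a change trial presents a different IS and requires a shift to one of the
    two other targets, so no fixed stimulus-to-response mapping can form.
    """
    stimuli, responses = [], []
    prev_s = rng.choice(STIMULI)
    prev_r = rng.choice(RESPONSE_TARGETS)
    for k in range(n_trials):
        if k > 0 and rng.random() < 0.5:  # repeat trial
            s, r = prev_s, prev_r
        else:  # change trial (first trial counts as change)
            s = rng.choice([x for x in STIMULI if x != prev_s]) if k > 0 else prev_s
            r = rng.choice([x for x in RESPONSE_TARGETS if x != prev_r]) if k > 0 else prev_r
        stimuli.append(s)
        responses.append(r)
        prev_s, prev_r = s, r
    return stimuli, responses


def generate_trial_table(config: SyntheticConfig, rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Trial table with the task timeline and 3-level condition labels.

    The timeline per trial is 1.0 s fixation, an IS period drawn uniformly
    from {1, 1.5, 2} s ending with the go signal, and a 2.5 s intertrial
    interval. Mapping tasks use a fixed stimulus-to-target assignment;
    strategy sessions follow the repeat/change rule. After an error the next
    trial re-presents the same conditions and is flagged as a correction
    trial; correctness follows the session's Bernoulli step learner.
    """
    config.validate()
    if rng is None:
        rng = stream_rng(config.seed, "session")
    brng = stream_rng(config.seed, "behavior")
    n = config.n_trials

    if config.task == "strategy":
        stimuli, responses = _strategy_conditions(rng, n)
        associations = list(stimuli)
    else:
        mapping = dict(zip(STIMULI, RESPONSE_TARGETS))
        stimuli = [rng.choice(STIMULI) for _ in range(n)]
        responses = [mapping[s] for s in stimuli]
        associations = [ASSOCIATIONS[STIMULI.index(s)] for s in stimuli]

    correct_draws = generate_behavior_sequence(config.learner, n, brng)

    rows = []
    t = 0.0
    prev_error = False
    for k in range(n):
        if prev_error and config.task != "strategy":
            # correction trial: same conditions as the failed trial
            stimuli[k], responses[k], associations[k] = (
                stimuli[k - 1], responses[k - 1], associations[k - 1],
            )
            correction = True
        else:
            correction = False
        is_dur = float(rng.choice(IS_DURATIONS))
        fixation_onset = t
        is_onset = fixation_onset + 1.0
        go = is_onset + is_dur
        correct = bool(correct_draws[k])
        rows.append(
            {
                "trial_id": k + 1,
                "stimulus_id": stimuli[k],
                "response_target": responses[k],
                "association_id": associations[k],
                "correct": correct,
                "correction": correction,
                "fixation_onset_s": fixation_onset,
                "is_onset_s": is_onset,
                "is_duration_s": is_dur,
                "go_s": go,
            }
        )
        prev_error = not correct
        t = go + 1.5 + 2.5  # saccade/reward epoch + intertrial
    return pd.DataFrame(rows)


def _unit_truth(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = ["BW"] * config.n_units_bw + ["NW"] * config.n_units_nw
    variable = config.variable()
    conditions = list(STIMULI if variable == "stimulus_id"
                      else RESPONSE_TARGETS if variable == "response_target"
                      else ASSOCIATIONS)
    rows = []
    for i, cls in enumerate(classes):
        mean = config.rate_bw if cls == "BW" else config.rate_nw
        shape = config.rate_dispersion
        rate = float(rng.gamma(shape, mean / shape))
        rate = max(rate, 0.2)
        preferred = conditions[i % 3]
        preferred_post = conditions[(i + 1) % 3]
        rows.append(
            {
                "unit_id": f"u{i:04d}",
                "cell_class": cls,
                "profile": config.selectivity_profile,
                "preferred": preferred,
                "preferred_post": preferred_post,
                "rate_base": rate,
            }
        )
    return pd.DataFrame(rows)


def generate_session(config: SyntheticConfig) -> tuple[Session, GroundTruth]:
    """Full synthetic session: trials, spikes, waveforms, units + ground truth."""
    config.validate()
    rng = stream_rng(config.seed, "session")
    trials = generate_trial_table(config, rng)
    waveforms, gt = generate_waveforms(config)
    truth_units = _unit_truth(config, rng)
    truth = truth_units.merge(gt.units[["unit_id", "t2p_ms", "contaminated"]], on="unit_id")
    spikes = generate_spike_trains(config, trials, truth)
    units = pd.DataFrame({"unit_id": truth["unit_id"], "tasks": config.task})
    session = Session(
        session_id=f"synthetic-{config.task}-{config.seed}",
        task=config.task,
        trials=trials,
        spikes=spikes,
        waveforms=waveforms,
        units=units,
        sampling_interval_us=RAW_DT_US,
        metadata={"generator": "pfcpop.synthetic", "seed": config.seed},
    )
    ground_truth = GroundTruth(
        units=truth, change_trial=config.learner.change_trial, variable=config.variable()
    )
    return session, ground_truth


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)


def config_from_file(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML (or JSON) mapping.

    The ``learner`` key may be a nested mapping with p_pre/p_post/
    change_trial; list-valued windows are coerced to tuples.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if "learner" in data and isinstance(data["learner"], dict):
        data["learner"] = LearnerConfig(**data["learner"])
    if "transient_window" in data:
        data["transient_window"] = tuple(data["transient_window"])
    cfg = SyntheticConfig(**data)
    cfg.validate()
    return cfg
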