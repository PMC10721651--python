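"""Session data model, on-disk format, spike binning and trial-count filters.

A *session* is one recording day of one task. On disk a session is a
directory of plain-text tables::

    trials.csv     trial_id, stimulus_id, response_target, association_id,
                   correct, correction, fixation_onset_s, is_onset_s,
                   is_duration_s, go_s
    spikes.csv     unit_id, trial_id, t_s          (t_s relative to fixation onset)
    waveforms.csv  unit_id, sample_idx, mean_v, sd_v
    units.csv      unit_id, tasks
    session.json   task, sampling_interval_us, metadata

Spike times are stored on a single canonical clock per trial (seconds from
that trial's fixation onset); alignment to other events is computed on the
fly by :func:`bin_spikes`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TASKS = ("strategy", "novelmap", "fammap")
RESPONSE_TARGETS = ("top", "right", "left")
IS_DURATIONS = (1.0, 1.5, 2.0)

TRIAL_COLUMNS = (
    "trial_id",
    "stimulus_id",
    "response_target",
    "association_id",
    "correct",
    "correction",
    "fixation_onset_s",
    "is_onset_s",
    "is_duration_s",
    "go_s",
)
SPIKE_COLUMNS = ("unit_id", "trial_id", "t_s")
WAVEFORM_COLUMNS = ("unit_id", "sample_idx", "mean_v", "sd_v")
UNIT_COLUMNS = ("unit_id", "tasks")


class SchemaError(ValueError):
    """A session table violates the on-disk schema."""


@dataclass
class Session:
    """One recording day: trial table, spike table, waveforms and unit metadata."""

    session_id: str
    task: str
    trials: pd.DataFrame
    spikes: pd.DataFrame
    waveforms: pd.DataFrame
    units: pd.DataFrame
    sampling_interval_us: float = 25.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_session(self)

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    def spikes_for_unit(self, unit_id) -> pd.DataFrame:
        return self.spikes[self.spikes["unit_id"] == unit_id]


@dataclass
class BinnedRateTensor:
    """Units x trials x bins firing rates with bin geometry.

    ``counts`` holds spike counts per half-open bin
    ``[t0 + b*step, t0 + b*step + width)`` relative to ``align``;
    ``rates`` = counts / width. ``valid`` marks, per (trial, bin), bins fully
    contained in the trial's recorded span — bins reaching past e.g. the end
    of a 1 s instruction stimulus are flagged invalid rather than zero
    filled. Bin timestamps are bin centers.
    """

    counts: np.ndarray
    width_ms: float
    step_ms: float
    align: str
    t0_s: float
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    valid: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        return self.counts / (self.width_ms / 1000.0)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_centers_s(self) -> np.ndarray:
        starts = self.t0_s + np.arange(self.n_bins) * self.step_ms / 1000.0
        return starts + self.width_ms / 2000.0

    def select_units(self, unit_ids) -> "BinnedRateTensor":
        idx = [int(np.flatnonzero(self.unit_ids == u)[0]) for u in unit_ids]
        return BinnedRateTensor(
            counts=self.counts[idx],
            width_ms=self.width_ms,
            step_ms=self.step_ms,
            align=self.align,
            t0_s=self.t0_s,
            unit_ids=np.asarray(unit_ids),
            trial_ids=self.trial_ids,
            valid=self.valid,
        )


def n_bins_in_window(window_s: tuple[float, float], width_ms: float, step_ms: float) -> int:
    """Number of fully contained bins tiling ``[t0, t1)``."""
    span_ms = (window_s[1] - window_s[0]) * 1000.0
    if span_ms < width_ms:
        return 0
    return int(np.floor((span_ms - width_ms) / step_ms + 1e-9)) + 1


def _require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing column(s): {', '.join(missing)}")


def validate_session(session: Session) -> None:
    if session.task not in TASKS:
        raise SchemaError(f"session.json: unknown task {session.task!r}; expected one of {TASKS}")
    _require_columns(session.trials, TRIAL_COLUMNS, "trials.csv")
    _require_columns(session.spikes, SPIKE_COLUMNS, "spikes.csv")
    _require_columns(session.waveforms, WAVEFORM_COLUMNS, "waveforms.csv")
    _require_columns(session.units, UNIT_COLUMNS, "units.csv")

    trials = session.trials
    tid = trials["trial_id"].to_numpy()
    if len(np.unique(tid)) != len(tid):
        raise SchemaError("trials.csv: trial_id values are not unique")
    if not np.all(np.diff(tid) > 0):
        raise SchemaError("trials.csv: trial_id values are not increasing")
    bad_dur = ~np.isin(trials["is_duration_s"].to_numpy(), IS_DURATIONS)
    if bad_dur.any():
        raise SchemaError(
            "trials.csv: is_duration_s must be one of {1, 1.5, 2}; "
            f"offending trial_id {trials['trial_id'].to_numpy()[bad_dur][0]}"
        )
    mono = (trials["is_onset_s"] > trials["fixation_onset_s"]) & (trials["go_s"] > trials["is_onset_s"])
    if not mono.all():
        raise SchemaError(
            "trials.csv: event times must be monotone within a trial "
            "(fixation_onset_s < is_onset_s < go_s); offending trial_id "
            f"{trials['trial_id'].to_numpy()[~mono.to_numpy()][0]}"
        )

    if len(session.spikes):
        if (session.spikes["t_s"].to_numpy() < 0).any():
            raise SchemaError("spikes.csv: t_s must be >= 0 (relative to fixation onset)")
        known_trials = set(tid.tolist())
        dangling = ~session.spikes["trial_id"].isin(known_trials)
        if dangling.any():
            raise SchemaError(
                "spikes.csv: trial_id references unknown trial "
                f"{session.spikes['trial_id'].to_numpy()[dangling.to_numpy()][0]}"
            )
        known_units = set(session.units["unit_id"].tolist())
        dangling_u = ~session.spikes["unit_id"].isin(known_units)
        if dangling_u.any():
            raise SchemaError(
                "spikes.csv: unit_id references unknown unit "
                f"{session.spikes['unit_id'].to_numpy()[dangling_u.to_numpy()][0]}"
            )


def write_session(session: Session, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(path / "trials.csv", index=False)
    session.spikes.to_csv(path / "spikes.csv", index=False)
    session.waveforms.to_csv(path / "waveforms.csv", index=False)
    session.units.to_csv(path / "units.csv", index=False)
    with open(path / "session.json", "w") as fh:
        json.dump(
            {
                "session_id": session.session_id,
                "task": session.task,
                "sampling_interval_us": session.sampling_interval_us,
                "metadata": session.metadata,
            },
            fh,
            indent=2,
        )


def read_session(path) -> Session:
    path = Path(path)
    for fname in ("trials.csv", "spikes.csv", "waveforms.csv", "units.csv", "session.json"):
        if not (path / fname).exists():
            raise SchemaError(f"session directory {path} is missing {fname}")
    with open(path / "session.json") as fh:
        meta = json.load(fh)
    return Session(
        session_id=meta.get("session_id", path.name),
        task=meta["task"],
        trials=pd.read_csv(path / "trials.csv"),
        spikes=pd.read_csv(path / "spikes.csv"),
        waveforms=pd.read_csv(path / "waveforms.csv"),
        units=pd.read_csv(path / "units.csv"),
        sampling_interval_us=meta.get("sampling_interval_us", 25.0),
        metadata=meta.get("metadata", {}),
    )


def _align_times(session: Session, align: str) -> np.ndarray:
    """Per-trial alignment-event time on the canonical (fixation-onset) clock."""
    trials = session.trials
    if align == "fixation_onset":
        return np.zeros(len(trials))
    if align == "is_onset":
        return (trials["is_onset_s"] - trials["fixation_onset_s"]).to_numpy()
    if align == "go":
        return (trials["go_s"] - trials["fixation_onset_s"]).to_numpy()
    raise ValueError(f"unknown alignment event {align!r}")


def bin_spikes(
    session: Session,
    align: str = "is_onset",
    window_s: tuple[float, float] = (0.0, 1.0),
    width_ms: float = 50.0,
    step_ms: float = 50.0,
    unit_ids=None,
) -> BinnedRateTensor:
    """Bin spikes into half-open bins relative to an alignment event.

    Bin ``b`` covers ``[t0 + b*step, t0 + b*step + width)``; a spike exactly
    on a bin's right edge is counted in the next bin. Bins that extend past
    the trial's recorded span (fixation onset to go signal) are marked
    invalid in the ``valid`` mask instead of being zero-filled.
    """
    if width_ms <= 0 or step_ms <= 0:
        raise ValueError("width_ms and step_ms must be positive")
    t0, t1 = window_s
    n_bins = n_bins_in_window(window_s, width_ms, step_ms)
    if n_bins == 0:
        raise ValueError("window shorter than one bin")
    if unit_ids is None:
        unit_ids = session.unit_ids
    unit_ids = np.asarray(unit_ids)
    trial_ids = session.trials["trial_id"].to_numpy()
    n_units, n_trials = len(unit_ids), len(trial_ids)

    offsets = _align_times(session, align)  # per trial, on the fixation clock
    starts_rel = t0 + np.arange(n_bins) * step_ms / 1000.0
    width_s = width_ms / 1000.0

    # recorded span per trial, relative to the alignment event
    span_lo = -offsets
    span_hi = (session.trials["go_s"] - session.trials["fixation_onset_s"]).to_numpy() - offsets
    valid = (starts_rel[None, :] >= span_lo[:, None] - 1e-9) & (
        starts_rel[None, :] + width_s <= span_hi[:, None] + 1e-9
    )

    counts = np.zeros((n_units, n_trials, n_bins), dtype=np.int32)
    unit_index = {u: i for i, u in enumerate(unit_ids)}
    trial_index = {t: i for i, t in enumerate(trial_ids)}
    sp = session.spikes
    if len(sp):
        keep = sp["unit_id"].isin(unit_index.keys()).to_numpy()
        u = sp["unit_id"].map(unit_index).to_numpy(dtype=float)[keep].astype(int)
        tr = sp["trial_id"].map(trial_index).to_numpy()[keep].astype(int)
        t = sp["t_s"].to_numpy()[keep] - offsets[tr]
        step_s = step_ms / 1000.0
        # when step < width a spike falls into several overlapping bins:
        # iterate over the bounded number of bin offsets, vectorized on spikes
        b_hi = np.floor((t - t0) / step_s + 1e-9).astype(int)
        n_overlap = int(np.ceil(width_ms / step_ms))
        for off in range(n_overlap):
            b = b_hi - off
            start = t0 + b * step_s
            ok = (b >= 0) & (b < n_bins) & (t >= start) & (t < start + width_s)
            np.add.at(counts, (u[ok], tr[ok], b[ok]), 1)
    return BinnedRateTensor(
        counts=counts,
        width_ms=width_ms,
        step_ms=step_ms,
        align=align,
        t0_s=t0,
        unit_ids=unit_ids,
        trial_ids=trial_ids,
        valid=valid,
    )


def condition_labels(session: Session, variable: str) -> np.ndarray:
    """Per-trial condition labels for one 3-level task variable."""
    if variable not in ("stimulus_id", "response_target", "association_id"):
        raise ValueError(f"unknown task variable {variable!r}")
    return session.trials[variable].to_numpy()


def usable_trial_mask(session: Session) -> np.ndarray:
    """Correct, non-correction trials — the trials entering condition-based analyses."""
    return (
        session.trials["correct"].to_numpy().astype(bool)
        & ~session.trials["correction"].to_numpy().astype(bool)
    )


def filter_units_by_trials(
    session: Session,
    variable: str,
    min_per_condition: int = 10,
    trial_mask: np.ndarray | None = None,
) -> list:
    """Units with at least ``min_per_condition`` usable trials in every condition.

    The default of 10 reflects the exclusion rule for the full-session
    analyses; learning/post-learning blocks use 6. ``min_per_condition=0``
    is the identity filter.
    """
    labels = condition_labels(session, variable)
    usable = usable_trial_mask(session)
    if trial_mask is not None:
        usable = usable & np.asarray(trial_mask, dtype=bool)
    conditions = np.unique(labels)
    kept = []
    for u in session.unit_ids:
        avail = unit_trial_mask(session, u)
        ok = all(
            int(np.sum(usable & avail & (labels == c))) >= min_per_condition
            for c in conditions
        )
        if ok:
            kept.append(u)
    return kept


def unit_trial_mask(session: Session, unit_id) -> np.ndarray:
    """Trials during which a unit was recorded.

    Units are assumed present for the whole session unless units.csv carries
    optional ``first_trial``/``last_trial`` columns bounding the stretch over
    which the unit was held.
    """
    trials = session.trials["trial_id"].to_numpy()
    row = session.units[session.units["unit_id"] == unit_id]
    if len(row) == 0:
        raise KeyError(f"unknown unit {unit_id!r}")
    mask = np.ones(len(trials), dtype=bool)
    if "first_trial" in session.units.columns:
        first = row["first_trial"].iloc[0]
        if pd.notna(first):
            mask &= trials >= int(first)
    if "last_trial" in session.units.columns:
        last = row["last_trial"].iloc[0]
        if pd.notna(last):
            mask &= trials <= int(last)
    return mask
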