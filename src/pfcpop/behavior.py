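"""Learning-point estimation from binary correctness sequences.

The learning-completion trial is found with a binomial moving-average rule:
a centered window of 2w+1 trials slides over the correctness sequence, and
the earliest window whose proportion correct is significantly above the
chance probability (binomial tail test) marks the learning trial k. With
the defaults (w=2, p_null=0.45, alpha=0.05) significance requires all 5
trials in the window to be correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

NOT_LEARNED = -1
UNATTAINABLE = -1


@dataclass
class PerformanceWindowSeries:
    """Moving-average performance p_k and the estimated learning trial.

    ``p_k[i]`` is the proportion correct in the window centered on trial
    ``k_values[i]`` (1-based); only fully contained windows are defined.
    ``k`` is the learning-completion trial or ``NOT_LEARNED``.
    """

    p_k: np.ndarray
    k_values: np.ndarray
    w: int
    p_null: float
    alpha: float
    k: int


def moving_average_performance(n: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """p_k = mean of the correctness indicators over trials [k-w, k+w].

    Returns (p_k, k_values) where k_values are the 1-based center trials of
    the fully contained windows (k from w+1 to len(n)-w).
    """
    n = np.asarray(n, dtype=float)
    win = 2 * w + 1
    if len(n) < win:
        raise ValueError(f"sequence of length {len(n)} shorter than window {win}")
    kernel = np.ones(win) / win
    p_k = np.convolve(n, kernel, mode="valid")
    k_values = np.arange(w + 1, len(n) - w + 1)
    return p_k, k_values


def min_successes(window_len: int, p_null: float, alpha: float) -> int:
    """Smallest success count m with P(Binomial(window_len, p_null) >= m) < alpha.

    Returns ``UNATTAINABLE`` when even an all-correct window is not
    significant (alpha below p_null**window_len).
    """
    if not 0.0 < p_null < 1.0:
        raise ValueError("p_null must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for m in range(window_len + 1):
        # P(X >= m) = sf(m - 1)
        if stats.binom.sf(m - 1, window_len, p_null) < alpha:
            return m
    return UNATTAINABLE


def estimate_learning_trial(
    n: np.ndarray,
    w: int = 2,
    p_null: float = 0.45,
    alpha: float = 0.05,
    min_trials: int | None = None,
) -> PerformanceWindowSeries:
    """Learning trial k = center of the earliest window meeting the binomial criterion.

    ``min_trials`` optionally enforces a minimum recorded-session length
    (the session-selection guard of 42 trials when replicating the original
    selection); pass None to disable.
    """
    n = np.asarray(n)
    if min_trials is not None and len(n) < min_trials:
        raise ValueError(f"sequence has {len(n)} trials; at least {min_trials} required")
    p_k, k_values = moving_average_performance(n, w)
    win = 2 * w + 1
    m = min_successes(win, p_null, alpha)
    if m == UNATTAINABLE:
        k = NOT_LEARNED
    else:
        successes = np.rint(p_k * win).astype(int)
        hits = np.flatnonzero(successes >= m)
        k = int(k_values[hits[0]]) if len(hits) else NOT_LEARNED
    return PerformanceWindowSeries(p_k=p_k, k_values=k_values, w=w, p_null=p_null, alpha=alpha, k=k)


def split_blocks(trial_ids: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition trials into the learning block (through trial k, inclusive)
    and the post-learning block (everything after)."""
    if k == NOT_LEARNED:
        raise ValueError("cannot split blocks: learning trial undefined (not learned)")
    trial_ids = np.asarray(trial_ids)
    learning = trial_ids[trial_ids <= k]
    post = trial_ids[trial_ids > k]
    return learning, post


def session_learning_trial(
    session,
    w: int = 2,
    p_null: float = 0.45,
    alpha: float = 0.05,
    per_association: bool = False,
    include_corrections: bool = False,
    min_trials: int | None = None,
):
    """Learning point of a session.

    Default mode estimates a single session-level k on the concatenated
    correctness sequence in session order; ``per_association=True`` instead
    returns {association: k} computed on each association's own subsequence
    (k expressed as the session trial id closing that association's window).
    Correction trials are excluded from the sequence unless requested.
    """
    trials = session.trials
    mask = np.ones(len(trials), dtype=bool)
    if not include_corrections:
        mask &= ~trials["correction"].to_numpy().astype(bool)
    sub = trials[mask]
    if not per_association:
        res = estimate_learning_trial(
            sub["correct"].to_numpy().astype(int), w, p_null, alpha, min_trials
        )
        if res.k != NOT_LEARNED:
            # map position in the filtered sequence back to a session trial id
            res.k = int(sub["trial_id"].to_numpy()[res.k - 1])
        return res
    out = {}
    for assoc in np.unique(sub["association_id"]):
        seq = sub[sub["association_id"] == assoc]
        try:
            res = estimate_learning_trial(
                seq["correct"].to_numpy().astype(int), w, p_null, alpha, min_trials
            )
        except ValueError:
            out[assoc] = NOT_LEARNED
            continue
        out[assoc] = (
            int(seq["trial_id"].to_numpy()[res.k - 1]) if res.k != NOT_LEARNED else NOT_LEARNED
        )
    return out


def performance_curve(
    correctness_by_session: list[np.ndarray],
    first_trials: int = 50,
    start_trial: int = 2,
    ci: float = 0.95,
) -> dict:
    """Across-session mean percentage correct per trial index with Wilson CIs.

    Mirrors the initial-trials learning curve (trial indices
    ``start_trial..first_trials``). Requires at least two sessions so the
    across-session proportion is defined.
    """
    if len(correctness_by_session) < 2:
        raise ValueError("performance_curve requires at least 2 sessions")
    idx = np.arange(start_trial, first_trials + 1)
    mean, lo, hi = [], [], []
    z = stats.norm.ppf(0.5 + ci / 2.0)
    for i in idx:
        vals = [s[i - 1] for s in correctness_by_session if len(s) >= i]
        if len(vals) < 2:
            mean.append(np.nan), lo.append(np.nan), hi.append(np.nan)
            continue
        k, m = int(np.sum(vals)), len(vals)
        p = k / m
        denom = 1 + z**2 / m
        center = (p + z**2 / (2 * m)) / denom
        half = z * np.sqrt(p * (1 - p) / m + z**2 / (4 * m**2)) / denom
        mean.append(100.0 * p)
        lo.append(100.0 * max(center - half, 0.0))
        hi.append(100.0 * min(center + half, 1.0))
    return {
        "trial": idx,
        "mean_pct": np.asarray(mean),
        "ci_low_pct": np.asarray(lo),
        "ci_high_pct": np.asarray(hi),
    }
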