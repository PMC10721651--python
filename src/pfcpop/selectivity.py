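"""Omega-squared explained-variance selectivity and population controls.

The selectivity of a unit for a 3-level task variable is the bias-adjusted
fraction of firing-rate variance explained by the variable:

    omega^2 = (SS_between - df * MSE) / (SS_total + MSE)

with df = G - 1 and MSE the within-group mean square (within-group sum of
squares divided by N - G). To counter the small-sample bias from unequal
condition counts, trials are balanced by subsampling every condition to the
smallest condition count; the subsampling is repeated (50 times by default)
and omega^2 averaged over repetitions. Time courses use 150 ms bins stepped
every 15 ms.

The module also provides selectivity onset latencies against a permutation
null, early/late-epoch selective-cell percentages, and the three population
controls: firing-rate matching, the task-related filter (Kruskal-Wallis
baseline vs IS epochs) and the low-rate exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from pfcpop import session_io

# epoch definitions (s, relative to IS onset); the selectivity histograms
# and the task-related filter use slightly different boundaries — both kept
# verbatim as named configs
EPOCHS_SELECTIVITY = {"early": (0.050, 0.450), "late": (0.500, 0.900)}
EPOCHS_TASK_RELATED = {"early": (0.050, 0.400), "late": (0.400, 0.900)}


@dataclass
class OmegaSeries:
    """Per-unit omega-squared time course (units x bins) with bin geometry."""

    omega: np.ndarray
    bin_centers_s: np.ndarray
    unit_ids: np.ndarray
    n_reps: int
    width_ms: float
    step_ms: float


def _label_codes(labels) -> tuple[np.ndarray, int]:
    uniq, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes, len(uniq)


def omega_squared(values, labels=None, strict_printed: bool = False) -> float:
    """Omega-squared for grouped observations.

    Accepts either a list of per-group arrays, or a flat array plus labels.
    Raw values are returned (possibly negative; retained in averages and
    clipped only for display); degenerate data with zero total variance
    return 0. ``strict_printed=True`` uses the raw within-group sum of
    squares in place of the within-group mean square — the literal printed
    form of the formula — for comparison purposes only.
    """
    if labels is None:
        groups = [np.asarray(g, dtype=float) for g in values]
        if any(len(g) == 0 for g in groups):
            raise ValueError("every group must be nonempty")
        x = np.concatenate(groups)
        codes = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
        G = len(groups)
    else:
        x = np.asarray(values, dtype=float)
        codes, G = _label_codes(labels)
    return float(_omega_stack(x[None, :], codes, G, strict_printed)[0])


def _omega_stack(x: np.ndarray, codes: np.ndarray, G: int,
                 strict_printed: bool = False) -> np.ndarray:
    """Vectorized omega-squared over the trailing axis.

    ``x`` has shape (..., N) and ``codes`` assigns each of the N
    observations to one of G groups; returns shape (...).
    """
    N = x.shape[-1]
    if N != len(codes):
        raise ValueError("labels length does not match observations")
    counts = np.bincount(codes, minlength=G).astype(float)
    if np.any(counts == 0):
        raise ValueError("every group must be nonempty")
    grand = x.mean(axis=-1)
    sums = np.stack([x[..., codes == g].sum(axis=-1) for g in range(G)], axis=-1)
    means = sums / counts
    ssb = (counts * (means - grand[..., None]) ** 2).sum(axis=-1)
    sst = ((x - grand[..., None]) ** 2).sum(axis=-1)
    ssw = sst - ssb
    df = G - 1
    mse = ssw if strict_printed else ssw / (N - G)
    denom = sst + mse
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ssb - df * mse) / denom
    return np.where(denom <= 0, 0.0, out)


def omega_timecourse(
    tensor: session_io.BinnedRateTensor,
    labels,
    n_reps: int = 50,
    rng: np.random.Generator | None = None,
    strict_printed: bool = False,
) -> OmegaSeries:
    """Balanced-subsample omega-squared per unit and time bin.

    Every condition is subsampled without replacement to the smallest
    condition count; omega^2 is averaged over ``n_reps`` subsample draws
    (one subsample index set per repetition, reused across bins). When
    counts are already equal the subsampling is a no-op and a single pass
    is computed. Trials must already be restricted to correct,
    non-correction trials.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = tensor.rates  # (units, trials, bins)
    codes, G = _label_codes(labels)
    counts = np.bincount(codes, minlength=G)
    if counts.min() < 2:
        raise ValueError("smallest condition has fewer than 2 trials")
    n_min = int(counts.min())
    balanced_codes = np.repeat(np.arange(G), n_min)
    if np.all(counts == n_min):
        omega = _omega_stack(np.moveaxis(x, 1, 2), codes, G, strict_printed)
    else:
        acc = np.zeros((x.shape[0], x.shape[2]))
        for _ in range(n_reps):
            idx = np.concatenate(
                [rng.choice(np.flatnonzero(codes == g), n_min, replace=False)
                 for g in range(G)]
            )
            sub = np.moveaxis(x[:, idx, :], 1, 2)  # (units, bins, N)
            acc += _omega_stack(sub, balanced_codes, G, strict_printed)
        omega = acc / n_reps
    return OmegaSeries(
        omega=omega,
        bin_centers_s=tensor.bin_centers_s,
        unit_ids=tensor.unit_ids,
        n_reps=n_reps,
        width_ms=tensor.width_ms,
        step_ms=tensor.step_ms,
    )


def omega_null_stack(
    tensor: session_io.BinnedRateTensor,
    labels,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
    population_mean: bool = True,
) -> np.ndarray:
    """Label-shuffle null for the omega-squared time course.

    Condition labels are permuted independently within each unit (one
    permutation per unit per iteration, shared across bins, preserving
    temporal autocorrelation). Returns (iterations, bins) population-mean
    series, or (iterations, units, bins) with ``population_mean=False``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = tensor.rates
    codes, G = _label_codes(labels)
    U, T, B = x.shape
    out = np.empty((iterations, B)) if population_mean else np.empty((iterations, U, B))
    xb = np.moveaxis(x, 1, 2)  # (units, bins, trials)
    for it in range(iterations):
        perm = np.argsort(rng.random((U, T)), axis=1)
        # permuting labels within a unit == permuting that unit's trials
        xp = np.take_along_axis(xb, perm[:, None, :], axis=2)
        om = _omega_stack(xp, codes, G)
        out[it] = om.mean(axis=0) if population_mean else om
    return out


def onset_latency(
    observed: np.ndarray,
    null_stack: np.ndarray,
    bin_centers_s: np.ndarray,
    percentile: float = 99.9,
    from_time_s: float = 0.0,
) -> float | None:
    """First bin center at or after ``from_time_s`` whose statistic exceeds
    the pointwise null percentile; None when no bin is significant."""
    thresh = np.percentile(null_stack, percentile, axis=0)
    sig = (bin_centers_s >= from_time_s) & (observed > thresh)
    hits = np.flatnonzero(sig)
    return float(bin_centers_s[hits[0]]) if len(hits) else None


def per_cell_onset_latencies(
    series: OmegaSeries,
    null_stack_units: np.ndarray,
    percentile: float = 99.9,
    from_time_s: float = 0.0,
) -> np.ndarray:
    """Per-unit onset latency (s) against each unit's own shuffle null; NaN
    where a unit never crosses its pointwise threshold."""
    thresh = np.percentile(null_stack_units, percentile, axis=0)  # (units, bins)
    eligible = series.bin_centers_s >= from_time_s
    out = np.full(series.omega.shape[0], np.nan)
    for u in range(series.omega.shape[0]):
        hits = np.flatnonzero(eligible & (series.omega[u] > thresh[u]))
        if len(hits):
            out[u] = series.bin_centers_s[hits[0]]
    return out


def compare_latency_distributions(lat_a, lat_b) -> tuple[float, float]:
    """Kruskal-Wallis comparison of two onset-latency distributions (NaNs dropped)."""
    a = np.asarray(lat_a, dtype=float)
    b = np.asarray(lat_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    stat, p = stats.kruskal(a, b)
    return float(stat), float(p)


def epoch_rates(session, epoch_s: tuple[float, float], unit_ids=None,
                align: str = "is_onset") -> np.ndarray:
    """(units, trials) mean firing rates within one epoch window."""
    width_ms = (epoch_s[1] - epoch_s[0]) * 1000.0
    tensor = session_io.bin_spikes(
        session, align=align, window_s=epoch_s, width_ms=width_ms,
        step_ms=width_ms, unit_ids=unit_ids,
    )
    return tensor.rates[:, :, 0]


def epoch_selective_cells(
    session,
    variable: str,
    epochs: dict = EPOCHS_SELECTIVITY,
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    n_reps: int = 50,
    rng: np.random.Generator | None = None,
    unit_ids=None,
) -> dict:
    """Per-unit selectivity flags in the early and late IS epochs.

    For each epoch, balanced omega^2 on the single epoch window is compared
    against that unit's own label-shuffle null (p < alpha). Returns
    {epoch: {"omega", "p", "significant"}} arrays over units; population
    percentages per cell type follow by masking with a label table and
    comparing with :func:`pfcpop.cluster_stats.compare_proportions`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    usable = session_io.usable_trial_mask(session)
    labels_all = session_io.condition_labels(session, variable)
    out = {}
    for name, window in epochs.items():
        rates = epoch_rates(session, window, unit_ids=unit_ids)[:, usable]
        labels = labels_all[usable]
        codes, G = _label_codes(labels)
        counts = np.bincount(codes, minlength=G)
        n_min = int(counts.min())
        if n_min < 2:
            raise ValueError("every condition needs at least 2 usable trials")
        balanced_codes = np.repeat(np.arange(G), n_min)
        U, T = rates.shape
        obs = np.zeros(U)
        for _ in range(n_reps):
            idx = np.concatenate(
                [rng.choice(np.flatnonzero(codes == g), n_min, replace=False)
                 for g in range(G)]
            )
            obs += _omega_stack(rates[:, idx], balanced_codes, G)
        obs /= n_reps
        null = np.empty((n_shuffle, U))
        for it in range(n_shuffle):
            perm = np.argsort(rng.random((U, T)), axis=1)
            xp = np.take_along_axis(rates, perm, axis=1)
            null[it] = _omega_stack(xp, codes, G)
        p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_shuffle)
        out[name] = {"omega": obs, "p": p, "significant": p < alpha}
    return out


def rate_match_population(
    rates: np.ndarray,
    target_mean: float = 2.5,
    tol: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Greedy firing-rate matching: remove the highest-rate unit until the
    population mean drops into ``target_mean + tol``.

    Returns (kept indices, number removed). Raises when no subset can reach
    the target band.
    """
    rates = np.asarray(rates, dtype=float)
    order = list(np.argsort(rates))  # ascending; removal pops from the top
    removed = 0
    while order and rates[order].mean() > target_mean + tol:
        order.pop()
        removed += 1
    if not order:
        raise ValueError(
            "cannot reach target mean by removing high-rate units; "
            f"closest achievable mean {rates.min():.3f}"
        )
    return np.sort(np.asarray(order)), removed


def epoch_rates_fixation(session, unit_ids=None) -> np.ndarray:
    """(units, trials) firing rates in the 1 s fixation epoch."""
    return epoch_rates(session, (0.0, 1.0), unit_ids=unit_ids, align="fixation_onset")


def task_related_filter(
    session,
    alpha: float = 0.05,
    epochs: dict = EPOCHS_TASK_RELATED,
    low_rate_hz: float = 0.5,
    unit_ids=None,
) -> dict:
    """Task-related and low-rate unit flags.

    A unit is task-related when its per-trial baseline (fixation 0-1 s)
    firing differs from the early or the late IS epoch (Kruskal-Wallis,
    p < alpha on either). The low-rate flag marks units firing at or below
    ``low_rate_hz`` across the whole session; it is a separate exclusion,
    not part of the task-related rule.
    """
    if unit_ids is None:
        unit_ids = session.unit_ids
    baseline = epoch_rates_fixation(session, unit_ids=unit_ids)
    early = epoch_rates(session, epochs["early"], unit_ids=unit_ids)
    late = epoch_rates(session, epochs["late"], unit_ids=unit_ids)
    task_related = np.zeros(len(unit_ids), dtype=bool)
    p_values = np.ones((len(unit_ids), 2))
    for i in range(len(unit_ids)):
        for j, other in enumerate((early[i], late[i])):
            try:
                _, p = stats.kruskal(baseline[i], other)
            except ValueError:  # all values identical
                p = 1.0
            p_values[i, j] = p
        task_related[i] = p_values[i].min() < alpha
    span = (session.trials["go_s"].max() + 0.5) - session.trials["fixation_onset_s"].min()
    overall = np.array([len(session.spikes_for_unit(u)) / span for u in unit_ids])
    return {
        "unit_ids": np.asarray(unit_ids),
        "task_related": task_related,
        "p_values": p_values,
        "low_rate": overall <= low_rate_hz,
        "overall_rate_hz": overall,
    }
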