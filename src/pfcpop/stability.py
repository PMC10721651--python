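"""Static/dynamic classification of cross-temporal bins and the stability index.

An off-diagonal bin (tp1, tp2) of the cross-temporal decoding matrix is
*static* when decoding generalizes across time: the accuracy drops from the
two corresponding on-diagonal bins are smaller than the 99.9th percentile
of the same differences under the label-shuffle null, the off-diagonal
accuracy itself beats its null at the same percentile, and both on-diagonal
bins are significantly above chance (Bonferroni-corrected permutation
test, alpha = 0.05 / number of on-diagonal bins). The schematic raw
inequality version of the rule is replaced by this statistical form — under
noise a raw inequality would mark almost nothing static.

The stability index of an on-diagonal bin is the proportion of its row and
column off-diagonal bins classified static, smoothed with a three-bin
moving average (rows/columns of the previous and next bin included,
truncated at the edges) and masked where the on-diagonal bin is not
significantly above chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pfcpop.decoding import CrossTemporalMatrix, NullCTMStack, cross_temporal_decode


@dataclass
class StaticBinaryMatrix:
    """Binary static/dynamic matrix; the diagonal is conventionally 0."""

    static: np.ndarray           # (bins, bins) in {0, 1}
    on_diag_significant: np.ndarray  # (bins,) bool
    diff_percentile: float
    bonferroni_alpha: float


@dataclass
class StabilityIndexSeries:
    """Per on-diagonal bin: proportion of off-diagonal bins static."""

    raw: np.ndarray
    smoothed: np.ndarray
    masked: np.ndarray           # bool; True where index undefined
    bin_centers_s: np.ndarray
    bootstrap_sd: np.ndarray | None = None


def classify_static_bins(
    ctm: CrossTemporalMatrix,
    null: NullCTMStack,
    diff_percentile: float = 99.9,
    accuracy_percentile: float = 99.9,
    on_diag_alpha: float | None = None,
) -> StaticBinaryMatrix:
    """Static binary matrix from a CTD and its label-shuffle null stack.

    ``on_diag_alpha`` defaults to 0.05 Bonferroni-corrected for the number
    of on-diagonal bins (0.0025 for 20 bins).
    """
    A = ctm.accuracy
    N = null.accuracy
    if N.shape[1:] != A.shape:
        raise ValueError("null stack and CTD geometries differ")
    if N.shape[0] < 100:
        raise ValueError("need at least 100 null iterations for stable percentiles")
    B = A.shape[0]
    if on_diag_alpha is None:
        on_diag_alpha = 0.05 / B

    diag = np.diag(A)
    null_diag = N[:, np.arange(B), np.arange(B)]           # (iters, B)
    # on-diagonal gate: permutation p-value with Bonferroni-corrected alpha
    p_diag = (1 + (null_diag >= diag[None, :]).sum(axis=0)) / (1 + N.shape[0])
    on_sig = p_diag < on_diag_alpha

    # accuracy drops re the two on-diagonal bins, observed and per null iter
    d1 = diag[:, None] - A                                  # train-diag drop
    d2 = diag[None, :] - A                                  # test-diag drop
    n1 = null_diag[:, :, None] - N
    n2 = null_diag[:, None, :] - N
    thr1 = np.percentile(n1, diff_percentile, axis=0)
    thr2 = np.percentile(n2, diff_percentile, axis=0)
    thr_acc = np.percentile(N, accuracy_percentile, axis=0)

    static = (
        (d1 < thr1)
        & (d2 < thr2)
        & (A > thr_acc)
        & on_sig[:, None]
        & on_sig[None, :]
    )
    np.fill_diagonal(static, False)
    return StaticBinaryMatrix(
        static=static.astype(np.int8),
        on_diag_significant=on_sig,
        diff_percentile=diff_percentile,
        bonferroni_alpha=on_diag_alpha,
    )


def stability_index(
    static: StaticBinaryMatrix,
    bin_centers_s: np.ndarray,
    smooth: bool = True,
) -> StabilityIndexSeries:
    """Stability index per on-diagonal bin.

    raw(k) = mean of the static flags over row k and column k excluding the
    diagonal; smoothed(k) additionally pools rows/columns k-1..k+1
    (truncated at the edges). Bins whose on-diagonal accuracy is not
    significant are masked (smoothing first, masking second).
    """
    S = static.static.astype(float)
    B = S.shape[0]
    raw = np.empty(B)
    for k in range(B):
        vals = np.concatenate([np.delete(S[k, :], k), np.delete(S[:, k], k)])
        raw[k] = vals.mean()
    if smooth:
        smoothed = np.empty(B)
        for k in range(B):
            ks = range(max(0, k - 1), min(B, k + 2))
            parts = [
                np.concatenate([np.delete(S[j, :], j), np.delete(S[:, j], j)])
                for j in ks
            ]
            smoothed[k] = np.concatenate(parts).mean()
    else:
        smoothed = raw.copy()
    masked = ~static.on_diag_significant
    return StabilityIndexSeries(
        raw=raw,
        smoothed=smoothed,
        masked=masked,
        bin_centers_s=np.asarray(bin_centers_s),
    )


def masked_index_values(series: StabilityIndexSeries, fill: float = np.nan) -> np.ndarray:
    """Smoothed index with masked (non-significant) bins replaced by ``fill``."""
    out = series.smoothed.copy()
    out[series.masked] = fill
    return out


def joint_significance_mask(a: StabilityIndexSeries, b: StabilityIndexSeries) -> np.ndarray:
    """Bins defined for both populations — two-population comparisons use
    only bins significant in both."""
    return ~(a.masked | b.masked)


def compute_stability(
    tensor,
    labels,
    n_units_match: int | None = None,
    folds: int = 10,
    runs: int = 50,
    shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> tuple[StabilityIndexSeries, StaticBinaryMatrix, CrossTemporalMatrix, NullCTMStack]:
    """Decode, classify static bins and compute the stability index in one go."""
    ctm, null = cross_temporal_decode(
        tensor, labels, n_units_match=n_units_match, folds=folds, runs=runs,
        shuffles=shuffles, rng=rng, **kwargs,
    )
    static = classify_static_bins(ctm, null)
    series = stability_index(static, ctm.bin_centers_s)
    return series, static, ctm, null


def bootstrap_stability_sd(
    tensor,
    labels,
    n_boot: int = 50,
    n_units_match: int | None = None,
    folds: int = 10,
    runs: int = 1,
    shuffles: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap SD of the smoothed stability index.

    Repeats the full decode + null + static classification with units
    resampled with replacement; returns the per-bin SD over the ``n_boot``
    smoothed indices (masked bins enter as NaN and are ignored via
    nan-aware SD).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    indices = []
    for _ in range(n_boot):
        series, *_ = compute_stability(
            tensor, labels, n_units_match=n_units_match, folds=folds, runs=runs,
            shuffles=shuffles, rng=rng, replace_units=True,
        )
        indices.append(masked_index_values(series))
    stack = np.stack(indices)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(stack, axis=0, ddof=1)
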