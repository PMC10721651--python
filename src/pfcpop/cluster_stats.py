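"""Cluster-based permutation statistics and proportion comparisons.

Time-resolved statistics (population omega^2 curves, stability-index
series, population differences) are tested nonparametrically: contiguous
time bins whose observed statistic exceeds the pointwise 99.9th percentile
of a null distribution form candidate clusters, each cluster's mass is the
sum of the observed statistic over its bins, and a cluster is significant
when its mass beats the null distribution of maximal cluster masses
(formed identically per null iteration against the same pointwise
thresholds). Three null constructions are supported:

1. *label_shuffle* — recompute the statistic with condition labels permuted
   within unit (chance-level null for one population);
2. *celltype_shuffle* — reassign units to two pseudo-populations of the
   original sizes (null for a between-population difference);
3. *mixed_populations* — for statistics too expensive to recompute per
   shuffle (the stability index), mix the two populations a small number of
   times, compute the statistic per mix, and use all pairwise differences
   between mixes as the null (46 mixes giving C(46,2) = 1035 differences by
   default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class Cluster:
    start: int          # first bin index (inclusive)
    stop: int           # last bin index (inclusive)
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    thresholds: np.ndarray       # per-bin cluster-forming thresholds
    null_max_mass: np.ndarray    # (iterations,)
    percentile: float
    alpha: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) inclusive index pairs."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i - 1))
            in_run = False
    if in_run:
        out.append((start, len(mask) - 1))
    return out


def cluster_permutation_test(
    observed: np.ndarray,
    null_stack: np.ndarray,
    cluster_percentile: float = 99.9,
    alpha: float = 0.001,
) -> ClusterResult:
    """Max-sum cluster permutation test of a 1-D statistic series.

    ``null_stack`` is (iterations, bins). Candidate clusters are maximal
    runs of bins with ``observed`` above the per-bin null percentile; the
    null max-mass distribution is built by clustering every null series
    against the same thresholds. Cluster p = (count of null max-masses >=
    observed mass) / iterations. An empty cluster list is a valid result.
    """
    observed = np.asarray(observed, dtype=float)
    null_stack = np.asarray(null_stack, dtype=float)
    if null_stack.ndim != 2 or null_stack.shape[1] != len(observed):
        raise ValueError("null stack must be (iterations, bins) matching observed")
    thresholds = np.percentile(null_stack, cluster_percentile, axis=0)

    exceed_null = null_stack > thresholds[None, :]
    n_iter = null_stack.shape[0]
    null_max = np.zeros(n_iter)
    padded = np.zeros((n_iter, exceed_null.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = exceed_null
    d = np.diff(padded, axis=1)
    cs = np.concatenate(
        [np.zeros((n_iter, 1)), np.cumsum(null_stack, axis=1)], axis=1
    )
    for it in range(n_iter):
        starts = np.flatnonzero(d[it] == 1)
        if len(starts):
            ends = np.flatnonzero(d[it] == -1)
            null_max[it] = (cs[it, ends] - cs[it, starts]).max()

    clusters = []
    for a, b in _runs(observed > thresholds):
        mass = observed[a:b + 1].sum()
        p = float((null_max >= mass).sum() / n_iter)
        clusters.append(Cluster(start=a, stop=b, mass=mass, p_value=p))
    return ClusterResult(
        clusters=clusters,
        thresholds=thresholds,
        null_max_mass=null_max,
        percentile=cluster_percentile,
        alpha=alpha,
    )


def label_shuffle_null(
    statistic_fn,
    labels,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mode 1: recompute a statistic with permuted condition labels.

    ``statistic_fn(permuted_labels)`` must return a 1-D series; a plain
    single permutation of the shared label vector is drawn per iteration
    (callers whose statistic resamples per unit should shuffle within the
    statistic instead — see :func:`pfcpop.selectivity.omega_null_stack`).
    """
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    if rng is None:
        rng = np.random.default_rng(0)
    labels = np.asarray(labels)
    out = None
    for it in range(iterations):
        series = np.asarray(statistic_fn(rng.permutation(labels)), dtype=float)
        if out is None:
            out = np.empty((iterations, len(series)))
        out[it] = series
    return out


def celltype_shuffle_null(
    series_a: np.ndarray,
    series_b: np.ndarray,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mode 2: null for the difference of two population-mean series.

    ``series_a``/``series_b`` are (units, bins) per-unit statistic series
    for the two cell-type populations. Units are pooled and randomly
    reassigned to two pseudo-populations of the original sizes; each
    iteration returns mean(pseudo-A) - mean(pseudo-B).
    """
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    if rng is None:
        rng = np.random.default_rng(0)
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    n = pooled.shape[0]
    out = np.empty((iterations, pooled.shape[1]))
    for it in range(iterations):
        perm = rng.permutation(n)
        out[it] = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
    return out


def mixed_population_null(
    index_fn,
    units_a: np.ndarray,
    units_b: np.ndarray,
    n_mixes: int = 46,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mode 3: pairwise-difference null for expensive two-population statistics.

    ``index_fn(unit_subset_1, unit_subset_2)`` returns a pair of 1-D series
    (one per pseudo-population). Units are pooled and split without
    replacement into two pseudo-populations matching the original sizes,
    ``n_mixes`` times; all C(n_mixes, 2) pairwise differences between the
    per-mix (pop1 - pop2) series form the null (1035 differences for 46
    mixes).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    units_a = np.asarray(units_a)
    units_b = np.asarray(units_b)
    pooled = np.concatenate([units_a, units_b])
    na = len(units_a)
    per_mix = []
    for _ in range(n_mixes):
        perm = rng.permutation(len(pooled))
        s1, s2 = index_fn(pooled[perm[:na]], pooled[perm[na:]])
        per_mix.append(np.asarray(s1, dtype=float) - np.asarray(s2, dtype=float))
    per_mix = np.stack(per_mix)
    diffs = [per_mix[i] - per_mix[j] for i, j in combinations(range(n_mixes), 2)]
    return np.stack(diffs)


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Chi-square test of equal proportions on a 2x2 table (no continuity
    correction). Raises when an expected cell count is zero."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        raise ValueError("expected cell count of zero; use an exact test instead")
    chi2 = ((table - expected) ** 2 / expected).sum()
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p
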