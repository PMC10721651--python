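"""Cross-temporal population decoding with a maximum-correlation classifier.

Condition identity is decoded from pseudo-population vectors of binned
firing rates (50 ms bins over the IS period). For every ordered pair of
time bins (tp1, tp2) a classifier is trained on bin tp1 and tested on bin
tp2; the resulting accuracy matrix (CTD) has same-bin training/testing on
the diagonal and cross-temporal generalization off it.

The classifier z-scores every unit with the mean/SD of the training trials
(all conditions pooled; the same statistics are applied to the test
vector), averages the training pseudotrials into one template per
condition, and predicts the condition whose template has the highest
Pearson correlation with the test vector across units. Cross-validation
follows a leave-one-pseudotrial-out scheme over 10 trials per condition,
repeated over runs that resample both trials and units; the null
distribution repeats the identical pipeline with condition labels shuffled
independently within each unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pfcpop.session_io import BinnedRateTensor

# populations are size-matched before decoding; the per-variable unit counts
# used for the number matching in the original analyses
DEFAULT_UNIT_MATCH = {
    "strategy_response": 200,
    "strategy_stimulus": 200,
    "novelmap": 165,
    "fammap": 80,
}


@dataclass
class CrossTemporalMatrix:
    """Train-bin x test-bin classification accuracies."""

    accuracy: np.ndarray  # (bins, bins), train axis first
    bin_centers_s: np.ndarray
    n_units: int
    n_runs: int
    chance: float


@dataclass
class NullCTMStack:
    """CTD-shaped accuracies with a leading shuffle-iteration axis."""

    accuracy: np.ndarray  # (iterations, bins, bins)
    bin_centers_s: np.ndarray
    n_units: int
    chance: float


class InsufficientDataError(ValueError):
    pass


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between columns of a (u, p) and b (u, q)."""
    a = a - a.mean(axis=0, keepdims=True)
    b = b - b.mean(axis=0, keepdims=True)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (a.T @ b) / np.outer(na, nb)


def max_corr_classifier(
    train: np.ndarray,
    train_labels,
    test_vector: np.ndarray,
    rng: np.random.Generator | None = None,
) -> object:
    """Predict the condition of one test population vector.

    ``train`` is (n_pseudotrials, n_units); units are z-scored with training
    mean/SD (zero-SD units are dropped), condition templates are the mean
    z-scored training vectors, and the prediction is the template with the
    highest Pearson correlation to the (identically z-scored) test vector.
    Exact ties — including a test vector that is constant across units —
    are broken uniformly at random with the supplied generator.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    train = np.asarray(train, dtype=float)
    test_vector = np.asarray(test_vector, dtype=float)
    labels = np.asarray(train_labels)
    conditions = np.unique(labels)
    if train.shape[1] != len(test_vector):
        raise ValueError("train and test unit dimensions differ")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    valid = sd > 0
    if not valid.any():
        return conditions[rng.integers(len(conditions))]
    z_train = (train[:, valid] - mu[valid]) / sd[valid]
    z_test = (test_vector[valid] - mu[valid]) / sd[valid]
    if z_test.std() <= 1e-9 * (np.abs(z_test).max() + 1.0):
        # constant across units: the correlation is undefined
        return conditions[rng.integers(len(conditions))]
    templates = np.stack([z_train[labels == c].mean(axis=0) for c in conditions], axis=1)
    r = _pearson_columns(z_test[:, None], templates)[0]
    best = np.flatnonzero(r >= r.max() - 1e-12)
    return conditions[best[rng.integers(len(best))]]


def _decode_once(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One cross-validated CTD from a pseudotrial tensor.

    ``X`` is (units, conditions, trials_per_condition, bins); the
    trials_per_condition axis is split leave-one-out into folds. Returns the
    (bins, bins) accuracy matrix averaged over folds and test conditions.
    Ties in the correlation scores are broken by seeded jitter.
    """
    U, G, F, B = X.shape
    acc = np.zeros((B, B))
    fold_ids = np.arange(F)
    for f in fold_ids:
        train = np.delete(X, f, axis=2)            # (U, G, F-1, B)
        test = X[:, :, f, :]                       # (U, G, B)
        flat = train.reshape(U, G * (F - 1), B)
        mu = flat.mean(axis=1)                     # (U, B)
        sd = flat.std(axis=1, ddof=0)
        templates = train.mean(axis=2)             # (U, G, B)
        for tp1 in range(B):
            valid = sd[:, tp1] > 0
            if valid.sum() < 2:
                acc[tp1, :] += 1.0 / G
                continue
            m, s = mu[valid, tp1, None], sd[valid, tp1, None]
            zt = (templates[valid, :, tp1] - m) / s          # (u, G)
            zx = (test[valid] - m[:, :, None]) / s[:, :, None]  # (u, G, B)
            r = np.einsum(
                "ug,ucb->gcb",
                _standardize(zt),
                _standardize(zx.reshape(valid.sum(), G * B)).reshape(valid.sum(), G, B),
            )  # (template G, test condition, tp2)
            r = r + rng.uniform(-1e-9, 1e-9, size=r.shape)   # seeded tie-break
            pred = np.argmax(r, axis=0)                      # (test condition, tp2)
            correct = pred == np.arange(G)[:, None]
            acc[tp1, :] += correct.mean(axis=0)
    return acc / F


def _standardize(a: np.ndarray) -> np.ndarray:
    """Center and L2-normalize columns over the unit axis (axis 0)."""
    a = a - a.mean(axis=0, keepdims=True)
    n = np.linalg.norm(a, axis=0, keepdims=True)
    n = np.where(n == 0, np.inf, n)
    return a / n


def _condition_pools(labels: np.ndarray, conditions: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == c) for c in conditions]


def _sample_pseudotrials(
    rates: np.ndarray,
    pools_by_unit: list[list[np.ndarray]],
    n_trials: int,
    unit_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(units, conditions, n_trials, bins) tensor with trials resampled
    independently per unit within condition (pseudo-population)."""
    U = len(unit_idx)
    G = len(pools_by_unit[0])
    B = rates.shape[2]
    X = np.empty((U, G, n_trials, B))
    for i, u in enumerate(unit_idx):
        for g in range(G):
            pick = rng.choice(pools_by_unit[u][g], size=n_trials, replace=False)
            X[i, g] = rates[u, pick, :]
    return X


def cross_temporal_decode(
    tensor: BinnedRateTensor | np.ndarray,
    labels,
    n_units_match: int | None = None,
    folds: int = 10,
    runs: int = 50,
    shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    bin_centers_s: np.ndarray | None = None,
    replace_units: bool = False,
) -> tuple[CrossTemporalMatrix, NullCTMStack]:
    """Cross-temporal decoding with run-resampling and a label-shuffle null.

    Per run, ``n_units_match`` units and ``folds`` trials per condition per
    unit are sampled; accuracies are averaged over the leave-one-out folds
    and over runs. The null stack repeats the identical procedure once per
    iteration with condition labels permuted independently within each
    unit. ``replace_units=True`` switches the unit resampling to with
    replacement (used by the stability bootstrap).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(tensor, BinnedRateTensor):
        rates = tensor.rates
        centers = tensor.bin_centers_s
    else:
        rates = np.asarray(tensor, dtype=float)
        centers = bin_centers_s if bin_centers_s is not None else np.arange(rates.shape[2], dtype=float)
    labels = np.asarray(labels)
    conditions = np.unique(labels)
    G = len(conditions)
    U, T, B = rates.shape

    pools = _condition_pools(labels, conditions)
    enough = [u for u in range(U) if all(len(p) >= folds for p in pools)]
    # per-unit pools are identical here (shared trial table); kept per unit so
    # shuffled-label nulls and multi-session pools can differ per unit
    pools_by_unit = [pools for _ in range(U)]
    usable = np.asarray(enough)
    if n_units_match is None:
        n_units_match = len(usable)
    if len(usable) < n_units_match or n_units_match < 2:
        raise InsufficientDataError(
            f"{len(usable)} usable units < requested {n_units_match}"
        )

    acc = np.zeros((B, B))
    for _ in range(runs):
        unit_idx = rng.choice(usable, size=n_units_match, replace=replace_units)
        X = _sample_pseudotrials(rates, pools_by_unit, folds, unit_idx, rng)
        acc += _decode_once(X, rng)
    acc /= runs

    null = np.empty((shuffles, B, B))
    for it in range(shuffles):
        shuf_pools = []
        for u in range(U):
            perm = rng.permutation(T)
            shuf_pools.append([perm[p] for p in pools])
        unit_idx = rng.choice(usable, size=n_units_match, replace=replace_units)
        Xn = _sample_pseudotrials(rates, shuf_pools, folds, unit_idx, rng)
        null[it] = _decode_once(Xn, rng)

    ctm = CrossTemporalMatrix(
        accuracy=acc, bin_centers_s=centers, n_units=n_units_match,
        n_runs=runs, chance=1.0 / G,
    )
    null_stack = NullCTMStack(
        accuracy=null, bin_centers_s=centers, n_units=n_units_match, chance=1.0 / G,
    )
    return ctm, null_stack


def normalize_ctm(ctm: CrossTemporalMatrix) -> np.ndarray:
    """Min-max rescaling of the accuracy matrix to [0, 1] — display only;
    all statistics operate on raw accuracies."""
    a = ctm.accuracy
    lo, hi = a.min(), a.max()
    if hi == lo:
        import warnings

        warnings.warn("constant accuracy matrix; returning 0.5 everywhere")
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)
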