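import numpy as np
import pytest
from scipy.stats import f_oneway

from pfcpop import selectivity, session_io, synthetic
from pfcpop.selectivity import (
    omega_null_stack,
    omega_squared,
    omega_timecourse,
    onset_latency,
    rate_match_population,
    task_related_filter,
)


def omega_from_anova(groups):
    """Independent oracle: omega^2 from the one-way ANOVA F statistic,
    omega^2 = (G-1)(F-1) / ((G-1)(F-1) + N)."""
    F = f_oneway(*groups).statistic
    G = len(groups)
    N = sum(len(g) for g in groups)
    return (G - 1) * (F - 1) / ((G - 1) * (F - 1) + N)


class TestOmegaSquared:
    def test_hand_example(self):
        # groups {1,2},{3,4},{5,6}: SSB=16, SST=17.5, MSE=0.5, df=2
        assert omega_squared([[1, 2], [3, 4], [5, 6]]) == pytest.approx(15 / 18)

    def test_degenerate_all_equal_returns_zero(self):
        assert omega_squared([[2, 2], [2, 2], [2, 2]]) == 0.0

    def test_strict_printed_form_differs(self):
        loose = omega_squared([[1, 2], [3, 4], [5, 6]])
        strict = omega_squared([[1, 2], [3, 4], [5, 6]], strict_printed=True)
        # raw within-group SS in place of the mean square changes the value
        assert strict != pytest.approx(loose)
        assert strict == pytest.approx((16 - 2 * 1.5) / (17.5 + 1.5))

    def test_matches_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            sizes = rng.integers(3, 12, size=3)
            groups = [rng.normal(rng.normal(), 1, s) for s in sizes]
            assert omega_squared(groups) == pytest.approx(
                omega_from_anova(groups), abs=1e-12
            )

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        base = omega_squared(groups)
        shifted = omega_squared([g * 3.7 - 11.0 for g in groups])
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_label_permutation_centers_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        vals = []
        for _ in range(3000):
            labels = rng.permutation(np.repeat([0, 1, 2], 10))
            vals.append(omega_squared(x, labels))
        assert abs(np.mean(vals)) < 0.01


class TestTimecourse:
    def _tensor(self, counts, width_ms=150.0, step_ms=15.0):
        U, T, B = counts.shape
        return session_io.BinnedRateTensor(
            counts=counts, width_ms=width_ms, step_ms=step_ms, align="is_onset",
            t0_s=0.0, unit_ids=np.array([f"u{i}" for i in range(U)]),
            trial_ids=np.arange(1, T + 1), valid=np.ones((T, B), bool),
        )

    def test_equal_counts_single_pass_equals_plain_omega(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3, size=(4, 30, 5)).astype(float)
        labels = np.repeat(["a", "b", "c"], 10)
        series = omega_timecourse(self._tensor(counts), labels, rng=rng)
        direct = omega_squared(counts[2, :, 3] / 0.15, labels)
        assert series.omega[2, 3] == pytest.approx(direct, abs=1e-12)

    def test_unbalanced_counts_are_subsampled(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3, size=(2, 33, 4)).astype(float)
        labels = np.array(["a"] * 15 + ["b"] * 10 + ["c"] * 8)
        series = omega_timecourse(self._tensor(counts), labels, n_reps=25, rng=rng)
        assert series.omega.shape == (2, 4)
        assert np.isfinite(series.omega).all()

    def test_effect_size_monotonicity(self):
        # stronger generator modulation -> larger population mean omega^2
        means = []
        for effect in (1.0, 2.0, 4.0):
            cfg = synthetic.SyntheticConfig(
                n_units_bw=15, n_units_nw=0, rate_bw=8.0, n_trials=90, seed=5,
                selectivity_profile="static", effect_size=effect,
            )
            sess, _ = synthetic.generate_session(cfg)
            tensor = session_io.bin_spikes(sess, "is_onset", (0.0, 1.0), 150, 150)
            usable = session_io.usable_trial_mask(sess)
            labels = session_io.condition_labels(sess, "association_id")[usable]
            sub = self._tensor(tensor.counts[:, usable, :].astype(float), 150, 150)
            series = omega_timecourse(sub, labels, rng=np.random.default_rng(0))
            means.append(series.omega.mean())
        assert means[0] < means[1] < means[2]


class TestLatency:
    def test_no_signal_gives_sentinel(self):
        rng = np.random.default_rng(6)
        null = rng.normal(0, 0.01, size=(500, 10))
        observed = np.zeros(10)
        assert onset_latency(observed, null, np.linspace(0.0, 0.9, 10)) is None

    def test_latency_tracks_injected_onset(self):
        # selectivity injected from bin 4 onward must be detected at bin 4
        rng = np.random.default_rng(7)
        null = rng.normal(0, 0.01, size=(500, 10))
        observed = np.where(np.arange(10) >= 4, 0.5, 0.0)
        centers = np.linspace(0.05, 0.95, 10)
        assert onset_latency(observed, null, centers) == pytest.approx(centers[4])

    def test_earlier_injection_decreases_latency(self):
        rng = np.random.default_rng(8)
        null = rng.normal(0, 0.01, size=(500, 10))
        centers = np.linspace(0.05, 0.95, 10)
        lat = [
            onset_latency(np.where(np.arange(10) >= b, 0.5, 0.0), null, centers)
            for b in (6, 4, 2)
        ]
        assert lat[0] > lat[1] > lat[2]


class TestEpochSelectivity:
    def test_modulated_units_flagged_in_correct_epoch(self):
        cfg = synthetic.SyntheticConfig(
            n_units_bw=10, n_units_nw=0, rate_bw=10.0, n_trials=100, seed=9,
            selectivity_profile="transient", effect_size=3.0,
            transient_window=(0.0, 0.45),
        )
        sess, _ = synthetic.generate_session(cfg)
        res = selectivity.epoch_selective_cells(
            sess, "association_id", n_shuffle=300, rng=np.random.default_rng(0)
        )
        early_pct = res["early"]["significant"].mean()
        late_pct = res["late"]["significant"].mean()
        assert early_pct > late_pct
        assert early_pct >= 0.8

    def test_all_zero_rates_flag_nothing(self):
        # silent session: every omega^2 is the guarded 0 and p = 1
        cfg = synthetic.SyntheticConfig(
            n_units_bw=4, n_units_nw=0, n_trials=60, seed=14,
            selectivity_profile="none",
        )
        sess, _ = synthetic.generate_session(cfg)
        sess.spikes = sess.spikes.iloc[0:0]
        res = selectivity.epoch_selective_cells(
            sess, "association_id", n_shuffle=100, rng=np.random.default_rng(0)
        )
        assert res["early"]["significant"].sum() == 0
        assert res["late"]["significant"].sum() == 0


class TestPopulationControls:
    def test_rate_match_greedy_trace(self):
        kept, removed = rate_match_population(np.array([1.0, 2.0, 3.0, 10.0]), 2.5, 0.2)
        assert removed == 1
        assert list(kept) == [0, 1, 2]

    def test_population_already_at_target(self):
        kept, removed = rate_match_population(np.array([2.0, 2.5, 3.0]), 2.5, 0.2)
        assert removed == 0 and len(kept) == 3

    def test_removal_count_antitone_in_target(self):
        rng = np.random.default_rng(10)
        rates = rng.gamma(2, 2.5, 50)
        removed = [rate_match_population(rates, t, 0.2)[1] for t in (2.0, 3.0, 4.0)]
        assert removed[0] >= removed[1] >= removed[2]

    def test_task_related_power_and_low_rate_flag(self):
        cfg = synthetic.SyntheticConfig(
            n_units_bw=12, n_units_nw=0, rate_bw=6.0, n_trials=120, seed=11,
            selectivity_profile="static", effect_size=3.0,
        )
        sess, _ = synthetic.generate_session(cfg)
        res = task_related_filter(sess)
        # the preferred condition fires 3x baseline on a third of trials:
        # most units are detected as task-related
        assert res["task_related"].mean() >= 0.75
        assert not res["low_rate"].any()

    def test_low_rate_threshold(self):
        cfg = synthetic.SyntheticConfig(
            n_units_bw=5, n_units_nw=0, rate_bw=0.3, rate_dispersion=400.0,
            n_trials=60, seed=12, selectivity_profile="none",
        )
        sess, _ = synthetic.generate_session(cfg)
        res = task_related_filter(sess)
        assert res["low_rate"].all()


class TestNullStack:
    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(4, size=(15, 30, 6)).astype(float)
        tensor = session_io.BinnedRateTensor(
            counts=counts, width_ms=150, step_ms=15, align="is_onset", t0_s=0.0,
            unit_ids=np.array([f"u{i}" for i in range(15)]),
            trial_ids=np.arange(1, 31), valid=np.ones((30, 6), bool),
        )
        labels = np.repeat(["a", "b", "c"], 10)
        null = omega_null_stack(tensor, labels, iterations=300, rng=rng)
        assert null.shape == (300, 6)
        assert abs(null.mean()) < 0.01
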