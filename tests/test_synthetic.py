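import numpy as np
import pandas as pd
import pytest

from pfcpop import cell_types, session_io, synthetic
from pfcpop.synthetic import LearnerConfig, SyntheticConfig


class TestWaveforms:
    def test_extrema_distance_matches_drawn_t2p(self):
        cfg = SyntheticConfig(n_units_bw=12, n_units_nw=12, seed=5)
        wf, gt = synthetic.generate_waveforms(cfg)
        for _, row in gt.units.iterrows():
            trace = wf[wf["unit_id"] == row["unit_id"]].sort_values("sample_idx")["mean_v"].to_numpy()
            trough = np.argmin(trace)
            peak = trough + np.argmax(trace[trough:])
            measured_ms = (peak - trough) * synthetic.RAW_DT_US / 1000.0
            # within one raw sample of the drawn duration
            assert abs(measured_ms - row["t2p_ms"]) <= synthetic.RAW_DT_US / 1000.0 + 1e-9

    def test_zero_contamination_passes_qc(self):
        cfg = SyntheticConfig(n_units_bw=15, n_units_nw=10, seed=6, contamination_fraction=0.0)
        wf, _ = synthetic.generate_waveforms(cfg)
        for rec in cell_types.waveform_table_records(wf):
            assert rec.qc_pass

    def test_contaminated_units_fail_qc(self):
        cfg = SyntheticConfig(n_units_bw=10, n_units_nw=0, seed=6, contamination_fraction=1.0)
        wf, gt = synthetic.generate_waveforms(cfg)
        fails = [not rec.qc_pass for rec in cell_types.waveform_table_records(wf)]
        assert all(fails)

    def test_t2p_class_means_recovered(self):
        # two-Gaussian draw at the published-figure geometry; measured means
        # must sit within 3 SE of the generator means, per class
        cfg = SyntheticConfig(
            n_units_bw=650, n_units_nw=650, seed=7,
            t2p_bw_mean=0.42, t2p_bw_sd=0.07, t2p_nw_mean=0.18, t2p_nw_sd=0.04,
        )
        wf, gt = synthetic.generate_waveforms(cfg)
        measured = {}
        for rec in cell_types.waveform_table_records(wf):
            t2p, _ = cell_types.measure_trough_to_peak(rec)
            measured[rec.unit_id] = t2p
        df = gt.units.assign(measured=gt.units["unit_id"].map(measured))
        for cls, mean, sd in (("BW", 0.42, 0.07), ("NW", 0.18, 0.04)):
            vals = df.loc[df["cell_class"] == cls, "measured"]
            se = sd / np.sqrt(len(vals))
            # generator truncation and sampling shift the mean by < 3 SE
            assert abs(vals.mean() - mean) < 3 * se + 0.003

    def test_nw_mean_must_be_below_bw_mean(self):
        with pytest.raises(ValueError, match="narrow t2p mean"):
            SyntheticConfig(t2p_nw_mean=0.5, t2p_bw_mean=0.4).validate()


class TestSpikeTrains:
    def _session_rates(self, profile, seed=8, effect=3.0, **kw):
        cfg = SyntheticConfig(
            n_units_bw=12, n_units_nw=0, rate_bw=10.0, n_trials=90, seed=seed,
            selectivity_profile=profile, effect_size=effect, **kw,
        )
        sess, gt = synthetic.generate_session(cfg)
        return sess, gt

    def test_no_modulation_under_unit_effect(self):
        sess, gt = self._session_rates("static", effect=1.0)
        rates = _is_rates(sess, (0.0, 1.0))
        labels = sess.trials["association_id"].to_numpy()
        for i, row in gt.units.iterrows():
            pref = rates[i, labels == row["preferred"]]
            non = rates[i, labels != row["preferred"]]
            se = np.sqrt(pref.var(ddof=1) / len(pref) + non.var(ddof=1) / len(non))
            assert abs(pref.mean() - non.mean()) < 3.5 * se + 1e-9

    def test_static_profile_elevates_preferred_all_is(self):
        sess, gt = self._session_rates("static")
        labels = sess.trials["association_id"].to_numpy()
        for window in [(0.0, 0.5), (0.5, 1.0)]:
            rates = _is_rates(sess, window)
            for i, row in gt.units.iterrows():
                assert rates[i, labels == row["preferred"]].mean() > \
                    rates[i, labels != row["preferred"]].mean()

    def test_switching_profile_swaps_preference(self):
        sess, gt = self._session_rates("switching", switch_time=0.5)
        labels = sess.trials["association_id"].to_numpy()
        early = _is_rates(sess, (0.0, 0.5))
        late = _is_rates(sess, (0.5, 1.0))
        for i, row in gt.units.iterrows():
            pref_early = labels == row["preferred"]
            pref_late = labels == row["preferred_post"]
            assert early[i, pref_early].mean() > early[i, ~pref_early].mean()
            assert late[i, pref_late].mean() > late[i, ~pref_late].mean()

    def test_gamma_renewal_regularizes_spiking(self):
        cfg = SyntheticConfig(n_units_bw=3, n_units_nw=0, rate_bw=20.0, n_trials=40,
                              seed=9, selectivity_profile="none", gamma_shape=200.0)
        sess, _ = synthetic.generate_session(cfg)
        trains = [
            g["t_s"].to_numpy() for _, g in
            sess.spikes[sess.spikes["unit_id"] == "u0000"].groupby("trial_id")
        ]
        m = cell_types.firing_metrics(trains, epoch=(0.0, 1.0), min_trials=30)
        assert m.cv < 0.2  # near-clock-like firing


class TestBehavior:
    def test_degenerate_probabilities(self):
        ones = synthetic.generate_behavior_sequence(LearnerConfig(1, 1, 1), 20, 0)
        assert ones.sum() == 20
        step = synthetic.generate_behavior_sequence(LearnerConfig(0, 1, 10), 20, 0)
        assert step[:9].sum() == 0 and step[9:].sum() == 11

    def test_monte_carlo_step_means(self):
        # empirical pre/post means over many seeds within 3 SE of p_pre/p_post
        learner = LearnerConfig(1 / 3, 0.95, 100)
        pre, post = [], []
        for seed in range(400):
            seq = synthetic.generate_behavior_sequence(learner, 200, seed)
            pre.append(seq[:99].mean())
            post.append(seq[99:].mean())
        n_pre, n_post = 400 * 99, 400 * 101
        assert abs(np.mean(pre) - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n_pre)
        assert abs(np.mean(post) - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n_post)


class TestSessions:
    def test_fammap_mapping_is_functional(self):
        cfg = SyntheticConfig(n_units_bw=2, n_units_nw=1, n_trials=60, seed=3, task="fammap")
        sess, _ = synthetic.generate_session(cfg)
        mapping = sess.trials.groupby("stimulus_id")["response_target"].nunique()
        assert (mapping == 1).all()

    def test_strategy_has_no_fixed_mapping(self):
        cfg = SyntheticConfig(n_units_bw=2, n_units_nw=1, n_trials=120, seed=3, task="strategy")
        sess, _ = synthetic.generate_session(cfg)
        mapping = sess.trials.groupby("stimulus_id")["response_target"].nunique()
        assert (mapping > 1).any()

    def test_is_durations_exact(self, small_session):
        sess, _ = small_session
        assert set(sess.trials["is_duration_s"]) <= {1.0, 1.5, 2.0}

    def test_class_proportions_exact(self, small_session):
        _, gt = small_session
        assert (gt.units["cell_class"] == "BW").sum() == 8
        assert (gt.units["cell_class"] == "NW").sum() == 4

    def test_seeded_reproducibility(self):
        cfg = SyntheticConfig(n_units_bw=3, n_units_nw=2, n_trials=30, seed=42)
        s1, _ = synthetic.generate_session(cfg)
        s2, _ = synthetic.generate_session(cfg)
        pd.testing.assert_frame_equal(s1.trials, s2.trials)
        pd.testing.assert_frame_equal(s1.spikes, s2.spikes)
        pd.testing.assert_frame_equal(s1.waveforms, s2.waveforms)

    def test_correction_trials_follow_errors(self):
        cfg = SyntheticConfig(n_units_bw=1, n_units_nw=0, n_trials=80, seed=11,
                              learner=LearnerConfig(0.3, 0.7, 40))
        sess, _ = synthetic.generate_session(cfg)
        t = sess.trials
        corr = t["correction"].to_numpy()
        prev_ok = t["correct"].shift(1).to_numpy()
        assert corr[1:][corr[1:]].size > 0
        assert not prev_ok[corr].any()  # corrections only ever follow errors


def test_config_from_yaml_roundtrip(tmp_path):
    cfg_file = tmp_path / "cfg.yaml"
    cfg_file.write_text(
        "n_units_bw: 5\nn_units_nw: 2\nn_trials: 40\nseed: 9\n"
        "selectivity_profile: transient\ntransient_window: [0.1, 0.4]\n"
        "learner: {p_pre: 0.3, p_post: 0.9, change_trial: 12}\n"
    )
    cfg = synthetic.config_from_file(cfg_file)
    assert cfg.n_units_bw == 5
    assert cfg.transient_window == (0.1, 0.4)
    assert cfg.learner.change_trial == 12
    sess, gt = synthetic.generate_session(cfg)
    assert len(sess.trials) == 40


def _is_rates(sess, window):
    tensor = session_io.bin_spikes(
        sess, align="is_onset", window_s=window,
        width_ms=(window[1] - window[0]) * 1000, step_ms=(window[1] - window[0]) * 1000,
    )
    return tensor.rates[:, :, 0]
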