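import numpy as np
import pytest
from scipy.stats import norm

from pfcpop import cell_types, synthetic
from pfcpop.cell_types import (
    assign_cell_types,
    clean_waveform,
    firing_metrics,
    fit_mixture_and_cutoffs,
    interpolate_waveform,
    make_waveform_record,
    measure_trough_to_peak,
    qc_exclude,
)
from pfcpop.cell_types import test_bimodality as dip_bimodality


def _trace(trough_amp=1.0, post_amp=0.4, pre_amp=0.2, t2p_samples=16, n=64, trough_at=20):
    """Synthetic raw trace with exactly placed extrema."""
    t = np.zeros(n)
    t[trough_at] = -trough_amp
    t[trough_at + t2p_samples] = post_amp
    if pre_amp:
        t[trough_at - 8] = pre_amp
    return t


class TestCleanWaveform:
    def test_identical_spikes_reject_nothing(self):
        spikes = np.tile(_trace(), (10, 1))
        mean, frac = clean_waveform(spikes)
        assert frac == 0.0
        np.testing.assert_allclose(mean, _trace())

    def test_single_artifact_spike_rejected(self):
        # identical spikes except one gross artifact: exactly that spike
        # exceeds 3 SD (other samples have zero SD and cannot trigger)
        spikes = np.tile(_trace(), (50, 1))
        spikes[7, 30] += 5.0
        mean, frac = clean_waveform(spikes)
        assert frac == pytest.approx(1 / 50)
        np.testing.assert_allclose(mean, _trace())

    def test_rejection_fraction_matches_multipoint_exceedance(self):
        # Gaussian noise: P(reject) = P(any of d samples beyond 3 SD)
        rng = np.random.default_rng(1)
        d = 16
        spikes = rng.normal(0, 1, size=(4000, d))
        _, frac = clean_waveform(spikes)
        p_point = 2 * norm.sf(3.0)
        expected = 1 - (1 - p_point) ** d
        se = np.sqrt(expected * (1 - expected) / 4000)
        # initial-mean estimation slightly perturbs the rule; allow 4 SE
        assert abs(frac - expected) < 4 * se + 0.005

    def test_all_rejected_is_an_error(self):
        # each spike carries a gross artifact at its own sample: every one
        # exceeds 3 SD somewhere, so the cleaned mean is undefined
        spikes = np.eye(12) * 100.0
        with pytest.raises(ValueError, match="all spike waveforms rejected"):
            clean_waveform(spikes)


class TestQC:
    def test_canonical_trace_kept(self):
        keep, reason = qc_exclude(_trace(1.0, 0.4, 0.2))
        assert keep and reason is None

    def test_axon_like_post_peak_dropped(self):
        keep, reason = qc_exclude(_trace(1.0, 1.1, 0.2))
        assert not keep and "post-peak" in reason

    def test_pre_peak_20pct_rule_boundary(self):
        keep, _ = qc_exclude(_trace(1.0, 0.4, 1.19))
        assert keep
        keep, reason = qc_exclude(_trace(1.0, 0.4, 1.21))
        assert not keep and "pre-peak" in reason

    def test_monotone_tail_without_peak_dropped(self):
        trace = -np.linspace(0.1, 1.0, 32)  # trough at the very end
        keep, reason = qc_exclude(trace)
        assert not keep and reason == "no peak"


class TestTroughToPeak:
    def test_constructed_extrema_160_interp_samples(self):
        rec = make_waveform_record("u", _trace(t2p_samples=16))
        t2p, flagged = measure_trough_to_peak(rec)
        # 16 raw samples at 25 us = 0.400 ms; interpolation keeps it within
        # one interpolated step
        assert t2p == pytest.approx(0.400, abs=0.0025 + 1e-9)
        assert not flagged

    def test_interpolation_factor_is_ten(self):
        raw = _trace()
        interp = interpolate_waveform(raw)
        assert len(interp) == (len(raw) - 1) * 10 + 1

    def test_normalized_trough_is_minus_one(self):
        rec = make_waveform_record("u", _trace(trough_amp=3.7))
        assert rec.interpolated.min() == pytest.approx(-1.0)

    def test_time_reversal_breaks_symmetry(self):
        raw = _trace(t2p_samples=16, pre_amp=0.0)
        rec = make_waveform_record("u", raw)
        fwd, _ = measure_trough_to_peak(rec)
        rev = make_waveform_record("u", raw[::-1].copy())
        # reversed trace measures the pre-trough distance instead
        if rev.qc_pass:
            bwd, _ = measure_trough_to_peak(rev)
            assert bwd != pytest.approx(fwd, abs=0.01)


class TestBimodality:
    def test_constant_sample_p_one(self):
        res = dip_bimodality(np.full(10, 0.3), n_boot=50)
        assert res.p_original == 1.0 and res.p_calibrated == 1.0

    def test_unimodal_sample_not_flagged(self):
        rng = np.random.default_rng(2)
        res = dip_bimodality(rng.normal(0.3, 0.05, 400), n_boot=500, rng=rng)
        assert res.p_original > 0.05

    def test_bimodal_mixture_flagged(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.18, 0.04, 400), rng.normal(0.42, 0.07, 400)])
        res = dip_bimodality(x, n_boot=500, rng=rng)
        assert res.p_original < 0.01
        assert res.p_calibrated < 0.01

    def test_calibrated_variant_is_more_sensitive(self):
        # mild bimodality: the Gaussian-reference calibration must never be
        # less powerful than the uniform reference
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.2, 0.05, 300), rng.normal(0.35, 0.05, 300)])
        res = dip_bimodality(x, n_boot=500, rng=rng)
        assert res.p_calibrated <= res.p_original + 0.02


class TestMixture:
    def test_well_separated_recovery(self):
        rng = np.random.default_rng(5)
        nw = rng.normal(0.18, 0.04, 400)
        bw = rng.normal(0.42, 0.07, 600)
        model = fit_mixture_and_cutoffs(np.concatenate([nw, bw]))
        assert model.prefers_two_components
        assert 0.18 < model.cutoff_low_ms < model.cutoff_high_ms < 0.45
        labels = assign_cell_types(np.concatenate([nw, bw]), model.cutoff_low_ms,
                                   model.cutoff_high_ms)
        truth = np.array(["NW"] * 400 + ["BW"] * 600)
        classified = labels != "NC"
        agree = (labels[classified] == truth[classified]).mean()
        assert agree >= 0.95

    def test_single_gaussian_prefers_one_component(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.3, 0.05, 800)
        model = fit_mixture_and_cutoffs(x)
        assert model.aic_1 < model.aic_2 or model.bic_1 < model.bic_2
        assert not model.prefers_two_components

    def test_symmetric_components_give_symmetric_cutoffs(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.2, 0.03, 2000), rng.normal(0.5, 0.03, 2000)])
        model = fit_mixture_and_cutoffs(x)
        mid = 0.35
        assert model.cutoff_low_ms + model.cutoff_high_ms == pytest.approx(2 * mid, abs=0.02)


class TestAssignment:
    def test_boundary_inclusive_toward_classified_side(self):
        labels = assign_cell_types([0.25, 0.30, 0.35], 0.25, 0.35)
        assert list(labels) == ["NW", "NC", "BW"]

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 0.6, 50)
        base = assign_cell_types(x, 0.25, 0.35)
        shifted = assign_cell_types(x + 0.1, 0.35, 0.45)
        assert np.array_equal(base, shifted)


class TestFiringMetrics:
    def test_hand_fano(self):
        trains = [np.linspace(0.1, 0.9, c) for c in (2, 4, 3, 3)]
        m = firing_metrics(trains, min_trials=4)
        # counts [2,4,3,3]: mean 3, sample variance 2/3, Fano = 2/9
        assert m.fano == pytest.approx((2 / 3) / 3, abs=1e-12)

    def test_regular_isis_cv_zero(self):
        trains = [np.arange(0.05, 1.0, 0.1) for _ in range(30)]
        m = firing_metrics(trains)
        assert m.cv == pytest.approx(0.0, abs=1e-9)

    def test_poisson_fano_and_cv_near_one(self):
        rng = np.random.default_rng(9)
        trains = [np.sort(rng.uniform(0, 1, rng.poisson(12))) for _ in range(500)]
        m = firing_metrics(trains)
        se_fano = np.sqrt(2 / 499)
        assert abs(m.fano - 1.0) < 3 * se_fano
        assert abs(m.cv - 1.0) < 0.1

    def test_min_trials_enforced(self):
        with pytest.raises(ValueError, match="minimum"):
            firing_metrics([np.array([0.1])] * 10)


class TestPipeline:
    def test_classify_units_end_to_end(self):
        cfg = synthetic.SyntheticConfig(n_units_bw=120, n_units_nw=80, seed=10)
        wf, gt = synthetic.generate_waveforms(cfg)
        table, model, dip = cell_types.classify_units(wf, n_boot=300,
                                                      rng=np.random.default_rng(0))
        assert dip.p_original < 0.01
        merged = table.merge(gt.units, on="unit_id")
        classified = merged[merged["label"].isin(["NW", "BW"])]
        agree = (classified["label"] == classified["cell_class"]).mean()
        assert agree >= 0.95

    def test_amplitude_rescaling_leaves_labels_unchanged(self):
        cfg = synthetic.SyntheticConfig(n_units_bw=60, n_units_nw=40, seed=11)
        wf, _ = synthetic.generate_waveforms(cfg)
        t1, m1, _ = cell_types.classify_units(wf, n_boot=100, rng=np.random.default_rng(0))
        wf2 = wf.copy()
        wf2["mean_v"] *= 7.3
        t2, m2, _ = cell_types.classify_units(wf2, n_boot=100, rng=np.random.default_rng(0))
        assert (t1["label"] == t2["label"]).all()
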