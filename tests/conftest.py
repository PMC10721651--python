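import numpy as np
import pandas as pd
import pytest

from pfcpop import session_io, synthetic


@pytest.fixture(scope="session")
def small_session():
    """A small mapping-task session with static selectivity."""
    cfg = synthetic.SyntheticConfig(
        n_units_bw=8, n_units_nw=4, n_trials=80, seed=123,
        selectivity_profile="static", effect_size=2.5,
    )
    sess, gt = synthetic.generate_session(cfg)
    return sess, gt


@pytest.fixture()
def toy_session():
    """Hand-built two-unit session for exact binning/filter arithmetic."""
    trials = pd.DataFrame(
        {
            "trial_id": [1, 2, 3],
            "stimulus_id": ["s1", "s2", "s3"],
            "response_target": ["top", "right", "left"],
            "association_id": ["a1", "a2", "a3"],
            "correct": [True, True, False],
            "correction": [False, False, False],
            "fixation_onset_s": [0.0, 10.0, 20.0],
            "is_onset_s": [1.0, 11.0, 21.0],
            "is_duration_s": [1.0, 2.0, 1.5],
            "go_s": [2.0, 13.0, 22.5],
        }
    )
    spikes = pd.DataFrame(
        {
            "unit_id": ["u0", "u0", "u0", "u1"],
            "trial_id": [1, 1, 2, 2],
            "t_s": [0.100, 0.120, 1.050, 0.500],
        }
    )
    waveforms = pd.DataFrame(
        {"unit_id": ["u0"] * 4, "sample_idx": range(4), "mean_v": [0, -1.0, 0.4, 0.1],
         "sd_v": [0.1] * 4}
    )
    units = pd.DataFrame({"unit_id": ["u0", "u1"], "tasks": ["novelmap"] * 2})
    return session_io.Session("toy", "novelmap", trials, spikes, waveforms, units)


def poisson_tensor(rng, n_units=20, n_trials=60, n_bins=10, rate_hz=8.0, width_ms=50.0):
    """Signal-free Poisson count tensor + balanced 3-level labels."""
    lam = rate_hz * width_ms / 1000.0
    counts = rng.poisson(lam, size=(n_units, n_trials, n_bins)).astype(float)
    labels = np.tile(np.array(["a1", "a2", "a3"]), n_trials // 3 + 1)[:n_trials]
    return counts, labels
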