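import numpy as np
import pytest

import eegdistract as ed


@pytest.fixture(scope="session")
def small_config():
    """One subject, one short session: 10 balanced trials."""
    return ed.SyntheticConfig(
        n_subjects=1, n_sessions_per_subject=1, n_trials_per_session=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return ed.generate_session(small_config, "S01")


@pytest.fixture(scope="session")
def effect_epochset():
    """180 epochs with a strong alpha-band class difference."""
    cfg = ed.SyntheticConfig(
        n_subjects=1, n_sessions_per_subject=2, effect_amplitude=3.0, seed=3,
    )
    return ed.generate_epochset(cfg)


@pytest.fixture(scope="session")
def null_epochset():
    """90 epochs with no class difference (effect_amplitude = 0)."""
    cfg = ed.SyntheticConfig(
        n_subjects=1, n_sessions_per_subject=1, effect_amplitude=0.0, seed=5,
    )
    return ed.generate_epochset(cfg)


@pytest.fixture(scope="session")
def bank12():
    return ed.design_filter_bank("proposed12", 512.0)


@pytest.fixture(scope="session")
def effect_covariances(effect_epochset, bank12):
    return ed.band_covariances(effect_epochset.data_array(), bank12)


def make_white_epochset(n_trials=8, n_channels=4, fs=128.0, window_s=1.0,
                        seed=0):
    """Tiny labelled epoch set of white noise (both classes identical)."""
    rng = np.random.default_rng(seed)
    n = int(window_s * fs)
    epochs = []
    for t in range(n_trials):
        for k in range(2):  # two epochs per trial
            epochs.append(ed.Epoch(
                data=rng.standard_normal((n_channels, n)),
                label="attentive" if t % 2 == 0 else "distracted",
                trial_id=t + 1, subject_id="S01", session_id=1,
                fs=fs, window_s=window_s,
            ))
    return ed.EpochSet(epochs)
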