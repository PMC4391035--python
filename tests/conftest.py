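"""Session-scoped synthetic fixtures shared across the suite.

Two scales are used: ``tiny`` (24-channel montage, 8 trials per object at
200 Hz) for algorithmic checks where channel count is irrelevant, and
``small`` (full 64-channel montage, 10 trials per object at 200 Hz) where
montage structure matters. The full study-scale run lives in the
acceptance tests only.
"""

import numpy as np
import pytest

import graspdecode as gd

TINY_INFORMATIVE = ("FC1", "C3", "CP5", "CP1", "CP2", "P3", "F3", "FC5")


@pytest.fixture(scope="session")
def tiny_spec():
    return gd.SyntheticSpec(
        n_channels=24, trials_per_object=8, fs=200.0,
        informative_channels=TINY_INFORMATIVE, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_spec):
    return gd.simulate_recording(tiny_spec)


@pytest.fixture(scope="session")
def tiny_processed(tiny_sim):
    rec, _ = tiny_sim
    cfg = gd.PipelineConfig(seed=11)
    prelag, trials, ser = gd.preprocess(rec, cfg)
    return prelag, trials, ser


@pytest.fixture(scope="session")
def small_spec():
    return gd.SyntheticSpec(trials_per_object=10, fs=200.0, seed=5)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return gd.simulate_recording(small_spec)


@pytest.fixture(scope="session")
def small_processed(small_sim):
    rec, _ = small_sim
    cfg = gd.PipelineConfig(seed=5)
    prelag, trials, ser = gd.preprocess(rec, cfg)
    return prelag, trials, ser


@pytest.fixture(scope="session")
def pulse_classification():
    """Synthetic recording whose between-object differences are confined to
    a velocity pulse in the first ~450 ms of each 1.5 s movement, segmented
    with margins covering -1 .. 3 s around onset."""
    from graspdecode.synthetic_data import BumpProfile as P

    amps = {"can": 10.0, "card": 18.0, "cd": 26.0, "penny": 34.0,
            "screwdriver": 42.0}
    profiles = {o: (P(a, 0.10, 0.05, 0.22, 0.05),
                    P(0.3 * a, 0.12, 0.05, 0.24, 0.05),
                    P(0.2 * a, 0.08, 0.04, 0.20, 0.05))
                for o, a in amps.items()}
    spec = gd.SyntheticSpec(
        n_channels=24, trials_per_object=8, fs=200.0,
        informative_channels=("FC1", "C3", "CP5", "CP1", "CP2", "P3",
                              "F3", "FC5"),
        duration_mean=1.5, duration_sd=0.0, rest_range=(1.4, 2.2),
        motor_noise_frac=0.3, object_profiles=profiles, seed=21)
    rec, _ = gd.simulate_recording(spec)
    cfg = gd.PipelineConfig(cv_folds=5, seed=3)
    _, trials, _ = gd.preprocess(rec, cfg, pre_ms=1100, post_ms=3100,
                                 post_from="onset")
    return trials, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
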