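import numpy as np
import pytest

import mooneyrsa as m
from mooneyrsa.preprocess import baseline_correct


@pytest.fixture(scope="session")
def tiny_design():
    """6 sets over 4 runs (2 introduced per run): full structural miniature."""
    d = m.build_design(n_real_sets=4, n_catch_sets=2, n_runs=4, seed=11)
    d.validate()
    return d


@pytest.fixture(scope="session")
def small_epochs(tiny_design):
    """3 subjects, 24 sensors, 20 Hz epochs with the default planted structure."""
    gt = m.make_ground_truth(tiny_design.n_sets, n_sensors=24, seed=21)
    ep = m.simulate_sensor_epochs(
        tiny_design, gt, n_subjects=3, sampling_rate=20.0, seed=31
    )
    return m.normalize_across_sensors(baseline_correct(ep))


@pytest.fixture(scope="session")
def small_ground_truth(tiny_design):
    return m.make_ground_truth(tiny_design.n_sets, n_sensors=24, seed=21)


@pytest.fixture(scope="module")
def recovery_session():
    """A moderate-scale session for planted-structure recovery checks:
    12 real sets, 4 subjects, 48 sensors, 20 Hz."""
    design = m.build_design(n_real_sets=12, n_catch_sets=0, n_runs=5, seed=1)
    gt = m.make_ground_truth(design.n_sets, n_sensors=48, seed=2)
    ep = m.simulate_sensor_epochs(design, gt, n_subjects=4, sampling_rate=20.0, seed=3)
    ep = m.normalize_across_sensors(baseline_correct(ep))
    return design, gt, ep
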