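import numpy as np
import pytest

import flukeprop as fp


@pytest.fixture(scope="session")
def blue_cfg():
    """Small blue-whale-scale deployment: 60 routine beats, one lunge."""
    return fp.SimConfig(n_routine_beats=60, n_lunges=1, seed=11)


@pytest.fixture(scope="session")
def deployment(blue_cfg):
    return fp.generate_deployment(blue_cfg)


@pytest.fixture(scope="session")
def fitted(deployment):
    morph, series, truth = deployment
    model = fp.SwimmingPerformance(
        series, morph, lunges=truth.lunge_times, whale_id="sim-11"
    )
    return model.fit()


@pytest.fixture(scope="session")
def blue_morph():
    """Blue-whale-scale morphology from printed routine means."""
    return fp.WhaleMorphology(
        species="blue",
        body_length_m=22.41,
        max_diameter_m=0.2 * 22.41,
        fluke_chord_m=1.2,
        fluke_area_m2=15.0,
        wetted_area_m2=200.0,
        mass_kg=1.0e5,
        added_mass_coeff=0.03,
    )


def make_series(time_s, gyro, speed=None, depth=None, fs=10.0):
    n = len(time_s)
    if speed is None:
        speed = np.full(n, 2.0)
    if depth is None:
        depth = np.full(n, 20.0)
    return fp.TagSeries(np.asarray(time_s), np.asarray(gyro), np.asarray(speed),
                        np.asarray(depth), sampling_hz=fs)
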