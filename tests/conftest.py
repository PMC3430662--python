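"""Shared fixtures: synthetic subjects, trials and calibration runs.

Calibration runs are expensive, so they are computed once per session and
shared between the calibration unit tests and the acceptance suite.
"""

from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import tahill as th
from tahill.calibration import CalibrationSpec, calibrate, predict

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def subject():
    return th.make_subject(1)


@pytest.fixture(scope="session")
def hop_trial(subject):
    return th.simulate_dynamic_trial(subject, "hop", seed=50)


@pytest.fixture(scope="session")
def calib_setup():
    """Synthetic subject with a deliberately mis-set baseline model, plus
    calibration and held-out trials (noiseless and noisy variants)."""
    s = th.make_subject(3)
    base = {m: replace(p, f_max=p.f_max / 1.3,
                       activation=replace(p.activation, shape_factor=-0.5))
            for m, p in s.muscle_params.items()}
    spec = CalibrationSpec(free_parameters=("f_max_scale", "shape_factor"),
                           seed=0, n_starts=2, max_evaluations=120)
    make = th.simulate_dynamic_trial
    return {
        "subject": s,
        "base": base,
        "spec": spec,
        "cal": [make(s, "hop", seed=11).series, make(s, "run", seed=12).series],
        "novel": [make(s, "hop", seed=21).series, make(s, "run", seed=22).series],
        "cal_noisy": [make(s, "hop", seed=11, envelope_noise_sigma=0.05).series,
                      make(s, "run", seed=12, envelope_noise_sigma=0.05).series],
        "novel_noisy": [make(s, "hop", seed=21, envelope_noise_sigma=0.05).series,
                        make(s, "run", seed=22, envelope_noise_sigma=0.05).series],
    }


@pytest.fixture(scope="session")
def ss_calibration(calib_setup):
    """Calibration + held-out prediction with the matched (generating) SEE."""
    s = calib_setup["subject"]
    result = calibrate(calib_setup["spec"], calib_setup["cal"], s.see_ss,
                       calib_setup["base"])
    outputs = predict(result, calib_setup["novel"], s.see_ss)
    return result, outputs


@pytest.fixture(scope="session")
def generic_calibration(calib_setup):
    """Same pipeline but calibrated and predicted with the (mismatched)
    generic SEE."""
    s = calib_setup["subject"]
    result = calibrate(calib_setup["spec"], calib_setup["cal"], s.see_generic,
                       calib_setup["base"])
    outputs = predict(result, calib_setup["novel"], s.see_generic)
    return result, outputs


@pytest.fixture(scope="session")
def noisy_calibration(calib_setup):
    """Matched-SEE calibration with noisy EMG envelopes."""
    s = calib_setup["subject"]
    result = calibrate(calib_setup["spec"], calib_setup["cal_noisy"], s.see_ss,
                       calib_setup["base"])
    outputs = predict(result, calib_setup["novel_noisy"], s.see_ss)
    return result, outputs
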