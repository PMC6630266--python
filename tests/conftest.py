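"""Shared fixtures: small synthetic cohorts, filters, calibrations.

Everything is generated programmatically at test time; session scope keeps
the expensive cohort builds to one per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgfall.preprocessing import apply_filter, design_bandpass
from emgfall.segmentation import calibrate_dataset, segmentation_params
from emgfall.synthetic import generate_dataset


@pytest.fixture(scope="session")
def bandpass_1500():
    return design_bandpass(1500.0)


@pytest.fixture(scope="session")
def easy_cohort_100(bandpass_1500):
    """100 recordings (5 subjects x 4 gestures x 5 reps), easy noise, filtered."""
    recs = generate_dataset(5, 5, seed=7, noise="easy")
    return [apply_filter(r, bandpass_1500) for r in recs]


@pytest.fixture(scope="session")
def easy_calibration(easy_cohort_100):
    """Pooled thresholds + energy series for the 100-recording cohort."""
    calib, series = calibrate_dataset(easy_cohort_100, 100)
    params = segmentation_params(1500.0, 100)
    return calib, series, params


@pytest.fixture(scope="session")
def tiny_cohort(bandpass_1500):
    """12 recordings (3 subjects x 4 gestures x 1 rep), for fast fold tests."""
    recs = generate_dataset(3, 1, seed=21, noise="easy")
    return [apply_filter(r, bandpass_1500) for r in recs]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
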