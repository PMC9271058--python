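"""Shared fixtures: small synthetic scenarios generated at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import coralvar as cv


@pytest.fixture(scope="session")
def scenario():
    """Default fjord scenario with a fixed seed."""
    return cv.default_scenario(seed=11)


@pytest.fixture(scope="session")
def station_stats(scenario):
    return cv.station_season_stats(scenario)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Default scenario with every instrument-noise SD at zero."""
    base = cv.default_scenario(seed=13)
    return dataclasses.replace(
        base,
        noise=cv.NoiseModel(
            balance_sd_g=0.0,
            o2_probe_sd=0.0,
            calliper_sd_mm=0.0,
            blank_drift=2.0,
            blank_sd=0.0,
        ),
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_scenario):
    specimens, weighings, geometry, incubations, truth = cv.gen_coral_cohort(
        noiseless_scenario
    )
    return specimens, weighings, geometry, incubations, truth


@pytest.fixture(scope="session")
def dataset(scenario, tmp_path_factory):
    """Full synthetic input-file set written to disk once per session."""
    ds = cv.generate_scenario(scenario)
    path = tmp_path_factory.mktemp("inputs")
    ds.write(path)
    return ds, path


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
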