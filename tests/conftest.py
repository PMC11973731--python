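"""Shared fixtures: reference models, ideal devices, small calibrated cohorts."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from reomsim.cohort import GOLD1_DEFAULT, GOLD4_DEFAULT, generate_cohort
from reomsim.mechanics import LungModel
from reomsim.simulate import DeviceModel, NoiseSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kelvin_model() -> LungModel:
    """Two-compartment model whose R5/R19 equal the severe-group medians."""
    return LungModel(Raw=0.365, Rve=3.87, tau_ve=0.1, Crs=1.0)


@pytest.fixture(scope="session")
def single_compartment() -> LungModel:
    return LungModel(Raw=0.5, Rve=0.0, tau_ve=0.1, Crs=2.0)


@pytest.fixture(scope="session")
def ideal_device() -> DeviceModel:
    """Essentially transparent sensor, no release overshoot."""
    return DeviceModel(sensor_fc=1e6, p_overshoot=1.0)


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseSpec:
    return NoiseSpec().quiet()


@pytest.fixture(scope="session")
def small_cohort():
    """3 + 3 calibrated participants (shared; treat as read-only)."""
    spec1 = dataclasses.replace(GOLD1_DEFAULT, n=3)
    spec4 = dataclasses.replace(GOLD4_DEFAULT, n=3)
    return generate_cohort(spec1, spec4, seed=1234)
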