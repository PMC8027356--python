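"""Shared fixtures: synthetic traces and cohort frames built at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from oxyscan.synthetic_cohort import (
    CellClassModel,
    ClassJitter,
    SimulationConfig,
    default_config,
)
from oxyscan.trace_io import OxygenscanTrace


def nominal_po2_profile(
    plateau_s: float = 100.0,
    deox_s: float = 1300.0,
    reox_s: float = 280.0,
    po2_high: float = 150.0,
    po2_low: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """The standard cycle at 1 Hz: plateau, linear decline, linear rise."""
    t = np.arange(0.0, plateau_s + deox_s + reox_s + 1.0)
    t1, t2 = plateau_s, plateau_s + deox_s
    po2 = np.where(
        t <= t1,
        po2_high,
        np.where(
            t <= t2,
            po2_high + (t - t1) / deox_s * (po2_low - po2_high),
            po2_low + (t - t2) / reox_s * (po2_high - po2_low),
        ),
    )
    return t, po2


def logistic_trace(
    upper: float, lower: float, p50: float, slope: float
) -> OxygenscanTrace:
    """Noiseless trace whose EI is a logistic function of pO2 (same curve on
    both the deoxygenation and reoxygenation paths)."""
    from scipy.special import expit

    t, po2 = nominal_po2_profile()
    ei = lower + (upper - lower) * expit((po2 - p50) / slope)
    return OxygenscanTrace(t, po2, ei)


@pytest.fixture(scope="session")
def calibrated_config() -> SimulationConfig:
    return default_config()


@pytest.fixture(scope="session")
def noiseless_config(calibrated_config) -> SimulationConfig:
    """The calibrated config with all randomness switched off — jitter and
    measurement noise zero; biomarker links keep their noise."""
    return dataclasses.replace(
        calibrated_config,
        jitter=ClassJitter(),
        measurement_noise_sd=0.0,
        po2_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def normal_control_config(calibrated_config) -> SimulationConfig:
    """Scenario config for non-sickling red cells: a single flat class
    (floor equal to ceiling up to 1%), no dense cells, no lysis."""
    flat = CellClassModel("f_cell", 0.60, 0.595, 10.0, 5.0, 0.0, 0.0)
    inert = CellClassModel("non_f_sickle", 0.60, 0.595, 10.0, 5.0, 0.0, 0.0)
    dense = CellClassModel("dense", 0.30, 0.03, 38.0, 8.0, 0.85, 0.35)
    return dataclasses.replace(
        calibrated_config,
        class_models=(flat, inert, dense),
        fcell_floor_hbf_slope=0.0,
        jitter=ClassJitter(),
        measurement_noise_sd=0.0,
        po2_noise_sd=0.0,
    )
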