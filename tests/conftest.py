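"""Shared fixtures: toy crystal, simulated series, DED maps.

Everything is generated at run time from the synthetic-data module; module
scope keeps the more expensive forward simulations to one evaluation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from trxmap import (
    KineticParams,
    build_toy_mof,
    default_delay_grid,
    simulate_timeseries,
    structure_factors,
)
from trxmap.density_maps import ded_map
from trxmap.reflections import difference_amplitudes, reference_amplitudes

HMAX, DMIN = 12, 1.6


@pytest.fixture(scope="session")
def species():
    return build_toy_mof()


@pytest.fixture(scope="session")
def kin():
    return KineticParams()


@pytest.fixture(scope="session")
def grid():
    return default_delay_grid()


@pytest.fixture(scope="session")
def f_ground(species):
    return structure_factors(species.ground, hmax=HMAX, dmin=DMIN)


@pytest.fixture(scope="session")
def series(species, kin, grid):
    """Noiseless three-species amplitude series at the default conditions."""
    return simulate_timeseries(
        species, kin, grid, excited_fraction=1.0, noise_sd=0.0, seed=0,
        hmax=HMAX, dmin=DMIN,
    )


@pytest.fixture(scope="session")
def ded_maps(series, grid, f_ground):
    ref = reference_amplitudes(series, grid)
    return {
        t: ded_map(difference_amplitudes(series[t], ref), f_ground)
        for t in grid.delays
    }


@pytest.fixture(scope="session")
def tr_only_maps(species, kin, grid, f_ground):
    """Noiseless transient-only series at the study's 0.20 yield."""
    ser = simulate_timeseries(
        species, kin, grid, excited_fraction=1.0, noise_sd=0.0, seed=0,
        peaks=(0.0, 0.20, 0.0), hmax=HMAX, dmin=DMIN,
    )
    ref = reference_amplitudes(ser, grid)
    return {
        t: ded_map(difference_amplitudes(ser[t], ref), f_ground)
        for t in grid.delays
    }


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel(), b.ravel()
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
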