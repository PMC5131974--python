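"""Shared fixtures: small synthetic oceans and pre-run simulations.

Expensive paired simulations are session-scoped so several tests can share
one run. All randomness is seeded; nothing is read from disk.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import thermodrift as td

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_forcing() -> td.ForcingSeries:
    """12×12 basin, 3 years — the workhorse for engine tests."""
    return td.generate_double_gyre(basin_size=(12, 12), n_years=3.0,
                                   T_equator=28.0, T_pole=8.0,
                                   seasonal_amplitude=4.0, lat0=10.0)


@pytest.fixture(scope="session")
def five_species() -> td.SpeciesSet:
    """Five widely spaced optima spanning the small basin's temperatures."""
    return td.SpeciesSet(np.array([10.0, 15.0, 20.0, 25.0, 30.0]))


@pytest.fixture(scope="session")
def gyre_forcing() -> td.ForcingSeries:
    """20×20 basin, 12 years — the atlas-scale synthetic ocean."""
    return td.generate_double_gyre(basin_size=(20, 20), n_years=12.0, lat0=6.0)


@pytest.fixture(scope="session")
def species50() -> td.SpeciesSet:
    return td.SpeciesSet.regular()


@pytest.fixture(scope="session")
def paired_run_bacteria(gyre_forcing, species50):
    """Calibrated paired Eulerian run at the heterotrophic-bacteria rate
    (0.14 d⁻¹), with and without advection, plus its atlas."""
    cfg = td.SimConfig(duration_years=12.0, target_mean_growth=0.14, rng_seed=1)
    params = td.calibrate_growth(cfg, gyre_forcing, species50)
    sp = species50.with_params(params)
    out_a = td.run_eulerian(cfg, gyre_forcing, sp)
    out_na = td.run_eulerian(replace(cfg, advection_enabled=False), gyre_forcing, sp)
    atlas = td.advective_differential(
        out_a, out_na, (4 * 365.0, 12 * 365.0), forcing=gyre_forcing, rate=0.14
    )
    return out_a, out_na, atlas


@pytest.fixture(scope="session")
def bacteria_atlas(paired_run_bacteria) -> td.DifferentialAtlas:
    return paired_run_bacteria[2]
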