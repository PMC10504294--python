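"""Shared fixtures: small solved flow fields reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from nanotear.constants import FluidProperties
from nanotear.flow_field import solve_flow
from nanotear.synthetic_data import generate_foam, generate_tip_array


@pytest.fixture(scope="session")
def water() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def small_tips():
    """A reduced 2x2 nanotip array (1-um tips) for fast flow solves."""
    return generate_tip_array(n_x=2, n_y=2, diameter=200e-9, length=1e-6, gap=0.8e-6)


@pytest.fixture(scope="session")
def small_tip_field(small_tips, water):
    return solve_flow(small_tips, water, inlet_speed=5.5e-4, spacing=50e-9)


@pytest.fixture(scope="session")
def small_foam():
    """A reduced foam slab (50-um pores in a 200x150x150 um box)."""
    return generate_foam(50e-6, (200e-6, 150e-6, 150e-6), porosity=0.9, seed=11)


@pytest.fixture(scope="session")
def paper_tip_field(water):
    """The bench-condition 5x5 nanotip array field (d = 200 nm, L = 5 um,
    1-um gaps, 5.5e-4 m/s at 45 degrees), solved at 50-nm spacing."""
    tips = generate_tip_array()
    return tips, solve_flow(tips, water, inlet_speed=5.5e-4, spacing=50e-9)


@pytest.fixture(scope="session")
def thickness_series(water):
    """Collision fractions for three foam slab thicknesses (fixed seeds)."""
    from nanotear.foam_transport import track_particles

    fractions = []
    for lx in (100e-6, 200e-6, 300e-6):
        foam = generate_foam(50e-6, (lx, 120e-6, 120e-6), 0.9, seed=5)
        fld = solve_flow(foam, water, inlet_speed=1e-3, spacing=4e-6, tolerance=1e-5)
        res = track_particles(fld, foam, n=150, dt=1e-3, max_time=1.0, seed=8)
        fractions.append(res.collision_fraction)
    return fractions


@pytest.fixture(scope="session")
def small_foam_field(small_foam, water):
    # 1e-5 mass-conservation tolerance: an order looser than the default,
    # still far below every statistic asserted on this fixture
    return solve_flow(small_foam, water, inlet_speed=1e-3, spacing=4e-6, tolerance=1e-5)
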