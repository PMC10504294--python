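"""Brownian particle tracking: forces, diffusion, capture statistics."""

import math

import numpy as np
import pytest

from nanotear.constants import PhysicalConstants, FluidProperties, WATER
from nanotear.foam_transport import (
    SphericalParticle,
    brownian_force,
    drag_force,
    extrapolate_collision_probability,
    track_particles,
)
from nanotear.flow_field import solve_flow
from nanotear.synthetic_data import generate_foam

ROOM = PhysicalConstants()


class TestDragForce:
    def test_equilibrium_zero_force(self):
        p = SphericalParticle(velocity=np.array([1e-4, 0, 0]))
        f = drag_force(p, np.array([1e-4, 0, 0]))
        assert np.allclose(f, 0.0)

    def test_near_wall_magnitude(self):
        p = SphericalParticle(radius=0.5e-6)
        f = drag_force(p, np.array([5e-5, 0, 0]))
        assert np.linalg.norm(f) == pytest.approx(4.7e-13, rel=0.01)

    def test_linearity_in_slip_velocity(self):
        p = SphericalParticle()
        f1 = drag_force(p, np.array([3e-5, 1e-5, 0]))
        f2 = drag_force(p, np.array([6e-5, 2e-5, 0]))
        assert np.allclose(f2, 2.0 * f1)

    def test_response_time_definition(self):
        p = SphericalParticle(radius=0.5e-6, density=1000.0)
        tau = p.response_time(WATER)
        assert tau == pytest.approx(p.mass / (3 * math.pi * 1e-3 * 1e-6), rel=1e-12)
        assert tau < 1e-6  # far below practical time steps


class TestBrownianForce:
    def test_variance_matches_closed_form(self):
        p = SphericalParticle()
        dt = 1e-4
        rng = np.random.default_rng(12)
        samples = brownian_force(p, ROOM, dt, rng, size=100_000)
        var_expected = (
            12 * math.pi * ROOM.k_B * 1e-3 * ROOM.temperature * p.radius / dt
        )
        var = samples.var(axis=0)
        se = var_expected * math.sqrt(2.0 / len(samples))
        assert np.all(np.abs(var - var_expected) < 3 * se)
        assert np.all(np.abs(samples.mean(axis=0)) < 3 * math.sqrt(var_expected / len(samples)))

    def test_cold_limit_vanishes(self):
        p = SphericalParticle()
        rng = np.random.default_rng(0)
        f = brownian_force(p, PhysicalConstants(temperature=1e-20), 1e-4, rng)
        assert np.linalg.norm(f) < 1e-20

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            brownian_force(SphericalParticle(), ROOM, 0.0, np.random.default_rng(0))

    def test_seeded_stream_reproducible(self):
        p = SphericalParticle()
        a = brownian_force(p, ROOM, 1e-4, np.random.default_rng(3), size=10)
        b = brownian_force(p, ROOM, 1e-4, np.random.default_rng(3), size=10)
        assert np.array_equal(a, b)


class TestTracking:
    def test_free_streaming_all_escape(self, water):
        """Uniform flow, no obstacles, no noise: every particle exits."""
        fld = solve_flow(
            None, water, inlet_speed=1e-3, spacing=1e-5, extent=(2e-4, 1e-4, 1e-4)
        )
        cold = PhysicalConstants(temperature=1e-12)
        res = track_particles(fld, None, n=50, dt=5e-3, max_time=0.5, seed=1, constants=cold)
        assert res.n_escaped == 50 and res.n_collided == 0
        assert res.n_collided + res.n_escaped + res.n_in_domain == res.n_released

    def test_free_diffusion_msd_is_6dt(self):
        """Quiescent, unbounded: ensemble MSD(t) = 6 D t within 3 SE."""
        n, dt, steps = 500, 1e-4, 100
        res = track_particles(None, None, n=n, dt=dt, max_time=steps * dt, seed=4)
        p = SphericalParticle()
        d_coef = p.diffusivity(WATER, ROOM)
        t = steps * dt
        disp = res.final_positions - res.initial_positions
        msd = float((disp**2).sum(axis=1).mean())
        se = math.sqrt(24.0 / n) * d_coef * t  # SD of a chi2_3 mean
        assert abs(msd - 6 * d_coef * t) < 3 * se

    def test_counts_partition_and_determinism(self, small_foam_field, small_foam):
        kw = dict(n=100, dt=1e-3, max_time=0.5, seed=7)
        res = track_particles(small_foam_field, small_foam, **kw)
        assert res.n_collided + res.n_escaped + res.n_in_domain == 100
        assert res.n_collided > 0
        res2 = track_particles(small_foam_field, small_foam, **kw)
        assert np.array_equal(res.final_positions, res2.final_positions)

    def test_step_size_guard(self, small_foam_field, small_foam):
        with pytest.raises(ValueError, match="time step"):
            track_particles(small_foam_field, small_foam, n=10, dt=1.0, max_time=2.0, seed=1)

    def test_overdamped_and_inertial_agree(self, small_foam_field, small_foam):
        """The exact OU integrator reduces to the overdamped limit for dt >> tau_p."""
        kw = dict(n=150, dt=1e-3, max_time=0.4)
        a = track_particles(small_foam_field, small_foam, seed=21, integrator="overdamped", **kw)
        b = track_particles(small_foam_field, small_foam, seed=22, integrator="inertial", **kw)
        pa, pb = a.collision_fraction, b.collision_fraction
        pool = (a.n_collided + b.n_collided) / (a.n_released + b.n_released)
        se = math.sqrt(pool * (1 - pool) * (1 / a.n_released + 1 / b.n_released))
        assert abs(pa - pb) <= 3 * se + 1e-12


@pytest.fixture(scope="module")
def thickness_series(water):
    fractions = []
    for lx in (100e-6, 200e-6, 300e-6):
        foam = generate_foam(50e-6, (lx, 120e-6, 120e-6), 0.9, seed=5)
        fld = solve_flow(foam, water, inlet_speed=1e-3, spacing=4e-6, tolerance=1e-5)
        res = track_particles(fld, foam, n=150, dt=1e-3, max_time=1.0, seed=8)
        fractions.append(res.collision_fraction)
    return fractions


class TestCaptureTrends:
    def test_collision_fraction_rises_with_thickness(self, thickness_series):
        assert fractions_non_decreasing(thickness_series)

    def test_collision_fraction_falls_with_porosity(self, water):
        fractions = []
        for porosity in (0.80, 0.88, 0.96):
            foam = generate_foam(50e-6, (150e-6, 120e-6, 120e-6), porosity, seed=6)
            fld = solve_flow(foam, water, inlet_speed=1e-3, spacing=4e-6, tolerance=1e-5)
            res = track_particles(fld, foam, n=150, dt=1e-3, max_time=1.0, seed=9)
            fractions.append(res.collision_fraction)
        assert fractions[0] >= fractions[1] >= fractions[2]


def fractions_non_decreasing(seq):
    return all(b >= a for a, b in zip(seq, seq[1:]))


class TestBenchFoam:
    def test_bench_condition_capture_and_extrapolation(self, water):
        """1-mm/s influent through the 520x420x420-um, 200-um-pore slab:
        a desk-scale ensemble is captured at a recorded fraction and the
        3-mm extrapolation can only increase it."""
        foam = generate_foam(200e-6, (520e-6, 420e-6, 420e-6), 0.95, seed=17)
        fld = solve_flow(foam, water, inlet_speed=1e-3, spacing=10e-6, tolerance=1e-5)
        res = track_particles(fld, foam, n=400, dt=1e-3, max_time=3.0, seed=18)
        assert res.n_collided + res.n_escaped + res.n_in_domain == 400
        assert 0.0 < res.collision_fraction < 1.0
        ratio = 3e-3 / foam.domain_extent[0]
        extrapolated = extrapolate_collision_probability(
            1.0 - res.collision_fraction, ratio
        )
        assert extrapolated >= res.collision_fraction


class TestExtrapolation:
    @pytest.mark.parametrize(
        "escape, ratio, expected",
        [(0.1, 6.0, 0.999999), (1.0, 3.0, 0.0), (0.5, 2.0, 0.75), (0.0, 1.0, 1.0)],
    )
    def test_independent_layer_arithmetic(self, escape, ratio, expected):
        assert extrapolate_collision_probability(escape, ratio) == pytest.approx(
            expected, abs=1e-12
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            extrapolate_collision_probability(1.2, 2.0)
        with pytest.raises(ValueError):
            extrapolate_collision_probability(0.5, 0.0)
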