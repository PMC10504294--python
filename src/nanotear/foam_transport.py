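"""Brownian-dynamics tracking of spherical bacteria through a foam flow field.

A bacterium is approximated as a 1-um sphere advected by the local flow,
dragged by Stokes friction and kicked by a Brownian force of per-component
magnitude ``sqrt(12 pi k_B mu T r_p / dt)`` (white noise consistent with
the Stokes drag through the fluctuation-dissipation relation, diffusivity
D = k_B T / (6 pi mu r_p)).  Gravity is negligible for micron particles in
water and is omitted.

Because the velocity response time tau_p = m_p / (3 pi mu d) is ~1e-7 s —
far below any practical time step — the default integrator is the
overdamped limit  dr = u dt + sqrt(2 D dt) xi.  An inertial integrator
(the exact Ornstein-Uhlenbeck discretization of the underdamped Langevin
equation, valid for any dt/tau_p) is provided for verification.

Particles are released uniformly over the fluid part of the inlet face,
stick permanently to the foam wall at first contact (centre within one
radius of the solid), and escape through the outlet face; lateral
boundaries are reflecting, mirroring the symmetry conditions of the flow
solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .constants import PhysicalConstants, FluidProperties, WATER
from .flow_field import FlowField, sample_velocity
from .synthetic_data import FoamGeometry

__all__ = [
    "SphericalParticle",
    "TransportResult",
    "drag_force",
    "brownian_force",
    "track_particles",
    "extrapolate_collision_probability",
]


@dataclass
class SphericalParticle:
    """A spherical bacterium surrogate (default: 1-um cell at water density)."""

    radius: float = 0.5e-6  # m
    density: float = 1000.0  # kg/m^3
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0:
            raise ValueError("radius and density must be positive")
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)

    @property
    def mass(self) -> float:
        return self.density * (4.0 / 3.0) * math.pi * self.radius**3

    def friction(self, fluid: FluidProperties) -> float:
        """Stokes friction coefficient 3 pi mu d, N s/m."""
        return 3.0 * math.pi * fluid.dynamic_viscosity * (2.0 * self.radius)

    def response_time(self, fluid: FluidProperties) -> float:
        """Velocity response time tau_p = m_p / (3 pi mu d), s."""
        return self.mass / self.friction(fluid)

    def diffusivity(self, fluid: FluidProperties, constants: PhysicalConstants) -> float:
        """Stokes-Einstein diffusivity k_B T / (6 pi mu r_p), m^2/s."""
        return constants.k_B * constants.temperature / (
            6.0 * math.pi * fluid.dynamic_viscosity * self.radius
        )


@dataclass
class TransportResult:
    """Outcome of a particle-tracking run; counts partition the release."""

    n_released: int
    n_collided: int
    n_escaped: int
    n_in_domain: int
    collision_points: np.ndarray  # (n_collided, 3), first-contact positions
    initial_positions: np.ndarray
    final_positions: np.ndarray
    elapsed_time: float
    trajectories: Optional[np.ndarray] = None  # (n_saved, n_particles, 3)

    def __post_init__(self) -> None:
        if self.n_collided + self.n_escaped + self.n_in_domain != self.n_released:
            raise ValueError("transport counts do not partition the released particles")

    @property
    def collision_fraction(self) -> float:
        return self.n_collided / self.n_released if self.n_released else 0.0

    @property
    def escape_fraction(self) -> float:
        return self.n_escaped / self.n_released if self.n_released else 0.0

    def collisions_to_csv(self, path) -> None:
        """Write first-collision positions as CSV (x_m, y_m, z_m)."""
        import pandas as pd

        pd.DataFrame(
            self.collision_points, columns=["x_m", "y_m", "z_m"]
        ).to_csv(path, index=False)


def drag_force(
    particle: SphericalParticle,
    local_velocity,
    fluid: FluidProperties = WATER,
) -> np.ndarray:
    """Stokes drag F_D = 3 pi mu d (u - v) = (m_p / tau_p)(u - v), N."""
    u = np.asarray(local_velocity, dtype=float)
    return particle.friction(fluid) * (u - particle.velocity)


def brownian_force(
    particle: SphericalParticle,
    constants: PhysicalConstants,
    dt: float,
    rng: np.random.Generator,
    fluid: FluidProperties = WATER,
    size: int = 1,
) -> np.ndarray:
    """Brownian force samples: each component zeta * sqrt(12 pi k_B mu T r_p / dt).

    ``zeta`` is standard normal; returns shape (size, 3) (or (3,) if size=1).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    amp = math.sqrt(
        12.0
        * math.pi
        * constants.k_B
        * fluid.dynamic_viscosity
        * constants.temperature
        * particle.radius
        / dt
    )
    out = amp * rng.standard_normal((size, 3))
    return out[0] if size == 1 else out


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mirror-reflect positions into [lo, hi] per axis."""
    span = hi - lo
    x = np.mod(pos - lo, 2.0 * span)
    x = np.where(x > span, 2.0 * span - x, x)
    return lo + x


def track_particles(
    field: FlowField | None,
    foam: FoamGeometry | None,
    n: int,
    dt: float,
    max_time: float,
    seed: int,
    particle: SphericalParticle | None = None,
    constants: PhysicalConstants | None = None,
    fluid: FluidProperties | None = None,
    integrator: Literal["overdamped", "inertial"] = "overdamped",
    release_positions: np.ndarray | None = None,
    extent: tuple[float, float, float] | None = None,
    save_every: int = 0,
) -> TransportResult:
    """Track ``n`` Brownian particles through the foam until contact or escape.

    Particles advance by the overdamped Langevin update (or the exact OU
    inertial update), freeze at first wall contact, and escape across the
    x+ outlet.  ``field=None`` means quiescent fluid, ``foam=None`` no
    obstacles, ``extent=None`` an unbounded bath (then nothing escapes) —
    the degenerate combinations used by the diffusion benchmarks.
    """
    if dt <= 0 or max_time <= 0:
        raise ValueError("dt and max_time must be positive")
    particle = particle or SphericalParticle()
    constants = constants or PhysicalConstants()
    fluid = fluid or (field.fluid if field is not None else WATER)
    rng = np.random.default_rng(seed)

    if extent is None and field is not None:
        extent = field.extent
    bounded = extent is not None
    if bounded:
        lo = np.zeros(3)
        hi = np.asarray(extent, dtype=float)

    diff = particle.diffusivity(fluid, constants)
    sigma_step = math.sqrt(2.0 * diff * dt)

    # guard: one step must not be able to cross a grid cell
    if field is not None:
        speeds = np.abs(
            np.concatenate([field.u.ravel(), field.v.ravel(), field.w.ravel()])
        )
        max_step = speeds.max() * dt + 3.0 * sigma_step
        if max_step > field.spacing:
            raise ValueError(
                f"time step too large: worst-case step {max_step:.3g} m exceeds "
                f"the grid spacing {field.spacing:.3g} m"
            )

    if release_positions is not None:
        pos = np.array(release_positions, dtype=float)
        if pos.shape != (n, 3):
            raise ValueError("release_positions must have shape (n, 3)")
    else:
        if not bounded:
            pos = np.zeros((n, 3))
        else:
            pos = np.empty((n, 3))
            pos[:, 0] = particle.radius
            pos[:, 1] = rng.uniform(0.0, hi[1], n)
            pos[:, 2] = rng.uniform(0.0, hi[2], n)
            if foam is not None and not foam.is_empty:
                for _ in range(200):  # re-draw points released inside the wall
                    bad = foam.clearance_to_solid(pos) <= particle.radius
                    if not bad.any():
                        break
                    k = int(bad.sum())
                    pos[bad, 1] = rng.uniform(0.0, hi[1], k)
                    pos[bad, 2] = rng.uniform(0.0, hi[2], k)
    initial = pos.copy()

    if integrator == "inertial":
        tau = particle.response_time(fluid)
        theta = dt / tau
        kt_m = constants.k_B * constants.temperature / particle.mass
        e1 = math.exp(-theta)
        var_v = kt_m * (1.0 - e1**2)
        var_r = kt_m * tau**2 * (2.0 * theta - 3.0 + 4.0 * e1 - e1**2)
        cov_vr = kt_m * tau * (1.0 - e1) ** 2
        # Cholesky of the per-component (r, v) noise covariance
        l_rr = math.sqrt(max(var_r, 0.0))
        l_vr = cov_vr / l_rr if l_rr > 0 else 0.0
        l_vv = math.sqrt(max(var_v - l_vr**2, 0.0))
        vel = np.zeros((n, 3))

    active = np.ones(n, dtype=bool)
    collided = np.zeros(n, dtype=bool)
    escaped = np.zeros(n, dtype=bool)
    n_steps = int(round(max_time / dt))
    frames = [] if save_every else None

    for step in range(n_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        p_act = pos[idx]
        if field is not None:
            u = sample_velocity(field, np.clip(p_act, 0.0, np.asarray(field.extent)))
        else:
            u = np.zeros_like(p_act)
        if integrator == "overdamped":
            p_new = p_act + u * dt + sigma_step * rng.standard_normal(p_act.shape)
        else:
            v_act = vel[idx]
            dv = v_act - u
            xi = rng.standard_normal((len(idx), 3, 2))
            noise_r = l_rr * xi[..., 0]
            noise_v = l_vr * xi[..., 0] + l_vv * xi[..., 1]
            p_new = p_act + u * dt + dv * tau * (1.0 - e1) + noise_r
            vel[idx] = u + dv * e1 + noise_v

        if bounded:
            # outlet first, then mirror the remaining lateral/inlet boundaries
            out = p_new[:, 0] >= hi[0]
            p_new = _reflect(p_new, lo, hi)
            p_new[out, 0] = hi[0]
        else:
            out = np.zeros(len(idx), dtype=bool)

        hit = np.zeros(len(idx), dtype=bool)
        if foam is not None and not foam.is_empty:
            hit = foam.clearance_to_solid(p_new) <= particle.radius
        hit &= ~out

        pos[idx] = p_new
        collided[idx[hit]] = True
        escaped[idx[out]] = True
        active[idx[hit | out]] = False
        if save_every and step % save_every == 0:
            frames.append(pos.copy())

    return TransportResult(
        n_released=n,
        n_collided=int(collided.sum()),
        n_escaped=int(escaped.sum()),
        n_in_domain=int(active.sum()),
        collision_points=pos[collided].copy(),
        initial_positions=initial,
        final_positions=pos.copy(),
        elapsed_time=n_steps * dt,
        trajectories=np.array(frames) if frames else None,
    )


def extrapolate_collision_probability(
    escape_fraction: float, thickness_ratio: float
) -> float:
    """Collision probability for a thicker foam under the independent-layer model.

    Treats each additional thickness of foam as an independent filter with
    the same per-layer escape probability: P_collide = 1 - e^ratio for
    escape fraction e.  A modelling idealisation — real layers are
    correlated through the flow — used only to extrapolate the simulated
    slab to a thicker membrane.
    """
    if not 0.0 <= escape_fraction <= 1.0:
        raise ValueError("escape_fraction must lie in [0, 1]")
    if thickness_ratio <= 0:
        raise ValueError("thickness_ratio must be positive")
    return 1.0 - escape_fraction**thickness_ratio
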