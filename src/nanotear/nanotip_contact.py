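"""Bead-stick Langevin dynamics of rod bacteria in a nanotip-array flow.

A rod-shaped bacterium is modelled as two drag-bearing beads joined by a
stiff harmonic spring (rest length 0.5 um, bead diameter 0.5 um, giving a
0.5 x 1 um spherocylinder).  Each bead obeys the overdamped Langevin
equation

    dr_i/dt = V(r_i) + (1/xi) [F_B + F_S + F_wall],

with V the local flow velocity, xi = 6 pi mu a the Stokes friction of a
bead, F_B the Brownian force, F_S the spring force along the stick and
F_wall a short-range harmonic repulsion from the tips and the base plane.
Translation and rotation both emerge from the two-bead kinematics
(hydrodynamic interaction between the beads is neglected).

A run terminates when the cell's surface comes within the contact
threshold of a tip (a contact event), reaches the base substrate, leaves
the flow domain, or times out.  Contacts are classified by where the tip
touches the cell's spherocylindrical surface: on a polar cap beyond a bead
centre (**end**) or on the lateral side between the bead centres
(**middle**).  An eight-way subtype code (six end, two middle) refines
this by which bead leads in the flow and which tip feature (top face, side
wall, or top rim) is touched; the end/middle dichotomy alone carries the
quantitative statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .constants import PhysicalConstants, FluidProperties, WATER
from .flow_field import FlowField, sample_velocity
from .synthetic_data import TipArray

__all__ = [
    "BeadStickCell",
    "CellParameters",
    "ContactEvent",
    "step_cell",
    "simulate_contacts",
    "classify_contact",
    "contact_statistics",
]

#: Surface gap defining a contact, m.
CONTACT_THRESHOLD = 5e-9

#: Range of the repulsive wall force, m.
WALL_RANGE = 10e-9

# subtype codes: 1..6 end (leading/trailing bead x tip top/side/rim), 7..8 middle
_END_CODES = {("lead", "top"): 1, ("lead", "side"): 2, ("lead", "rim"): 3,
              ("trail", "top"): 4, ("trail", "side"): 5, ("trail", "rim"): 6}
_MIDDLE_CODES = {"top": 7, "side": 8, "rim": 7}


@dataclass(frozen=True)
class CellParameters:
    """Geometry and mechanics of the two-bead cell."""

    bead_radius: float = 0.25e-6  # m
    rest_length: float = 0.5e-6  # m, bead-centre separation
    spring_stiffness: float = 2.0e-4  # N/m
    wall_stiffness: float = 2.0e-4  # N/m
    contact_threshold: float = CONTACT_THRESHOLD
    wall_range: float = WALL_RANGE

    def friction(self, fluid: FluidProperties) -> float:
        """Per-bead Stokes drag coefficient xi = 6 pi mu a, N s/m."""
        return 6.0 * math.pi * fluid.dynamic_viscosity * self.bead_radius

    @property
    def total_length(self) -> float:
        return self.rest_length + 2.0 * self.bead_radius


@dataclass
class BeadStickCell:
    """State of one bead-stick bacterium."""

    r1: np.ndarray
    r2: np.ndarray
    params: CellParameters = field(default_factory=CellParameters)

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)

    @property
    def bond_length(self) -> float:
        return float(np.linalg.norm(self.r2 - self.r1))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.r1 + self.r2)


@dataclass(frozen=True)
class ContactEvent:
    """Terminal event of one simulated cell."""

    cell_id: int
    time: float  # s
    tip_index: int  # -1 when no tip involved
    contact_class: Literal["end", "middle", "none"]
    subtype: int  # 1-6 end, 7-8 middle, 0 none
    point: tuple[float, float, float]
    reason: Literal["tip", "exit", "substrate", "timeout"] = "tip"


# ---------------------------------------------------------------------------
# tip geometry


def _paired_tip_distance(pts: np.ndarray, centers: np.ndarray, radius: float, length: float):
    """Distance from each point to its paired capped cylinder; also the
    (side, height-above-top) decomposition used for feature labelling."""
    dxy = pts[:, :2] - centers[:, :2]
    rho = np.hypot(dxy[:, 0], dxy[:, 1])
    z = pts[:, 2] - length
    side = rho - radius
    dist = np.where(z <= 0, side, np.where(side <= 0, z, np.hypot(side, z)))
    return dist, side, z


def _segment_tip_gap(r1, r2, centers, radius, length, bead_radius, n_golden=28):
    """Minimum surface gap between paired cell segments and tips.

    ``r1``, ``r2``, ``centers`` all have shape (p, 3); the gap between the
    spherocylinder around segment [r1, r2] and each paired capped cylinder
    is minimised over the segment parameter s in [0, 1] by golden-section
    search (distance to a convex solid is convex along a segment).
    Returns (gap, s_star), both (p,).
    """
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    seg = r2 - r1
    a = np.zeros(r1.shape[0])
    b = np.ones_like(a)

    def dist_at(s):
        pts = r1 + s[:, None] * seg
        d, _, _ = _paired_tip_distance(pts, centers, radius, length)
        return d

    c = b - invphi * (b - a)
    d_ = a + invphi * (b - a)
    fc = dist_at(c)
    fd = dist_at(d_)
    for _ in range(n_golden):
        take_c = fc < fd
        b = np.where(take_c, d_, b)
        a = np.where(take_c, a, c)
        c = b - invphi * (b - a)
        d_ = a + invphi * (b - a)
        fc = dist_at(c)
        fd = dist_at(d_)
    s_star = 0.5 * (a + b)
    # endpoints can beat the interior bracket when the minimum sits on a cap
    f0 = dist_at(np.zeros_like(a))
    f1 = dist_at(np.ones_like(a))
    best = np.minimum(np.minimum(fc, fd), np.minimum(f0, f1))
    s_star = np.where(f0 <= best, 0.0, np.where(f1 <= best, 1.0, s_star))
    return best - bead_radius, s_star


def _tip_feature(side: float, z: float, radius: float) -> str:
    """Tip feature at a closest point: top face, side wall, or top rim."""
    edge_band = 0.15 * radius
    if z > 0 and side <= -edge_band:
        return "top"
    if z <= 0 and side > 0:
        return "side"
    return "rim"


def _tip_centers_3d(tips: TipArray) -> np.ndarray:
    from .flow_field import TIP_MARGIN_PITCH

    c2 = tips.tip_centers(margin=TIP_MARGIN_PITCH * tips.pitch)
    return np.column_stack([c2, np.zeros(len(c2))])


# ---------------------------------------------------------------------------
# dynamics


def _velocity_function(field) -> Callable[[np.ndarray], np.ndarray]:
    if field is None:
        return lambda pts: np.zeros_like(pts)
    if isinstance(field, FlowField):
        ext = np.asarray(field.extent)
        return lambda pts: sample_velocity(field, np.clip(pts, 0.0, ext))
    if callable(field):
        return field
    raise TypeError("field must be a FlowField, a callable, or None")


def _wall_forces(flat, params, centers, tip_radius, tip_length, base_plane):
    """Short-range harmonic repulsion on bead positions ``flat`` (m, 3)."""
    kw = params.wall_stiffness
    rng_ = params.wall_range
    a = params.bead_radius
    f = np.zeros_like(flat)
    if centers is not None and len(centers):
        # all bead-tip pairs (bead counts are small once candidates are culled)
        m, k = len(flat), len(centers)
        bi = np.repeat(np.arange(m), k)
        tj = np.tile(np.arange(k), m)
        d, side, z = _paired_tip_distance(flat[bi], centers[tj], tip_radius, tip_length)
        gap = d - a
        near = gap < rng_
        if near.any():
            bi, tj = bi[near], tj[near]
            si, zi, gi = side[near], z[near], gap[near]
            dxy = flat[bi, :2] - centers[tj, :2]
            rho = np.linalg.norm(dxy, axis=1, keepdims=True)
            n_side = np.concatenate(
                [np.where(rho > 0, dxy / rho, 0.0), np.zeros((len(bi), 1))], axis=1
            )
            up = np.array([0.0, 0.0, 1.0])
            corner = (n_side * si[:, None] + up * zi[:, None])
            corner /= np.maximum(np.linalg.norm(corner, axis=1, keepdims=True), 1e-30)
            normal = np.where(
                (zi > 0)[:, None], np.where((si <= 0)[:, None], up, corner), n_side
            )
            np.add.at(f, bi, normal * (kw * (rng_ - gi))[:, None])
    if base_plane:
        gap_z = flat[:, 2] - a
        nearb = gap_z < rng_
        f[nearb, 2] += kw * (rng_ - gap_z[nearb])
    return f


def _spring_forces(r, params):
    k = params.spring_stiffness
    bond = r[:, 1] - r[:, 0]
    blen = np.linalg.norm(bond, axis=1, keepdims=True)
    unit = bond / np.where(blen > 0, blen, 1.0)
    fs = k * (blen - params.rest_length) * unit
    f = np.zeros_like(r)
    f[:, 0] += fs
    f[:, 1] -= fs
    return f


def _check_dt(dt, params, fluid):
    xi = params.friction(fluid)
    kmax = max(params.spring_stiffness, params.wall_stiffness)
    limit = xi / kmax / 10.0
    if dt > limit:
        raise ValueError(
            f"dt = {dt:g} s unstable for stiffness {kmax:g} N/m; need dt < {limit:g} s"
        )


def _step_batch(
    r, vel_fn, params, constants, fluid, dt, rng,
    centers=None, tip_radius=0.0, tip_length=0.0, base_plane=False,
):
    xi = params.friction(fluid)
    flat = r.reshape(-1, 3)
    u = vel_fn(flat).reshape(r.shape)
    f = _spring_forces(r, params)
    f += _wall_forces(flat, params, centers, tip_radius, tip_length, base_plane).reshape(r.shape)
    drift = u + f / xi
    kT = constants.k_B * constants.temperature
    if kT > 0:
        noise = math.sqrt(2.0 * kT / xi * dt) * rng.standard_normal(r.shape)
    else:
        noise = 0.0
    return r + drift * dt + noise


def step_cell(
    cell: BeadStickCell,
    field,
    constants: PhysicalConstants,
    dt: float,
    rng: np.random.Generator,
    tips: TipArray | None = None,
    fluid: FluidProperties = WATER,
) -> BeadStickCell:
    """Advance one bead-stick cell by one overdamped Langevin step.

    Raises ``ValueError`` for a time step unstable against the spring
    stiffness and ``RuntimeError`` when the bond stretches beyond 50% of
    rest length (integration blow-up).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_dt(dt, cell.params, fluid)
    r = np.stack([cell.r1, cell.r2])[None, :, :]
    r_new = _step_batch(
        r, _velocity_function(field), cell.params, constants, fluid, dt, rng,
        centers=_tip_centers_3d(tips) if tips is not None else None,
        tip_radius=tips.tip_diameter / 2.0 if tips is not None else 0.0,
        tip_length=tips.tip_length if tips is not None else 0.0,
        base_plane=tips is not None,
    )
    out = BeadStickCell(r_new[0, 0], r_new[0, 1], cell.params)
    stretch = abs(out.bond_length - cell.params.rest_length) / cell.params.rest_length
    if stretch > 0.5:
        raise RuntimeError(
            f"bead-stick integration unstable: bond stretched {stretch:.1%} "
            f"(length {out.bond_length:.3g} m vs rest {cell.params.rest_length:.3g} m)"
        )
    return out


# ---------------------------------------------------------------------------
# contact classification


def classify_contact(
    cell: BeadStickCell,
    tips: TipArray,
    threshold: float | None = None,
    flow_direction: np.ndarray | None = None,
) -> tuple[Literal["end", "middle", "none"], int]:
    """Classify the cell-tip contact (if any) as end or middle, with subtype.

    The closest approach between the cell's spherocylinder surface and each
    tip is minimised along the cell axis; a surface gap at or below
    ``threshold`` is a contact.  **End**: the minimiser sits at a bead
    centre, so the tip touches a polar cap.  **Middle**: the minimiser is
    interior, so the tip touches the lateral side.  Subtypes 1-6 split end
    contacts by leading/trailing bead (relative to ``flow_direction``) and
    tip feature (top/side/rim); 7-8 split middle contacts by tip apex
    versus shaft.
    """
    threshold = cell.params.contact_threshold if threshold is None else threshold
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    centers = _tip_centers_3d(tips)
    k = len(centers)
    gap, s_star = _segment_tip_gap(
        np.broadcast_to(cell.r1, (k, 3)), np.broadcast_to(cell.r2, (k, 3)),
        centers, tips.tip_diameter / 2.0, tips.tip_length, cell.params.bead_radius,
    )
    j = int(np.argmin(gap))
    if gap[j] > threshold:
        return "none", 0
    s = float(s_star[j])
    point = cell.r1 + s * (cell.r2 - cell.r1)
    _, side, z = _paired_tip_distance(
        point[None, :], centers[j : j + 1], tips.tip_diameter / 2.0, tips.tip_length
    )
    feature = _tip_feature(float(side[0]), float(z[0]), tips.tip_diameter / 2.0)
    end_tol = 1e-3
    if s <= end_tol or s >= 1.0 - end_tol:
        which_bead = 0 if s <= end_tol else 1
        if flow_direction is not None and np.linalg.norm(flow_direction) > 0:
            axis = (cell.r2 - cell.r1) * (1.0 if which_bead == 1 else -1.0)
            lead = "lead" if float(axis @ np.asarray(flow_direction)) > 0 else "trail"
        else:
            lead = "lead" if which_bead == 1 else "trail"
        return "end", _END_CODES[(lead, feature)]
    return "middle", _MIDDLE_CODES[feature]


# ---------------------------------------------------------------------------
# ensemble simulation


def simulate_contacts(
    field,
    tips: TipArray,
    n_cells: int = 100,
    seed: int = 0,
    params: CellParameters | None = None,
    constants: PhysicalConstants | None = None,
    fluid: FluidProperties | None = None,
    dt: float = 1e-6,
    max_time: float = 0.05,
    domain_extent: tuple[float, float, float] | None = None,
    release_height: float | None = None,
) -> list[ContactEvent]:
    """Release cells upstream of the array and record each terminal event.

    Cells start on a plane above the tip tops, spanning the array footprint
    shifted upstream along the incident-flow direction, with uniformly
    random orientations; ``field`` may be a solved :class:`FlowField`, a
    callable ``points -> velocities``, or ``None`` (quiescent).  Every cell
    yields exactly one event: its first tip contact (classified
    end/middle), the base substrate, a domain exit, or a timeout.
    """
    from .flow_field import TIP_MARGIN_PITCH, tip_domain_extent

    params = params or CellParameters()
    constants = constants or PhysicalConstants()
    fluid = fluid or (field.fluid if isinstance(field, FlowField) else WATER)
    _check_dt(dt, params, fluid)
    rng = np.random.default_rng(seed)
    vel_fn = _velocity_function(field)

    extent = np.asarray(
        domain_extent
        or (field.extent if isinstance(field, FlowField) else tip_domain_extent(tips)),
        dtype=float,
    )
    centers = _tip_centers_3d(tips)
    tip_r = tips.tip_diameter / 2.0
    margin = TIP_MARGIN_PITCH * tips.pitch
    fx, fy = tips.footprint
    a = params.bead_radius
    half = params.rest_length / 2.0

    z0 = release_height if release_height is not None else 0.5 * (
        tips.tip_length + extent[2]
    )
    theta = math.radians(tips.incident_flow_angle)
    shift = (z0 - tips.tip_length) / math.tan(theta) if theta < math.pi / 2 else 0.0

    cpos = np.empty((n_cells, 3))
    cpos[:, 0] = np.clip(
        rng.uniform(margin - shift, margin + fx - shift, n_cells), a, extent[0] - a
    )
    cpos[:, 1] = rng.uniform(margin, margin + fy, n_cells)
    cpos[:, 2] = z0
    axes = rng.standard_normal((n_cells, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    r = np.stack([cpos - half * axes, cpos + half * axes], axis=1)

    flow_dir = np.array([math.cos(theta), 0.0, -math.sin(theta)])
    active = np.ones(n_cells, dtype=bool)
    events: dict[int, ContactEvent] = {}
    n_steps = int(round(max_time / dt))

    # a tip can only touch a cell whose midpoint is laterally within half a
    # cell length of its column and whose lowest bead nears the tip height
    reach = half + a + tip_r + 0.3e-6
    z_reach = tips.tip_length + half + a + 0.3e-6

    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        ri = r[idx]
        mid = ri.mean(axis=1)

        near_z = mid[:, 2] < z_reach
        cand = np.zeros((len(idx), len(centers)), dtype=bool)
        if near_z.any():
            sub = np.flatnonzero(near_z)
            dxy = np.hypot(
                mid[sub, None, 0] - centers[None, :, 0],
                mid[sub, None, 1] - centers[None, :, 1],
            )
            cand[sub] = dxy < reach

        tip_sel = cand.any(axis=0)
        sel_centers = centers[tip_sel] if tip_sel.any() else None
        r_new = _step_batch(
            ri, vel_fn, params, constants, fluid, dt, rng,
            centers=sel_centers, tip_radius=tip_r,
            tip_length=tips.tip_length, base_plane=True,
        )

        # mirror at the lateral (y) boundaries, matching the flow symmetry
        over = r_new[..., 1] > extent[1] - a
        r_new[..., 1] = np.where(over, 2 * (extent[1] - a) - r_new[..., 1], r_new[..., 1])
        under = r_new[..., 1] < a
        r_new[..., 1] = np.where(under, 2 * a - r_new[..., 1], r_new[..., 1])
        r[idx] = r_new

        exited = (
            (r_new[:, :, 0].max(axis=1) > extent[0] - a)
            | (r_new[:, :, 0].min(axis=1) < 0.5 * a)
            | (r_new[:, :, 2].max(axis=1) > extent[2] - 0.5 * a)
        )
        substrate = r_new[:, :, 2].min(axis=1) - a <= params.contact_threshold

        touching = np.zeros(len(idx), dtype=bool)
        touch_tip = np.full(len(idx), -1)
        touch_s = np.zeros(len(idx))
        pi, pj = np.nonzero(cand)
        if len(pi):
            gap, s_star = _segment_tip_gap(
                r_new[pi, 0], r_new[pi, 1], centers[pj],
                tip_r, tips.tip_length, a,
            )
            row_min = np.full(len(idx), np.inf)
            np.minimum.at(row_min, pi, gap)
            hit_rows = np.flatnonzero(row_min <= params.contact_threshold)
            for k in hit_rows:
                sel = np.flatnonzero(pi == k)
                best = sel[np.argmin(gap[sel])]
                touching[k] = True
                touch_tip[k] = pj[best]
                touch_s[k] = s_star[best]

        done = exited | substrate | touching
        for k in np.flatnonzero(done):
            cid = int(idx[k])
            t = step * dt
            if touching[k]:
                s = float(touch_s[k])
                cls = "end" if (s <= 1e-3 or s >= 1.0 - 1e-3) else "middle"
                pt = r_new[k, 0] + s * (r_new[k, 1] - r_new[k, 0])
                _, side, z = _paired_tip_distance(
                    pt[None, :], centers[int(touch_tip[k])][None, :],
                    tip_r, tips.tip_length,
                )
                feature = _tip_feature(float(side[0]), float(z[0]), tip_r)
                if cls == "end":
                    which = 0 if s <= 1e-3 else 1
                    axis_v = (r_new[k, 1] - r_new[k, 0]) * (1.0 if which == 1 else -1.0)
                    lead = "lead" if float(axis_v @ flow_dir) > 0 else "trail"
                    sub_code = _END_CODES[(lead, feature)]
                else:
                    sub_code = _MIDDLE_CODES[feature]
                events[cid] = ContactEvent(
                    cid, t, int(touch_tip[k]), cls, sub_code, tuple(pt), "tip"
                )
            elif substrate[k]:
                pt = r_new[k][int(np.argmin(r_new[k][:, 2]))]
                events[cid] = ContactEvent(cid, t, -1, "none", 0, tuple(pt), "substrate")
            else:
                pt = r_new[k].mean(axis=0)
                events[cid] = ContactEvent(cid, t, -1, "none", 0, tuple(pt), "exit")
            active[cid] = False

    for cid in np.flatnonzero(active):
        pt = r[cid].mean(axis=0)
        events[int(cid)] = ContactEvent(
            int(cid), n_steps * dt, -1, "none", 0, tuple(pt), "timeout"
        )
    return [events[k] for k in sorted(events)]


def contact_statistics(events: list[ContactEvent]) -> dict:
    """End/middle fractions over tip-contacting cells, with a Wilson 95% CI.

    Raises ``ValueError`` on an empty contact set (no statistics to form).
    """
    contacts = [e for e in events if e.contact_class in ("end", "middle")]
    n = len(contacts)
    if n == 0:
        raise ValueError("no tip contacts in the event list")
    n_end = sum(1 for e in contacts if e.contact_class == "end")
    p = n_end / n
    z = 1.959963984540054
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    hw = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return {
        "n_contacts": n,
        "n_end": n_end,
        "n_middle": n - n_end,
        "end_fraction": p,
        "middle_fraction": 1.0 - p,
        "end_fraction_ci95": (max(0.0, center - hw), min(1.0, center + hw)),
        "n_events": len(events),
        "n_no_contact": len(events) - n,
    }
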