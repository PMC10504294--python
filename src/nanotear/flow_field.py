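"""Steady incompressible Stokes flow on a uniform staggered (MAC) grid.

At the scales of interest here (micron-to-hundred-micron obstacles,
sub-mm/s water) the Reynolds number is 1e-4 to 1e-1, so the inertial terms
of the momentum balance are negligible and the steady Stokes equations

    -mu * laplacian(u) + grad p = F,      div u = 0

are solved directly as one symmetric saddle-point system.  Velocities live
on cell faces, pressure at cell centres; solid cells (from a rasterized
foam or nanotip geometry) impose no-slip by eliminating every adjacent
face velocity (a first-order staircase wall).  Boundary conditions per box
face are ``inlet`` (Dirichlet velocity), ``wall`` (no-slip), ``outflow``
(zero normal gradient with ambient pressure) and ``symmetry`` (free slip).

The system is nondimensionalized (lengths by the cell width, velocities by
the inlet scale, pressure by mu*U/h) and solved with MINRES, preconditioned
block-diagonally: velocity blocks by a DST/DCT diagonalization of the
unmasked component Laplacian (exact away from obstacles), the pressure
block by the identity (the Stokes Schur complement is spectrally equivalent
to the pressure mass matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, minres

from .constants import FluidProperties
from .synthetic_data import FoamGeometry, TipArray

__all__ = [
    "FluidProperties",
    "BoundaryCondition",
    "FlowField",
    "FlowConvergenceError",
    "solve_flow",
    "sample_velocity",
    "flow_report",
    "tip_array_solid_mask",
    "tip_domain_extent",
]

BCKind = Literal["inlet", "wall", "outflow", "symmetry"]

#: Lateral margin around a tip array's footprint, as a multiple of the pitch.
TIP_MARGIN_PITCH = 0.5

#: Headroom above the tip tops, as a fraction of the tip length.
TIP_CLEARANCE_FRACTION = 0.2


class FlowConvergenceError(RuntimeError):
    """The Stokes solve missed its tolerance; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass(frozen=True)
class BoundaryCondition:
    kind: BCKind
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class FlowField:
    """A solved MAC-grid flow: face velocities, cell pressures, solid mask."""

    shape: tuple[int, int, int]  # cells per axis
    spacing: float  # m
    u: np.ndarray  # (nx+1, ny, nz) x-face velocities, m/s
    v: np.ndarray  # (nx, ny+1, nz)
    w: np.ndarray  # (nx, ny, nz+1)
    p: np.ndarray  # (nx, ny, nz) cell pressures, Pa
    solid: np.ndarray  # (nx, ny, nz) bool
    boundary: dict[str, BoundaryCondition]
    fluid: FluidProperties
    report: dict = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing for n in self.shape)

    def cell_center_velocity(self) -> np.ndarray:
        """(nx, ny, nz, 3) velocity averaged to cell centres (zero in solid)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        out = np.stack([uc, vc, wc], axis=-1)
        out[self.solid] = 0.0
        return out

    def divergence(self) -> np.ndarray:
        """Discrete divergence per fluid cell, 1/s (zeroed in solid)."""
        div = (
            np.diff(self.u, axis=0) + np.diff(self.v, axis=1) + np.diff(self.w, axis=2)
        ) / self.spacing
        div[self.solid] = 0.0
        return div

    def to_vtk(self, path) -> None:
        from .vtk_io import write_structured_points

        write_structured_points(
            path,
            spacing=(self.spacing,) * 3,
            scalars={"pressure": self.p, "solid": self.solid.astype(float)},
            vectors={"velocity": self.cell_center_velocity()},
        )


# ---------------------------------------------------------------------------
# geometry rasterization


def tip_domain_extent(tips: TipArray) -> tuple[float, float, float]:
    """Simulation box: array footprint plus margins, tip height plus headroom."""
    fx, fy = tips.footprint
    margin = TIP_MARGIN_PITCH * tips.pitch
    lz = tips.tip_length * (1.0 + TIP_CLEARANCE_FRACTION)
    return (fx + 2 * margin, fy + 2 * margin, lz)


def tip_array_solid_mask(
    tips: TipArray, shape: tuple[int, int, int], extent: tuple[float, float, float]
) -> np.ndarray:
    """Rasterize vertical cylinders (on the base plane z = 0) to cell centres."""
    nx, ny, nz = shape
    xs = (np.arange(nx) + 0.5) * extent[0] / nx
    ys = (np.arange(ny) + 0.5) * extent[1] / ny
    zs = (np.arange(nz) + 0.5) * extent[2] / nz
    centers = tips.tip_centers(margin=TIP_MARGIN_PITCH * tips.pitch)
    r = tips.tip_diameter / 2.0
    in_column = np.zeros((nx, ny), dtype=bool)
    for cx, cy in centers:
        in_column |= (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r * r
    return in_column[:, :, None] & (zs <= tips.tip_length)[None, None, :]


def _default_boundaries(geometry) -> dict[str, BoundaryCondition]:
    bc = {
        "x-": BoundaryCondition("inlet"),
        "x+": BoundaryCondition("outflow"),
        "y-": BoundaryCondition("symmetry"),
        "y+": BoundaryCondition("symmetry"),
        "z-": BoundaryCondition("symmetry"),
        "z+": BoundaryCondition("symmetry"),
    }
    if isinstance(geometry, TipArray):
        # the 45-degree impact is decomposed onto the box: flow enters through
        # the top and the upstream side, leaves through the downstream side
        bc["z-"] = BoundaryCondition("wall")
        bc["z+"] = BoundaryCondition("inlet")
    return bc


# ---------------------------------------------------------------------------
# staggered-grid operator machinery
#
# Ghost rules per axis end for each velocity component:
#   ODD  — Dirichlet half a cell outside (no-slip wall / inlet seen by a
#          tangential component): ghost = 2*bc - edge
#   EVEN — zero normal gradient (symmetry / outflow): ghost = edge
#   NODE — the array carries the boundary node itself (normal component);
#          Dirichlet nodes are eliminated via the active mask, active
#          outflow nodes use an EVEN exterior ghost.


def _component_rules(comp: int, bc: dict[str, BoundaryCondition]):
    rules = {}
    for axis in range(3):
        for end, tag in ((0, "-"), (1, "+")):
            b = bc["xyz"[axis] + tag]
            if axis == comp:
                rules[(axis, end)] = ("NODE", b.velocity[comp], b.kind)
            elif b.kind in ("inlet", "wall"):
                rules[(axis, end)] = ("ODD", b.velocity[comp], b.kind)
            else:
                rules[(axis, end)] = ("EVEN", 0.0, b.kind)
    return rules


def _active_and_dirichlet(comp, shape, solid, bc):
    """Active mask and Dirichlet-value array for one velocity component."""
    fshape = list(shape)
    fshape[comp] += 1
    active = np.ones(tuple(fshape), dtype=bool)
    dirichlet = np.zeros(tuple(fshape))

    for end in (0, 1):
        b = bc["xyz"[comp] + ("-" if end == 0 else "+")]
        idx = [slice(None)] * 3
        idx[comp] = 0 if end == 0 else fshape[comp] - 1
        if b.kind in ("inlet", "wall", "symmetry"):
            active[tuple(idx)] = False
            dirichlet[tuple(idx)] = b.velocity[comp] if b.kind == "inlet" else 0.0

    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[comp] = slice(0, fshape[comp] - 1)
    hi[comp] = slice(1, fshape[comp])
    solid_adjacent = np.zeros(tuple(fshape), dtype=bool)
    solid_adjacent[tuple(lo)] |= solid
    solid_adjacent[tuple(hi)] |= solid
    active &= ~solid_adjacent
    dirichlet[solid_adjacent] = 0.0
    return active, dirichlet


def _ghost(x, axis, end, rule, inhomogeneous):
    kind, value, _bc = rule
    n = x.shape[axis]
    edge = x.take([n - 1] if end == 1 else [0], axis=axis)
    if kind == "ODD":
        return (2.0 * value - edge) if inhomogeneous else -edge
    return edge  # EVEN and NODE exterior ghosts are zero-gradient


def _apply_laplacian(x, rules, inhomogeneous=False):
    """Unit-spacing 7-point Laplacian with the component's ghost rules."""
    lap = -6.0 * x
    for axis in range(3):
        n = x.shape[axis]
        up = np.concatenate(
            [x.take(range(1, n), axis=axis), _ghost(x, axis, 1, rules[(axis, 1)], inhomogeneous)],
            axis=axis,
        )
        dn = np.concatenate(
            [_ghost(x, axis, 0, rules[(axis, 0)], inhomogeneous), x.take(range(0, n - 1), axis=axis)],
            axis=axis,
        )
        lap += up + dn
    return lap


def _divergence_faces(u, v, w):
    return np.diff(u, axis=0) + np.diff(v, axis=1) + np.diff(w, axis=2)


def _gradient_faces(p, bc):
    """(p_right - p_left) on every face; ghost pressure 0 beyond outflow faces."""
    out = []
    for axis in range(3):
        n = p.shape[axis]
        shp = list(p.shape)
        shp[axis] += 1
        g = np.zeros(tuple(shp))
        interior = [slice(None)] * 3
        interior[axis] = slice(1, n)
        right = [slice(None)] * 3
        right[axis] = slice(1, n)
        left = [slice(None)] * 3
        left[axis] = slice(0, n - 1)
        g[tuple(interior)] = p[tuple(right)] - p[tuple(left)]
        for end in (0, 1):
            if bc["xyz"[axis] + ("-" if end == 0 else "+")].kind == "outflow":
                face = [slice(None)] * 3
                cell = [slice(None)] * 3
                if end == 0:  # ghost cell (p = 0) to the left of cell 0
                    face[axis] = slice(0, 1)
                    cell[axis] = slice(0, 1)
                    g[tuple(face)] = p[tuple(cell)]
                else:  # ghost cell (p = 0) to the right of the last cell
                    face[axis] = slice(n, n + 1)
                    cell[axis] = slice(n - 1, n)
                    g[tuple(face)] = -p[tuple(cell)]
        out.append(g)
    return out


class _StokesSystem:
    """Nondimensional symmetric saddle operator [[A, G], [G^T, 0]].

    Unit spacing and unit viscosity; callers scale in and out.  Eliminated
    unknowns (Dirichlet faces, solid faces/cells) are carried as identity
    rows so the operator stays symmetric positive on the full vector space.
    """

    def __init__(self, shape, solid, bc):
        self.shape = tuple(shape)
        self.bc = bc
        self.solid = solid
        self.rules = [_component_rules(c, bc) for c in range(3)]
        self.active = []
        self.dirichlet = []
        for c in range(3):
            a, d = _active_and_dirichlet(c, self.shape, solid, bc)
            self.active.append(a)
            self.dirichlet.append(d)
        self.sizes = [a.size for a in self.active] + [solid.size]
        self.total = sum(self.sizes)
        self.offsets = np.cumsum([0] + self.sizes)

    def unpack(self, x):
        parts = []
        for c in range(3):
            a = self.active[c]
            parts.append(x[self.offsets[c] : self.offsets[c + 1]].reshape(a.shape).copy())
        parts.append(x[self.offsets[3] :].reshape(self.shape).copy())
        return parts

    def matvec(self, x):
        u, v, w, p = self.unpack(x)
        held = [arr[~self.active[c]].copy() for c, arr in enumerate((u, v, w))]
        held_p = p[self.solid].copy()
        for c, arr in enumerate((u, v, w)):
            arr[~self.active[c]] = 0.0
        p[self.solid] = 0.0
        grads = _gradient_faces(p, self.bc)
        res = []
        for c, arr in enumerate((u, v, w)):
            r = -_apply_laplacian(arr, self.rules[c]) + grads[c]
            r[~self.active[c]] = held[c]  # identity on eliminated unknowns
            res.append(r)
        rp = -_divergence_faces(u, v, w)
        rp[self.solid] = held_p
        return np.concatenate([r.ravel() for r in res] + [rp.ravel()])

    def rhs(self, body_force):
        """RHS from body force and Dirichlet boundary/obstacle values."""
        parts = []
        u0 = []
        for c in range(3):
            d = self.dirichlet[c]
            lap_bc = _apply_laplacian(d, self.rules[c], inhomogeneous=True)
            b = np.full(d.shape, body_force[c]) + lap_bc
            b[~self.active[c]] = 0.0
            parts.append(b)
            u0.append(d)
        gp = _divergence_faces(*u0)  # G^T u_act = -div u_act = +div U0
        gp[self.solid] = 0.0
        return np.concatenate([b.ravel() for b in parts] + [gp.ravel()])

    # -- preconditioner ----------------------------------------------------
    def _transform_plan(self, comp):
        plan = []
        for axis in range(3):
            n = self.active[comp].shape[axis]
            lo_kind, _, lo_bc = self.rules[comp][(axis, 0)]
            hi_kind, _, hi_bc = self.rules[comp][(axis, 1)]
            if axis == comp:  # NODE axes: map the bc kind onto a ghost family
                lo_kind = "ODD" if lo_bc in ("inlet", "wall", "symmetry") else "EVEN"
                hi_kind = "ODD" if hi_bc in ("inlet", "wall", "symmetry") else "EVEN"
            k = np.arange(n)
            if lo_kind == "ODD" and hi_kind == "ODD":
                fam, typ = "dst", 2
                lam = 2.0 * np.cos(np.pi * (k + 1) / n) - 2.0
            elif lo_kind == "EVEN" and hi_kind == "EVEN":
                fam, typ = "dct", 2
                lam = 2.0 * np.cos(np.pi * k / n) - 2.0
            elif lo_kind == "ODD":
                fam, typ = "dst", 4
                lam = 2.0 * np.cos(np.pi * (k + 0.5) / n) - 2.0
            else:
                fam, typ = "dct", 4
                lam = 2.0 * np.cos(np.pi * (k + 0.5) / n) - 2.0
            plan.append((fam, typ, lam))
        return plan

    def build_preconditioner(self):
        plans = [self._transform_plan(c) for c in range(3)]
        eigs = []
        for plan in plans:
            lx, ly, lz = (pl[2] for pl in plan)
            lam = -(lx[:, None, None] + ly[None, :, None] + lz[None, None, :])
            eigs.append(np.maximum(lam, 1e-10))

        inv_type = {1: 1, 2: 3, 3: 2, 4: 4}

        def apply(x):
            u, v, w, p = self.unpack(x)
            out = []
            for c, arr in enumerate((u, v, w)):
                held = arr[~self.active[c]].copy()
                work = arr
                work[~self.active[c]] = 0.0
                for axis, (fam, typ, _) in enumerate(plans[c]):
                    f = sp_fft.dst if fam == "dst" else sp_fft.dct
                    work = f(work, type=typ, axis=axis, norm="ortho")
                work /= eigs[c]
                for axis, (fam, typ, _) in enumerate(plans[c]):
                    f = sp_fft.dst if fam == "dst" else sp_fft.dct
                    work = f(work, type=inv_type[typ], axis=axis, norm="ortho")
                work[~self.active[c]] = held
                out.append(work.ravel())
            out.append(p.ravel())  # Schur ~ identity in nondimensional scaling
            return np.concatenate(out)

        return apply


def _flood_fill_fluid(solid: np.ndarray) -> np.ndarray:
    """Close off fluid pockets unreachable from the open boundary faces."""
    fluid = ~solid
    labels, n = ndimage.label(fluid)
    if n <= 1:
        return solid
    reachable: set[int] = set()
    for face in (
        labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]
    ):
        reachable |= set(np.unique(face))
    reachable.discard(0)
    pocket = fluid & ~np.isin(labels, sorted(reachable))
    if pocket.any():
        solid = solid.copy()
        solid[pocket] = True
    return solid


def solve_flow(
    geometry: FoamGeometry | TipArray | None,
    fluid: FluidProperties,
    inlet_speed: float,
    inlet_direction: tuple[float, float, float] | None = None,
    spacing: float | None = None,
    extent: tuple[float, float, float] | None = None,
    boundary: dict[str, BoundaryCondition] | None = None,
    solid: np.ndarray | None = None,
    tolerance: float = 1e-6,
    max_iterations: int = 4000,
    min_obstacle_cells: int = 4,
) -> FlowField:
    """Solve steady Stokes flow around a foam slab or nanotip array.

    The convergence criterion is on mass conservation: the maximum cell
    divergence, normalised by inlet_speed / spacing, must fall below
    ``tolerance``.  ``geometry=None`` with explicit ``extent`` (plus
    optional ``solid`` mask and ``boundary`` overrides) solves a bare box —
    used for channel benchmarks.  A Reynolds number above 1 (leaving the
    Stokes regime) is recorded as a warning in the report; non-convergence
    raises :class:`FlowConvergenceError` with the residual history.
    """
    if geometry is not None:
        if spacing is None:
            spacing = (
                geometry.tip_diameter / min_obstacle_cells
                if isinstance(geometry, TipArray)
                else geometry.mean_pore_size / 20.0
            )
        if isinstance(geometry, FoamGeometry):
            extent = geometry.domain_extent
            shape = tuple(max(2, round(e / spacing)) for e in extent)
            mask = geometry.solid_mask(shape)
            scale = geometry.mean_pore_size
        else:
            extent = tip_domain_extent(geometry)
            shape = tuple(max(2, round(e / spacing)) for e in extent)
            mask = tip_array_solid_mask(geometry, shape, extent)
            scale = geometry.tip_diameter
        if not geometry_is_empty(geometry) and scale / spacing < min_obstacle_cells - 1e-9:
            raise ValueError(
                f"spacing {spacing:g} m does not resolve the smallest obstacle "
                f"({scale:g} m) with at least {min_obstacle_cells} cells"
            )
        bc = _default_boundaries(geometry)
    else:
        if extent is None or spacing is None:
            raise ValueError("bare-box solves need explicit extent and spacing")
        shape = tuple(max(2, round(e / spacing)) for e in extent)
        mask = (
            np.zeros(shape, dtype=bool) if solid is None else np.asarray(solid, dtype=bool)
        )
        scale = min(extent)
        bc = _default_boundaries(None)
    if boundary:
        bc = {**bc, **boundary}

    if inlet_direction is None:
        if isinstance(geometry, TipArray):
            th = math.radians(geometry.incident_flow_angle)
            inlet_direction = (math.cos(th), 0.0, -math.sin(th))
        else:
            inlet_direction = (1.0, 0.0, 0.0)
    direction = np.asarray(inlet_direction, dtype=float)
    nrm = float(np.linalg.norm(direction))
    if inlet_speed != 0 and nrm == 0:
        raise ValueError("inlet_direction must be a non-zero vector")
    direction = direction / nrm if nrm else direction
    inlet_velocity = tuple(float(inlet_speed) * direction)
    bc = {
        face: (
            BoundaryCondition("inlet", inlet_velocity) if b.kind == "inlet" else b
        )
        for face, b in bc.items()
    }

    mask = _flood_fill_fluid(mask)
    warnings: list[str] = []
    reynolds = fluid.density * abs(inlet_speed) * scale / fluid.dynamic_viscosity
    if reynolds > 1.0:
        warnings.append(
            f"Reynolds number {reynolds:.3g} > 1: outside the Stokes regime"
        )

    # nondimensionalize: lengths by spacing, velocity by uref, p by mu*uref/h
    body = fluid.body_force_array()
    mu = fluid.dynamic_viscosity
    uref = max(
        abs(inlet_speed),
        float(np.max(np.abs(body))) * spacing**2 / mu,
    )
    if uref == 0.0:
        zero = FlowField(
            shape=shape,
            spacing=spacing,
            u=np.zeros((shape[0] + 1, shape[1], shape[2])),
            v=np.zeros((shape[0], shape[1] + 1, shape[2])),
            w=np.zeros((shape[0], shape[1], shape[2] + 1)),
            p=np.zeros(shape),
            solid=mask,
            boundary=bc,
            fluid=fluid,
            report={"reynolds": 0.0, "iterations": 0, "warnings": warnings,
                    "relative_residual": 0.0, "max_divergence_normalised": 0.0,
                    "residual_history": []},
        )
        return zero

    bc_scaled = {
        face: BoundaryCondition(b.kind, tuple(np.asarray(b.velocity) / uref))
        for face, b in bc.items()
    }
    sys_ = _StokesSystem(shape, mask, bc_scaled)
    b_vec = sys_.rhs(body * spacing**2 / (mu * uref))
    op = LinearOperator((sys_.total, sys_.total), matvec=sys_.matvec, dtype=float)
    M = LinearOperator(
        (sys_.total, sys_.total), matvec=sys_.build_preconditioner(), dtype=float
    )

    bnorm = float(np.linalg.norm(b_vec))
    history: list[float] = []
    n_iter = [0]

    def cb(_xk):
        n_iter[0] += 1

    def div_norm_of(x_vec):
        uu, vv, ww, _ = sys_.unpack(x_vec)
        for c, arr in enumerate((uu, vv, ww)):
            # sys_ was built from the nondimensional boundary conditions
            arr[~sys_.active[c]] = sys_.dirichlet[c][~sys_.active[c]]
        div = np.abs(_divergence_faces(uu, vv, ww))
        div[mask] = 0.0
        return float(div.max())  # nondimensional: already per cell width / uref

    # MINRES with restarts: the preconditioned residual estimate can stall
    # marginally above the mass-conservation target, so iterate in chunks
    # against the divergence criterion itself
    chunk = max(200, max_iterations // 8)
    x = np.zeros(sys_.total)
    resid = 1.0
    while True:
        x, _info = minres(op, b_vec, x0=x, rtol=1e-12, maxiter=chunk, M=M, callback=cb)
        resid = float(np.linalg.norm(sys_.matvec(x) - b_vec) / bnorm) if bnorm else 0.0
        history.append(resid)
        if div_norm_of(x) <= tolerance or n_iter[0] >= max_iterations:
            break
        if len(history) >= 3 and abs(history[-1] - history[-2]) < 1e-3 * history[-1]:
            break  # fully stagnated
    u, v, w, p = sys_.unpack(x)

    for c, arr in enumerate((u, v, w)):
        arr[~sys_.active[c]] = sys_.dirichlet[c][~sys_.active[c]]
    p[mask] = 0.0

    field_ = FlowField(
        shape=shape,
        spacing=spacing,
        u=u * uref,
        v=v * uref,
        w=w * uref,
        p=p * mu * uref / spacing,
        solid=mask,
        boundary=bc,
        fluid=fluid,
    )
    div_norm = float(
        np.abs(field_.divergence()).max() * spacing / max(abs(inlet_speed), uref)
    )
    field_.report = {
        "reynolds": reynolds,
        "iterations": n_iter[0],
        "relative_residual": resid,
        "max_divergence_normalised": div_norm,
        "residual_history": history,
        "warnings": warnings,
        "shape": shape,
        "spacing": spacing,
    }
    if div_norm > tolerance:
        raise FlowConvergenceError(
            f"Stokes solve missed the divergence tolerance "
            f"({div_norm:.3g} > {tolerance:g}) after {n_iter[0]} iterations",
            history,
        )
    return field_


def geometry_is_empty(geometry) -> bool:
    return isinstance(geometry, FoamGeometry) and geometry.is_empty


# ---------------------------------------------------------------------------
# sampling and reporting


def _interp_component(arr, pts, h, node_axis):
    coords = []
    for axis in range(3):
        c = pts[:, axis] / h - (0.0 if axis == node_axis else 0.5)
        coords.append(np.clip(c, 0.0, arr.shape[axis] - 1.0))
    i0 = [np.minimum(np.floor(c).astype(int), arr.shape[a] - 1) for a, c in enumerate(coords)]
    i1 = [np.minimum(i + 1, arr.shape[a] - 1) for a, i in enumerate(i0)]
    f = [c - i for c, i in zip(coords, i0)]
    out = np.zeros(len(pts))
    for dx in (0, 1):
        wx = f[0] if dx else 1 - f[0]
        ix = i1[0] if dx else i0[0]
        for dy in (0, 1):
            wy = f[1] if dy else 1 - f[1]
            iy = i1[1] if dy else i0[1]
            for dz in (0, 1):
                wz = f[2] if dz else 1 - f[2]
                iz = i1[2] if dz else i0[2]
                out += wx * wy * wz * arr[ix, iy, iz]
    return out


def sample_velocity(field: FlowField, position) -> np.ndarray:
    """Trilinear velocity at arbitrary points, exactly zero inside solids.

    ``position`` is a 3-vector or an (n, 3) array in metres; points outside
    the domain raise ``ValueError``.
    """
    single = np.asarray(position).ndim == 1
    pts = np.atleast_2d(np.asarray(position, dtype=float))
    ext = np.asarray(field.extent)
    if np.any(pts < -1e-9 * ext) or np.any(pts > ext * (1 + 1e-9)):
        raise ValueError("position outside the flow domain")
    h = field.spacing
    out = np.column_stack(
        [
            _interp_component(field.u, pts, h, 0),
            _interp_component(field.v, pts, h, 1),
            _interp_component(field.w, pts, h, 2),
        ]
    )
    cell = np.clip((pts / h).astype(int), 0, np.asarray(field.shape) - 1)
    out[field.solid[cell[:, 0], cell[:, 1], cell[:, 2]]] = 0.0
    return out[0] if single else out


def flow_report(field: FlowField) -> dict:
    """Summary: speed range, divergence norm, inflow/outflow flux balance."""
    speed = np.linalg.norm(field.cell_center_velocity(), axis=-1)
    fluid_cells = ~field.solid
    area = field.spacing**2
    flux_in = flux_out = 0.0
    for axis, arr in enumerate((field.u, field.v, field.w)):
        lo = float(arr.take([0], axis=axis).sum()) * area  # + sense = inflow at lo
        hi = float(arr.take([arr.shape[axis] - 1], axis=axis).sum()) * area
        flux_in += max(lo, 0.0) + max(-hi, 0.0)
        flux_out += max(-lo, 0.0) + max(hi, 0.0)
    balance = abs(flux_in - flux_out) / max(flux_in, flux_out, 1e-300)
    return {
        "min_speed": float(speed[fluid_cells].min()) if fluid_cells.any() else 0.0,
        "max_speed": float(speed[fluid_cells].max()) if fluid_cells.any() else 0.0,
        "max_divergence": float(np.abs(field.divergence()).max()),
        "flux_in": flux_in,
        "flux_out": flux_out,
        "flux_balance_error": float(balance),
        **field.report,
    }
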