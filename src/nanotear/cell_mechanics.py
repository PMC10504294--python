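"""AFM indentation mechanics and envelope rupture-stress assessment.

Two questions are answered here for a rod-shaped bacterium in flow past a
nanotip array:

1. How stiff is the cell?  Sneddon (conical indenter) and Hertz (spherical
   indenter) contact laws are fitted to AFM force-indentation curves to
   extract a Young's modulus, and the breakthrough (puncture) indentation is
   located from the force drop on the approach branch.

2. Can the flow rupture it?  Two loading modes are assessed against a
   critical envelope stress ``sigma_c`` (default 0.05 MPa, the puncture
   threshold measured by AFM):

   * **collision** — an instantaneous impact on a nanotip.  The impact energy
     (the cell's kinetic energy at the near-wall flow speed) is stored
     quasi-statically in the thin-shell indentation stiffness of the envelope
     (Reissner point-load stiffness ``k = 4 E t^2 / (R sqrt(3 (1 - nu^2)))``),
     and the resulting concentrated load produces a local bending stress in
     the shell wall.

   * **tearing** — the cell is anchored to a tip by dispersion adhesion while
     the flow drags it.  The Stokes drag is transmitted through the adhesive
     contact as a concentrated load on the load-bearing outer membrane, whose
     local bending stress is evaluated with the same point-load formula.

   Both modes use the classical concentrated-load bending stress of a thin
   plate/shallow shell (Roark), ``sigma = 3 P / (2 pi t^2) *
   [(1 + nu) ln(b / a') + 1]``, where ``b`` is the supported patch radius,
   and ``a'`` is Roark's equivalent contact radius
   ``sqrt(1.6 a^2 + t^2) - 0.675 t``, which regularises loads concentrated
   below the wall-thickness scale.  The two modes differ in which layer bears
   the load: collisions compress the composite envelope (default 20 nm),
   tearing peels the outer lipid bilayer (default 4 nm).  These are
   deliberately simple desk-scale closed forms; only orders of magnitude and
   the collision-vs-tearing ordering are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "IndentationModel",
    "ForceCurve",
    "FitResult",
    "StressAssessment",
    "indentation_force",
    "fit_modulus",
    "detect_puncture",
    "spherocylinder_volume",
    "kinetic_energy",
    "collision_stress",
    "stokes_drag_force",
    "tearing_stress",
    "rupture_verdict",
]

#: Critical envelope rupture stress, Pa (0.05 MPa from the AFM puncture test).
CRITICAL_STRESS = 5.0e4

#: Default composite envelope thickness for collision loading, m.
ENVELOPE_THICKNESS = 20e-9

#: Default load-bearing outer-membrane (bilayer) thickness for tearing, m.
MEMBRANE_THICKNESS = 4e-9


@dataclass(frozen=True)
class IndentationModel:
    """Indenter geometry for a contact-mechanics force law.

    ``sneddon_cone`` requires ``half_opening_angle`` (degrees);
    ``hertz_sphere`` requires ``tip_radius`` (m).  ``poisson_ratio`` defaults
    to 0.5 (incompressible cell).
    """

    kind: Literal["sneddon_cone", "hertz_sphere"]
    tip_radius: Optional[float] = None
    half_opening_angle: Optional[float] = None
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.kind == "sneddon_cone":
            if self.half_opening_angle is None or not 0 < self.half_opening_angle < 90:
                raise ValueError("sneddon_cone requires half_opening_angle in (0, 90) deg")
        elif self.kind == "hertz_sphere":
            if self.tip_radius is None or self.tip_radius <= 0:
                raise ValueError("hertz_sphere requires a positive tip_radius")
        else:
            raise ValueError(f"unknown indentation model kind {self.kind!r}")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")

    @property
    def exponent(self) -> float:
        """Power-law exponent of F(delta) for this indenter."""
        return 2.0 if self.kind == "sneddon_cone" else 1.5


@dataclass(frozen=True)
class ForceCurve:
    """An AFM displacement-force series for one branch of a force cycle."""

    displacement: np.ndarray  # m, strictly monotone within the branch
    force: np.ndarray  # N
    branch: Literal["approach", "retract"] = "approach"

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D arrays")
        steps = np.diff(d)
        if len(steps) and not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("displacement must be strictly monotone within a branch")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class FitResult:
    """Elastic modulus extracted from a force curve."""

    youngs_modulus: float  # Pa
    fit_window: tuple[int, int]  # [start, stop) sample indices used
    rms_residual: float  # N

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("fitted Young's modulus must be positive")


@dataclass(frozen=True)
class StressAssessment:
    """Maximum envelope stress of one loading mode versus the critical stress."""

    mode: Literal["collision", "tearing"]
    contact_form: Literal["end", "middle"]
    max_stress: float  # Pa
    critical_stress: float  # Pa
    verdict: Literal["intact", "ruptured"]
    model_notes: str = ""


def _reduced_modulus(youngs_modulus: float, poisson_ratio: float) -> float:
    return youngs_modulus / (1.0 - poisson_ratio**2)


def indentation_force(model: IndentationModel, youngs_modulus: float, delta) -> np.ndarray | float:
    """Contact force F(delta) of the forward indentation model.

    sneddon_cone: F = (2/pi) tan(alpha) E/(1-nu^2) delta^2
    hertz_sphere: F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2)
    """
    if youngs_modulus <= 0:
        raise ValueError("Young's modulus must be positive")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation depth must be non-negative")
    e_star = _reduced_modulus(youngs_modulus, model.poisson_ratio)
    if model.kind == "sneddon_cone":
        alpha = math.radians(model.half_opening_angle)
        out = (2.0 / math.pi) * math.tan(alpha) * e_star * d**2
    else:
        out = (4.0 / 3.0) * e_star * math.sqrt(model.tip_radius) * d**1.5
    return out if out.ndim else float(out)


def fit_modulus(
    curve: ForceCurve,
    model: IndentationModel,
    window: float = 0.5,
) -> FitResult:
    """Least-squares Young's modulus from the early part of an approach curve.

    The model power law ``F = c * delta^m`` is linear in ``c``; the fit uses
    samples with ``delta <= window * max(delta)``.  The modulus follows from
    ``c`` by inverting the prefactor of :func:`indentation_force`.
    """
    if curve.branch != "approach":
        raise ValueError("modulus is fitted on the approach branch")
    if not 0 < window <= 1:
        raise ValueError("window must be a fraction of max indentation in (0, 1]")
    d = curve.displacement
    f = curve.force
    if d[0] > d[-1]:  # normalise to increasing indentation
        d, f = d[::-1], f[::-1]
    d0 = d - d[0]
    stop = int(np.searchsorted(d0, window * d0[-1], side="right"))
    if stop < 3:
        raise ValueError("fit window contains fewer than 3 samples")
    dd, ff = d0[:stop], f[:stop]
    m = model.exponent
    basis = dd**m
    denom = float(basis @ basis)
    if denom == 0:
        raise ValueError("fit window has zero indentation range")
    c = float(basis @ ff) / denom
    if c <= 0:
        raise ValueError("non-positive contact stiffness: curve does not look like loading")
    unit = indentation_force(model, 1.0, 1.0)  # prefactor at E = 1 Pa, delta = 1 m
    modulus = c / unit
    resid = ff - c * basis
    return FitResult(
        youngs_modulus=modulus,
        fit_window=(0, stop),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def detect_puncture(curve: ForceCurve, drop_threshold: float = 0.1) -> Optional[float]:
    """Breakthrough indentation: first force drop >= threshold of the running max.

    Returns the displacement (relative to the curve start) at which the force
    last peaked before the drop, or ``None`` for a monotone curve.  A zero
    threshold degenerates to the first non-increasing sample.
    """
    if curve.branch != "approach":
        raise ValueError("puncture is detected on the approach branch")
    if drop_threshold < 0:
        raise ValueError("drop_threshold must be non-negative")
    d = curve.displacement
    f = curve.force
    if d[0] > d[-1]:
        d, f = d[::-1], f[::-1]
    running_max = np.maximum.accumulate(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = np.where(running_max > 0, (running_max - f) / running_max, 0.0)
    hits = np.flatnonzero(drop > drop_threshold) if drop_threshold == 0 else np.flatnonzero(
        drop >= drop_threshold
    )
    if drop_threshold == 0:
        hits = np.flatnonzero(running_max - f > 0)
    if len(hits) == 0:
        return None
    i = hits[0]
    peak = int(np.argmax(f[: i + 1]))
    return float(d[peak] - d[0])


def spherocylinder_volume(diameter: float, total_length: float) -> float:
    """Volume of a cylinder with hemispherical caps (total tip-to-tip length)."""
    if diameter <= 0 or total_length < diameter:
        raise ValueError("need diameter > 0 and total_length >= diameter")
    r = diameter / 2.0
    return math.pi * r**2 * (total_length - diameter) + (4.0 / 3.0) * math.pi * r**3


def kinetic_energy(
    diameter: float,
    total_length: float,
    density: float,
    speed: float,
) -> float:
    """Kinetic energy (1/2) m v^2 of a spherocylindrical cell, J."""
    if density <= 0:
        raise ValueError("density must be positive")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    mass = density * spherocylinder_volume(diameter, total_length)
    return 0.5 * mass * speed**2


def stokes_drag_force(diameter: float, viscosity: float, relative_speed: float) -> float:
    """Stokes drag F_D = 3 pi mu d du on a sphere in creeping flow, N."""
    if diameter < 0 or viscosity < 0 or relative_speed < 0:
        raise ValueError("inputs must be non-negative")
    return 3.0 * math.pi * viscosity * diameter * relative_speed


def _roark_equivalent_radius(contact_radius: float, thickness: float) -> float:
    """Roark's equivalent radius for loads concentrated below the wall thickness."""
    if contact_radius >= 0.5 * thickness:
        return contact_radius
    return math.sqrt(1.6 * contact_radius**2 + thickness**2) - 0.675 * thickness


def _point_load_bending_stress(
    load: float,
    thickness: float,
    patch_radius: float,
    contact_radius: float,
    poisson_ratio: float,
) -> float:
    """Concentrated-load bending stress of a thin plate/shallow shell (Roark).

    sigma = 3 P / (2 pi t^2) * [(1 + nu) ln(b / a') + 1], with a' the
    equivalent contact radius and b the supported patch radius.
    """
    a_eq = _roark_equivalent_radius(contact_radius, thickness)
    a_eq = min(a_eq, patch_radius / math.e)  # keep the log factor >= 1
    factor = (1.0 + poisson_ratio) * math.log(patch_radius / a_eq) + 1.0
    return 3.0 * load / (2.0 * math.pi * thickness**2) * factor


def collision_stress(
    kinetic_energy_loss: float,
    youngs_modulus: float,
    tip_diameter: float = 200e-9,
    contact_form: Literal["end", "middle"] = "end",
    cell_diameter: float = 0.5e-6,
    shell_thickness: float = ENVELOPE_THICKNESS,
    poisson_ratio: float = 0.5,
    critical_stress: float = CRITICAL_STRESS,
) -> StressAssessment:
    """Maximum envelope stress when a collision's kinetic energy loads the shell.

    The work done by the tip equals the lost kinetic energy and is stored in
    the thin-shell point-load stiffness ``k = 4 E t^2 / (R sqrt(3(1-nu^2)))``
    (Reissner), so the peak transmitted load is ``P = sqrt(2 E_k k)``.  The
    resulting local bending stress is evaluated with the plate point-load
    formula; the contact radius follows the Hertzian estimate
    ``a = sqrt(R_c * delta)`` with the contact curvature ``R_c`` set by the
    contact form (cell pole cap on the flat tip top for ``end``; crossed
    cell-side/tip-rim curvatures for ``middle``).
    """
    if kinetic_energy_loss < 0:
        raise ValueError("kinetic energy loss must be non-negative")
    if youngs_modulus <= 0 or tip_diameter <= 0 or cell_diameter <= 0:
        raise ValueError("moduli and dimensions must be positive")
    r_shell = cell_diameter / 2.0
    t = shell_thickness
    stiffness = 4.0 * youngs_modulus * t**2 / (
        r_shell * math.sqrt(3.0 * (1.0 - poisson_ratio**2))
    )
    if kinetic_energy_loss == 0:
        return StressAssessment(
            mode="collision",
            contact_form=contact_form,
            max_stress=0.0,
            critical_stress=critical_stress,
            verdict="intact",
            model_notes="zero impact energy",
        )
    delta = math.sqrt(2.0 * kinetic_energy_loss / stiffness)
    if delta > r_shell:
        raise ValueError(
            "impact energy exceeds the validity of the thin-shell contact model "
            f"(delta = {delta:.3g} m > cell radius {r_shell:.3g} m)"
        )
    load = stiffness * delta
    if contact_form == "end":
        r_contact = r_shell  # pole cap pressed on the flat tip top
    elif contact_form == "middle":
        r_rim = tip_diameter / 2.0
        r_contact = 1.0 / (1.0 / r_shell + 1.0 / r_rim)  # crossed curvatures
    else:
        raise ValueError(f"unknown contact form {contact_form!r}")
    a = math.sqrt(r_contact * delta)
    patch = math.sqrt(r_shell * t)  # shell bending length bounds the stressed zone
    stress = _point_load_bending_stress(load, t, patch, a, poisson_ratio)
    assessment = StressAssessment(
        mode="collision",
        contact_form=contact_form,
        max_stress=stress,
        critical_stress=critical_stress,
        verdict="ruptured" if stress >= critical_stress else "intact",
        model_notes=(
            f"Reissner shell stiffness k={stiffness:.3g} N/m, "
            f"delta_max={delta:.3g} m, peak load P={load:.3g} N"
        ),
    )
    return assessment


def tearing_stress(
    drag: float,
    contact_patch_diameter: float = 200e-9,
    shell_thickness: float = MEMBRANE_THICKNESS,
    contact_form: Literal["end", "middle"] = "end",
    poisson_ratio: float = 0.5,
    critical_stress: float = CRITICAL_STRESS,
) -> StressAssessment:
    """Maximum membrane stress when flow drag peels an adhesion-anchored cell.

    The Stokes drag on the trapped cell is transmitted through the dispersion
    adhesion contact as a concentrated load on the load-bearing outer
    membrane (thickness ``shell_thickness``, default a 4-nm bilayer).  The
    local bending stress at the contact follows the plate point-load formula
    with the adhered patch radius set by the tip (``contact_patch_diameter``).
    The stress is linear in the drag force.
    """
    if drag < 0:
        raise ValueError("drag force must be non-negative")
    if contact_patch_diameter <= 0 or shell_thickness <= 0:
        raise ValueError("patch diameter and shell thickness must be positive")
    if contact_form not in ("end", "middle"):
        raise ValueError(f"unknown contact form {contact_form!r}")
    patch = contact_patch_diameter / 2.0
    stress = _point_load_bending_stress(
        drag, shell_thickness, patch, 0.0, poisson_ratio
    )
    return StressAssessment(
        mode="tearing",
        contact_form=contact_form,
        max_stress=stress,
        critical_stress=critical_stress,
        verdict="ruptured" if stress >= critical_stress else "intact",
        model_notes=(
            f"point load {drag:.3g} N on a {shell_thickness * 1e9:.3g}-nm membrane, "
            f"patch radius {patch * 1e9:.3g} nm"
        ),
    )


def rupture_verdict(assessment: StressAssessment) -> str:
    """Rupture verdict: 'ruptured' iff max_stress >= critical stress (tie inclusive)."""
    return "ruptured" if assessment.max_stress >= assessment.critical_stress else "intact"
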