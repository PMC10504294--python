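"""Configuration and pipeline runner chaining all analysis stages.

One :class:`PipelineConfig` (a plain YAML-serializable record with explicit
units on every physical quantity) drives the chain

    tip-array flow solve -> bead-stick contact simulation ->
    collision/tearing stress assessment -> disinfection metrics
    [-> optional foam transport stage]

and produces a :class:`PipelineReport` whose every number is traceable to a
stage output.  Seeds are explicit, so a saved config re-runs to identical
results for the deterministic stages and to identical stochastic draws for
the sampled ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import cell_mechanics as cm
from . import disinfection_metrics as dm
from .constants import FluidProperties, PhysicalConstants
from .flow_field import FlowField, solve_flow, flow_report
from .foam_transport import track_particles, extrapolate_collision_probability
from .nanotip_contact import CellParameters, simulate_contacts, contact_statistics
from .synthetic_data import TipArray, generate_tip_array, generate_foam

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "validate_config"]


@dataclass
class TipArrayConfig:
    n_x: int = 5
    n_y: int = 5
    tip_diameter_nm: float = 200.0
    tip_length_um: float = 5.0
    gap_um: float = 1.0
    incident_angle_deg: float = 45.0

    def build(self) -> TipArray:
        return generate_tip_array(
            self.n_x, self.n_y, self.tip_diameter_nm * 1e-9,
            self.tip_length_um * 1e-6, self.gap_um * 1e-6, self.incident_angle_deg,
        )


@dataclass
class FoamConfig:
    enabled: bool = False
    mean_pore_um: float = 200.0
    domain_um: tuple[float, float, float] = (520.0, 420.0, 420.0)
    porosity: float = 0.95
    influent_speed_mm_s: float = 1.0
    n_particles: int = 1681
    dt_s: float = 2e-3
    max_time_s: float = 4.0
    spacing_um: float = 10.0
    target_thickness_mm: float = 3.0


@dataclass
class FluidConfig:
    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 1.0e-3
    temperature_k: float = 298.0

    def build(self) -> FluidProperties:
        return FluidProperties(self.density_kg_m3, self.viscosity_pa_s)

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(temperature=self.temperature_k)


@dataclass
class ContactConfig:
    n_cells: int = 100
    dt_s: float = 1e-6
    max_time_s: float = 0.05
    bead_radius_um: float = 0.25
    rest_length_um: float = 0.5
    spring_stiffness_n_m: float = 2.0e-4

    def build(self) -> CellParameters:
        return CellParameters(
            bead_radius=self.bead_radius_um * 1e-6,
            rest_length=self.rest_length_um * 1e-6,
            spring_stiffness=self.spring_stiffness_n_m,
        )


@dataclass
class MechanicsConfig:
    youngs_modulus_mpa: float = 0.5
    poisson_ratio: float = 0.5
    critical_stress_mpa: float = 0.05
    envelope_thickness_nm: float = 20.0
    membrane_thickness_nm: float = 4.0
    cell_diameter_um: float = 0.5
    cell_total_length_um: float = 1.0
    cell_density_kg_m3: float = 1000.0
    near_wall_speed_m_s: float = 5.0e-5
    drag_diameter_um: float = 1.0


@dataclass
class OperatingConfig:
    flow_rate_ml_min: float = 2.7
    filtration_area_mm2: float = 78.5
    foam_thickness_mm: float = 4.0
    duration_days: float = 30.0
    chamber_volume_ml: float = 10.9
    influent_cfu_ml: float = 4.0e6


@dataclass
class PipelineConfig:
    """Full pipeline configuration; bench units in field names, SI internally."""

    tips: TipArrayConfig = field(default_factory=TipArrayConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    operating: OperatingConfig = field(default_factory=OperatingConfig)
    foam: FoamConfig = field(default_factory=FoamConfig)
    main_flow_speed_m_s: float = 5.5e-4
    flow_spacing_nm: float = 50.0
    flow_tolerance: float = 1e-6
    seed: int = 0
    output_dir: Optional[str] = None

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for name, sub in (
            ("tips", TipArrayConfig), ("fluid", FluidConfig),
            ("contact", ContactConfig), ("mechanics", MechanicsConfig),
            ("operating", OperatingConfig), ("foam", FoamConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                d = dict(kwargs[name])
                if name == "foam" and "domain_um" in d:
                    d["domain_um"] = tuple(d["domain_um"])
                kwargs[name] = sub(**d)
        return cls(**kwargs)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where artifacts land is not physics
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Per-stage summaries plus provenance; serializable to JSON."""

    provenance: dict
    flow: dict
    contacts: dict
    stresses: dict
    metrics: dict
    foam: Optional[dict] = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=str))
        return path

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[dict]:
    """Unit, regime and stability checks; returns findings, raises nothing."""
    findings: list[dict] = []

    def add(level, message):
        findings.append({"level": level, "message": message})

    if config.fluid.viscosity_pa_s <= 0:
        add("error", "fluid viscosity must be positive")
    if config.fluid.density_kg_m3 <= 0:
        add("error", "fluid density must be positive")
    if config.fluid.temperature_k <= 0:
        add("error", "temperature must be positive")
    if config.mechanics.youngs_modulus_mpa <= 0:
        add("error", "Young's modulus must be positive")
    if not 0 <= config.mechanics.poisson_ratio <= 0.5:
        add("error", "Poisson ratio must lie in [0, 0.5]")
    if config.flow_spacing_nm * 1e-9 > config.tips.tip_diameter_nm * 1e-9 / 4:
        add("error", "grid spacing does not resolve the tip diameter with 4 cells")

    if config.fluid.viscosity_pa_s > 0:
        re = (
            config.fluid.density_kg_m3
            * config.main_flow_speed_m_s
            * config.tips.tip_diameter_nm
            * 1e-9
            / config.fluid.viscosity_pa_s
        )
        level = "info" if re <= 1 else "warning"
        add(level, f"tip-scale Reynolds number {re:.3g} ({'Stokes regime' if re <= 1 else 'beyond Stokes regime'})")

        params = config.contact.build()
        xi = params.friction(config.fluid.build())
        limit = xi / params.spring_stiffness / 10.0
        if config.contact.dt_s > limit:
            add("error", f"contact dt {config.contact.dt_s:g} s unstable; need < {limit:g} s")
    return findings


def _near_wall_speed(fld: FlowField) -> float:
    """Mean speed one grid cell away from the nearest solid face."""
    from scipy import ndimage

    if not fld.solid.any():
        return float("nan")
    dist = ndimage.distance_transform_edt(~fld.solid)
    band = (dist >= 0.5) & (dist < 1.5)
    speed = np.linalg.norm(fld.cell_center_velocity(), axis=-1)
    return float(speed[band].mean())


def run_pipeline(config: PipelineConfig, flow_field: FlowField | None = None) -> PipelineReport:
    """Execute the full analysis chain and return one report.

    ``flow_field`` may inject an already-solved field (e.g. to share one
    expensive solve across analyses); it must match the configured geometry.
    Stage failures propagate with the failing stage's diagnostics after the
    report assembled so far is written to ``output_dir`` (when set).
    """
    errors = [f for f in validate_config(config) if f["level"] == "error"]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(f["message"] for f in errors))

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    tips = config.tips.build()
    fluid = config.fluid.build()
    constants = config.fluid.constants()

    # stage 1: flow ---------------------------------------------------------
    if flow_field is None:
        flow_field = solve_flow(
            tips, fluid, config.main_flow_speed_m_s,
            spacing=config.flow_spacing_nm * 1e-9,
            tolerance=config.flow_tolerance,
        )
    flow_summary = flow_report(flow_field)
    flow_summary["near_wall_speed_m_s"] = _near_wall_speed(flow_field)
    if outdir:
        (outdir / "flow_report.json").write_text(json.dumps(flow_summary, indent=1, default=str))

    # stage 2: contacts -----------------------------------------------------
    events = simulate_contacts(
        flow_field, tips,
        n_cells=config.contact.n_cells,
        seed=config.seed,
        params=config.contact.build(),
        constants=constants,
        fluid=fluid,
        dt=config.contact.dt_s,
        max_time=config.contact.max_time_s,
    )
    try:
        stats = contact_statistics(events)
    except ValueError:
        stats = {"n_contacts": 0, "n_events": len(events)}
    contact_summary = {**stats}
    if outdir:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "cell": e.cell_id, "time_s": e.time, "tip": e.tip_index,
                    "class": e.contact_class, "subtype": e.subtype,
                    "x_m": e.point[0], "y_m": e.point[1], "z_m": e.point[2],
                    "reason": e.reason,
                }
                for e in events
            ]
        ).to_csv(outdir / "contact_events.csv", index=False)

    # stage 3: stresses -----------------------------------------------------
    mech = config.mechanics
    e_pa = mech.youngs_modulus_mpa * 1e6
    sigma_c = mech.critical_stress_mpa * 1e6
    e_k = cm.kinetic_energy(
        mech.cell_diameter_um * 1e-6, mech.cell_total_length_um * 1e-6,
        mech.cell_density_kg_m3, mech.near_wall_speed_m_s,
    )
    drag = cm.stokes_drag_force(
        mech.drag_diameter_um * 1e-6, fluid.dynamic_viscosity, mech.near_wall_speed_m_s
    )
    assessments = {}
    for form in ("end", "middle"):
        col = cm.collision_stress(
            e_k, e_pa, tips.tip_diameter, form,
            cell_diameter=mech.cell_diameter_um * 1e-6,
            shell_thickness=mech.envelope_thickness_nm * 1e-9,
            poisson_ratio=mech.poisson_ratio,
            critical_stress=sigma_c,
        )
        tear = cm.tearing_stress(
            drag, tips.tip_diameter,
            shell_thickness=mech.membrane_thickness_nm * 1e-9,
            contact_form=form,
            poisson_ratio=mech.poisson_ratio,
            critical_stress=sigma_c,
        )
        assessments[form] = {
            "collision_stress_mpa": col.max_stress / 1e6,
            "collision_verdict": col.verdict,
            "tearing_stress_mpa": tear.max_stress / 1e6,
            "tearing_verdict": tear.verdict,
        }
    stress_summary = {
        "kinetic_energy_j": e_k,
        "stokes_drag_n": drag,
        "critical_stress_mpa": mech.critical_stress_mpa,
        "per_contact_form": assessments,
    }
    if outdir:
        (outdir / "stress_assessments.json").write_text(
            json.dumps(stress_summary, indent=1)
        )

    # stage 4 (optional): foam transport ------------------------------------
    foam_summary = None
    if config.foam.enabled:
        fc = config.foam
        foam = generate_foam(
            fc.mean_pore_um * 1e-6,
            tuple(d * 1e-6 for d in fc.domain_um),
            fc.porosity,
            seed=config.seed + 1,
        )
        foam_field = solve_flow(
            foam, fluid, fc.influent_speed_mm_s * 1e-3, spacing=fc.spacing_um * 1e-6
        )
        result = track_particles(
            foam_field, foam, fc.n_particles, fc.dt_s, fc.max_time_s,
            seed=config.seed + 2, constants=constants,
        )
        ratio = fc.target_thickness_mm * 1e-3 / foam.domain_extent[0]
        # particles still in the domain at cutoff are counted as not collided
        non_collided = 1.0 - result.collision_fraction
        foam_summary = {
            "porosity": foam.porosity,
            "mean_pore_size_um": foam.mean_pore_size * 1e6,
            "n_released": result.n_released,
            "n_collided": result.n_collided,
            "n_escaped": result.n_escaped,
            "n_in_domain": result.n_in_domain,
            "collision_fraction": result.collision_fraction,
            "extrapolated_collision_probability": extrapolate_collision_probability(
                non_collided, ratio
            ),
            "thickness_ratio": ratio,
        }
        if outdir:
            (outdir / "foam_transport.json").write_text(json.dumps(foam_summary, indent=1))

    # stage 5: disinfection metrics -----------------------------------------
    op = config.operating
    v_water, capacity = dm.treating_capacity(
        op.flow_rate_ml_min, op.duration_days * 24 * 60, op.chamber_volume_ml
    )
    metrics = {
        "flux_m3_h_m2": dm.flux(op.flow_rate_ml_min, op.filtration_area_mm2),
        "residence_time_s": dm.residence_time(
            op.filtration_area_mm2, op.foam_thickness_mm, op.flow_rate_ml_min
        ),
        "treated_volume_l": v_water,
        "treating_capacity_ratio": capacity,
        "log_removal_complete_inactivation": dm.log_removal(
            op.influent_cfu_ml, dm.DisinfectionSample(0.0, True, 0)
        ),
    }
    if outdir:
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))

    import nanotear

    report = PipelineReport(
        provenance={
            "config_digest": config.digest(),
            "seed": config.seed,
            "package_version": getattr(nanotear, "__version__", "unknown"),
        },
        flow={k: flow_summary[k] for k in (
            "min_speed", "max_speed", "near_wall_speed_m_s", "flux_balance_error",
            "max_divergence_normalised", "reynolds", "iterations",
        ) if k in flow_summary},
        contacts=contact_summary,
        stresses=stress_summary,
        metrics=metrics,
        foam=foam_summary,
    )
    if outdir:
        report.to_json(outdir / "report.json")
    return report
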