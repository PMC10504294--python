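"""Plate-count and hydraulic bookkeeping for flow-through disinfection tests.

Concentrations are expressed in CFU/mL, flows in mL/min, areas in mm^2 and
thicknesses in mm — the bench units of a flow-through filtration cell — and
converted internally only where a derived quantity demands it.  The log-removal
convention follows standard practice in water treatment: a sample with no
colonies on any plate is reported as below the 1 CFU/mL detection limit and the
removal credited is log10(C0) (complete inactivation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

__all__ = [
    "PlateCountSet",
    "DisinfectionSample",
    "OperatingPoint",
    "cfu_concentration",
    "log_removal",
    "flux",
    "residence_time",
    "treating_capacity",
]

#: Detection limit of the spread-plate assay, CFU/mL.
DETECTION_LIMIT = 1.0

#: Conventional countable range of colonies per plate.
COUNTABLE_RANGE = (30, 300)


@dataclass(frozen=True)
class PlateCountSet:
    """Colony counts from a serial-dilution spread-plate assay.

    ``colonies[i][j]`` is the colony count of replicate ``j`` plated at
    ``dilution_factors[i]``; ``plated_volume`` is the volume spread per plate
    in mL.
    """

    dilution_factors: tuple[int, ...]
    colonies: tuple[tuple[int, ...], ...]
    plated_volume: float = 0.1

    def __post_init__(self) -> None:
        if len(self.dilution_factors) != len(self.colonies):
            raise ValueError("one colony tuple is required per dilution factor")
        if any(d < 1 for d in self.dilution_factors):
            raise ValueError("dilution factors must be >= 1")
        if any(c < 0 for row in self.colonies for c in row):
            raise ValueError("colony counts must be non-negative")
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive")


@dataclass(frozen=True)
class DisinfectionSample:
    """A water sample's viable concentration derived from plate counts."""

    concentration: float  # CFU/mL; 0.0 when below detection
    below_detection: bool
    n_countable_plates: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.below_detection:
            return f"< {DETECTION_LIMIT:g} CFU/mL"
        return f"{self.concentration:g} CFU/mL"


@dataclass(frozen=True)
class OperatingPoint:
    """Hydraulic operating point of a flow-through disinfection cell."""

    flow_rate: float  # Q, mL/min
    filtration_area: float  # A, mm^2
    foam_thickness: float = 0.0  # total foam thickness in the flow path, mm
    duration: float = 0.0  # min
    chamber_volume: float = 0.0  # V_0, effective chamber volume, mL

    def __post_init__(self) -> None:
        for name in ("flow_rate", "filtration_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("foam_thickness", "duration", "chamber_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def cfu_concentration(
    counts: PlateCountSet,
    countable_range: tuple[int, int] = COUNTABLE_RANGE,
) -> DisinfectionSample:
    """Viable concentration from a serial-dilution plate count.

    Each countable plate (colonies within ``countable_range``) yields the
    estimate ``count * dilution / plated_volume`` in CFU/mL; the sample
    concentration is the mean over countable plates.  When every plate at
    every dilution is zero the sample is reported below the detection limit.

    Raises
    ------
    ValueError
        If no plate is countable but colonies were observed (the assay is
        uncountable rather than sterile).
    """
    lo, hi = countable_range
    estimates = []
    any_colony = False
    for dilution, row in zip(counts.dilution_factors, counts.colonies):
        for c in row:
            any_colony = any_colony or c > 0
            if lo <= c <= hi:
                estimates.append(c * dilution / counts.plated_volume)
    if estimates:
        return DisinfectionSample(
            concentration=float(np.mean(estimates)),
            below_detection=False,
            n_countable_plates=len(estimates),
        )
    if not any_colony:
        return DisinfectionSample(0.0, below_detection=True, n_countable_plates=0)
    raise ValueError(
        "no plate fell in the countable range "
        f"{countable_range}; re-plate at other dilutions"
    )


def log_removal(c0: float, c: float | DisinfectionSample) -> float:
    """Logarithmic removal efficiency -log10(C/C0) in log10 units.

    ``c`` may be a concentration in CFU/mL or a :class:`DisinfectionSample`.
    A below-detection sample means complete inactivation and is credited
    log10(C0).
    """
    if c0 <= 0:
        raise ValueError(f"influent concentration C0 must be positive, got {c0}")
    if isinstance(c, DisinfectionSample):
        if c.below_detection:
            return math.log10(c0)
        c = c.concentration
    if c < 0:
        raise ValueError(f"effluent concentration must be non-negative, got {c}")
    if c == 0:
        return math.log10(c0)
    return -math.log10(c / c0)


def flux(flow_rate: float, area: float) -> float:
    """Superficial loading Q/A converted to m^3 h^-1 m^-2.

    Parameters are the bench units: ``flow_rate`` in mL/min, ``area`` in mm^2.
    """
    if area <= 0:
        raise ValueError(f"filtration area must be positive, got {area}")
    q_m3_per_h = flow_rate * 1e-6 * 60.0
    a_m2 = area * 1e-6
    return q_m3_per_h / a_m2


def residence_time(area: float, total_thickness: float, flow_rate: float) -> float:
    """Contact time in seconds for a foam stack of bulk volume A*thickness.

    Uses the bulk-volume convention (no porosity correction): the treated
    volume per pass is the full geometric volume of the foam pieces.
    ``area`` in mm^2, ``total_thickness`` in mm, ``flow_rate`` in mL/min.
    """
    if flow_rate <= 0:
        raise ValueError(f"flow rate must be positive, got {flow_rate}")
    if total_thickness < 0:
        raise ValueError("thickness must be non-negative")
    volume_ml = area * total_thickness * 1e-3  # mm^3 -> mL
    return volume_ml / flow_rate * 60.0


def treating_capacity(
    flow_rate: float, duration: float, chamber_volume: float
) -> tuple[float, float]:
    """Treated volume V_water (L) and the capacity ratio V_water / V_0.

    ``flow_rate`` in mL/min, ``duration`` in min, ``chamber_volume`` V_0 in mL.
    """
    if flow_rate <= 0 or duration < 0 or chamber_volume <= 0:
        raise ValueError("flow_rate and chamber_volume must be positive, duration >= 0")
    v_water_ml = flow_rate * duration
    return v_water_ml / 1000.0, v_water_ml / chamber_volume
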