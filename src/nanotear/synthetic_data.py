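"""Synthetic geometry and data generators for every pipeline stage.

All quantities are SI (metres, seconds, Pa) unless a function says otherwise.
Four generators cover the inputs the physical stages consume:

* :func:`generate_foam` — an open-cell metal-foam slab built as a Boolean
  (inverse-opal) model: spherical voids with diameters ~ N(mean_pore, 10%)
  are carved from a solid cuboid until the target porosity is reached.
* :func:`generate_tip_array` — a rectangular array of vertical cylindrical
  nanotips on a base plane, with the incident-flow angle recorded.
* :func:`generate_force_curve` — a forward-model AFM indentation curve with
  optional Gaussian force noise and an optional puncture force drop.
* :func:`generate_plate_counts` — Poisson colony counts for a serial
  dilution series.

Each generator takes one integer seed and draws all randomness from a single
``numpy.random.Generator``, so fixed seeds give identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cell_mechanics import ForceCurve, IndentationModel, indentation_force
from .disinfection_metrics import PlateCountSet

__all__ = [
    "FoamGeometry",
    "TipArray",
    "generate_foam",
    "generate_tip_array",
    "generate_force_curve",
    "generate_plate_counts",
]


@dataclass(frozen=True)
class FoamGeometry:
    """A porous slab: solid cuboid minus a union of spherical voids.

    ``domain_extent`` is the (Lx, Ly, Lz) box in metres; void spheres are
    given by ``void_centers`` (n, 3) and ``void_radii`` (n,).  ``porosity``
    and ``mean_pore_size`` are the realized values measured on the
    generator's raster / the realized sphere population.  ``porosity == 1``
    denotes an empty (all-fluid) domain with no solid at all.
    """

    domain_extent: tuple[float, float, float]
    void_centers: np.ndarray
    void_radii: np.ndarray
    porosity: float
    mean_pore_size: float
    seed: int

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.domain_extent):
            raise ValueError(f"degenerate domain extent {self.domain_extent}")
        if not 0 < self.porosity <= 1:
            raise ValueError("porosity must lie in (0, 1]")

    @property
    def is_empty(self) -> bool:
        """True when the domain contains no solid (porosity one)."""
        return len(self.void_radii) == 0 and self.porosity == 1.0

    def clearance_to_solid(self, points: np.ndarray) -> np.ndarray:
        """Conservative distance from points to the solid phase, metres.

        For a point inside void sphere i the clearance is at least
        ``r_i - |p - c_i|``; the maximum of that bound over all spheres is
        returned (a slight underestimate inside overlap lenses).  Points in
        the solid get a non-positive value.  An empty foam returns +inf.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.is_empty:
            return np.full(len(pts), np.inf)
        if len(self.void_radii) == 0:
            return np.full(len(pts), -np.inf)
        d = np.linalg.norm(pts[:, None, :] - self.void_centers[None, :, :], axis=2)
        return np.max(self.void_radii[None, :] - d, axis=1)

    def solid_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Rasterized solid indicator on cell centres of a uniform grid."""
        nx, ny, nz = shape
        ext = self.domain_extent
        xs = (np.arange(nx) + 0.5) * ext[0] / nx
        ys = (np.arange(ny) + 0.5) * ext[1] / ny
        zs = (np.arange(nz) + 0.5) * ext[2] / nz
        if self.is_empty:
            return np.zeros(shape, dtype=bool)
        solid = np.ones(shape, dtype=bool)
        for c, r in zip(self.void_centers, self.void_radii):
            # only touch the sphere's bounding box
            ix = np.flatnonzero(np.abs(xs - c[0]) <= r)
            iy = np.flatnonzero(np.abs(ys - c[1]) <= r)
            iz = np.flatnonzero(np.abs(zs - c[2]) <= r)
            if not (len(ix) and len(iy) and len(iz)):
                continue
            dx2 = (xs[ix] - c[0])[:, None, None] ** 2
            dy2 = (ys[iy] - c[1])[None, :, None] ** 2
            dz2 = (zs[iz] - c[2])[None, None, :] ** 2
            inside = dx2 + dy2 + dz2 <= r * r
            solid[np.ix_(ix, iy, iz)] &= ~inside
        return solid

    def to_vtk(self, path: str | Path, shape: tuple[int, int, int] = (64, 52, 52)) -> Path:
        """Write the rasterized solid mask as a legacy-ASCII VTK grid."""
        from .vtk_io import write_structured_points

        mask = self.solid_mask(shape)
        spacing = tuple(e / n for e, n in zip(self.domain_extent, shape))
        return write_structured_points(
            Path(path), spacing, scalars={"solid": mask.astype(float)}
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "domain_extent_m": list(self.domain_extent),
            "porosity": self.porosity,
            "mean_pore_size_m": self.mean_pore_size,
            "seed": self.seed,
            "void_centers_m": self.void_centers.tolist(),
            "void_radii_m": self.void_radii.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass(frozen=True)
class TipArray:
    """A rectangular n_x x n_y array of vertical cylindrical nanotips.

    Tips stand on the base plane z = 0, have diameter ``tip_diameter`` and
    height ``tip_length`` (metres); ``gap`` is the surface-to-surface spacing
    between neighbouring tips.  ``incident_flow_angle`` (degrees, measured
    from the base plane in the x-z plane) records how the main flow impacts
    the array.
    """

    n_x: int
    n_y: int
    tip_diameter: float
    tip_length: float
    gap: float
    incident_flow_angle: float = 45.0

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("tip counts must be >= 1")
        for name in ("tip_diameter", "tip_length", "gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (tips must not overlap)")
        if not 0 < self.incident_flow_angle <= 90:
            raise ValueError("incident_flow_angle must lie in (0, 90] degrees")

    @property
    def n_tips(self) -> int:
        return self.n_x * self.n_y

    @property
    def pitch(self) -> float:
        """Centre-to-centre tip spacing."""
        return self.tip_diameter + self.gap

    @property
    def footprint(self) -> tuple[float, float]:
        """Extent of the array (outer tip surfaces) in x and y."""
        return (
            (self.n_x - 1) * self.pitch + self.tip_diameter,
            (self.n_y - 1) * self.pitch + self.tip_diameter,
        )

    def tip_centers(self, margin: float = 0.0) -> np.ndarray:
        """(n_tips, 2) x-y centres, first tip surface at ``margin`` from origin."""
        x0 = margin + self.tip_diameter / 2.0
        xs = x0 + self.pitch * np.arange(self.n_x)
        ys = x0 + self.pitch * np.arange(self.n_y)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def generate_foam(
    mean_pore: float,
    domain: tuple[float, float, float],
    porosity: float,
    seed: int,
    raster_shape: tuple[int, int, int] = (64, 52, 52),
    pore_sd_fraction: float = 0.1,
) -> FoamGeometry:
    """Carve spherical voids from a solid slab until the porosity target is met.

    Void diameters are drawn from N(mean_pore, ``pore_sd_fraction`` *
    mean_pore) truncated positive, centres uniformly in the domain; spheres
    are added until the raster-measured void fraction reaches ``porosity``.
    The realized solid fraction therefore lands within one sphere's marginal
    coverage (a few per cent relative) of ``1 - porosity``.
    """
    domain = tuple(float(e) for e in domain)
    if any(e <= 0 for e in domain):
        raise ValueError(f"degenerate domain extent {domain}: all extents must be > 0")
    if not 0 < porosity <= 1:
        raise ValueError("porosity must lie in (0, 1]")
    if porosity == 1.0:
        return FoamGeometry(
            domain_extent=domain,
            void_centers=np.empty((0, 3)),
            void_radii=np.empty(0),
            porosity=1.0,
            mean_pore_size=mean_pore,
            seed=seed,
        )
    if not 0 < mean_pore < min(domain):
        raise ValueError("mean_pore must be positive and smaller than the domain")

    rng = np.random.default_rng(seed)
    nx, ny, nz = raster_shape
    xs = (np.arange(nx) + 0.5) * domain[0] / nx
    ys = (np.arange(ny) + 0.5) * domain[1] / ny
    zs = (np.arange(nz) + 0.5) * domain[2] / nz
    covered = np.zeros(raster_shape, dtype=bool)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    n_cells = covered.size
    max_spheres = max(100, int(20 * np.prod(domain) / (math.pi / 6 * mean_pore**3)))
    solid_band = 0.04 * (1.0 - porosity)  # keep the solid fraction within 5%

    def coverage(c, r):
        ix = np.flatnonzero(np.abs(xs - c[0]) <= r)
        iy = np.flatnonzero(np.abs(ys - c[1]) <= r)
        iz = np.flatnonzero(np.abs(zs - c[2]) <= r)
        if not (len(ix) and len(iy) and len(iz)):
            return None
        dx2 = (xs[ix] - c[0])[:, None, None] ** 2
        dy2 = (ys[iy] - c[1])[None, :, None] ** 2
        dz2 = (zs[iz] - c[2])[None, None, :] ** 2
        return np.ix_(ix, iy, iz), dx2 + dy2 + dz2 <= r * r

    while covered.sum() / n_cells < porosity:
        if len(radii) >= max_spheres:
            raise RuntimeError(
                f"porosity target {porosity} not reached after {max_spheres} voids"
            )
        c = rng.uniform([0.0, 0.0, 0.0], domain)
        r = 0.0
        while r <= 0.25 * mean_pore:  # reject non-physical tiny/negative draws
            r = 0.5 * rng.normal(mean_pore, pore_sd_fraction * mean_pore)
        # shrink a final sphere that would overshoot the porosity band
        while True:
            cov = coverage(c, r)
            gain = (cov[1] & ~covered[cov[0]]).sum() / n_cells if cov else 0.0
            new_porosity = covered.sum() / n_cells + gain
            if new_porosity <= porosity + solid_band or r <= 0.3 * mean_pore:
                break
            r *= 0.7
        if cov:
            covered[cov[0]] |= cov[1]
        centers.append(c)
        radii.append(r)
    radii_arr = np.asarray(radii)
    return FoamGeometry(
        domain_extent=domain,
        void_centers=np.asarray(centers),
        void_radii=radii_arr,
        porosity=float(covered.sum() / n_cells),
        mean_pore_size=float(2.0 * radii_arr.mean()),
        seed=seed,
    )


def generate_tip_array(
    n_x: int = 5,
    n_y: int = 5,
    diameter: float = 200e-9,
    length: float = 5e-6,
    gap: float = 1e-6,
    angle: float = 45.0,
) -> TipArray:
    """A nanotip array; defaults reproduce the 5 x 5, d = 200 nm, L = 5 um,
    1-um-gap array impacted at 45 degrees."""
    return TipArray(
        n_x=n_x,
        n_y=n_y,
        tip_diameter=diameter,
        tip_length=length,
        gap=gap,
        incident_flow_angle=angle,
    )


def generate_force_curve(
    model: IndentationModel,
    modulus: float,
    max_indentation: float,
    puncture_depth: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 512,
    drop_fraction: float = 0.3,
) -> ForceCurve:
    """Forward-model AFM approach curve with optional puncture drop and noise.

    The force is evaluated on an even indentation grid [0, max_indentation];
    beyond ``puncture_depth`` (if given) a constant drop of ``drop_fraction``
    of the breakthrough force is subtracted, mimicking the tip breaking
    through the envelope.  Gaussian noise of SD ``noise_sd`` (newtons) is
    then added.
    """
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    if max_indentation <= 0:
        raise ValueError("max_indentation must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if puncture_depth is not None and not 0 < puncture_depth < max_indentation:
        raise ValueError("puncture_depth must lie in (0, max_indentation)")
    delta = np.linspace(0.0, max_indentation, n_samples)
    force = np.asarray(indentation_force(model, modulus, delta), dtype=float)
    if puncture_depth is not None:
        drop = drop_fraction * float(indentation_force(model, modulus, puncture_depth))
        force = np.where(delta > puncture_depth, force - drop, force)
    if noise_sd > 0:
        force = force + np.random.default_rng(seed).normal(0.0, noise_sd, force.shape)
    return ForceCurve(displacement=delta, force=force, branch="approach")


def generate_plate_counts(
    true_conc: float,
    dilutions: list[int] | tuple[int, ...],
    plated_volume: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> PlateCountSet:
    """Poisson colony counts: each plate ~ Poisson(true_conc * volume / dilution).

    ``true_conc`` in CFU/mL, ``plated_volume`` in mL.
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for d in dilutions:
        if d < 1:
            raise ValueError("dilution factors must be >= 1")
        mean = true_conc * plated_volume / d
        rows.append(tuple(int(c) for c in rng.poisson(mean, n_replicates)))
    return PlateCountSet(
        dilution_factors=tuple(int(d) for d in dilutions),
        colonies=tuple(rows),
        plated_volume=plated_volume,
    )


def save_force_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write a force curve as a 2-column CSV (displacement_m, force_n)."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {"displacement_m": curve.displacement, "force_n": curve.force}
    ).to_csv(path, index=False)
    return path


def save_plate_counts(counts: PlateCountSet, path: str | Path) -> Path:
    """Write plate counts as CSV rows of (dilution, colonies) per replicate."""
    import pandas as pd

    path = Path(path)
    rows = [
        {"dilution": d, "colonies": c}
        for d, reps in zip(counts.dilution_factors, counts.colonies)
        for c in reps
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
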