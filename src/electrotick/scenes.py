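"""Boundary-value descriptions of the electrostatic scenes.

A :class:`FieldScene` bundles a rectangular domain, a list of conductors
(shape + fixed potential) and a list of dielectric bodies (shape + material
constants).  Conductor surfaces are treated as pure Dirichlet boundaries:
the host surface, electrode, plate, soil and vegetation are all equipotential,
so the air-gap problem reduces to Laplace's equation between them and the
interior material constants of the dielectrics never enter the solve — they
are carried as metadata only.

Exterior boundary conditions are fixed by convention: the bottom face of the
domain is electrical ground (0 V), all other faces are zero-normal-flux, and
axisymmetric scenes use the symmetry condition at r = 0.

Three builders cover the quantitative scenes: the laboratory rig (grounded
plate and a charged sphere above it), the magnified host-vegetation scene
(grounded soil and grass blade facing a charged ellipsoid), and an ideal
parallel-plate capacitor used as an analytic validation fixture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .shapes import (
    Box,
    Cylinder,
    Ellipsoid,
    InvalidGeometryError,
    Shape,
    Sphere,
    shape_from_dict,
    shapes_intersect,
)

AXISYMMETRIC = "axisymmetric"
CARTESIAN3D = "cartesian3d"

#: Radius of a disc with the same area as the rig's 200 mm x 130 mm plate.
RIG_PLATE_RADIUS = math.sqrt(0.200 * 0.130 / math.pi)
RIG_PLATE_THICKNESS = 0.001
RIG_DOMAIN_SIZE = 0.3
HOST_SURFACE_VOLTAGE = 750.0


@dataclass(frozen=True)
class Conductor:
    shape: Shape
    potential: float
    name: str = ""


@dataclass(frozen=True)
class Dielectric:
    shape: Shape
    eps_r: float
    sigma: float
    name: str = ""


@dataclass
class FieldScene:
    """Domain box, conductors and dielectrics for one electrostatic problem.

    ``domain_lo``/``domain_hi`` are the corners of the domain in metres; for
    axisymmetric scenes x is the radial coordinate (domain_lo[0] == 0) and the
    y extent is ignored.  ``min_gap`` records the smallest conductor-conductor
    air gap so the solver can warn about under-resolved grids.
    """

    domain_lo: Tuple[float, float, float]
    domain_hi: Tuple[float, float, float]
    conductors: List[Conductor]
    dielectrics: List[Dielectric] = field(default_factory=list)
    symmetry: str = CARTESIAN3D
    grounded_bottom: bool = True
    min_gap: Optional[float] = None
    name: str = ""

    def __post_init__(self):
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        lo = np.asarray(self.domain_lo, float)
        hi = np.asarray(self.domain_hi, float)
        if self.symmetry not in (AXISYMMETRIC, CARTESIAN3D):
            raise InvalidGeometryError(f"unknown symmetry {self.symmetry!r}")
        if np.any(hi[[0, 2]] <= lo[[0, 2]]) or (
            self.symmetry == CARTESIAN3D and hi[1] <= lo[1]
        ):
            raise InvalidGeometryError("domain box has non-positive extent")
        if self.symmetry == AXISYMMETRIC and lo[0] != 0.0:
            raise InvalidGeometryError("axisymmetric domain must start at r = 0")
        tol = 1e-12
        for c in self.conductors:
            slo, shi = c.shape.bounds()
            if self.symmetry == AXISYMMETRIC:
                inside = (
                    shi[0] <= hi[0] + tol
                    and slo[2] >= lo[2] - tol
                    and shi[2] <= hi[2] + tol
                )
            else:
                inside = bool(np.all(slo >= lo - tol) and np.all(shi <= hi + tol))
            if not inside:
                raise InvalidGeometryError(
                    f"conductor {c.name or c.shape.kind} lies outside the domain box"
                )
        for a_i in range(len(self.conductors)):
            for b_i in range(a_i + 1, len(self.conductors)):
                a, b = self.conductors[a_i], self.conductors[b_i]
                if a.potential != b.potential and shapes_intersect(a.shape, b.shape):
                    raise InvalidGeometryError(
                        f"conductors {a.name!r} and {b.name!r} at different "
                        "potentials intersect"
                    )
        has_ground = self.grounded_bottom or any(
            c.potential == 0.0 for c in self.conductors
        )
        if not has_ground:
            raise InvalidGeometryError("scene has no 0 V ground reference")

    @property
    def potentials(self) -> np.ndarray:
        p = [c.potential for c in self.conductors]
        if self.grounded_bottom:
            p.append(0.0)
        return np.asarray(p, float)

    def scaled(self, factor: float) -> "FieldScene":
        """Same geometry with all conductor potentials multiplied by ``factor``."""
        return FieldScene(
            domain_lo=self.domain_lo,
            domain_hi=self.domain_hi,
            conductors=[
                Conductor(c.shape, c.potential * factor, c.name)
                for c in self.conductors
            ],
            dielectrics=list(self.dielectrics),
            symmetry=self.symmetry,
            grounded_bottom=self.grounded_bottom,
            min_gap=self.min_gap,
            name=self.name,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "symmetry": self.symmetry,
            "domain_lo": list(self.domain_lo),
            "domain_hi": list(self.domain_hi),
            "grounded_bottom": self.grounded_bottom,
            "min_gap": self.min_gap,
            "conductors": [
                {"name": c.name, "potential": c.potential, "shape": c.shape.to_dict()}
                for c in self.conductors
            ],
            "dielectrics": [
                {
                    "name": d.name,
                    "eps_r": d.eps_r,
                    "sigma": d.sigma,
                    "shape": d.shape.to_dict(),
                }
                for d in self.dielectrics
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldScene":
        return cls(
            domain_lo=tuple(d["domain_lo"]),
            domain_hi=tuple(d["domain_hi"]),
            conductors=[
                Conductor(shape_from_dict(c["shape"]), float(c["potential"]), c.get("name", ""))
                for c in d["conductors"]
            ],
            dielectrics=[
                Dielectric(
                    shape_from_dict(x["shape"]),
                    float(x["eps_r"]),
                    float(x["sigma"]),
                    x.get("name", ""),
                )
                for x in d.get("dielectrics", [])
            ],
            symmetry=d.get("symmetry", CARTESIAN3D),
            grounded_bottom=bool(d.get("grounded_bottom", True)),
            min_gap=d.get("min_gap"),
            name=d.get("name", ""),
        )

    def save(self, path: str) -> None:
        text = (
            json.dumps(self.to_dict(), indent=2)
            if str(path).endswith(".json")
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str) -> "FieldScene":
        with open(path) as fh:
            text = fh.read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------

def build_rig_scene(
    gap: float,
    voltage: float,
    sphere_diameter: float = 0.015,
    plate_radius: float = RIG_PLATE_RADIUS,
    include_rod: bool = False,
) -> FieldScene:
    """Axisymmetric model of the laboratory rig.

    A grounded aluminium plate (equal-area disc of the rectangular plate,
    1 mm thick, top surface at z = 0) sits on the grounded bottom face of a
    0.3 m domain.  The spherical electrode hangs on the axis with its lowest
    point ``gap`` metres above the plate top.  The wooden support rod behind
    the electrode is a dielectric and, under the pure-Dirichlet treatment,
    does not influence the solution; it is carried as metadata when
    ``include_rod`` is set.

    Heights elsewhere in the package ("0.5 mm above the plate") are measured
    from the plate top, i.e. ``z = RIG_PLATE_THICKNESS + height``.
    """
    if gap <= 0:
        raise InvalidGeometryError(f"gap must be positive, got {gap}")
    if sphere_diameter <= 0:
        raise InvalidGeometryError("sphere_diameter must be positive")
    if plate_radius <= 0:
        raise InvalidGeometryError("plate_radius must be positive")
    r_sphere = sphere_diameter / 2
    plate_top = RIG_PLATE_THICKNESS
    sphere_center_z = plate_top + gap + r_sphere
    conductors = [
        Conductor(
            Cylinder(center=(0.0, 0.0, plate_top / 2), radius=plate_radius,
                     height=RIG_PLATE_THICKNESS),
            0.0,
            "plate",
        ),
        Conductor(
            Sphere(center=(0.0, 0.0, sphere_center_z), radius=r_sphere),
            voltage,
            "electrode",
        ),
    ]
    dielectrics = []
    if include_rod:
        # 1 cm diameter, 15 cm long wooden rod overlapping the sphere by 1.5 mm.
        rod_bottom = sphere_center_z + r_sphere - 0.0015
        dielectrics.append(
            Dielectric(
                Cylinder(center=(0.0, 0.0, rod_bottom + 0.075), radius=0.005,
                         height=0.15),
                eps_r=3.0,
                sigma=1e-10,
                name="wooden rod",
            )
        )
    return FieldScene(
        domain_lo=(0.0, 0.0, 0.0),
        domain_hi=(RIG_DOMAIN_SIZE / 2, 0.0, RIG_DOMAIN_SIZE),
        conductors=conductors,
        dielectrics=dielectrics,
        symmetry=AXISYMMETRIC,
        min_gap=gap,
        name=f"rig gap={gap * 1e3:g}mm V={voltage:g}",
    )


def rig_probe_point(height_above_plate: float) -> Tuple[float, float]:
    """On-axis probe position (r, z) a given height above the plate top."""
    return (0.0, RIG_PLATE_THICKNESS + height_above_plate)


def build_single_blade_scene(
    gap: float = 0.0025,
    voltage: float = HOST_SURFACE_VOLTAGE,
    blade_height: float = 0.30,
    blade_cross_section: Tuple[float, float] = (0.001, 0.005),
    ellipsoid_semiaxes: Tuple[float, float, float] = (0.4, 0.4, 0.2),
) -> FieldScene:
    """Magnified host-vegetation scene: one grounded grass blade and a host.

    A 1 m domain holds a grounded soil slab (1 x 1 x 0.1 m), a vertical
    grounded blade (ribbon of the given cross-section) rooted in the soil,
    and a charged ellipsoid representing the host whose nearest surface point
    lies ``gap`` metres from the blade's upper tip along x.  The blade stands
    at x = -0.4 m so the host ellipsoid fits inside the cube.
    """
    if gap <= 0:
        raise InvalidGeometryError("gap must be positive")
    t, w = blade_cross_section
    soil_top = 0.1
    tip_z = soil_top + blade_height
    if tip_z >= 1.0:
        raise InvalidGeometryError("blade height exceeds the domain")
    blade_x = -0.4
    a, b, c = ellipsoid_semiaxes
    ell_center = (blade_x + t / 2 + gap + a, 0.0, tip_z)
    conductors = [
        Conductor(Box(center=(0.0, 0.0, soil_top / 2), size=(1.0, 1.0, soil_top)),
                  0.0, "soil"),
        Conductor(
            Box(center=(blade_x, 0.0, soil_top + blade_height / 2),
                size=(t, w, blade_height)),
            0.0,
            "blade",
        ),
        Conductor(Ellipsoid(center=ell_center, semiaxes=(a, b, c)), voltage, "host"),
    ]
    return FieldScene(
        domain_lo=(-0.5, -0.5, 0.0),
        domain_hi=(0.5, 0.5, 1.0),
        conductors=conductors,
        symmetry=CARTESIAN3D,
        min_gap=gap,
        name=f"single-blade gap={gap * 1e3:g}mm V={voltage:g}",
    )


def blade_probe_point(scene: FieldScene, distance_from_blade: float) -> Tuple[float, float, float]:
    """Probe on the blade-tip/host line, ``distance_from_blade`` from the blade face."""
    blade = next(c for c in scene.conductors if c.name == "blade")
    _, hi = blade.shape.bounds()
    return (hi[0] + distance_from_blade, 0.0, hi[2])


def build_parallel_plate_scene(gap: float, voltage: float, radius: float = 0.05) -> FieldScene:
    """Ideal parallel-plate capacitor (analytic fixture, |E| = V/gap).

    Two full-radius discs bound the air region 0 <= z <= gap; the side wall is
    zero-flux, consistent with the uniform vertical field, so the discrete
    solution is exact.  Plate thickness is gap/10; grids whose spacing divides
    gap/10 place nodes exactly on both plate faces.
    """
    if gap <= 0:
        raise InvalidGeometryError("gap must be positive")
    t = gap / 10
    return FieldScene(
        domain_lo=(0.0, 0.0, -t),
        domain_hi=(radius, 0.0, gap + t),
        conductors=[
            Conductor(Cylinder(center=(0.0, 0.0, -t / 2), radius=radius, height=t),
                      0.0, "bottom plate"),
            Conductor(Cylinder(center=(0.0, 0.0, gap + t / 2), radius=radius, height=t),
                      voltage, "top plate"),
        ],
        symmetry=AXISYMMETRIC,
        grounded_bottom=False,
        min_gap=gap,
        name=f"parallel-plate gap={gap * 1e3:g}mm V={voltage:g}",
    )
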