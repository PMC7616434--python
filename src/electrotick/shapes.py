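"""Geometric primitives used to describe conductors and dielectrics.

All lengths are SI metres.  Shapes are axis-aligned and immutable; each one
knows how to test point membership (vectorised, boundary-inclusive) and to
report an axis-aligned bounding box.  Axisymmetric scenes evaluate the same
shapes at y = 0, with x playing the role of the radial coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Tuple

import numpy as np

Vec3 = Tuple[float, float, float]

#: geometric tolerance (metres) for boundary-inclusive membership tests;
#: sub-nanometre, so physically negligible, but it keeps grid nodes that
#: coincide with a conductor face (up to float rounding) inside the conductor
GEOM_EPS = 1e-9


class InvalidGeometryError(ValueError):
    """A shape or scene violates a geometric precondition."""


def _check_positive(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v) or v <= 0:
            raise InvalidGeometryError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class Shape:
    """Base class; subclasses define ``contains`` and ``bounds``."""

    center: Vec3

    @property
    def kind(self) -> str:
        return type(self).__name__.lower()

    def contains(self, x, y, z) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d


@dataclass(frozen=True)
class Sphere(Shape):
    radius: float

    def __post_init__(self):
        _check_positive("Sphere.radius", self.radius)

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= (
            self.radius + GEOM_EPS
        ) ** 2

    def bounds(self):
        c = np.asarray(self.center, float)
        r = self.radius
        return c - r, c + r


@dataclass(frozen=True)
class Ellipsoid(Shape):
    semiaxes: Vec3

    def __post_init__(self):
        _check_positive("Ellipsoid.semiaxes", *self.semiaxes)

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        a, b, c = self.semiaxes
        a, b, c = a + GEOM_EPS, b + GEOM_EPS, c + GEOM_EPS
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0

    def bounds(self):
        c = np.asarray(self.center, float)
        s = np.asarray(self.semiaxes, float)
        return c - s, c + s


@dataclass(frozen=True)
class Box(Shape):
    """Axis-aligned cuboid; also serialises the slab and ribbon kinds."""

    size: Vec3

    def __post_init__(self):
        _check_positive("Box.size", *self.size)

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        sx, sy, sz = (s / 2 + GEOM_EPS for s in self.size)
        return (
            (np.abs(x - cx) <= sx) & (np.abs(y - cy) <= sy) & (np.abs(z - cz) <= sz)
        )

    def bounds(self):
        c = np.asarray(self.center, float)
        h = np.asarray(self.size, float) / 2
        return c - h, c + h


@dataclass(frozen=True)
class Cylinder(Shape):
    """Right circular cylinder with axis parallel to z; covers the disc kind."""

    radius: float
    height: float

    def __post_init__(self):
        _check_positive("Cylinder.radius", self.radius)
        _check_positive("Cylinder.height", self.height)

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return ((x - cx) ** 2 + (y - cy) ** 2 <= (self.radius + GEOM_EPS) ** 2) & (
            np.abs(z - cz) <= self.height / 2 + GEOM_EPS
        )

    def bounds(self):
        cx, cy, cz = self.center
        r, h = self.radius, self.height / 2
        return (
            np.array([cx - r, cy - r, cz - h]),
            np.array([cx + r, cy + r, cz + h]),
        )


_KIND_ALIASES = {
    "sphere": Sphere,
    "ellipsoid": Ellipsoid,
    "box": Box,
    "slab": Box,
    "ribbon": Box,
    "cylinder": Cylinder,
    "disc": Cylinder,
}


def shape_from_dict(d: dict) -> Shape:
    d = dict(d)
    kind = d.pop("kind")
    try:
        cls = _KIND_ALIASES[kind]
    except KeyError:
        raise InvalidGeometryError(f"unknown shape kind {kind!r}") from None
    kwargs = {
        k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()
    }
    return cls(**kwargs)


def shapes_intersect(a: Shape, b: Shape, n_samples: int = 4096) -> bool:
    """Approximate intersection test: bounding-box overlap refined by sampling.

    Deterministic (fixed sampling sequence).  Used to enforce the invariant
    that conductors at different potentials never touch.
    """
    lo_a, hi_a = a.bounds()
    lo_b, hi_b = b.bounds()
    lo = np.maximum(lo_a, lo_b)
    hi = np.minimum(hi_a, hi_b)
    if np.any(lo > hi):
        return False
    rng = np.random.default_rng(0)
    span = np.where(hi > lo, hi - lo, 0.0)
    pts = lo + rng.random((n_samples, 3)) * span
    inside = a.contains(pts[:, 0], pts[:, 1], pts[:, 2]) & b.contains(
        pts[:, 0], pts[:, 1], pts[:, 2]
    )
    return bool(np.any(inside))
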