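"""Physics of electrostatic tick lift.

A questing tick is lifted off a grounded surface when the electric force on
it exceeds gravity.  Because the electric force is proportional to the local
field, the voltage required to lift a tick across a gap d grows linearly
with d, with zero intercept — by definition no voltage is needed at zero
distance.  The slope G of the forced-origin regression V = G d is the
threshold field strength for lift-off, and it extrapolates in both
directions: V(d) = G d gives the voltage needed across any gap, and
d(V) = V / G the reach of a given surface voltage.

Two candidate coupling mechanisms are modelled for the mechanism experiment:
a fixed net surface charge q (force q E, sign-sensitive) and an induced
polarization with effective polarizability alpha (force alpha/2 grad |E|^2,
sign-blind).  Equal attraction to both electrode polarities therefore
implicates the induced-polarization route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .scenes import rig_probe_point
from .solver import FieldSolution, rig_solution
from .stats import OriginFit, regression_through_origin

#: standard gravitational acceleration, m/s^2
G_ACCEL = 9.81
#: typical mass of a nymph, kg (~0.1 mg)
NYMPH_MASS = 1e-7


@dataclass(frozen=True)
class ParticleModel:
    """Point-particle model of a tick nymph.

    mass in kg (default 0.1 mg), net charge q in coulombs, effective
    polarizability alpha in C m^2/V.  alpha has no measured value; it is
    used only for direction/sign properties of the induced-dipole force.
    """

    mass: float = NYMPH_MASS
    g: float = G_ACCEL
    q: float = 0.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.mass <= 0 or self.g <= 0:
            raise ValueError("mass and g must be positive")

    @property
    def weight(self) -> float:
        return self.mass * self.g


@dataclass
class ThresholdFit:
    """Fitted threshold law V = G d (G in V/m) with model diagnostics."""

    gradient: float
    r_squared: float
    f_stat: float
    df: Tuple[int, int]
    p_value: float
    n: int
    origin_fit: OriginFit

    @property
    def gradient_kV_per_m(self) -> float:
        return self.gradient / 1e3

    def to_dict(self) -> dict:
        d = self.origin_fit.to_dict()
        d["gradient_V_per_m"] = self.gradient
        return d


def fit_threshold_law(data: pd.DataFrame) -> ThresholdFit:
    """Fit the zero-intercept distance-voltage law to a threshold dataset.

    ``data`` uses the package CSV schema: columns ``distance_mm`` and
    ``threshold_voltage_V`` (other columns are ignored).  All voltages must
    be positive (use magnitudes for negative-polarity trials) and at least
    two distinct distances are required.
    """
    d_m = np.asarray(data["distance_mm"], float) * 1e-3
    v = np.asarray(data["threshold_voltage_V"], float)
    if np.unique(d_m).size < 2:
        raise ValueError("need at least 2 distinct distances")
    if np.any(v <= 0):
        raise ValueError("threshold voltages must be positive magnitudes")
    fit = regression_through_origin(d_m, v)
    return ThresholdFit(
        gradient=fit.slope,
        r_squared=fit.r_squared,
        f_stat=fit.f_stat,
        df=fit.df,
        p_value=fit.p_value,
        n=fit.n,
        origin_fit=fit,
    )


def predict_threshold_voltage(gradient: float, distance: float) -> float:
    """Voltage (V) needed to lift a tick across ``distance`` metres."""
    if gradient <= 0 or distance <= 0:
        raise ValueError("gradient and distance must be positive")
    return gradient * distance


def predict_attraction_range(gradient: float, surface_voltage: float) -> float:
    """Largest gap (m) a surface at ``surface_voltage`` can lift a tick across."""
    if gradient <= 0:
        raise ValueError("gradient must be positive")
    return surface_voltage / gradient


def average_threshold_field(
    distances: Sequence[float],
    voltages: Sequence[float],
    probe_height: float = 0.0005,
    sphere_diameter: float = 0.015,
    h_fine: float = 5e-5,
) -> float:
    """Mean |E| at the tick position over per-distance rig solves.

    For each (distance, voltage) pair the rig model is solved and probed on
    the axis ``probe_height`` above the plate; the returned value is the
    mean field magnitude (V/m).  This converts the fitted voltage law into
    an average threshold field that accounts for the rig's non-uniform
    field.
    """
    distances = list(distances)
    voltages = list(voltages)
    if len(distances) != len(voltages) or not distances:
        raise ValueError("distances and voltages must be equal-length, non-empty")
    if probe_height >= min(distances):
        raise ValueError("probe height must be below the smallest gap")
    point = rig_probe_point(probe_height)
    out = []
    for d, v in zip(distances, voltages):
        if v == 0.0:
            out.append(0.0)
            continue
        sol = rig_solution(
            gap=d, voltage=v, sphere_diameter=sphere_diameter, h_fine=h_fine
        )
        out.append(sol.probe([point])[0].E_magnitude)
    return float(np.mean(out))


def lift_condition(
    E: float,
    particle: ParticleModel,
    coupling: str = "fixed_charge",
) -> Tuple[bool, float]:
    """Does the particle lift at field magnitude ``E``, and what charge would?

    Returns ``(lifts, q_eff)``: with the fixed-charge coupling the particle
    lifts iff q E >= m g; ``q_eff = m g / E`` is the minimum effective
    charge for lift at this field regardless of mechanism.
    """
    if E < 0:
        raise ValueError("field magnitude must be non-negative")
    if coupling not in ("fixed_charge", "effective_charge"):
        raise ValueError(f"unknown coupling {coupling!r}")
    if E == 0.0:
        if coupling == "effective_charge":
            raise ZeroDivisionError("effective charge undefined at E = 0")
        return False, np.inf
    q_eff = particle.weight / E
    lifts = particle.q * E >= particle.weight
    return bool(lifts), float(q_eff)


def mechanism_forces(
    solution: FieldSolution,
    particle: ParticleModel,
    position: Sequence[float],
    step: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Induced-dipole and fixed-charge forces at a point (newtons).

    The induced-dipole force is alpha/2 * grad(|E|^2), evaluated by centred
    differences of the probed field (stencil half-width ``step``, default
    two grid cells); the fixed-charge force is q E.  Under a sign flip of
    every boundary voltage the former is unchanged and the latter negated.
    """
    pos = np.asarray(position, float)
    h = step if step is not None else 2 * solution.h
    probe = solution.probe([pos])[0]
    e_vec = np.asarray(probe.E_vector)
    grad_e2 = np.zeros(len(pos))
    for axis in range(len(pos)):
        plus = pos.copy()
        minus = pos.copy()
        plus[axis] += h
        minus[axis] -= h
        if len(pos) == 2 and axis == 0 and minus[0] < 0:
            minus[0] = -minus[0]  # axisymmetric mirror: |E| is even in r
        res = solution.probe([plus, minus])
        grad_e2[axis] = (res[0].E_magnitude**2 - res[1].E_magnitude**2) / (2 * h)
    induced = 0.5 * particle.alpha * grad_e2
    fixed = particle.q * e_vec
    return induced, fixed
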