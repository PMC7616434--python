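"""Seed-reproducible synthetic data with the structure of each experiment.

Three generators emulate the study designs so every downstream analysis is
testable without the deposited raw data:

* a staircase threshold experiment — per tick, a true threshold voltage
  V* = E* d L is drawn (L a unit-median lognormal factor with the given
  coefficient of variation) and the
  recorded value is the first protocol voltage (start + k step) at or above
  V*, reproducing the upward quantization of the 50 V staircase;
* fixed-voltage lift trials — treatment ticks fully lift when the applied
  probe-height field (V/d times the rig geometry factor, taken from the
  solver) exceeds their drawn threshold field, partially lift when it falls
  within a band just below threshold, and control ticks only ever show a
  small spontaneous-movement rate of partial lifts;
* polarity groups — two groups drawn from the same |threshold| distribution
  (the induced-polarization null), so a rank test between them should reject
  only at the nominal rate.

The between-tick threshold spread is a modelling stand-in: the study reports
no distributional information, so a lognormal with CV 0.15 (positive, and
visually consistent with the published scatter) is used and exposed as a
parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .scenes import rig_probe_point
from .stats import ContingencyTable

#: experimental design of the staircase threshold experiment
STAIRCASE_DISTANCES_MM = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
TICKS_PER_DISTANCE = 12

OUTCOME_LABELS = ("fully_lifted", "partially_lifted", "not_lifted")
GROUP_LABELS = ("treatment", "control")


class ProtocolWarning(UserWarning):
    """The staircase protocol cannot resolve the population thresholds."""


@dataclass(frozen=True)
class StaircaseProtocol:
    """Voltage staircase: start at ``start`` V, increase by ``step`` V until
    lift-off; ``dwell_s`` (connection time per level) is metadata."""

    start: float = 50.0
    step: float = 50.0
    dwell_s: float = 20.0
    polarity: str = "+"

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("staircase step must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")

    def quantize(self, v_true: np.ndarray) -> np.ndarray:
        """First staircase voltage at or above each true threshold."""
        k = np.ceil((np.asarray(v_true, float) - self.start) / self.step)
        return self.start + np.maximum(k, 0.0) * self.step


@dataclass(frozen=True)
class TickPopulationModel:
    """Generative model of between-tick threshold variability.

    ``threshold_field`` E* (V/m) is the population-median threshold field;
    individual thresholds are E* times a unit-median lognormal factor with
    coefficient of variation ``cv`` (the multiplicative noise is symmetric
    in the log domain, so recorded staircase voltages are biased upward only
    by the quantization).  ``partial_band`` is the fraction just
    below threshold in which a tick is visibly pulled but not lifted.
    Humidity covariates are Gaussian (percent RH).
    """

    threshold_field: float = 258e3
    cv: float = 0.15
    partial_band: float = 0.0866
    humidity_mean: float = 60.0
    humidity_sd: float = 3.0

    def __post_init__(self):
        if self.threshold_field <= 0:
            raise ValueError("threshold_field must be positive")
        if self.cv < 0 or not 0 <= self.partial_band < 1:
            raise ValueError("cv >= 0 and 0 <= partial_band < 1 required")

    def _sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))

    def draw_factors(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Unit-median multiplicative threshold factors."""
        if self.cv == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, self._sigma(), size=n))

    def factor_quantile(self, p: float) -> float:
        if self.cv == 0:
            return 1.0
        return float(np.exp(self._sigma() * sps.norm.ppf(p)))


def calibrated_lift_population(
    applied_field: float,
    p_full: float = 0.75,
    p_partial: float = 0.15,
    cv: float = 0.15,
    **kwargs,
) -> TickPopulationModel:
    """Population whose lift-trial outcome rates hit the given targets.

    Solves the lognormal quantile equations so that, at ``applied_field``,
    the expected fully-lifted and partially-lifted fractions equal
    ``p_full`` and ``p_partial``.  Used to emulate the fixed-voltage
    experiment, whose live ticks lifted at lower fields than the dead-tick
    staircase average.
    """
    if not 0 < p_full < 1 or not 0 <= p_partial < 1 - p_full:
        raise ValueError("need 0 < p_full < 1 and 0 <= p_partial < 1 - p_full")
    base = TickPopulationModel(cv=cv, **kwargs)
    q_full = base.factor_quantile(p_full)
    e_star = applied_field / q_full
    if p_partial > 0:
        q_both = base.factor_quantile(p_full + p_partial)
        band = 1.0 - q_full / q_both
    else:
        band = 0.0
    return replace(base, threshold_field=e_star, partial_band=band)


@lru_cache(maxsize=32)
def rig_geometry_factor(
    gap: float,
    probe_height: float = 0.0005,
    sphere_diameter: float = 0.015,
    h_fine: float = 5e-5,
) -> float:
    """Probe-height field divided by the nominal V/gap, from the rig solver.

    The rig's field at the tick position is slightly below the parallel-plate
    value V/gap because the electrode is a sphere; this factor (~0.88 at a
    3 mm gap) is computed from the solver rather than hard-coded.
    """
    from .solver import rig_solution  # deferred: heavy import chain

    sol = rig_solution(gap=gap, voltage=750.0, sphere_diameter=sphere_diameter,
                       h_fine=h_fine)
    e = sol.probe([rig_probe_point(probe_height)])[0].E_magnitude
    return float(e / (750.0 / gap))


def _humidity(pop: TickPopulationModel, n: int, rng) -> np.ndarray:
    return np.clip(rng.normal(pop.humidity_mean, pop.humidity_sd, size=n), 0, 100)


def simulate_staircase_experiment(
    pop: TickPopulationModel,
    protocol: StaircaseProtocol = StaircaseProtocol(),
    distances: Sequence[float] = tuple(d * 1e-3 for d in STAIRCASE_DISTANCES_MM),
    n_per_distance: int = TICKS_PER_DISTANCE,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the distance-voltage staircase experiment.

    Distances in metres.  Returns the threshold-dataset schema (tick_id,
    distance_mm, threshold_voltage_V, polarity, humidity_pct); recorded
    voltages are magnitudes and always lie on the staircase.
    """
    if n_per_distance < 1:
        raise ValueError("n_per_distance must be at least 1")
    if not distances:
        raise ValueError("need at least one distance")
    rng = np.random.default_rng(seed)
    if protocol.start > pop.threshold_field * min(distances):
        warnings.warn(
            "staircase start voltage exceeds the typical population threshold "
            "at the smallest distance; thresholds will pile up at the start",
            ProtocolWarning,
            stacklevel=2,
        )
    rows = []
    tick = 0
    for d in distances:
        factors = pop.draw_factors(n_per_distance, rng)
        v_true = pop.threshold_field * d * factors
        v_rec = protocol.quantize(v_true)
        hum = _humidity(pop, n_per_distance, rng)
        for j in range(n_per_distance):
            rows.append(
                (f"t{tick:04d}", d * 1e3, v_rec[j], protocol.polarity, hum[j])
            )
            tick += 1
    return pd.DataFrame(
        rows,
        columns=["tick_id", "distance_mm", "threshold_voltage_V", "polarity",
                 "humidity_pct"],
    )


def simulate_lift_trials(
    pop: TickPopulationModel,
    applied_voltage: float = 750.0,
    gap: float = 0.003,
    n_treatment: int = 20,
    n_control: int = 20,
    seed: int = 0,
    spontaneous_rate: float = 0.05,
    geometry_factor: Optional[float] = None,
) -> ContingencyTable:
    """Simulate the fixed-voltage treatment/control lift experiment.

    Treatment ticks experience the probe-height field (applied voltage over
    gap, scaled by the rig geometry factor); each fully lifts if that field
    reaches its drawn threshold, partially lifts if the field lands within
    ``pop.partial_band`` below threshold.  Control ticks see no field and
    partially lift only at the spontaneous-movement rate.  Pass
    ``geometry_factor`` to skip the field solve (e.g. in tight loops).
    """
    if n_treatment < 0 or n_control < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    if applied_voltage == 0.0:
        applied_field = 0.0
    else:
        gf = geometry_factor if geometry_factor is not None else rig_geometry_factor(gap)
        applied_field = abs(applied_voltage) / gap * gf
    thresholds = pop.threshold_field * pop.draw_factors(n_treatment, rng)
    full = applied_field >= thresholds
    partial = ~full & (applied_field >= (1 - pop.partial_band) * thresholds)
    spont_t = rng.random(n_treatment) < spontaneous_rate
    partial |= ~full & spont_t
    counts_t = [int(full.sum()), int(partial.sum()),
                int(n_treatment - full.sum() - partial.sum())]
    spont_c = rng.random(n_control) < spontaneous_rate
    counts_c = [0, int(spont_c.sum()), int(n_control - spont_c.sum())]
    return ContingencyTable(
        np.array([counts_t, counts_c]), GROUP_LABELS, OUTCOME_LABELS
    )


def simulate_polarity_groups(
    pop: TickPopulationModel,
    protocol: StaircaseProtocol = StaircaseProtocol(),
    gap: float = 0.0025,
    n_per_group: int = 12,
    seed: int = 0,
    negative_scale: float = 1.0,
    humidity_by_group: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate the positive/negative polarity threshold comparison.

    Both groups draw |threshold| voltages from the same distribution (the
    induced-polarization null).  ``negative_scale`` multiplies the negative
    group's thresholds to emulate a fixed-charge alternative (e.g. 2.0).
    ``humidity_by_group`` optionally maps polarity to (mean, sd) to emulate
    the humidity-confound conditions.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    rng = np.random.default_rng(seed)
    frames = []
    for sign, scale in (("+", 1.0), ("-", negative_scale)):
        factors = pop.draw_factors(n_per_group, rng)
        v_true = pop.threshold_field * gap * factors * scale
        v_rec = protocol.quantize(v_true)
        if humidity_by_group and sign in humidity_by_group:
            mean, sd = humidity_by_group[sign]
            hum = np.clip(rng.normal(mean, sd, n_per_group), 0, 100)
        else:
            hum = _humidity(pop, n_per_group, rng)
        frames.append(pd.DataFrame({
            "tick_id": [f"{sign}{i:03d}" for i in range(n_per_group)],
            "distance_mm": gap * 1e3,
            "threshold_voltage_V": v_rec,
            "polarity": sign,
            "humidity_pct": hum,
        }))
    return pd.concat(frames, ignore_index=True)
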