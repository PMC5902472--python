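"""Colony spread rates, nutrient diffusivities and the relative spread Δ.

The relative spread Δ = Δ_m / Δ_n compares the average rate of change of the
colony area Δ_m (which has the units of a diffusivity) with the nutrient
diffusivity Δ_n.  Δ of order one or larger means cells spread at least as fast
as the nutrient, so local nutrient depletion can shape the colony
(diffusion-limited growth is possible); Δ ≪ 1 means nutrient gradients
equilibrate long before the colony edge moves and DLG cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: diffusivity of glucose in water, mm^2/min
GLUCOSE_D0_MM2_MIN = 4.03e-2

#: conversion factors to m^2/s for supported area-rate units
_TO_M2_S = {
    "m2/s": 1.0,
    "mm2/min": 1e-6 / 60.0,
    "mm2/s": 1e-6,
    "m2/min": 1.0 / 60.0,
}


def _to_m2_s(value: float, units: str) -> float:
    try:
        return value * _TO_M2_S[units]
    except KeyError:
        raise ValueError(
            f"unsupported units {units!r}; expected one of {sorted(_TO_M2_S)}"
        ) from None


def convert_rate(value: float, units: str, to: str) -> float:
    """Convert an area rate / diffusivity between supported unit systems."""
    return _to_m2_s(value, units) / _TO_M2_S[to]


def agar_diffusivity(w: float, D0: float = GLUCOSE_D0_MM2_MIN) -> float:
    """Nutrient diffusivity in an agar gel with agar weight fraction ``w``.

    Applies the linear correction ``(1 - 2.3 w) * D0`` to the aqueous
    diffusivity ``D0``; ``w`` is a fraction (0.003 for 0.3% agar).  Valid for
    ``0 <= w < 1/2.3``; the diffusivity changes little over typical gels.
    """
    if not 0.0 <= w < 1.0 / 2.3:
        raise ValueError("agar fraction w must satisfy 0 <= w < 1/2.3")
    return (1.0 - 2.3 * w) * D0


@dataclass
class AreaSeries:
    """Colony area observations over time, with explicit units."""

    times: np.ndarray
    areas: np.ndarray
    time_units: str = "min"
    area_units: str = "mm2"
    #: clock time (same axis as ``times``) at which the colony had zero
    #: area; allows a rate from a single observation
    age_origin: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape or self.times.ndim != 1:
            raise ValueError("times and areas must be 1-D arrays of equal length")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")

    @property
    def rate_units(self) -> str:
        return f"{self.area_units}/{self.time_units}"


@dataclass
class SpreadRates:
    """Δ_m, Δ_n (in m^2/s) and their dimensionless ratio Δ."""

    delta_m: float
    delta_n: float
    delta: float
    units: str = "m2/s"


def delta_m(series: AreaSeries) -> float:
    """Average areal spread rate: the least-squares slope of area vs time.

    With two points this reduces to the difference quotient.  A single
    observation is accepted only with a known ``age_origin``, in which case
    the colony is assumed to have had zero area at age zero.
    """
    t, a = series.times, series.areas
    if len(t) == 1:
        if series.age_origin is None:
            raise ValueError(
                "a single observation needs an age_origin to define a rate"
            )
        if series.age_origin >= t[0]:
            raise ValueError("age_origin must precede the observation time")
        t = np.array([series.age_origin, t[0]])
        a = np.array([0.0, a[0]])
    if len(t) < 2:
        raise ValueError("need at least two observations")
    slope = np.polynomial.polynomial.polyfit(t, a, 1)[1]
    return float(slope)


def delta_ratio(
    dm: float,
    dn: float,
    dm_units: str = "m2/s",
    dn_units: str = "mm2/min",
) -> SpreadRates:
    """Dimensionless relative spread Δ = Δ_m / Δ_n after unit reconciliation."""
    dm_si = _to_m2_s(dm, dm_units)
    dn_si = _to_m2_s(dn, dn_units)
    if dm_si <= 0 or dn_si <= 0:
        raise ValueError("both rates must be positive")
    return SpreadRates(delta_m=dm_si, delta_n=dn_si, delta=dm_si / dn_si)


def lattice_nutrient_diffusivity(config) -> float:
    """Effective diffusivity of a nutrient packet, in sites^2 per time step.

    A packet makes ``s`` unit moves with probability ``p_m`` each step, so its
    mean-squared displacement per step is ``p_m * s`` and the 2-D diffusion
    coefficient is ``MSD / (4 t) = p_m * s / 4``.
    """
    return config.p_m * config.s / 4.0


def delta_from_lattice(result) -> SpreadRates:
    """Relative spread Δ of a lattice simulation.

    Δ_m is the least-squares slope of the occupied-site count against the
    time step (one site = one unit of area); Δ_n is the packet diffusivity
    ``p_m * s / 4``.  Both are in lattice units, so Δ is dimensionless.
    """
    traj = result.trajectory
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least two records")
    t = traj[:, 0].astype(float)
    nu = traj[:, 1].astype(float)
    dm = float(np.polynomial.polynomial.polyfit(t, nu, 1)[1])
    dn = lattice_nutrient_diffusivity(result.config)
    return SpreadRates(delta_m=dm, delta_n=dn, delta=dm / dn, units="sites2/step")


def mask_area(mask: np.ndarray, pixel_scale: float) -> float:
    """Colony area of a binary mask: set-pixel count times pixel area."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    return float(mask.sum()) * pixel_scale**2
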