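"""Number-concentration estimation and sampling-time planning.

The total number of particles drawn through the impactor during a
sample is Sp = t * Q * C.  Collected samples are usable for statistics
when Sp lies between a lower limit (too few particles for statistics)
and an upper limit (co-deposition); the planner inverts Sp = t Q C for
the sampling-time window at a given concentration.

Linking image statistics back to airborne concentration uses the
calibration

    t Q C = A * sum_{dp >= D50} N_dp / Ceff(dp)

where N_dp are per-size-bin particle number densities (um^-2) measured
on the grid and A is an effective-area constant (um^2 under this
density convention) determined from samples with known concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .collection_efficiency import EfficiencyCurve, evaluate_ceff
from .errors import CalibrationError

#: Loading limits on the total sampled particle number Sp, determined
#: for a PSD dominated by 100-200 nm particles.
SP_LOWER_DEFAULT = 3.9e6
SP_UPPER_DEFAULT = 6.7e7

#: Unit helper: L/min -> cm^3/s.
LPM_TO_CCS = 1000.0 / 60.0


@dataclass(frozen=True)
class SamplingPlan:
    """A planned impactor sample and its loading window."""

    flow: float  # cm^3 s^-1
    concentration: float  # cm^-3
    time: float  # s
    sp_lower: float = SP_LOWER_DEFAULT
    sp_upper: float = SP_UPPER_DEFAULT

    def __post_init__(self) -> None:
        if min(self.flow, self.concentration, self.time) < 0:
            raise ValueError("flow, concentration and time must be >= 0")
        if not self.sp_lower < self.sp_upper:
            raise ValueError("Sp lower limit must be below the upper limit")

    @property
    def total_sampled(self) -> float:
        return total_sampled(self.time, self.flow, self.concentration)

    @property
    def within_limits(self) -> bool:
        return self.sp_lower <= self.total_sampled <= self.sp_upper


@dataclass(frozen=True)
class CalibrationA:
    """Effective-area constant A of the concentration calibration.

    Units are um^2 when densities are given in um^-2 (the value is not
    dimensionless; its magnitude depends on that convention).
    """

    a: float  # um^2
    sigma_a: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("A must be positive")
        if self.sigma_a < 0:
            raise ValueError("sigma_A must be non-negative")


def total_sampled(t: float, q: float, c: float) -> float:
    """Total particles through the impactor: Sp = t * Q * C.

    ``t`` in s, ``q`` in cm^3/s, ``c`` in cm^-3.
    """
    if min(t, q, c) < 0:
        raise ValueError("t, Q and C must be non-negative")
    return t * q * c


def _efficiency_weighted_sum(densities: dict[float, float],
                             curve: EfficiencyCurve) -> float:
    """sum N_dp / Ceff(dp) over representative diameters >= fitted D50."""
    total = 0.0
    for dp, n in densities.items():
        if dp >= curve.d50 and n > 0:
            total += n / evaluate_ceff(curve, dp)
    return total


def calibrate_a(t: float, q: float, c_smps: float,
                densities: dict[float, float],
                curve: EfficiencyCurve) -> CalibrationA:
    """Calibrate A from one sample with known SMPS concentration.

    ``densities`` maps representative bin diameter (nm) to measured
    number density (um^-2); only bins at or above the fitted D50 enter
    the sum (below it the image statistics are unreliable and are never
    extrapolated).
    """
    s = _efficiency_weighted_sum(densities, curve)
    if s <= 0:
        raise CalibrationError(
            "no positive number density at or above the fitted D50")
    return CalibrationA(a=t * q * c_smps / s)


def combine_calibrations(cals: list[CalibrationA]) -> CalibrationA:
    """Mean A over samples; sigma_A is their sample standard deviation."""
    if not cals:
        raise CalibrationError("no calibrations to combine")
    vals = np.array([c.a for c in cals])
    sigma = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return CalibrationA(a=float(vals.mean()), sigma_a=sigma)


def estimate_concentration(densities: dict[float, float],
                           curve: EfficiencyCurve, calibration: CalibrationA,
                           t: float, q: float) -> tuple[float, float]:
    """Airborne number concentration from impactor image statistics.

    Inverse of :func:`calibrate_a`:
    C = A * sum(N_dp / Ceff(dp)) / (t Q), with relative uncertainty at
    least sigma_A / A.  Returns (C, sigma_C) in cm^-3.
    """
    if t * q <= 0:
        raise ValueError("t and Q must be positive")
    s = _efficiency_weighted_sum(densities, curve)
    c = calibration.a * s / (t * q)
    return c, c * (calibration.sigma_a / calibration.a)


def sampling_window(c: float, q: float,
                    sp_lower: float = SP_LOWER_DEFAULT,
                    sp_upper: float = SP_UPPER_DEFAULT,
                    midpoint: str = "geometric") -> tuple[float, float, float]:
    """Sampling-time window (t_min, t_opt, t_max) in seconds.

    t_min and t_max invert Sp = t Q C at the lower and upper loading
    limits.  The optimum is their geometric midpoint (the limits span
    about a decade and loading plots are log-log); ``midpoint=
    'arithmetic'`` selects the arithmetic mean instead.
    """
    if c <= 0 or q <= 0:
        raise ValueError("C and Q must be positive")
    if midpoint not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown midpoint rule {midpoint!r}")
    t_min = sp_lower / (q * c)
    t_max = sp_upper / (q * c)
    t_opt = math.sqrt(t_min * t_max) if midpoint == "geometric" \
        else (t_min + t_max) / 2.0
    return t_min, t_opt, t_max


def coverage_fraction(mask: np.ndarray) -> float:
    """Percentage of a segmentation mask recognized as particles."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(mask.sum()) / mask.size
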