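"""Experimental collection efficiency and sigmoid curve fitting.

The impactor collection efficiency is measured with paired CPC series
up- and downstream of the impactor, run both with and without the
collection plate installed.  The with-plate removal includes impaction
plus parasitic losses; the without-plate removal includes the losses
only, so the difference isolates the efficiency of the plate itself.
The resulting s-shaped points are fitted with

    Ceff(d) = cmax / (1 + (D50 / d)^(2 s))

where ``cmax`` is the plateau efficiency (below 1 when particles
bounce), ``D50`` the cut-off and ``s`` a steepness parameter.  The
plateau is estimated first from points above a plateau diameter and
held fixed while (D50, s) are fitted by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (FitFailureError, InsufficientDataError,
                     InvalidDiameterError, PairingError)

#: Default DMA sample/sheath flow ratio; relative half width of the
#: transfer function, hence the relative diameter uncertainty.
DEFAULT_DMA_FLOW_RATIO = 0.1


@dataclass
class CpcSeries:
    """One CPC concentration time series at a fixed DMA setpoint."""

    selected_diameter: float  # nm
    timestamps: np.ndarray  # s
    concentrations: np.ndarray  # cm^-3
    position: str = "upstream"  # upstream | downstream
    configuration: str = "with_plate"  # with_plate | without_plate

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.timestamps.shape != self.concentrations.shape:
            raise ValueError("timestamps and concentrations must align")
        if self.concentrations.size == 0:
            raise ValueError("empty CPC series")
        if np.any(self.concentrations < 0):
            raise ValueError("CPC concentrations must be non-negative")
        if self.position not in ("upstream", "downstream"):
            raise ValueError(f"unknown position {self.position!r}")
        if self.configuration not in ("with_plate", "without_plate"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.concentrations.size < 2:
            warnings.warn("CPC series has a single sample; the averaging "
                          "window should span at least two readings",
                          stacklevel=2)

    @property
    def mean(self) -> float:
        return float(np.mean(self.concentrations))

    @property
    def std(self) -> float:
        return float(np.std(self.concentrations, ddof=1)) \
            if self.concentrations.size > 1 else 0.0


@dataclass(frozen=True)
class RemovalPoint:
    """Fractional removal (or plate efficiency) at one diameter."""

    diameter: float  # nm
    removal: float  # dimensionless; may leave [0, 1] through noise
    sigma: float = 0.0
    diameter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.diameter_sigma < 0:
            raise ValueError("uncertainties must be non-negative")

    @property
    def flagged(self) -> bool:
        """True when the point is implausibly far outside [0, 1]."""
        return not (-0.2 <= self.removal <= 1.2)


@dataclass(frozen=True)
class EfficiencyCurve:
    """Fitted sigmoid collection-efficiency curve."""

    cmax: float
    d50: float  # nm
    steepness: float
    cmax_sigma: float = 0.0
    d50_sigma: float = 0.0
    steepness_sigma: float = 0.0
    covariance: np.ndarray | None = field(default=None, repr=False)  # (D50, s)

    def __post_init__(self) -> None:
        if not 0 < self.cmax <= 1:
            raise ValueError("cmax must lie in (0, 1]")
        if not self.d50 > 0:
            raise ValueError("D50 must be positive")
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")

    def __call__(self, d):
        return evaluate_ceff(self, d)


def fractional_removal(upstream: CpcSeries, downstream: CpcSeries,
                       dma_flow_ratio: float = DEFAULT_DMA_FLOW_RATIO) -> RemovalPoint:
    """Fractional removal 1 - mean(downstream)/mean(upstream).

    The uncertainty is first-order propagation of the standard
    deviations of the two averaging windows; the diameter uncertainty is
    the DMA transfer-function half width ``dma_flow_ratio * d``.
    """
    if upstream.selected_diameter != downstream.selected_diameter:
        raise PairingError(
            f"setpoint mismatch: {upstream.selected_diameter} nm vs "
            f"{downstream.selected_diameter} nm")
    mu, md = upstream.mean, downstream.mean
    if mu == 0:
        raise ZeroDivisionError("mean upstream concentration is zero")
    removal = 1.0 - md / mu
    sigma = float(np.hypot(downstream.std / mu, md * upstream.std / mu**2))
    return RemovalPoint(diameter=upstream.selected_diameter, removal=removal,
                        sigma=sigma,
                        diameter_sigma=dma_flow_ratio * upstream.selected_diameter)


def experimental_ceff(with_plate: RemovalPoint,
                      without_plate: RemovalPoint) -> RemovalPoint:
    """Difference-method plate efficiency at one diameter.

    Assumes wall/orifice/pump losses are identical in both
    configurations, so Ceff_exp = removal_with - removal_without; the
    uncertainties add in quadrature.
    """
    if with_plate.diameter != without_plate.diameter:
        raise PairingError(
            f"diameter mismatch: {with_plate.diameter} nm vs "
            f"{without_plate.diameter} nm")
    return RemovalPoint(
        diameter=with_plate.diameter,
        removal=with_plate.removal - without_plate.removal,
        sigma=float(np.hypot(with_plate.sigma, without_plate.sigma)),
        diameter_sigma=with_plate.diameter_sigma)


def estimate_cmax(points: list[RemovalPoint],
                  plateau_diameter: float = 120.0) -> tuple[float, float]:
    """Plateau efficiency: mean of points with d >= plateau_diameter.

    Returns (cmax, sigma) where sigma is the sample standard deviation
    of the plateau points (0 for a single point).
    """
    plateau = [p.removal for p in points if p.diameter >= plateau_diameter]
    if not plateau:
        raise InsufficientDataError(
            f"no points at or above the {plateau_diameter} nm plateau")
    vals = np.asarray(plateau)
    sigma = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sigma


def _sigmoid(d, cmax, d50, s):
    return cmax / (1.0 + (d50 / d) ** (2.0 * s))


def _initial_d50(d: np.ndarray, c: np.ndarray, cmax: float) -> float:
    """Diameter where the data first cross cmax/2, by linear interpolation."""
    half = cmax / 2.0
    above = np.nonzero(c >= half)[0]
    if above.size == 0 or above[0] == 0:
        return float(np.median(d))
    i = above[0]
    d0, d1, c0, c1 = d[i - 1], d[i], c[i - 1], c[i]
    if c1 == c0:
        return float(d1)
    return float(d0 + (half - c0) * (d1 - d0) / (c1 - c0))


def fit_sigmoid(points: list[RemovalPoint], cmax: float,
                *, cmax_sigma: float = 0.0, weighted: bool = True,
                fit_cmax: bool = False,
                d_range: tuple[float, float] | None = None) -> EfficiencyCurve:
    """Least-squares fit of the sigmoid efficiency curve.

    ``cmax`` is held fixed (two-step procedure) unless ``fit_cmax`` is
    set, in which case all three parameters are free.  Points are
    weighted by 1/sigma^2 when all sigmas are positive and ``weighted``
    is true.  ``d_range`` optionally restricts the fitted diameters
    (e.g. to exclude the loss-dominated sub-50 nm region).
    """
    pts = list(points)
    if d_range is not None:
        pts = [p for p in pts if d_range[0] <= p.diameter <= d_range[1]]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need at least 3 points for the sigmoid fit, got {len(pts)}")
    d = np.array([p.diameter for p in pts], dtype=float)
    c = np.array([p.removal for p in pts], dtype=float)
    sig = np.array([p.sigma for p in pts], dtype=float)
    use_sigma = weighted and np.all(sig > 0)
    kw = {"sigma": sig, "absolute_sigma": True} if use_sigma else {}

    d50_0 = _initial_d50(d, c, cmax)
    try:
        if fit_cmax:
            popt, pcov = curve_fit(
                _sigmoid, d, c, p0=[cmax, d50_0, 2.0],
                bounds=([1e-6, 1e-3, 1e-3], [1.0, np.inf, np.inf]),
                maxfev=20_000, **kw)
            cmax_f, d50, s = popt
            cmax_sig = float(np.sqrt(pcov[0, 0]))
            cov = pcov[1:, 1:]
            d50_sig, s_sig = np.sqrt(np.diag(cov))
        else:
            popt, pcov = curve_fit(
                lambda dd, d50, s: _sigmoid(dd, cmax, d50, s),
                d, c, p0=[d50_0, 2.0],
                bounds=([1e-3, 1e-3], [np.inf, np.inf]),
                maxfev=20_000, **kw)
            cmax_f, (d50, s) = cmax, popt
            cmax_sig, cov = cmax_sigma, pcov
            d50_sig, s_sig = np.sqrt(np.diag(pcov))
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitFailureError(
            f"sigmoid fit did not converge on {len(pts)} points "
            f"(d0={d50_0:.1f} nm): {exc}") from exc
    return EfficiencyCurve(cmax=float(cmax_f), d50=float(d50),
                           steepness=float(s), cmax_sigma=float(cmax_sig),
                           d50_sigma=float(d50_sig),
                           steepness_sigma=float(s_sig), covariance=cov)


def evaluate_ceff(curve: EfficiencyCurve, d):
    """Evaluate the sigmoid curve at diameter(s) ``d`` in nm."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise InvalidDiameterError("diameter must be positive")
    out = _sigmoid(d_arr, curve.cmax, curve.d50, curve.steepness)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def fit_pipeline(pairs, *, plateau_diameter: float = 120.0,
                 weighted: bool = True,
                 d_range: tuple[float, float] | None = None) -> EfficiencyCurve:
    """Full reduction: CPC pairs -> removals -> difference -> fit.

    ``pairs`` is an iterable of 4-tuples of :class:`CpcSeries`
    (upstream_with, downstream_with, upstream_without, downstream_without),
    one per DMA setpoint.
    """
    points = []
    for up_w, down_w, up_wo, down_wo in pairs:
        r_with = fractional_removal(up_w, down_w)
        r_without = fractional_removal(up_wo, down_wo)
        points.append(experimental_ceff(r_with, r_without))
    cmax, cmax_sigma = estimate_cmax(points, plateau_diameter)
    return fit_sigmoid(points, cmax, cmax_sigma=cmax_sigma,
                       weighted=weighted, d_range=d_range)
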