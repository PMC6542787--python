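"""Inertial impactor design theory.

Closed-form and iterative calculations for a round-jet impactor stage:
mean jet velocity, jet Reynolds number, Cunningham slip correction, and
the theoretical cut-off diameter D50 obtained from the critical Stokes
number.  The cut-off is the diameter collected with 50 % efficiency,

    Stk50 = rho_p * d50^2 * Cc(d50) * U / (9 * mu * W)

which is solved for ``d50`` iteratively because the slip correction
``Cc`` itself depends on the diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidDiameterError, InvalidGeometryError, NoSolutionError

#: Reference air state used for pressure/temperature scaling of defaults.
_T_REF = 298.15  # K
_P_REF = 101_325.0  # Pa
_MU_REF = 1.849e-5  # Pa s at 25 degC
_LAMBDA_REF = 66.4e-9  # m at 25 degC, 101.325 kPa
_M_AIR = 0.028964  # kg/mol
_R_GAS = 8.314462  # J/(mol K)

#: Published round-jet design window for sharp collection curves.
REYNOLDS_DESIGN_RANGE = (500.0, 3000.0)
#: Published jet-to-plate spacing criterion for round jets.
S_OVER_W_DESIGN_RANGE = (1.0, 5.0)


@dataclass(frozen=True)
class GasState:
    """Thermodynamic state and transport properties of the carrier gas.

    Defaults are ambient air at 25 degC and 101.325 kPa.  The mean free
    path scales inversely with pressure and linearly with temperature;
    use :meth:`ambient` to build a consistent state at other conditions.
    """

    temperature: float = _T_REF  # K
    pressure: float = _P_REF  # Pa
    density: float = 1.184  # kg m^-3
    dynamic_viscosity: float = _MU_REF  # Pa s
    mean_free_path: float = _LAMBDA_REF  # m

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "density",
                     "dynamic_viscosity", "mean_free_path"):
            if not getattr(self, name) > 0:
                raise ValueError(f"GasState.{name} must be strictly positive")

    @classmethod
    def ambient(cls, temperature_c: float = 25.0,
                pressure_pa: float = _P_REF) -> "GasState":
        """Air properties at the given temperature and pressure.

        Density follows the ideal gas law, viscosity a Sutherland law
        anchored at the 25 degC reference, and the mean free path the
        usual lambda ~ T/P scaling.
        """
        t = temperature_c + 273.15
        if t <= 0 or pressure_pa <= 0:
            raise ValueError("temperature and pressure must be positive")
        rho = pressure_pa * _M_AIR / (_R_GAS * t)
        mu = _MU_REF * (t / _T_REF) ** 1.5 * (_T_REF + 110.4) / (t + 110.4)
        lam = _LAMBDA_REF * (_P_REF / pressure_pa) * (t / _T_REF)
        return cls(temperature=t, pressure=pressure_pa, density=rho,
                   dynamic_viscosity=mu, mean_free_path=lam)


@dataclass(frozen=True)
class ImpactorStageSpec:
    """Geometry and operating point of one round-jet impactor stage.

    ``stk50`` is the critical Stokes number (default 0.24, the standard
    round-jet value, i.e. sqrt(Stk50) = 0.49); ``particle_density``
    defaults to unit density (1000 kg m^-3, PSL calibration spheres).
    """

    orifice_diameter: float  # m
    volumetric_flow: float  # m^3 s^-1
    jet_to_plate_ratio: float = 1.3
    stk50: float = 0.24
    particle_density: float = 1000.0  # kg m^-3

    def __post_init__(self) -> None:
        if not self.orifice_diameter > 0:
            raise InvalidGeometryError("orifice diameter must be positive")
        if self.volumetric_flow < 0:
            raise InvalidGeometryError("volumetric flow must be non-negative")
        if not 0 < self.stk50 < 1:
            raise InvalidGeometryError("stk50 must lie in (0, 1)")
        if not self.particle_density > 0:
            raise InvalidGeometryError("particle density must be positive")

    @classmethod
    def from_practical_units(cls, orifice_mm: float, flow_lpm: float,
                             **kwargs) -> "ImpactorStageSpec":
        """Build a stage from orifice in mm and flow in L/min."""
        return cls(orifice_diameter=orifice_mm * 1e-3,
                   volumetric_flow=flow_lpm * 1e-3 / 60.0, **kwargs)


def jet_velocity(stage: ImpactorStageSpec) -> float:
    """Mean jet velocity U = 4 Q / (pi W^2) in m/s."""
    w = stage.orifice_diameter
    return 4.0 * stage.volumetric_flow / (math.pi * w * w)


def reynolds_number(stage: ImpactorStageSpec, gas: GasState | None = None) -> float:
    """Jet Reynolds number Re = rho U W / mu = 4 rho Q / (pi mu W)."""
    gas = gas or GasState()
    return (4.0 * gas.density * stage.volumetric_flow
            / (math.pi * gas.dynamic_viscosity * stage.orifice_diameter))


def slip_correction(d, gas: GasState | None = None):
    """Cunningham slip correction Cc = 1 + Kn (1.257 + 0.4 exp(-1.1/Kn)).

    ``d`` is the particle diameter in metres (scalar or array);
    Kn = 2 lambda / d.  Cc >= 1 and decreases monotonically towards the
    continuum limit Cc -> 1 for large particles.
    """
    gas = gas or GasState()
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise InvalidDiameterError("particle diameter must be positive")
    kn = 2.0 * gas.mean_free_path / d_arr
    cc = 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))
    return float(cc) if np.isscalar(d) or d_arr.ndim == 0 else cc


def _impaction_parameter_target(stage: ImpactorStageSpec, gas: GasState) -> float:
    """Right-hand side of d^2 Cc(d) = 9 mu W Stk50 / (rho_p U)."""
    u = jet_velocity(stage)
    if u <= 0:
        raise InvalidGeometryError("cut-off undefined at zero flow")
    return (9.0 * gas.dynamic_viscosity * stage.orifice_diameter * stage.stk50
            / (stage.particle_density * u))


def cutoff_diameter(stage: ImpactorStageSpec, gas: GasState | None = None,
                    *, slip: bool = True, rtol: float = 1e-6) -> float:
    """Theoretical cut-off diameter D50 in metres.

    Solves ``d^2 Cc(d) = 9 mu W Stk50 / (rho_p U)`` by bisection on
    [1 nm, 100 um].  With ``slip=False`` the closed-form no-slip root
    sqrt(9 mu W Stk50 / (rho_p U)) is returned.
    """
    gas = gas or GasState()
    target = _impaction_parameter_target(stage, gas)
    if not slip:
        return math.sqrt(target)

    def f(d: float) -> float:
        return d * d * slip_correction(d, gas) - target

    lo, hi = 1e-9, 100e-6
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise NoSolutionError(
            f"no cut-off in [1 nm, 100 um]: f(lo)={flo:.3g}, f(hi)={fhi:.3g}")
    return brentq(f, lo, hi, rtol=rtol)


@dataclass(frozen=True)
class DesignReport:
    """Result of the impactor stage design check."""

    jet_velocity: float  # m/s
    reynolds: float
    cutoff: float  # m
    reynolds_ok: bool
    s_over_w_ok: bool
    flags: tuple = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return self.reynolds_ok and self.s_over_w_ok


def design_check(stage: ImpactorStageSpec, gas: GasState | None = None) -> DesignReport:
    """Check a stage against published round-jet design criteria.

    Flags a Reynolds number outside 500-3000 (sharpness of the
    collection curve) and a jet-to-plate ratio outside the published
    S/W window.  The report carries U, Re and D50.
    """
    gas = gas or GasState()
    u = jet_velocity(stage)
    re = reynolds_number(stage, gas)
    d50 = cutoff_diameter(stage, gas)
    flags = []
    re_lo, re_hi = REYNOLDS_DESIGN_RANGE
    re_ok = re_lo <= re <= re_hi
    if re < re_lo:
        flags.append(f"Re={re:.0f} below design range {re_lo:.0f}-{re_hi:.0f}")
    elif re > re_hi:
        flags.append(f"Re={re:.0f} above design range {re_lo:.0f}-{re_hi:.0f}")
    sw_lo, sw_hi = S_OVER_W_DESIGN_RANGE
    sw_ok = sw_lo <= stage.jet_to_plate_ratio <= sw_hi
    if not sw_ok:
        flags.append(
            f"S/W={stage.jet_to_plate_ratio:.2f} outside {sw_lo}-{sw_hi}")
    return DesignReport(jet_velocity=u, reynolds=re, cutoff=d50,
                        reynolds_ok=re_ok, s_over_w_ok=sw_ok,
                        flags=tuple(flags))
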