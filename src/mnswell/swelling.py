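"""Hydrogel swelling: percentage series, pseudo-second-order kinetics and
gel characterisation.

The swelling percentage of an array weighed dry (``m0``) and again at time
``t`` (``m_t``) is ``S% = (m_t - m0)/m0 * 100``.  Swelling of crosslinked
hydrogels is modelled with pseudo-second-order kinetics,

    dS/dt = k_s * (S_inf - S)^2,

whose integrated form ``S(t) = k_s * S_inf^2 * t / (1 + k_s * S_inf * t)``
linearises to ``t/S = 1/(k_s * S_inf^2) + t/S_inf``: an ordinary
least-squares line of ``t/S`` on ``t`` yields ``S_inf = 1/slope`` and
``k_s = slope^2 / intercept``.

Gel characterisation from equilibrium and xerogel masses:

* equilibrium water content  EWC% = (m_inf - m_x)/m_x * 100
* gel fraction               GF%  = m_x/m0 * 100
* solvent-displacement porosity  phi = (m_EtOH - m0)/(V_T * rho_EtOH)

Unit convention: S is stored in percent throughout, so ``k_s`` carries
units of %^-1 min^-1.  :func:`convert_ks` rescales to the mass-fraction
(mg/mg) convention, which differs by a fixed factor of 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateFitError, InsufficientDataError, ValidationError

__all__ = [
    "MassSeries",
    "PsoParams",
    "GelMasses",
    "swelling_percent_series",
    "pso_fit",
    "pso_fit_nls",
    "pso_predict",
    "ewc",
    "gel_fraction",
    "porosity",
    "convert_ks",
    "mass_at_equilibrium",
]


@dataclass(frozen=True)
class MassSeries:
    """Array mass vs time.

    t : minutes, nonnegative, strictly increasing.
    m : masses in mg, positive.
    m0 : initial dry (xerogel-state) mass in mg.
    """

    t: np.ndarray
    m: np.ndarray
    m0: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "m", m)
        if len(t) != len(m):
            raise ValidationError("t and m must have equal length")
        if self.m0 <= 0:
            raise ValidationError("initial mass m0 must be positive")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("t must be nonnegative and strictly increasing")
        if np.any(m <= 0):
            raise ValidationError("masses must be positive")


@dataclass(frozen=True)
class PsoParams:
    """Fitted pseudo-second-order parameters.

    S_inf : equilibrium swelling (%).
    k_s : rate constant (%^-1 min^-1).
    r2 : coefficient of determination of the linearised t vs t/S fit.
    intercept, slope : the linearised regression coefficients.
    """

    S_inf: float
    k_s: float
    r2: float
    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.S_inf <= 0 or self.k_s <= 0:
            raise ValidationError("S_inf and k_s must be positive")
        if not 0 <= self.r2 <= 1:
            raise ValidationError("r2 must lie in [0, 1]")


@dataclass(frozen=True)
class GelMasses:
    """Scalar masses for gel characterisation (mg; V_T in cm^3)."""

    m0: float
    m_inf: float
    m_x: float
    m_EtOH: float
    V_T: float
    rho_EtOH: float = 0.789  # g/cm^3, absolute ethanol

    def __post_init__(self) -> None:
        for name in ("m0", "m_inf", "m_x", "m_EtOH", "V_T", "rho_EtOH"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def swelling_percent_series(series: MassSeries) -> tuple[np.ndarray, np.ndarray]:
    """Convert a mass series to (t, S%) with S = (m - m0)/m0 * 100.

    Negative S values (mass below the initial dry mass, e.g. evaporation
    artifacts) are rejected.
    """
    S = (series.m - series.m0) / series.m0 * 100.0
    if np.any(S < 0):
        raise ValidationError("negative swelling percentage: mass fell below m0")
    return series.t.copy(), S


def _usable(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (t > 0) & (y > 0)
    return t[keep], y[keep]


def pso_fit(t: np.ndarray, S: np.ndarray) -> PsoParams:
    """Linearised pseudo-second-order fit of a swelling-percentage series.

    Ordinary least squares of ``y = t/S`` on ``t``; points with ``t <= 0``
    or ``S <= 0`` are dropped first (t/S undefined at the origin).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points.
    DegenerateFitError
        Nonpositive slope or intercept: the data are inconsistent with the
        model (e.g. a constant series gives a line through the origin).
    """
    t, S = _usable(t, S)
    if len(t) < 3:
        raise InsufficientDataError("pseudo-second-order fit needs >= 3 points with t > 0, S > 0")
    y = t / S
    res = stats.linregress(t, y)
    if res.slope <= 0 or res.intercept <= 0:
        raise DegenerateFitError(
            f"linearised fit slope={res.slope:.3g}, intercept={res.intercept:.3g}: "
            "data inconsistent with pseudo-second-order kinetics"
        )
    S_inf = 1.0 / res.slope
    k_s = res.slope**2 / res.intercept
    return PsoParams(S_inf=S_inf, k_s=k_s, r2=min(res.rvalue**2, 1.0),
                     intercept=float(res.intercept), slope=float(res.slope))


def pso_fit_nls(t: np.ndarray, S: np.ndarray) -> PsoParams:
    """Unconstrained nonlinear least-squares fit of the forward model.

    Independent of the linearisation; used as a cross-check (on noise-free
    data both routes agree, under noise they may differ and the discrepancy
    is reported by the pipeline rather than hidden).
    """
    t, S = _usable(t, S)
    if len(t) < 3:
        raise InsufficientDataError("pseudo-second-order fit needs >= 3 points with t > 0, S > 0")

    def model(t, S_inf, k_s):
        return k_s * S_inf**2 * t / (1.0 + k_s * S_inf * t)

    # moment-style start: plateau from the last point, rate from the half rise
    s0 = float(np.max(S)) * 1.1
    k0 = 1.0 / (s0 * max(float(np.median(t)), 1e-9))
    popt, _ = optimize.curve_fit(model, t, S, p0=(s0, k0), maxfev=20000)
    S_inf, k_s = float(popt[0]), float(popt[1])
    if S_inf <= 0 or k_s <= 0:
        raise DegenerateFitError("nonlinear fit converged to nonpositive parameters")
    resid = S - model(t, S_inf, k_s)
    ss_tot = float(np.sum((S - S.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PsoParams(S_inf=S_inf, k_s=k_s, r2=float(np.clip(r2, 0.0, 1.0)),
                     intercept=1.0 / (k_s * S_inf**2), slope=1.0 / S_inf)


def pso_predict(params: PsoParams, t: np.ndarray | float) -> np.ndarray | float:
    """Forward model ``S(t) = k_s S_inf^2 t / (1 + k_s S_inf t)`` (percent).

    S(0) = 0; S is nondecreasing and approaches S_inf from below.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be nonnegative")
    out = params.k_s * params.S_inf**2 * t_arr / (1.0 + params.k_s * params.S_inf * t_arr)
    return float(out) if np.isscalar(t) else out


def ewc(masses: GelMasses) -> float:
    """Equilibrium water content EWC% = (m_inf - m_x)/m_x * 100."""
    return (masses.m_inf - masses.m_x) / masses.m_x * 100.0


def gel_fraction(masses: GelMasses) -> float:
    """Gel fraction GF% = m_x/m0 * 100 (crosslinked insoluble mass)."""
    return masses.m_x / masses.m0 * 100.0


def porosity(masses: GelMasses) -> float:
    """Solvent-displacement porosity phi = (m_EtOH - m0)/(V_T * rho_EtOH).

    Masses in mg are converted to g so that the ratio against
    ``V_T [cm^3] * rho_EtOH [g/cm^3]`` is dimensionless.  A value outside
    [0, 1] triggers a warning (physically a pore fraction) but is returned.
    """
    import warnings

    phi = (masses.m_EtOH - masses.m0) / 1000.0 / (masses.V_T * masses.rho_EtOH)
    if not 0.0 <= phi <= 1.0:
        warnings.warn(f"porosity {phi:.3g} outside [0, 1]; check masses/volume", stacklevel=2)
    return phi


def convert_ks(k_s: float, to: str) -> float:
    """Convert the rate constant between percent and mass-fraction scales.

    With S in percent, ``k_s`` has units %^-1 min^-1; with S as a mg/mg
    fraction (S_frac = S%/100) the same kinetics require
    ``k_frac = 100 * k_percent``.
    """
    if to == "fraction":
        return k_s * 100.0
    if to == "percent":
        return k_s / 100.0
    raise ValidationError("to must be 'fraction' or 'percent'")


def mass_at_equilibrium(m0: float, S_inf: float) -> float:
    """Equilibrium-swollen mass from the fitted plateau:
    ``m_inf = m0 * (1 + S_inf/100)``.

    Used when no measured plateau mass is available; a measured value can
    be supplied to :class:`GelMasses` directly instead.
    """
    if m0 <= 0:
        raise ValidationError("m0 must be positive")
    if S_inf < 0:
        raise ValidationError("S_inf must be nonnegative")
    return m0 * (1.0 + S_inf / 100.0)
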