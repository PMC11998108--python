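"""Drug release: aliquot-replacement correction, cumulative profiles and
ultra-fast release kinetics.

In a stirred-chamber release test, each sampled aliquot is replaced with
fresh buffer, diluting the chamber; the standard dissolution-testing
correction restores the cumulative concentration:

    C_cum(t_i) = C_sample(t_i) + (V_aliquot / V_reservoir) * sum_{j<i} C_sample(t_j).

Cumulative release is expressed as a percentage of ``C_max``, the total
(corrected) concentration at 24 h, so the final point is 100 %.

Ultra-fast release is modelled with the saturating two-parameter form

    Q_t / Q_24h = y = k*t / (1 + a*t),

linearised as ``1/y = (1/k)(1/t) + a/k``: ordinary least squares of
``1/y`` on ``1/t`` gives ``k = 1/slope`` and ``a = intercept * k``.  The
curve rises from 0 with initial rate ``k`` and saturates at the plateau
``k/a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateFitError, InsufficientDataError, ValidationError

__all__ = [
    "ReleaseSeries",
    "ReleaseParams",
    "cumulative_correct",
    "cumulative_percent",
    "taolu_fit",
    "taolu_fit_nls",
    "taolu_predict",
    "release_rate",
]


@dataclass(frozen=True)
class ReleaseSeries:
    """Aliquot concentrations sampled from a release chamber.

    t : sampling times (min, strictly increasing, > 0).
    C_sample : measured concentration in each extracted aliquot (mg/mL).
    V_reservoir : chamber volume (mL), default 14.
    V_aliquot : extracted/replaced volume (mL), default 1.
    """

    t: np.ndarray
    C_sample: np.ndarray
    V_reservoir: float = 14.0
    V_aliquot: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        C = np.asarray(self.C_sample, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "C_sample", C)
        if len(t) != len(C) or len(t) == 0:
            raise ValidationError("t and C_sample must be nonempty and equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("t must be positive and strictly increasing")
        if not 0 <= self.V_aliquot <= self.V_reservoir:
            raise ValidationError("require 0 <= V_aliquot <= V_reservoir")


@dataclass(frozen=True)
class ReleaseParams:
    """Fitted ultra-fast release parameters.

    k : release rate constant (min^-1), the initial fractional rate.
    a : empirical saturation parameter (min^-1).
    r2 : coefficient of determination of the linearised 1/t vs 1/y fit.
    plateau : asymptotic fraction k/a.
    """

    k: float
    a: float
    r2: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.a <= 0:
            raise ValidationError("k and a must be positive")
        if not 0 <= self.r2 <= 1:
            raise ValidationError("r2 must lie in [0, 1]")

    @property
    def plateau(self) -> float:
        return self.k / self.a


def cumulative_correct(series: ReleaseSeries) -> np.ndarray:
    """Aliquot-replacement-corrected cumulative concentrations (mg/mL).

    Reduces to the raw samples when ``V_aliquot == 0``.  The corrected
    series is nondecreasing whenever consecutive samples satisfy
    ``C_i >= (1 - V_aliquot/V_reservoir) * C_{i-1}`` — i.e. the chamber
    concentration never falls by more than the replacement dilution
    itself, which holds for any physically consistent release measurement.
    """
    C = series.C_sample
    if np.any(C < 0):
        raise ValidationError("concentrations must be nonnegative")
    frac = series.V_aliquot / series.V_reservoir
    prior = np.concatenate([[0.0], np.cumsum(C)[:-1]])
    return C + frac * prior


def cumulative_percent(C_cum: np.ndarray, C_max: float) -> np.ndarray:
    """Cumulative release as percent of the 24-h total ``C_max``."""
    if C_max <= 0:
        raise ValidationError("C_max must be positive")
    C_cum = np.asarray(C_cum, dtype=float)
    return C_cum / C_max * 100.0


def taolu_fit(t: np.ndarray, frac: np.ndarray) -> ReleaseParams:
    """Linearised fit of the ultra-fast release model y = k*t/(1 + a*t).

    OLS of ``1/frac`` on ``1/t`` over points with ``t > 0`` and
    ``frac > 0``; ``k = 1/slope``, ``a = intercept * k``.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points.
    DegenerateFitError
        Nonpositive slope (e.g. a series already at plateau) or
        nonpositive intercept.
    """
    t = np.asarray(t, dtype=float)
    frac = np.asarray(frac, dtype=float)
    keep = (t > 0) & (frac > 0)
    t, frac = t[keep], frac[keep]
    if len(t) < 3:
        raise InsufficientDataError("ultra-fast release fit needs >= 3 points with t > 0, frac > 0")
    res = stats.linregress(1.0 / t, 1.0 / frac)
    if res.slope <= 0 or res.intercept <= 0:
        raise DegenerateFitError(
            f"linearised fit slope={res.slope:.3g}, intercept={res.intercept:.3g}: "
            "data inconsistent with the saturating release model"
        )
    k = 1.0 / res.slope
    a = res.intercept * k
    return ReleaseParams(k=k, a=a, r2=min(res.rvalue**2, 1.0))


def taolu_fit_nls(t: np.ndarray, frac: np.ndarray) -> ReleaseParams:
    """Nonlinear least-squares fit of the forward model (linearisation-free
    oracle; more noise-robust since it does not reciprocal-weight early
    points)."""
    t = np.asarray(t, dtype=float)
    frac = np.asarray(frac, dtype=float)
    keep = (t > 0) & (frac > 0)
    t, frac = t[keep], frac[keep]
    if len(t) < 3:
        raise InsufficientDataError("ultra-fast release fit needs >= 3 points with t > 0, frac > 0")

    def model(t, k, a):
        return k * t / (1.0 + a * t)

    plateau0 = float(np.max(frac))
    a0 = 1.0 / max(float(np.median(t)), 1e-9)
    popt, _ = optimize.curve_fit(model, t, frac, p0=(plateau0 * a0, a0), maxfev=20000)
    k, a = float(popt[0]), float(popt[1])
    if k <= 0 or a <= 0:
        raise DegenerateFitError("nonlinear fit converged to nonpositive parameters")
    resid = frac - model(t, k, a)
    ss_tot = float(np.sum((frac - frac.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ReleaseParams(k=k, a=a, r2=float(np.clip(r2, 0.0, 1.0)))


def taolu_predict(params: ReleaseParams, t: np.ndarray | float) -> np.ndarray | float:
    """Forward model ``y(t) = k*t / (1 + a*t)``: 0 at t = 0, strictly
    increasing, approaching the plateau k/a."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be nonnegative")
    out = params.k * t_arr / (1.0 + params.a * t_arr)
    return float(out) if np.isscalar(t) else out


def release_rate(C_percent: np.ndarray, t: np.ndarray, window_end: float) -> float:
    """Initial release rate in %/min: least-squares slope of C% vs t over
    ``[0, window_end]`` minutes."""
    t = np.asarray(t, dtype=float)
    C = np.asarray(C_percent, dtype=float)
    if len(t) != len(C):
        raise ValidationError("t and C_percent must have equal length")
    keep = (t >= 0) & (t <= window_end)
    t, C = t[keep], C[keep]
    if len(t) < 2:
        raise InsufficientDataError("release rate needs >= 2 points within the window")
    slope, _ = np.polyfit(t, C, 1)
    return float(slope)
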