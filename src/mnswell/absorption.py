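"""Drug absorption into a swollen hydrogel array: loading and transport
parameters.

An array submerged in a finite drug reservoir takes up solute until the
two compartments equilibrate.  For equal effective compartments the
uptake obeys

    ln[1 - 2*Ct/C0] = -(2*A/V) * P * t,

so the permeability coefficient is ``P = -(V / (2*A*t)) * ln(1 - 2*Ct/C0)``
with ``Ct`` the concentration absorbed into the array, ``C0`` the initial
bulk concentration, ``A`` the permeation area and ``V`` the solution
volume.  The partition coefficient is the equilibrium concentration ratio
``K_d = C_m / C_24`` (gel vs reservoir at 24 h), and the diffusion
coefficient follows from ``D = P * L / K_d`` with ``L`` the array
thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import TransportDomainError, ValidationError

__all__ = [
    "AbsorptionRecord",
    "TransportParams",
    "absorbed_amount",
    "permeability",
    "partition_coefficient",
    "diffusion_coefficient",
    "transport_params",
    "SECONDS_PER_24H",
]

SECONDS_PER_24H = 86_400.0


@dataclass(frozen=True)
class AbsorptionRecord:
    """One array's absorption experiment.

    C0 : initial bulk concentration (mg/mL).
    Ct : drug concentration absorbed in the array at time t (mg/mL).
    C24 : reservoir concentration remaining at 24 h (mg/mL).
    Cm : absorbed concentration in the array at equilibrium (mg/mL).
    V : drug solution volume (mL).
    A : permeation area (cm^2) — total external array surface; no default.
    L : array thickness after 24 h (cm).
    t : exposure time (s); defaults to 24 h.
    Mx : array mass (mg).
    V_res : re-swell reservoir volume (mL).
    """

    C0: float
    Ct: float
    C24: float
    Cm: float
    V: float
    A: float
    L: float
    Mx: float
    V_res: float
    t: float = SECONDS_PER_24H

    def __post_init__(self) -> None:
        for name in ("C0", "C24", "Cm", "V", "A", "L", "Mx", "V_res", "t"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.Ct < 0:
            raise ValidationError("Ct must be nonnegative")
        if self.Ct >= self.C0 / 2.0:
            raise ValidationError(
                "Ct must be below C0/2 (two-compartment equilibrium bound)"
            )


@dataclass(frozen=True)
class TransportParams:
    """Mass-transport parameter bundle; D = P*L/K_d holds by construction."""

    P: float
    Kd: float
    D: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.Kd <= 0 or self.D < 0:
            raise ValidationError("require P >= 0, Kd > 0, D >= 0")


def absorbed_amount(
    C_measured: float, V_res: float, Mx: float, paper_literal: bool = False
) -> float:
    """Drug loading of an array in ug drug per mg array.

    Default: ``(C_measured [mg/mL] * V_res [mL]) * 1000 / Mx [mg]``, i.e.
    the absorbed drug mass divided by array mass — the only reading that
    actually carries the ug/mg unit.  With ``paper_literal=True`` the bare
    concentration-over-mass ratio ``C_measured / Mx`` is returned instead,
    reproducing the printed formula verbatim.
    """
    if Mx <= 0:
        raise ValidationError("array mass Mx must be positive")
    if C_measured < 0:
        raise ValidationError("concentration must be nonnegative")
    if paper_literal:
        return C_measured / Mx
    if V_res <= 0:
        raise ValidationError("reservoir volume V_res must be positive")
    return C_measured * V_res * 1000.0 / Mx


def permeability(
    Ct: float, C0: float, A: float, V: float, t: float = SECONDS_PER_24H
) -> float:
    """Permeability coefficient from two-compartment uptake.

    ``P = -(V / (2*A*t)) * ln(1 - 2*Ct/C0)`` in cm/s for V in mL (= cm^3),
    A in cm^2 and t in s.

    Raises
    ------
    TransportDomainError
        ``Ct >= C0/2``: the log argument is nonpositive (equilibrium
        reached or measurement error).
    """
    if C0 <= 0 or A <= 0 or V <= 0 or t <= 0:
        raise ValidationError("C0, A, V and t must be positive")
    if Ct < 0:
        raise ValidationError("Ct must be nonnegative")
    arg = 1.0 - 2.0 * Ct / C0
    if arg <= 0:
        raise TransportDomainError(
            f"Ct = {Ct:g} >= C0/2 = {C0 / 2:g}: two-compartment equilibrium "
            "reached; permeability is undefined"
        )
    return -(V / (2.0 * A * t)) * math.log(arg)


def partition_coefficient(Cm: float, C24: float) -> float:
    """Partition coefficient K_d = Cm / C24 (gel vs reservoir at 24 h)."""
    if C24 <= 0:
        raise ValidationError("reservoir concentration C24 must be positive")
    if Cm < 0:
        raise ValidationError("Cm must be nonnegative")
    return Cm / C24


def diffusion_coefficient(P: float, L: float, Kd: float) -> float:
    """Diffusion coefficient D = P * L / K_d (cm^2/s)."""
    if Kd <= 0:
        raise ValidationError("partition coefficient Kd must be positive")
    if L <= 0:
        raise ValidationError("thickness L must be positive")
    if P < 0:
        raise ValidationError("permeability P must be nonnegative")
    return P * L / Kd


def transport_params(rec: AbsorptionRecord) -> TransportParams:
    """Full transport bundle (P, K_d, D) from one absorption record."""
    P = permeability(rec.Ct, rec.C0, rec.A, rec.V, rec.t)
    Kd = partition_coefficient(rec.Cm, rec.C24)
    D = diffusion_coefficient(P, rec.L, Kd)
    return TransportParams(P=P, Kd=Kd, D=D)
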