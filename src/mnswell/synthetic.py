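"""Seeded synthetic-data generators emulating the study's measurement
processes.

Each generator draws from the forward model of the stage it feeds
(pseudo-second-order swelling, saturating ultra-fast release with aliquot
sampling, two-compartment absorption uptake, analytic needle profiles)
and perturbs it with multiplicative Gaussian noise of a given coefficient
of variation — the natural error model for balance and HPLC readings
whose error scales with the measured value.  Every fixture records the
generating truth and seed, so recovery tests compare against the embedded
truth rather than re-entering it by hand.

Default truth bundles mirror the optimised 20 % (w/w) PMVE/MA formulation:
equilibrium swelling 714 % with rate constant 5.35e-5 %^-1 min^-1 on an
18-point 10-180 min grid, release rate constant 0.056 min^-1 sampled every
10 min to 1 h then out to 24 h from a 14 mL chamber with 1 mL aliquots,
and a permeability of 18e-6 cm/s out of a 4 mL, 10 mg/mL reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import ValidationError
from .geometry import RadialProfile, ShapeParams, shape_profile
from .release import ReleaseParams, ReleaseSeries, taolu_predict
from .swelling import MassSeries, PsoParams, pso_predict

__all__ = [
    "SimSpec",
    "SWELLING_GRID_MIN",
    "RELEASE_GRID_MIN",
    "DEFAULT_TRUTH",
    "gen_swelling_series",
    "gen_release_series",
    "gen_absorption_course",
    "gen_profile",
]

#: Swelling sampling grid: every 10 min for 3 h.
SWELLING_GRID_MIN = np.arange(10.0, 181.0, 10.0)

#: Release sampling grid: every 10 min to 1 h, then 2, 4, 8 and 24 h.
RELEASE_GRID_MIN = np.array([10., 20., 30., 40., 50., 60., 120., 240., 480., 1440.])

#: Study-condition truth bundles per model (see module docstring).
DEFAULT_TRUTH: dict[str, dict[str, float]] = {
    "pso_swelling": {"S_inf": 714.0, "k_s": 5.35e-5, "m0": 260.0},
    "taolu_release": {
        "k": 0.056,
        # saturation parameter anchored so the true curve passes through
        # the 24-h normalisation point y(1440) = 1
        "a": (0.056 * 1440.0 - 1.0) / 1440.0,
        "C_max": 1.876,  # 101 ug/mg * 260 mg in 14 mL
        "V_reservoir": 14.0,
        "V_aliquot": 1.0,
    },
    "absorption_course": {"P": 18e-6, "C0": 10.0, "A": 1.0, "V": 4.0},
}

_MODELS = ("pso_swelling", "taolu_release", "absorption_course", "needle_profile")


@dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic dataset.

    model : which forward model to draw from.
    truth : generating parameters; ``None`` selects the study-condition
        defaults (needle_profile has no default and requires an explicit
        ``shape`` plus ``jitter_um``).
    grid : time points (min) or axial sample count, model-dependent;
        ``None`` selects the default grid.
    noise_cv : multiplicative coefficient of variation (>= 0).
    seed : integer seed; mandatory so every fixture is reproducible.
    """

    model: str
    seed: int
    truth: dict[str, Any] | None = None
    grid: np.ndarray | None = None
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValidationError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValidationError("an integer seed is mandatory")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if np.any(np.diff(g) <= 0):
                raise ValidationError("grid must be strictly increasing")
            object.__setattr__(self, "grid", g)

    def resolved_truth(self) -> dict[str, Any]:
        if self.truth is not None:
            return dict(self.truth)
        if self.model not in DEFAULT_TRUTH:
            raise ValidationError(f"model {self.model!r} has no default truth; supply one")
        return dict(DEFAULT_TRUTH[self.model])


def _rng(spec: SimSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    return 1.0 + rng.normal(0.0, cv, size=n) if cv > 0 else np.ones(n)


def gen_swelling_series(spec: SimSpec) -> tuple[MassSeries, dict[str, Any]]:
    """Synthetic array-mass series from pseudo-second-order swelling.

    ``m(t_i) = m0 * (1 + S(t_i)/100) * (1 + eps_i)`` with
    ``eps_i ~ N(0, noise_cv)``.  Returns the series and the recorded truth
    (including the seed).
    """
    if spec.model != "pso_swelling":
        raise ValidationError("spec.model must be 'pso_swelling'")
    truth = spec.resolved_truth()
    t = SWELLING_GRID_MIN.copy() if spec.grid is None else spec.grid
    params = PsoParams(S_inf=truth["S_inf"], k_s=truth["k_s"], r2=1.0,
                       intercept=1.0 / (truth["k_s"] * truth["S_inf"] ** 2),
                       slope=1.0 / truth["S_inf"])
    S = pso_predict(params, t)
    m = truth["m0"] * (1.0 + S / 100.0) * _noise(_rng(spec), len(t), spec.noise_cv)
    truth["seed"] = spec.seed
    return MassSeries(t=t, m=m, m0=truth["m0"]), truth


def gen_release_series(spec: SimSpec) -> tuple[ReleaseSeries, dict[str, Any]]:
    """Synthetic aliquot-concentration series from the ultra-fast release
    model, with the aliquot-replacement dilution applied in reverse.

    The true cumulative curve ``C_cum(t) = C_max * y(t)`` is inverted
    through the sampling correction so that ``cumulative_correct`` of the
    emitted samples reproduces the truth exactly at ``noise_cv = 0``;
    multiplicative noise is then applied to the per-sample measurements.
    """
    if spec.model != "taolu_release":
        raise ValidationError("spec.model must be 'taolu_release'")
    truth = spec.resolved_truth()
    t = RELEASE_GRID_MIN.copy() if spec.grid is None else spec.grid
    params = ReleaseParams(k=truth["k"], a=truth["a"], r2=1.0)
    C_cum = truth["C_max"] * np.asarray(taolu_predict(params, t))
    frac = truth["V_aliquot"] / truth["V_reservoir"]
    # invert C_cum_i = C_i + frac * sum_{j<i} C_j  for the raw samples
    C_sample = np.empty_like(C_cum)
    running = 0.0
    for i, c in enumerate(C_cum):
        C_sample[i] = c - frac * running
        running += C_sample[i]
    C_sample = np.maximum(C_sample, 0.0) * _noise(_rng(spec), len(t), spec.noise_cv)
    truth["seed"] = spec.seed
    series = ReleaseSeries(t=t, C_sample=C_sample,
                           V_reservoir=truth["V_reservoir"],
                           V_aliquot=truth["V_aliquot"])
    return series, truth


def gen_absorption_course(spec: SimSpec) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Synthetic two-compartment uptake course.

    ``Ct(t) = (C0/2) * (1 - exp(-2*A*P*t/V))`` with multiplicative noise,
    truncated into ``[0, C0/2)``.  Times are in seconds.  Returns
    ``(t, Ct, truth)``.
    """
    if spec.model != "absorption_course":
        raise ValidationError("spec.model must be 'absorption_course'")
    truth = spec.resolved_truth()
    t = (np.linspace(3600.0, 86400.0, 24) if spec.grid is None else spec.grid)
    half = truth["C0"] / 2.0
    Ct = half * (1.0 - np.exp(-2.0 * truth["A"] * truth["P"] * t / truth["V"]))
    Ct = Ct * _noise(_rng(spec), len(t), spec.noise_cv)
    Ct = np.clip(Ct, 0.0, np.nextafter(half, 0.0))
    truth["seed"] = spec.seed
    return t, Ct, truth


def gen_profile(spec: SimSpec) -> tuple[RadialProfile, dict[str, Any]]:
    """Jittered needle radius profile: ``shape_profile`` sampled and
    radius-perturbed by seeded Gaussian jitter (um), clipped at 0."""
    if spec.model != "needle_profile":
        raise ValidationError("spec.model must be 'needle_profile'")
    truth = spec.resolved_truth()
    shape = truth["shape"]
    if not isinstance(shape, ShapeParams):
        shape = ShapeParams(**shape)
    jitter = float(truth.get("jitter_um", 0.0))
    if jitter < 0:
        raise ValidationError("jitter_um must be nonnegative")
    n = int(truth.get("n_samples", 901))
    profile = shape_profile(shape, n)
    if jitter > 0:
        r = profile.r + _rng(spec).normal(0.0, jitter, size=len(profile.r))
        profile = RadialProfile(x=profile.x, r=np.maximum(r, 0.0), label=profile.label)
    truth["seed"] = spec.seed
    return profile, truth
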