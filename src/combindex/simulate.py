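"""Synthetic dose-effect data with the statistical structure the analysis assumes.

Single agents follow the median-effect model exactly: on the transformed
scale y = log10(fa/fu) the truth is the straight line m*log10(D/Dm), and
Gaussian noise of standard deviation ``noise_sd`` is added on that scale.
Transformed-scale noise keeps generated fractions strictly inside (0, 1)
and matches the scale on which the fit is linear; a raw-fa mode
(clipped Gaussian on fa itself) is available for robustness testing.

Fixed-ratio mixtures are generated from a *target combination index*: at
each total dose the noiseless effect level fa solves

    d1 / Dx1(fa) + d2 / Dx2(fa) = true_ci

by bracketing root-finding (the left side is strictly decreasing in fa).
true_ci = 1 produces an exactly Loewe-additive mixture — the null against
which the CI pipeline is validated; other values plant a known constant
synergism (CI < 1) or antagonism (CI > 1).

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` instance; no global state.
"""

from __future__ import annotations

from typing import Callable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq

from .assay import KineticTrace
from .median_effect import DoseEffectSeries, MedianEffectResults

__all__ = [
    "GeneratorSpec",
    "ComboGeneratorSpec",
    "generate_single",
    "generate_combination",
    "simulate_kinetic_trace",
]

_FA_EPS = 1e-9  # root-search bracket for fa


class GeneratorSpec(BaseModel):
    """Recipe for a synthetic single-agent dose-effect series.

    Doses are given either explicitly (``doses``) or as a log- or
    linear-spaced range (``dose_min``, ``dose_max``, ``n_doses``,
    ``log_spaced``).  ``replicates`` independent noisy readings are drawn
    per dose (conventional triplicate by default).
    """

    model_config = ConfigDict(frozen=True)

    agent_id: str = "agent"
    dm: float = Field(gt=0, description="true median-effect dose, mg/mL")
    m: float = Field(gt=0, description="true sigmoidicity coefficient")
    doses: tuple[float, ...] | None = None
    dose_min: float | None = None
    dose_max: float | None = None
    n_doses: int = 10
    log_spaced: bool = True
    noise_sd: float = Field(default=0.0, ge=0,
                            description="Gaussian sd on the log10(fa/fu) scale")
    noise_scale: Literal["transformed", "raw"] = "transformed"
    replicates: int = Field(default=3, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_doses(self) -> "GeneratorSpec":
        if self.doses is not None:
            if len(self.doses) == 0 or any(d <= 0 for d in self.doses):
                raise ValueError("explicit doses must be non-empty and > 0")
        else:
            if self.dose_min is None or self.dose_max is None:
                raise ValueError("give either doses or (dose_min, dose_max)")
            if not 0 < self.dose_min < self.dose_max:
                raise ValueError("need 0 < dose_min < dose_max")
        return self

    def dose_grid(self) -> np.ndarray:
        if self.doses is not None:
            return np.asarray(self.doses, dtype=float)
        if self.log_spaced:
            return np.geomspace(self.dose_min, self.dose_max, self.n_doses)
        return np.linspace(self.dose_min, self.dose_max, self.n_doses)


class ComboGeneratorSpec(BaseModel):
    """Recipe for a fixed-ratio mixture series with a known true CI.

    ``true_ci`` is imposed pointwise at every total dose (constant-CI
    alternative); pass a callable ``ci_of_dose`` for a dose-varying
    profile instead.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    agent_id: str = "mixture"
    dm1: float = Field(gt=0)
    m1: float = Field(gt=0)
    dm2: float = Field(gt=0)
    m2: float = Field(gt=0)
    ratio: float = Field(gt=0, lt=1, description="fraction of component 1 in total dose")
    true_ci: float = Field(default=1.0, gt=0)
    ci_of_dose: Callable[[float], float] | None = None
    total_doses: tuple[float, ...]
    noise_sd: float = Field(default=0.0, ge=0)
    replicates: int = Field(default=3, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ComboGeneratorSpec":
        if len(self.total_doses) == 0 or any(d <= 0 for d in self.total_doses):
            raise ValueError("total_doses must be non-empty and > 0")
        return self


def _fa_from_y(y: np.ndarray) -> np.ndarray:
    p = 10.0 ** y
    return p / (1.0 + p)


def generate_single(spec: GeneratorSpec) -> DoseEffectSeries:
    """Draw a noisy single-agent series from the median-effect model.

    noise_sd = 0 returns the exact median-effect curve; identical spec
    and seed give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    doses = np.repeat(spec.dose_grid(), spec.replicates)
    y_true = spec.m * np.log10(doses / spec.dm)
    if spec.noise_scale == "transformed":
        y = y_true + rng.normal(0.0, spec.noise_sd, size=doses.size)
        fa = _fa_from_y(y)
    else:  # raw-fa Gaussian, clipped just inside (0, 1)
        fa = _fa_from_y(y_true) + rng.normal(0.0, spec.noise_sd, size=doses.size)
        fa = np.clip(fa, _FA_EPS, 1.0 - _FA_EPS)
    return DoseEffectSeries(spec.agent_id, doses, fa)


def _loewe_fa(d1: float, d2: float, fit1_dm: float, fit1_m: float,
              fit2_dm: float, fit2_m: float, target_ci: float) -> float:
    """Solve d1/Dx1(fa) + d2/Dx2(fa) = target_ci for fa.

    The left side is strictly decreasing in fa (each Dx_i is strictly
    increasing), so a sign change over (eps, 1-eps) pins a unique root.
    """

    def g(fa: float) -> float:
        odds = fa / (1.0 - fa)
        dx1 = fit1_dm * odds ** (1.0 / fit1_m)
        dx2 = fit2_dm * odds ** (1.0 / fit2_m)
        return d1 / dx1 + d2 / dx2 - target_ci

    lo, hi = _FA_EPS, 1.0 - _FA_EPS
    g_lo, g_hi = g(lo), g(hi)
    if not (g_lo > 0 > g_hi):
        attainable = (g_hi + target_ci, g_lo + target_ci)
        raise ValueError(
            f"no effect level in ({lo:g}, {1 - _FA_EPS:g}) yields CI = {target_ci:g} "
            f"at total dose {d1 + d2:g} mg/mL; attainable CI range is "
            f"({attainable[0]:.3g}, {attainable[1]:.3g})")
    return brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)


def generate_combination(spec: ComboGeneratorSpec) -> DoseEffectSeries:
    """Draw a fixed-ratio mixture series with the specified true CI.

    Per total dose the noiseless fa satisfies the combination-index
    identity at ``true_ci`` (or ``ci_of_dose(total)``); noise is then
    applied on the transformed scale exactly as in
    :func:`generate_single`.
    """
    rng = np.random.default_rng(spec.seed)
    totals = np.repeat(np.asarray(spec.total_doses, dtype=float), spec.replicates)
    fa0 = np.empty_like(totals)
    for i, d in enumerate(totals):
        ci = spec.ci_of_dose(d) if spec.ci_of_dose is not None else spec.true_ci
        fa0[i] = _loewe_fa(spec.ratio * d, (1.0 - spec.ratio) * d,
                           spec.dm1, spec.m1, spec.dm2, spec.m2, ci)
    y = np.log10(fa0 / (1.0 - fa0)) + rng.normal(0.0, spec.noise_sd, size=totals.size)
    return DoseEffectSeries(spec.agent_id, totals, _fa_from_y(y))


def simulate_kinetic_trace(sample_id: str, od0: float, activity: float,
                           timepoints: Sequence[float] = (0.0, 5.0),
                           role: str = "sample") -> KineticTrace:
    """Linear-decay OD trace with a prescribed activity (OD/min).

    Convenience for exercising the assay stage; real traces curve as
    substrate depletes, which this helper deliberately ignores.
    """
    t = np.asarray(timepoints, dtype=float)
    od = np.maximum(od0 - activity * t, 0.0)
    return KineticTrace(sample_id, t, od, role)  # type: ignore[arg-type]
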