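"""Two-agent constant-ratio combination analysis: CI profiles and DRI tables.

A constant-ratio combination mixes two agents at a fixed dose ratio
(conventionally equal multiples of their IC50s) and titrates the total
dose.  The mixture is then fitted as a single entity with the
median-effect model, and at any effect level fa the combination index of
Chou-Talalay quantifies departure from Loewe additivity::

    CI(fa) = (D)_1 / (Dx)_1  +  (D)_2 / (Dx)_2

where (D)_i are the component doses inside the mixture achieving fa and
(Dx)_i the doses of each agent alone that would achieve the same fa.
CI < 1 is synergism, CI = 1 additive, CI > 1 antagonism; a tolerance band
(default 0.9-1.1) absorbs estimation noise.  The dose-reduction index
DRI_i = (Dx)_i / (D)_i is the fold dose sparing the combination affords
each agent (favorable when > 1), and CI = sum_i 1/DRI_i identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .median_effect import (
    DoseEffectSeries,
    MedianEffectModel,
    MedianEffectResults,
    compute_dx,
)

__all__ = [
    "ConstantRatioDesign",
    "CombinationModel",
    "CombinationResults",
    "CIProfile",
    "DRITable",
    "make_design",
    "fit_combination",
    "compute_ci",
    "compute_dri",
    "classify_ci",
    "dri_from_doses",
    "PAPER_MULTIPLIERS",
    "DEFAULT_CI_BANDS",
    "DEFAULT_DRI_LEVELS",
]

#: IC50 multiples of the standard published constant-ratio design
PAPER_MULTIPLIERS = (2.5, 2.0, 1.0, 0.5, 0.2)

#: (lower, upper) CI band for the additive call; outside -> synergism/antagonism
DEFAULT_CI_BANDS = (0.9, 1.1)

DEFAULT_DRI_LEVELS = (0.50, 0.75, 0.90, 0.95)


@dataclass(frozen=True)
class ConstantRatioDesign:
    """IC50-multiple dose grid for a two-agent constant-ratio combination.

    Component concentrations at each level are multiplier x IC50; the
    component ratio is therefore identical at every level.  Values are
    nominal (pre-mix); equal-volume mixing halves in-reaction
    concentrations, recorded in ``dilution_factor`` (the CI arithmetic is
    scale-equivariant, so the choice does not affect CI).
    """

    agent_ids: tuple[str, str]
    ic50s: tuple[float, float]
    multipliers: tuple[float, ...]
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.multipliers) == 0:
            raise ValueError("multipliers must be non-empty")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError(f"multipliers must be > 0, got {self.multipliers}")
        if any(x <= 0 for x in self.ic50s):
            raise ValueError(f"IC50s must be > 0, got {self.ic50s}")

    @property
    def ratio(self) -> float:
        """Fraction of component 1 in the total dose (constant across levels)."""
        return self.ic50s[0] / (self.ic50s[0] + self.ic50s[1])

    def levels(self) -> pd.DataFrame:
        """One row per multiplier: component concentrations and their total."""
        mult = np.asarray(self.multipliers)
        c1 = mult * self.ic50s[0] / self.dilution_factor
        c2 = mult * self.ic50s[1] / self.dilution_factor
        return pd.DataFrame({
            "multiplier": mult,
            self.agent_ids[0]: c1,
            self.agent_ids[1]: c2,
            "total": c1 + c2,
        })

    def to_table(self, decimals: int = 4) -> pd.DataFrame:
        """Wide report layout: rows = agents, columns = IC50 multiples."""
        lv = self.levels()
        out = pd.DataFrame(
            [lv[self.agent_ids[0]].to_numpy(), lv[self.agent_ids[1]].to_numpy()],
            index=list(self.agent_ids),
            columns=[f"{m:g} IC50" for m in self.multipliers],
        )
        return out.map(lambda v: _round_half_up(v, decimals))


def _round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, matching how report tables are printed.

    Goes through a decimal rendering so that products of decimal inputs
    (e.g. 2.5 * 0.9659 = 2.41475, stored in binary just under the half)
    round the way a hand calculation would.
    """
    from decimal import ROUND_HALF_UP, Decimal

    d = Decimal(f"{x:.{decimals + 6}f}")
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def make_design(ic50_1: float, ic50_2: float,
                multipliers: Sequence[float] = PAPER_MULTIPLIERS,
                agent_ids: tuple[str, str] = ("agent1", "agent2"),
                dilution_factor: float = 1.0) -> ConstantRatioDesign:
    """Build the constant-ratio design from two IC50s and IC50 multiples."""
    return ConstantRatioDesign(tuple(agent_ids), (float(ic50_1), float(ic50_2)),
                               tuple(float(m) for m in multipliers),
                               dilution_factor=dilution_factor)


def classify_ci(ci: float, bands: tuple[float, float] = DEFAULT_CI_BANDS,
                strict: bool = False) -> str:
    """Label a combination-index value.

    Default uses a tolerance band (additive when lower <= CI <= upper);
    ``strict=True`` applies the literal <1 / =1 / >1 trichotomy, which is
    only meaningful for noise-free values.
    """
    if not np.isfinite(ci) or ci <= 0:
        raise ValueError(f"CI must be a positive finite number, got {ci}")
    lo, hi = (1.0, 1.0) if strict else bands
    if ci < lo:
        return "synergism"
    if ci > hi:
        return "antagonism"
    return "additive"


class CombinationModel:
    """Fixed-ratio mixture fitted as a single entity.

    Parameters
    ----------
    series : DoseEffectSeries
        Effect data against *total* mixture dose.
    ratio : float in (0, 1)
        Fraction of component 1 in the total dose.  For a design mixing
        equal IC50 multiples this is ic50_1/(ic50_1 + ic50_2)
        (:attr:`ConstantRatioDesign.ratio`).
    """

    def __init__(self, series: DoseEffectSeries, ratio: float, **fit_kwargs) -> None:
        if not 0.0 < ratio < 1.0:
            raise ValueError(f"ratio must be in (0, 1), got {ratio}")
        self.series = series
        self.ratio = float(ratio)
        self._fit_kwargs = fit_kwargs

    @classmethod
    def from_design(cls, series: DoseEffectSeries, design: ConstantRatioDesign,
                    **fit_kwargs) -> "CombinationModel":
        return cls(series, design.ratio, **fit_kwargs)

    def fit(self) -> "CombinationResults":
        mix = MedianEffectModel.from_series(self.series, **self._fit_kwargs).fit()
        return CombinationResults(mixture=mix, ratio=self.ratio)


@dataclass(frozen=True)
class CombinationResults:
    """Mixture median-effect fit plus the constant component ratio.

    ``d_split(D)`` divides a total dose into component doses; at the
    mixture's own median effect the split of Dm gives the component doses
    reported alongside combination Dm values.
    """

    mixture: MedianEffectResults
    ratio: float

    @property
    def dm(self) -> float:
        return self.mixture.dm

    @property
    def dm_split(self) -> tuple[float, float]:
        """Component doses (D)_1, (D)_2 at the mixture's median effect."""
        return self.d_split(self.mixture.dm)

    def d_split(self, total_dose) -> tuple:
        d = np.asarray(total_dose, dtype=float)
        d1, d2 = self.ratio * d, (1.0 - self.ratio) * d
        if d.ndim == 0:
            return float(d1), float(d2)
        return d1, d2

    def ci_profile(self, fit1: MedianEffectResults, fit2: MedianEffectResults,
                   fa_grid: Sequence[float] | None = None, **kwargs) -> "CIProfile":
        return compute_ci(self, fit1, fit2, fa_grid, **kwargs)

    def dri_table(self, fit1: MedianEffectResults, fit2: MedianEffectResults,
                  levels: Sequence[float] = DEFAULT_DRI_LEVELS) -> "DRITable":
        return compute_dri(self, fit1, fit2, levels)

    def summary(self) -> str:
        d1, d2 = self.dm_split
        lines = [
            self.mixture.summary(),
            f"mixing ratio (component 1): {self.ratio:.4f}",
            f"component doses at mixture Dm: ({d1:.4f}, {d2:.4f}) mg/mL",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class CIProfile:
    """Combination index across an effect-level grid (Fa-CI curve data)."""

    table: pd.DataFrame = field(repr=False)
    agent_ids: tuple[str, str] = ("agent1", "agent2")

    @property
    def fa(self) -> np.ndarray:
        return self.table["fa"].to_numpy()

    @property
    def ci(self) -> np.ndarray:
        return self.table["CI"].to_numpy()

    def plot(self, ax=None):
        """Fa-CI plot with the CI = 1 additivity reference line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fa, self.ci, marker="", lw=1.5,
                label=" + ".join(self.agent_ids))
        ax.axhline(1.0, color="k", ls="--", lw=0.8, label="additive (CI = 1)")
        ax.set_xlabel("fraction affected (fa)")
        ax.set_ylabel("combination index (CI)")
        ax.legend()
        return ax

    def to_csv(self, path) -> None:
        self.table[["fa", "CI"]].to_csv(path, index=False)


@dataclass(frozen=True)
class DRITable:
    """Dose-reduction index per agent at selected effect levels."""

    table: pd.DataFrame = field(repr=False)
    agent_ids: tuple[str, str] = ("agent1", "agent2")

    def to_frame(self) -> pd.DataFrame:
        return self.table


def fit_combination(series: DoseEffectSeries, ratio: float,
                    **fit_kwargs) -> CombinationResults:
    """Fit a fixed-ratio mixture as a single entity (functional form)."""
    return CombinationModel(series, ratio, **fit_kwargs).fit()


def compute_ci(combo: CombinationResults, fit1: MedianEffectResults,
               fit2: MedianEffectResults, fa_grid: Sequence[float] | None = None,
               bands: tuple[float, float] = DEFAULT_CI_BANDS,
               strict: bool = False) -> CIProfile:
    """Combination index across ``fa_grid`` (default 0.01 ... 0.99, 99 points).

    At each fa: total mixture dose from the mixture fit, component doses
    by the constant ratio, single-agent equipotent doses from the
    single-agent fits, then CI = (D)_1/(Dx)_1 + (D)_2/(Dx)_2.
    """
    if fa_grid is None:
        fa_grid = np.linspace(0.01, 0.99, 99)
    fa = np.asarray(fa_grid, dtype=float)
    if fa.size == 0:
        raise ValueError("fa_grid must be non-empty")
    if np.any(fa <= 0) or np.any(fa >= 1):
        raise ValueError("fa_grid values must lie strictly in (0, 1)")

    total = compute_dx(combo.mixture, fa)
    d1, d2 = combo.d_split(total)
    dx1 = compute_dx(fit1, fa)
    dx2 = compute_dx(fit2, fa)
    ci = d1 / dx1 + d2 / dx2
    labels = [classify_ci(c, bands=bands, strict=strict) for c in np.atleast_1d(ci)]
    tbl = pd.DataFrame({
        "fa": fa, "total_dose": total, "D1": d1, "D2": d2,
        "Dx1": dx1, "Dx2": dx2, "CI": ci, "classification": labels,
    })
    return CIProfile(tbl, (fit1.agent_id, fit2.agent_id))


def dri_from_doses(dx_alone: float, d_in_combo: float) -> float:
    """Dose-reduction index from a single-agent dose and a component dose.

    Bypass mode for worked examples where the component doses are quoted
    directly (e.g. at the mixture's median effect) rather than derived
    from a mixture fit.
    """
    if dx_alone <= 0 or d_in_combo <= 0:
        raise ValueError("doses must be > 0")
    return dx_alone / d_in_combo


def compute_dri(combo: CombinationResults, fit1: MedianEffectResults,
                fit2: MedianEffectResults,
                levels: Sequence[float] = DEFAULT_DRI_LEVELS) -> DRITable:
    """DRI_i = (Dx)_i / (D)_i at each effect level, with favorability flags."""
    prof = compute_ci(combo, fit1, fit2, fa_grid=list(levels))
    t = prof.table
    dri1 = t["Dx1"].to_numpy() / t["D1"].to_numpy()
    dri2 = t["Dx2"].to_numpy() / t["D2"].to_numpy()
    tbl = pd.DataFrame({
        "fa": t["fa"],
        f"DRI_{fit1.agent_id}": dri1,
        f"favorable_{fit1.agent_id}": dri1 > 1.0,
        f"DRI_{fit2.agent_id}": dri2,
        f"favorable_{fit2.agent_id}": dri2 > 1.0,
    })
    return DRITable(tbl, (fit1.agent_id, fit2.agent_id))
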