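"""Median-effect model of Chou and Talalay, statsmodels-style.

The median-effect equation relates dose D to the fraction of the system
affected, fa (here: fractional enzyme inhibition)::

    fa / fu = (D / Dm) ** m,        fu = 1 - fa

where Dm is the median-effect dose (the IC50) and m the sigmoidicity
coefficient (a Hill-type slope).  Taking log10 of both sides linearises
the model — the "median-effect plot"::

    log10(fa/fu) = m * log10(D) - m * log10(Dm)

so (m, Dm) are estimated by ordinary least squares of y = log10(fa/fu) on
x = log10(D).  The Pearson correlation r of the transformed points is the
conventional goodness-of-fit statistic; r >= 0.95 is the usual
acceptability rule for in vitro dose-effect data.

Typical use::

    model = MedianEffectModel(doses, fa, agent_id="bromelain")
    res = model.fit()
    res.dm, res.m, res.r
    res.dx(0.9)          # dose for 90% inhibition
    res.predict_fa(0.5)  # inhibition at 0.5 mg/mL
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseEffectSeries",
    "MedianEffectModel",
    "MedianEffectResults",
    "UnusablePointsError",
    "fit_median_effect",
    "compute_dx",
    "predict_fa",
    "DEFAULT_USABILITY_BAND",
]

#: fa outside this open interval cannot be log-odds transformed with any
#: numerical headroom; such points are excluded from the regression
#: (CompuSyn-style treatment of 0%/100% observations).
DEFAULT_USABILITY_BAND = (0.005, 0.995)


class UnusablePointsError(ValueError):
    """Raised when fewer than two usable points remain for the regression."""

    def __init__(self, agent_id: str, excluded: list[tuple[int, float, float, str]]):
        self.excluded = excluded
        detail = "; ".join(
            f"point {i} (D={d:g}, fa={fa:g}): {why}" for i, d, fa, why in excluded)
        super().__init__(
            f"{agent_id!r}: fewer than 2 usable points for the median-effect fit. "
            f"Excluded -> {detail if detail else 'none'}")


@dataclass(frozen=True)
class DoseEffectSeries:
    """Paired doses and fractions affected for one agent or fixed-ratio mixture.

    Doses are strictly positive (mg/mL); for a mixture they are the
    *total* mixture dose.  fu is defined as 1 - fa.
    """

    agent_id: str
    doses: np.ndarray
    fa: np.ndarray

    def __init__(self, agent_id: str, doses: Sequence[float], fa: Sequence[float]) -> None:
        d = np.asarray(doses, dtype=float)
        f = np.asarray(fa, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError(f"{agent_id!r}: doses and fa must be equal-length 1-D arrays")
        if d.size == 0:
            raise ValueError(f"{agent_id!r}: empty series")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError(f"{agent_id!r}: all doses must be finite and > 0")
        if not np.all(np.isfinite(f)) or np.any(f < 0) or np.any(f > 1):
            raise ValueError(f"{agent_id!r}: fa must lie in [0, 1]")
        object.__setattr__(self, "agent_id", agent_id)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "fa", f)

    @property
    def fu(self) -> np.ndarray:
        return 1.0 - self.fa

    def __len__(self) -> int:
        return self.doses.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"agent_id": self.agent_id,
                             "dose_mg_per_ml": self.doses,
                             "fraction_affected": self.fa})


class MedianEffectModel:
    """Median-effect (mass-action) dose-effect model for one agent.

    Parameters
    ----------
    doses, fa : array-like
        Doses (mg/mL, > 0) and fractions affected in [0, 1].  Replicate
        points enter the regression individually; pass ``average=True``
        to pre-average fa per distinct dose instead.
    agent_id : str
    usability_band : (low, high)
        Open interval of fa retained for the fit; points outside are
        excluded (the log-odds transform diverges at 0 and 1).
    """

    def __init__(self, doses: Sequence[float], fa: Sequence[float],
                 agent_id: str = "agent",
                 usability_band: tuple[float, float] = DEFAULT_USABILITY_BAND,
                 average: bool = False) -> None:
        self.series = DoseEffectSeries(agent_id, doses, fa)
        lo, hi = usability_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid usability band {usability_band}")
        self.usability_band = (float(lo), float(hi))
        self.average = bool(average)

    @classmethod
    def from_series(cls, series: DoseEffectSeries, **kwargs) -> "MedianEffectModel":
        return cls(series.doses, series.fa, agent_id=series.agent_id, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, agent_id: str | None = None,
                       dose_col: str = "dose_mg_per_ml",
                       fa_col: str = "fraction_affected", **kwargs) -> "MedianEffectModel":
        if agent_id is not None and "agent_id" in df.columns:
            df = df[df["agent_id"] == agent_id]
        return cls(df[dose_col].to_numpy(), df[fa_col].to_numpy(),
                   agent_id=agent_id or "agent", **kwargs)

    def _usable(self) -> tuple[np.ndarray, np.ndarray, list[tuple[int, float, float, str]]]:
        d, f = self.series.doses, self.series.fa
        if self.average:
            frame = pd.DataFrame({"d": d, "f": f}).groupby("d", as_index=False).mean()
            d, f = frame["d"].to_numpy(), frame["f"].to_numpy()
        lo, hi = self.usability_band
        excluded = []
        keep = np.ones(d.size, dtype=bool)
        for i, fa_i in enumerate(f):
            if fa_i <= lo:
                keep[i] = False
                excluded.append((i, d[i], fa_i, f"fa <= {lo} (below usability band)"))
            elif fa_i >= hi:
                keep[i] = False
                excluded.append((i, d[i], fa_i, f"fa >= {hi} (above usability band)"))
        return d[keep], f[keep], excluded

    def fit(self) -> "MedianEffectResults":
        """OLS on the median-effect plot; returns a results object."""
        d, f, excluded = self._usable()
        if d.size < 2:
            raise UnusablePointsError(self.series.agent_id, excluded)
        if np.unique(d).size < 2:
            raise ValueError(
                f"{self.series.agent_id!r}: all usable doses identical "
                f"({d[0]:g} mg/mL); regression is degenerate")
        x = np.log10(d)
        y = np.log10(f / (1.0 - f))
        reg = stats.linregress(x, y)
        m = reg.slope
        dm = 10.0 ** (-reg.intercept / m)
        return MedianEffectResults(
            agent_id=self.series.agent_id, dm=float(dm), m=float(m),
            r=float(reg.rvalue), m_se=float(reg.stderr),
            intercept=float(reg.intercept), intercept_se=float(reg.intercept_stderr),
            n_used=int(d.size), excluded=tuple(excluded), model=self)


@dataclass(frozen=True)
class MedianEffectResults:
    """Fitted median-effect parameters with diagnostics.

    Attributes
    ----------
    dm : float
        Median-effect dose (IC50), mg/mL.
    m : float
        Sigmoidicity coefficient (slope of the median-effect plot).
    r : float
        Pearson correlation of the transformed points (signed).
    m_se : float
        Standard error of m.
    n_used : int
        Points retained by the usability filter.
    excluded : tuple
        (index, dose, fa, reason) for each excluded point.
    """

    agent_id: str
    dm: float
    m: float
    r: float
    m_se: float
    intercept: float
    intercept_se: float
    n_used: int
    excluded: tuple = ()
    model: MedianEffectModel | None = None

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError(f"{self.agent_id!r}: Dm must be > 0, got {self.dm}")
        if self.n_used < 2:
            raise ValueError(f"{self.agent_id!r}: n_used must be >= 2")

    @property
    def r_acceptable(self) -> bool:
        """Conventional QC rule: |r| of the linearised fit at least 0.95."""
        return self.r >= 0.95

    def dx(self, fa: float | np.ndarray) -> float | np.ndarray:
        """Dose producing effect level ``fa``: Dm * (fa/(1-fa))**(1/m)."""
        return compute_dx(self, fa)

    def predict_fa(self, dose: float | np.ndarray) -> float | np.ndarray:
        """Effect at ``dose``: 1 / (1 + (Dm/D)**m)."""
        return predict_fa(self, dose)

    def summary(self) -> str:
        lines = [
            "Median-Effect Model Results",
            "=" * 46,
            f"agent:            {self.agent_id}",
            f"n (used/total):   {self.n_used}/{self.n_used + len(self.excluded)}",
            f"Dm (mg/mL):       {self.dm:.4f}",
            f"m:                {self.m:.4f} +/- {self.m_se:.4f}",
            f"r:                {self.r:.4f}"
            + ("" if self.r_acceptable else "   [below 0.95 acceptability rule]"),
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"agent_id": self.agent_id, "Dm": self.dm, "m": self.m,
                "r": self.r, "m_se": self.m_se, "n_used": self.n_used,
                "r_acceptable": self.r_acceptable}


def fit_median_effect(series: DoseEffectSeries, **kwargs) -> MedianEffectResults:
    """Fit the median-effect model to a dose-effect series (functional form)."""
    return MedianEffectModel.from_series(series, **kwargs).fit()


def compute_dx(fit: MedianEffectResults, fa) -> float | np.ndarray:
    """Invert the median-effect equation: dose for effect level fa in (0, 1)."""
    fa_arr = np.asarray(fa, dtype=float)
    if np.any(fa_arr <= 0) or np.any(fa_arr >= 1):
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa}")
    if fit.m <= 0:
        raise ValueError(
            f"{fit.agent_id!r}: non-physical fit (m = {fit.m:g} <= 0); "
            "dose inversion undefined")
    out = fit.dm * (fa_arr / (1.0 - fa_arr)) ** (1.0 / fit.m)
    return float(out) if np.isscalar(fa) or out.ndim == 0 else out


def predict_fa(fit: MedianEffectResults, dose) -> float | np.ndarray:
    """Fraction affected at a dose; inverse of :func:`compute_dx`."""
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError(f"dose must be > 0, got {dose}")
    out = 1.0 / (1.0 + (fit.dm / d) ** fit.m)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out
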