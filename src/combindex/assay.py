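"""Colorimetric enzyme-inhibition kinetics: raw optical density to percent inhibition.

A phospholipase assay read on a plate reader yields, per well, optical
density (OD) over time.  Hydrolysis of the colorimetric substrate lowers
the OD, so enzyme activity is the rate of OD loss over the kinetic
window::

    activity = (OD(0) - OD(t)) / t        [OD units / min]

and inhibition of a sample is expressed relative to a negative control
(enzyme without inhibitor)::

    % inhibition = (activity_control - activity_sample) / activity_control * 100

Samples more active than the control produce negative inhibition
(apparent activation); this is retained and flagged rather than clamped,
so any downstream filtering is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticTrace",
    "ActivityRecord",
    "InhibitionRecord",
    "compute_activity",
    "compute_inhibition",
    "read_kinetics",
    "write_inhibition_table",
]

Role = Literal["sample", "negative_control", "blank"]

#: default tolerance (minutes) when matching a requested timepoint to a
#: jittered plate-reader timestamp
TIME_TOLERANCE_MIN = 0.25


@dataclass(frozen=True)
class KineticTrace:
    """Timestamped OD readings for one reaction well.

    Parameters
    ----------
    sample_id : str
        Opaque well/sample label.
    timepoints : sequence of float
        Reading times in minutes; strictly increasing, first entry 0.
    od : sequence of float
        Optical density at each timepoint (dimensionless, >= 0).
    role : {"sample", "negative_control", "blank"}
    """

    sample_id: str
    timepoints: tuple[float, ...]
    od: tuple[float, ...]
    role: Role = "sample"

    def __init__(self, sample_id: str, timepoints: Sequence[float],
                 od: Sequence[float], role: Role = "sample") -> None:
        t = tuple(float(x) for x in timepoints)
        y = tuple(float(x) for x in od)
        if len(t) < 2:
            raise ValueError(f"trace {sample_id!r}: need at least 2 timepoints, got {len(t)}")
        if len(t) != len(y):
            raise ValueError(
                f"trace {sample_id!r}: {len(t)} timepoints but {len(y)} OD readings")
        if t[0] != 0.0:
            raise ValueError(f"trace {sample_id!r}: first timepoint must be 0, got {t[0]}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"trace {sample_id!r}: timepoints must be strictly increasing")
        if not all(np.isfinite(y)) or any(v < 0 for v in y):
            raise ValueError(f"trace {sample_id!r}: OD readings must be finite and non-negative")
        if role not in ("sample", "negative_control", "blank"):
            raise ValueError(f"trace {sample_id!r}: unknown role {role!r}")
        object.__setattr__(self, "sample_id", sample_id)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "od", y)
        object.__setattr__(self, "role", role)

    def od_at(self, t: float, tolerance: float = TIME_TOLERANCE_MIN) -> float:
        """OD of the reading nearest to time ``t`` within ``tolerance`` minutes."""
        times = np.asarray(self.timepoints)
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > tolerance:
            raise ValueError(
                f"trace {self.sample_id!r}: no reading within {tolerance} min of "
                f"t={t} min (nearest is {times[i]} min)")
        return self.od[i]

    def subtract_blank(self, blank: "KineticTrace",
                       tolerance: float = TIME_TOLERANCE_MIN) -> "KineticTrace":
        """Pointwise blank subtraction; blank readings matched by time."""
        corrected = [max(o - blank.od_at(t, tolerance), 0.0)
                     for t, o in zip(self.timepoints, self.od)]
        return KineticTrace(self.sample_id, self.timepoints, corrected, self.role)


@dataclass(frozen=True)
class ActivityRecord:
    """Enzyme activity of one well in OD units per minute."""

    sample_id: str
    activity: float
    duration: float  # minutes of kinetic window used

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"{self.sample_id!r}: duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class InhibitionRecord:
    """Percent inhibition of one sample relative to its negative control."""

    sample_id: str
    dose: float  # mg/mL, final in-reaction concentration
    percent_inhibition: float
    fraction_affected: float = field(init=False)
    flag: str = ""  # "" if valid; "activation" when inhibition < 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction_affected", self.percent_inhibition / 100.0)


def compute_activity(trace: KineticTrace, duration: float,
                     blank: KineticTrace | None = None,
                     tolerance: float = TIME_TOLERANCE_MIN) -> ActivityRecord:
    """Enzyme activity from a kinetic trace over a window of ``duration`` minutes.

    activity = (OD at t=0  -  OD at t=duration) / duration.

    ``duration`` has no default because published protocols use both 5 and
    15 minute windows; the caller must state which applies.  Readings are
    matched to the requested times within ``tolerance`` minutes.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0 min, got {duration}")
    if blank is not None:
        trace = trace.subtract_blank(blank, tolerance)
    od0 = trace.od_at(0.0, tolerance)
    odt = trace.od_at(duration, tolerance)
    return ActivityRecord(trace.sample_id, (od0 - odt) / duration, duration)


def compute_inhibition(sample: ActivityRecord, control: ActivityRecord,
                       dose: float) -> InhibitionRecord:
    """Percent inhibition of ``sample`` relative to the negative ``control``.

    Negative values (sample more active than control) are kept and flagged
    ``"activation"``.
    """
    if control.activity == 0:
        raise ValueError(
            f"control {control.sample_id!r} has zero activity; inhibition undefined")
    pct = (control.activity - sample.activity) / control.activity * 100.0
    rec = InhibitionRecord(sample.sample_id, dose, pct)
    if pct < 0:
        object.__setattr__(rec, "flag", "activation")
    return rec


def read_kinetics(path) -> dict[str, KineticTrace]:
    """Read long-format kinetics (columns sample_id, role, time_min, od).

    Comma or tab delimiter is autodetected.  Returns traces keyed by
    sample_id.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "role", "time_min", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    traces: dict[str, KineticTrace] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_min")
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"{path}: sample {sid!r} has conflicting roles {list(roles)}")
        traces[str(sid)] = KineticTrace(str(sid), grp["time_min"].tolist(),
                                        grp["od"].tolist(), roles[0])
    return traces


def write_inhibition_table(records: Sequence[InhibitionRecord], path) -> None:
    """Write inhibition records as CSV."""
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "dose_mg_per_ml": [r.dose for r in records],
            "percent_inhibition": [r.percent_inhibition for r in records],
            "fraction_affected": [r.fraction_affected for r in records],
            "flag": [r.flag for r in records],
        }
    ).to_csv(path, index=False)
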