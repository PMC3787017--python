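"""Ex vivo transporter occupancy from radioligand-binding initial rates.

Occupancy of NET or SERT by an administered drug slows the initial rate of
radioligand binding ([3H]-nisoxetine for NET, [3H]-citalopram for SERT) in
cortical homogenates. Each animal contributes a short binding time course
(0-3 min); the initial rate v_i is the ordinary least-squares slope (free
intercept: nonzero t=0 background is plausible). Percent occupancy for a
treated animal is the fractional rate suppression relative to the mean rate
of vehicle animals:

    occupancy% = 100 * (1 - v_i / mean(v_vehicle))

0% when the rate matches vehicle, 100% at complete blockade. Negative
values from noise are retained, never clipped. A historically printed form
of this expression, 100 * (1 - v_i) / mean(v_vehicle), is dimensionally
inconsistent (it subtracts a rate from a pure number) and is available only
behind ``literal=True`` for archival fidelity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindingTimeCourse",
    "OccupancyRecord",
    "initial_rate",
    "occupancy_percent",
    "summarize_occupancy",
    "occupancy_table",
]

TRANSPORTERS = ("NET", "SERT")


@dataclass(frozen=True)
class BindingTimeCourse:
    """One animal's radioligand binding time course for one transporter."""

    animal_id: str
    arm: str
    transporter: str  # NET | SERT
    points: tuple[tuple[float, float], ...]  # (time min, bound signal a.u.)
    session: str = "s1"

    def __post_init__(self) -> None:
        if self.transporter not in TRANSPORTERS:
            raise ValueError(f"transporter must be one of {TRANSPORTERS}")
        if len(self.points) < 2:
            raise ValueError(f"{self.animal_id}: need >= 2 time points")
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.animal_id}: times must be strictly increasing")
        if any(t < 0 or t > 3.0 for t in times):
            raise ValueError(f"{self.animal_id}: times must lie in [0, 3] min")
        if any(s < 0 for _, s in self.points):
            raise ValueError(f"{self.animal_id}: signals must be >= 0")


@dataclass(frozen=True)
class OccupancyRecord:
    """Per-animal initial rate and vehicle-normalised percent occupancy."""

    animal_id: str
    transporter: str
    v_i: float  # signal/min, >= 0
    occupancy_pct: float  # <= 100; may be negative from noise
    arm: str = ""
    session: str = "s1"

    def __post_init__(self) -> None:
        if self.v_i < 0:
            raise ValueError("initial rate must be >= 0")
        if self.occupancy_pct > 100.0 + 1e-9:
            raise ValueError("occupancy cannot exceed 100%")


def initial_rate(tc: BindingTimeCourse) -> float:
    """OLS slope (signal/min) of the binding time course, intercept free.

    Negative slopes are floored at 0 with a warning (binding cannot run
    backwards; a negative estimate is noise).
    """
    t = np.array([p[0] for p in tc.points], dtype=float)
    s = np.array([p[1] for p in tc.points], dtype=float)
    slope = float(np.polyfit(t, s, 1)[0])
    if -1e-9 * max(1.0, float(s.max())) < slope < 0:
        return 0.0  # rounding noise from an exactly flat course
    if slope < 0:
        warnings.warn(
            f"negative binding slope {slope:.4g} for animal {tc.animal_id}; floored at 0",
            stacklevel=2,
        )
        slope = 0.0
    return slope


def occupancy_percent(
    v_i: float, vehicle_rates: Sequence[float], literal: bool = False
) -> float:
    """Percent transporter occupancy from an initial rate and vehicle rates.

    Default: 100 * (1 - v_i / mean(vehicle_rates)). With ``literal=True``
    the dimensionally inconsistent archival form 100 * (1 - v_i) / mean is
    evaluated instead (not recommended for analysis).
    """
    rates = np.asarray(list(vehicle_rates), dtype=float)
    if rates.size == 0:
        raise ValueError("vehicle_rates must be non-empty")
    ref = float(rates.mean())
    if ref <= 0:
        raise ValueError(f"mean vehicle rate must be > 0, got {ref!r}")
    if v_i < 0:
        raise ValueError("initial rate must be >= 0")
    if literal:
        return 100.0 * (1.0 - v_i) / ref
    return 100.0 * (1.0 - v_i / ref)


def summarize_occupancy(
    records: Sequence[OccupancyRecord], arm: str, transporter: str
) -> tuple[float, Optional[float], int]:
    """Mean, SEM and n of percent occupancy for one (arm, transporter) group.

    SEM is None for a single animal.
    """
    vals = np.array(
        [r.occupancy_pct for r in records if r.arm == arm and r.transporter == transporter],
        dtype=float,
    )
    if vals.size == 0:
        raise ValueError(f"no occupancy records for arm {arm!r}, transporter {transporter!r}")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
    return mean, sem, int(vals.size)


def occupancy_table(
    courses: Sequence[BindingTimeCourse],
    vehicle_arm: str = "vehicle",
    per_session: bool = True,
    literal: bool = False,
) -> list[OccupancyRecord]:
    """Per-animal occupancy for a set of binding time courses.

    Vehicle normalisation is per (session, transporter) by default,
    mirroring concurrent-vehicle behavioural normalisation; with
    ``per_session=False`` vehicle rates are pooled across sessions.
    """
    rows = [
        {
            "session": tc.session,
            "animal_id": tc.animal_id,
            "arm": tc.arm,
            "transporter": tc.transporter,
            "v_i": initial_rate(tc),
        }
        for tc in courses
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no binding time courses supplied")
    keys = ["session", "transporter"] if per_session else ["transporter"]
    veh = df[df["arm"] == vehicle_arm]
    if veh.empty:
        raise ValueError(f"no vehicle arm {vehicle_arm!r} among time courses")
    veh_rates = veh.groupby(keys)["v_i"].agg(list)
    records = []
    for _, row in df.iterrows():
        key = tuple(row[k] for k in keys) if len(keys) > 1 else row[keys[0]]
        try:
            rates = veh_rates.loc[key]
        except KeyError:
            raise ValueError(
                f"no concurrent vehicle rates for session {row['session']!r}, "
                f"transporter {row['transporter']!r}"
            ) from None
        records.append(
            OccupancyRecord(
                animal_id=row["animal_id"],
                transporter=row["transporter"],
                v_i=row["v_i"],
                occupancy_pct=occupancy_percent(row["v_i"], rates, literal=literal),
                arm=row["arm"],
                session=row["session"],
            )
        )
    return records
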