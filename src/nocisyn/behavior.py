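"""Formalin-test flinch data: phase-2A totals, percent inhibition, summaries.

The formalin test produces a biphasic flinching response; antinociception is
quantified on the second-phase "phase 2A" window, 15-40 min post-formalin.
Per-animal flinch counts arrive time-binned; the phase-2A total sums bins
over a half-open window [15, 40) with proportional apportionment of bins
that straddle a window edge. Percent inhibition normalises each treated
animal's total to the mean total of the concurrently run vehicle group:

    pct = 100 * (vehicle_mean - treatment) / vehicle_mean

Negative values (flinching above vehicle) are retained, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlinchRecord",
    "FlinchDataset",
    "GroupSummary",
    "PHASE2A_WINDOW",
    "phase2a_total",
    "percent_inhibition",
    "summarize_arm",
    "inhibition_table",
]

#: Phase-2A scoring window, minutes post-formalin, half-open [start, end).
PHASE2A_WINDOW = (15.0, 40.0)


@dataclass(frozen=True)
class FlinchRecord:
    """One time bin of automated flinch counts for one animal."""

    animal_id: str
    arm: str
    drug_doses: Mapping[str, float]  # drug name -> mg/kg (empty for vehicle)
    bin_start: float  # min post-formalin
    bin_end: float
    flinches: int
    session: str = "s1"  # batch key; vehicle normalisation is per session

    def __post_init__(self) -> None:
        if not (self.bin_start < self.bin_end):
            raise ValueError(
                f"{self.animal_id}: bin_start {self.bin_start} must be < bin_end {self.bin_end}"
            )
        if self.flinches < 0 or int(self.flinches) != self.flinches:
            raise ValueError(
                f"{self.animal_id}: flinches must be a non-negative integer, got {self.flinches!r}"
            )
        for drug, dose in self.drug_doses.items():
            if dose < 0:
                raise ValueError(f"{self.animal_id}: negative dose {dose} for {drug}")

    @property
    def total_dose(self) -> float:
        """Total administered dose, mg/kg (sum over mixture components)."""
        return float(sum(self.drug_doses.values()))


@dataclass
class FlinchDataset:
    """Collection of per-animal, time-binned flinch records."""

    records: list[FlinchRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_animal: dict[tuple[str, str], list[FlinchRecord]] = {}
        for r in self.records:
            by_animal.setdefault((r.session, r.animal_id), []).append(r)
        for (session, animal), recs in by_animal.items():
            recs = sorted(recs, key=lambda r: r.bin_start)
            for a, b in zip(recs, recs[1:]):
                if b.bin_start < a.bin_end:
                    raise ValueError(
                        f"overlapping bins for animal {animal} (session {session}): "
                        f"[{a.bin_start}, {a.bin_end}) and [{b.bin_start}, {b.bin_end})"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def arms(self) -> list[str]:
        return sorted({r.arm for r in self.records})

    def animal_records(self, session: str, animal_id: str) -> list[FlinchRecord]:
        return [
            r for r in self.records if r.session == session and r.animal_id == animal_id
        ]

    def animals(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for r in self.records:
            seen.setdefault((r.session, r.animal_id))
        return list(seen)

    def extend(self, other: "FlinchDataset") -> "FlinchDataset":
        return FlinchDataset(records=self.records + other.records)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM of per-animal percent inhibition for one treatment arm."""

    arm: str
    n: int
    mean_pct_inhibition: float
    sem_pct_inhibition: Optional[float]  # absent (None) when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sem_pct_inhibition is not None and self.sem_pct_inhibition < 0:
            raise ValueError("SEM must be >= 0")


def phase2a_total(
    animal_records: Iterable[FlinchRecord],
    window_start: float = PHASE2A_WINDOW[0],
    window_end: float = PHASE2A_WINDOW[1],
) -> float:
    """Total flinches over [window_start, window_end) for one animal.

    Bins partially overlapping the window contribute proportionally to the
    overlapped fraction of their width (the automated counter bins finely,
    so apportionment matters mainly for coarse synthetic bins).
    """
    if not (window_start < window_end):
        raise ValueError("window_start must be < window_end")
    total = 0.0
    any_overlap = False
    for r in animal_records:
        lo = max(r.bin_start, window_start)
        hi = min(r.bin_end, window_end)
        if hi > lo:
            any_overlap = True
            total += r.flinches * (hi - lo) / (r.bin_end - r.bin_start)
    if not any_overlap:
        raise ValueError(
            f"no flinch bins intersect window [{window_start}, {window_end})"
        )
    return total


def percent_inhibition(treatment_total: float, vehicle_mean: float) -> float:
    """Vehicle-normalised percent inhibition of flinching.

    May be negative (flinching above vehicle level); not clipped.
    """
    if vehicle_mean <= 0:
        raise ValueError(f"vehicle mean must be > 0, got {vehicle_mean!r}")
    if treatment_total < 0:
        raise ValueError("treatment total must be >= 0")
    return 100.0 * (vehicle_mean - treatment_total) / vehicle_mean


def summarize_arm(per_animal_pct: Sequence[float], arm: str = "") -> GroupSummary:
    """Mean and SEM (sample SD / sqrt(n)) of per-animal percent inhibition."""
    vals = np.asarray(list(per_animal_pct), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarise an empty group")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
    return GroupSummary(arm=arm, n=int(vals.size), mean_pct_inhibition=mean,
                        sem_pct_inhibition=sem)


def inhibition_table(
    ds: FlinchDataset,
    window: tuple[float, float] = PHASE2A_WINDOW,
    vehicle_arm: str = "vehicle",
) -> pd.DataFrame:
    """Per-animal phase-2A totals and percent inhibition for a whole dataset.

    Each animal is normalised to the mean phase-2A total of the vehicle arm
    run in the *same session* (concurrent controls). Returns a DataFrame with
    columns session, animal_id, arm, drug_doses, total_dose, phase2a,
    pct_inhibition.
    """
    rows = []
    for session, animal in ds.animals():
        recs = ds.animal_records(session, animal)
        rows.append(
            {
                "session": session,
                "animal_id": animal,
                "arm": recs[0].arm,
                "drug_doses": dict(recs[0].drug_doses),
                "total_dose": recs[0].total_dose,
                "phase2a": phase2a_total(recs, *window),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("empty dataset")
    veh = df[df["arm"] == vehicle_arm]
    if veh.empty:
        raise ValueError(f"no vehicle arm {vehicle_arm!r} in dataset")
    veh_mean = veh.groupby("session")["phase2a"].mean()
    missing = set(df["session"]) - set(veh_mean.index)
    if missing:
        raise ValueError(f"sessions without concurrent vehicle animals: {sorted(missing)}")
    ref = df["session"].map(veh_mean)
    if (ref <= 0).any():
        raise ValueError("vehicle mean phase-2A total must be > 0")
    df["pct_inhibition"] = 100.0 * (ref - df["phase2a"]) / ref
    return df
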