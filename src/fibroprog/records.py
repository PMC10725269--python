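"""Patient observation records and the long-format CSV interface.

Each patient contributes an ordered sequence of observations: staged
biopsies (``STAGE``), blood-only visits where the patient declined a biopsy
but is known alive (``ALIVE_UNSTAGED``), and at most one terminal death
record at its registry date (``DEATH``).  Times are years since the first
biopsy; the first observation is always a staged biopsy, which initializes
the Markov chain.

The CSV layout is one row per observation with columns
``ID, TIME, OBS_KIND, STATE, STEATOSIS, T2D, AGE_BL`` (comma-separated,
UTF-8, '.' decimal, empty string for missing values).

Steatosis-change covariate (DSTEA)
----------------------------------
The forward rates depend on the change in steatosis grade between visits.
Two per-interval conventions are implemented:

``carry_forward`` (default)
    The interval starting at visit *j* uses the most recent observed
    grade change at or before *j* (zero until two grades have been seen).
    The covariate is then known at the start of each interval, which makes
    the fitted model a coherent generative process -- in particular the
    rates in force before a death do not depend on an observation that was
    never made.

``interval_change``
    Grade at the interval's end minus the last grade observed at or before
    its start; zero when either endpoint grade is missing (refused biopsy,
    death, or the degenerate first interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .states import DiseaseState

CSV_COLUMNS = ["ID", "TIME", "OBS_KIND", "STATE", "STEATOSIS", "T2D", "AGE_BL"]

DSTEA_CONVENTIONS = ("carry_forward", "interval_change")


class ObsKind(str, Enum):
    STAGE = "STAGE"
    ALIVE_UNSTAGED = "ALIVE_UNSTAGED"
    DEATH = "DEATH"


@dataclass(frozen=True)
class Observation:
    time: float
    kind: ObsKind
    state: int | None = None
    steatosis: int | None = None

    def __post_init__(self) -> None:
        if self.kind is ObsKind.STAGE:
            if self.state is None or not 0 <= int(self.state) <= 5:
                raise ValueError(
                    f"STAGE observation needs a state in F0..DC, got {self.state!r}"
                )
        elif self.state is not None:
            raise ValueError(f"{self.kind.value} observation must not carry a state")
        if self.steatosis is not None and not 0 <= int(self.steatosis) <= 3:
            raise ValueError(f"steatosis grade must be 0..3, got {self.steatosis!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One subject's observation sequence plus baseline covariates."""

    id: str
    observations: tuple[Observation, ...]
    t2d: bool
    age_at_first_biopsy: float

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if not obs:
            raise ValueError(f"patient {self.id}: empty observation sequence")
        if obs[0].kind is not ObsKind.STAGE:
            raise ValueError(
                f"patient {self.id}: first observation must be a staged biopsy"
            )
        times = [o.time for o in obs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"patient {self.id}: times must be strictly increasing")
        deaths = [i for i, o in enumerate(obs) if o.kind is ObsKind.DEATH]
        if deaths and (len(deaths) > 1 or deaths[0] != len(obs) - 1):
            raise ValueError(f"patient {self.id}: DEATH must be the single last record")
        if self.age_at_first_biopsy < 0:
            raise ValueError(f"patient {self.id}: negative baseline age")

    @property
    def died(self) -> bool:
        return self.observations[-1].kind is ObsKind.DEATH

    @property
    def n_intervals(self) -> int:
        return len(self.observations) - 1


@dataclass(frozen=True)
class Interval:
    """One observation interval with the covariates in force over it."""

    t_start: float
    t_end: float
    dstea: float
    t2d: bool
    age_start: float
    end_kind: ObsKind
    end_state: int | None = None

    @property
    def dt(self) -> float:
        return self.t_end - self.t_start


def derive_intervals(
    record: PatientRecord, dstea_convention: str = "carry_forward"
) -> list[Interval]:
    """Split a record into observation intervals with per-interval covariates."""
    if dstea_convention not in DSTEA_CONVENTIONS:
        raise ValueError(
            f"unknown dstea convention {dstea_convention!r}; "
            f"expected one of {DSTEA_CONVENTIONS}"
        )
    grades: list[tuple[float, int]] = []  # (time, grade) of observed steatosis
    intervals: list[Interval] = []
    for a, b in zip(record.observations, record.observations[1:]):
        if a.steatosis is not None:
            grades.append((a.time, int(a.steatosis)))
        if dstea_convention == "carry_forward":
            dstea = float(grades[-1][1] - grades[-2][1]) if len(grades) >= 2 else 0.0
        else:
            if b.steatosis is not None and grades:
                dstea = float(int(b.steatosis) - grades[-1][1])
            else:
                dstea = 0.0
        intervals.append(
            Interval(
                t_start=a.time,
                t_end=b.time,
                dstea=dstea,
                t2d=record.t2d,
                age_start=record.age_at_first_biopsy + a.time,
                end_kind=b.kind,
                end_state=None if b.state is None else int(b.state),
            )
        )
    return intervals


def _opt_int(value: object) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(float(value))


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a long-format cohort CSV into validated patient records."""
    df = pd.read_csv(path, dtype={"ID": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[PatientRecord] = []
    for pid, grp in df.groupby("ID", sort=False):
        grp = grp.sort_values("TIME", kind="stable")
        t2d_vals = grp["T2D"].astype(float).unique()
        age_vals = grp["AGE_BL"].astype(float).unique()
        if len(t2d_vals) != 1 or len(age_vals) != 1:
            raise ValueError(f"patient {pid}: T2D and AGE_BL must be constant")
        obs = []
        for row_no, row in enumerate(grp.itertuples(index=False)):
            try:
                kind = ObsKind(row.OBS_KIND)
            except ValueError:
                raise ValueError(
                    f"patient {pid}, row {row_no}: unknown OBS_KIND {row.OBS_KIND!r}"
                ) from None
            obs.append(
                Observation(
                    time=float(row.TIME),
                    kind=kind,
                    state=_opt_int(row.STATE),
                    steatosis=_opt_int(row.STEATOSIS),
                )
            )
        records.append(
            PatientRecord(
                id=str(pid),
                observations=tuple(obs),
                t2d=bool(t2d_vals[0]),
                age_at_first_biopsy=float(age_vals[0]),
            )
        )
    if not records:
        raise ValueError(f"{path}: no patient records found")
    return records


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Write patient records to the long-format CSV layout."""
    rows = []
    for rec in records:
        for o in rec.observations:
            rows.append(
                {
                    "ID": rec.id,
                    "TIME": repr(float(o.time)),
                    "OBS_KIND": o.kind.value,
                    "STATE": "" if o.state is None else int(o.state),
                    "STEATOSIS": "" if o.steatosis is None else int(o.steatosis),
                    "T2D": int(rec.t2d),
                    "AGE_BL": repr(float(rec.age_at_first_biopsy)),
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def observed_state(value: int) -> DiseaseState:
    return DiseaseState(int(value))
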