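"""Cohort containers for excess-hazard profile regression.

One row per subject: a censored survival outcome on the age scale (in
days), delayed entry at the age of hire, three cumulative radiological
exposures, age at first exposure, and three categorical work-history
covariates.  Subjects with all three exposures equal to zero form the
*reference* group: they are never part of the exposure mixture and carry
excess risk beta = 0 by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

#: Age cutpoints of the piecewise-constant baseline hazard, in years.
CUTPOINTS_YEARS = (40.0, 55.0, 70.0)
CUTPOINTS_DAYS = tuple(c * DAYS_PER_YEAR for c in CUTPOINTS_YEARS)
N_INTERVALS = 4

JOB_LEVELS = (1, 2, 3, 4, 5)
MINE_LEVELS = (1, 2)  # 1 = Herault (sedimentary deposit), 2 = other districts
DURATION_LEVELS = (1, 2, 3, 4)  # <=5, 6-12, 13-18, >=19 years exposed

COHORT_COLUMNS = [
    "y",
    "delta",
    "entry_age",
    "x_radon",
    "x_gamma",
    "x_dust",
    "age_first_exposure",
    "job",
    "mine",
    "duration_class",
]


@dataclass
class MinerRecord:
    """A single subject.

    Parameters
    ----------
    y : float
        Exit age in days: age at death by lung cancer if ``delta == 1``,
        otherwise the right-censoring age.
    delta : int
        Event indicator (1 = death by lung cancer).
    entry_age : float
        Age in days at entry into follow-up (delayed entry).
    x_radon, x_gamma, x_dust : float
        Cumulative exposures (WLM, mSv, kBq.m-3.h); all three zero marks
        a reference (unexposed) subject.
    age_first_exposure : float
        Age in years at first exposure; ignored for reference subjects.
    job : int
        Job type, 1-5.
    mine : int
        Mining district, 1 = Herault, 2 = other.
    duration_class : int
        Exposure-duration class, 1-4.
    """

    y: float
    delta: int
    entry_age: float
    x_radon: float
    x_gamma: float
    x_dust: float
    age_first_exposure: float
    job: int
    mine: int
    duration_class: int

    def __post_init__(self) -> None:
        if self.delta not in (0, 1):
            raise ValueError(f"delta must be 0 or 1, got {self.delta}")
        if not (self.y > self.entry_age >= 0):
            raise ValueError(
                f"need y > entry_age >= 0, got y={self.y}, entry_age={self.entry_age}"
            )
        for name in ("x_radon", "x_gamma", "x_dust"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.job not in JOB_LEVELS:
            raise ValueError(f"job must be in {JOB_LEVELS}, got {self.job}")
        if self.mine not in MINE_LEVELS:
            raise ValueError(f"mine must be in {MINE_LEVELS}, got {self.mine}")
        if self.duration_class not in DURATION_LEVELS:
            raise ValueError(
                f"duration_class must be in {DURATION_LEVELS}, got {self.duration_class}"
            )
        if self.is_exposed and self.age_first_exposure <= 0:
            raise ValueError("exposed subjects need age_first_exposure > 0")

    @property
    def is_exposed(self) -> bool:
        return (self.x_radon > 0) or (self.x_gamma > 0) or (self.x_dust > 0)

    @property
    def exposures(self) -> np.ndarray:
        return np.array([self.x_radon, self.x_gamma, self.x_dust])


class Cohort:
    """A table of :class:`MinerRecord` rows backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame, true_labels: np.ndarray | None = None):
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort frame is missing columns {missing}")
        self.frame = frame.reset_index(drop=True)
        self.true_labels = None if true_labels is None else np.asarray(true_labels)
        _validate_frame(self.frame)

    @classmethod
    def from_records(
        cls, records: Iterable[MinerRecord], true_labels: Sequence[int] | None = None
    ) -> "Cohort":
        names = [f.name for f in fields(MinerRecord)]
        frame = pd.DataFrame([{k: getattr(r, k) for k in names} for r in records])
        labels = None if true_labels is None else np.asarray(true_labels)
        return cls(frame, labels)

    def records(self) -> list[MinerRecord]:
        return [
            MinerRecord(**{k: row[k] for k in COHORT_COLUMNS})
            for _, row in self.frame.iterrows()
        ]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["delta"].sum())

    @property
    def exposed_mask(self) -> np.ndarray:
        f = self.frame
        return (
            (f["x_radon"].to_numpy() > 0)
            | (f["x_gamma"].to_numpy() > 0)
            | (f["x_dust"].to_numpy() > 0)
        )

    def summary(self) -> dict:
        f = self.frame
        exposed = self.exposed_mask
        return {
            "n": len(f),
            "events": self.n_events,
            "event_fraction": float(f["delta"].mean()),
            "exposed_fraction": float(exposed.mean()),
            "mean_entry_age_years": float(f["entry_age"].mean() / DAYS_PER_YEAR),
            "mean_exit_age_years": float(f["y"].mean() / DAYS_PER_YEAR),
        }


def _validate_frame(f: pd.DataFrame) -> None:
    def bad(mask: np.ndarray, msg: str) -> None:
        if mask.any():
            lines = np.flatnonzero(mask)[:5] + 2  # 1-based + header line
            raise ValueError(f"{msg} (first offending file lines: {lines.tolist()})")

    for col in COHORT_COLUMNS:
        if not np.issubdtype(f[col].to_numpy().dtype, np.number):
            raise ValueError(f"column {col} is not numeric")
    bad(~f["delta"].isin([0, 1]).to_numpy(), "delta must be 0 or 1")
    bad((f["y"] <= f["entry_age"]).to_numpy(), "need y > entry_age")
    bad((f["entry_age"] < 0).to_numpy(), "entry_age must be >= 0")
    for col in ("x_radon", "x_gamma", "x_dust"):
        bad((f[col] < 0).to_numpy(), f"{col} must be non-negative")
    bad(~f["job"].isin(JOB_LEVELS).to_numpy(), "job code out of range")
    bad(~f["mine"].isin(MINE_LEVELS).to_numpy(), "mine code out of range")
    bad(~f["duration_class"].isin(DURATION_LEVELS).to_numpy(), "duration_class out of range")
    exposed = (
        (f["x_radon"].to_numpy() > 0)
        | (f["x_gamma"].to_numpy() > 0)
        | (f["x_dust"].to_numpy() > 0)
    )
    bad(exposed & (f["age_first_exposure"].to_numpy() <= 0),
        "exposed subjects need age_first_exposure > 0")


def person_time_by_interval(entry: np.ndarray, exit: np.ndarray) -> np.ndarray:
    """Days spent in each baseline-hazard age interval, shape (n, 4)."""
    entry = np.atleast_1d(np.asarray(entry, dtype=float))
    exit = np.atleast_1d(np.asarray(exit, dtype=float))
    bounds = np.concatenate(([0.0], CUTPOINTS_DAYS, [np.inf]))
    lo = np.maximum(entry[:, None], bounds[:-1][None, :])
    hi = np.minimum(exit[:, None], bounds[1:][None, :])
    return np.clip(hi - lo, 0.0, None)


def interval_index(t: np.ndarray) -> np.ndarray:
    """Index (0-3) of the age interval containing age ``t`` (days).

    Intervals are half-open ``[lower, upper)``: an age exactly at a
    cutpoint belongs to the older interval.
    """
    return np.searchsorted(np.asarray(CUTPOINTS_DAYS), np.asarray(t), side="right")


class CohortArrays:
    """Pre-computed numpy views of a cohort used by likelihood kernels.

    Attributes
    ----------
    e : (n, 4) person-time in days within each baseline age interval.
    ev_int : (n,) index of the interval containing the exit age.
    exposed_idx : indices of mixture (exposed) subjects.
    logx : (m, 4) log of radon, gamma, dust exposure and age at first
        exposure (years) for exposed subjects.
    """

    def __init__(
        self,
        cohort: Cohort,
        zero_policy: str = "impute_half_min",
        delayed_entry: bool = True,
    ):
        if zero_policy not in ("impute_half_min", "to_reference"):
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        f = cohort.frame
        self.n = len(f)
        self.y = f["y"].to_numpy(dtype=float)
        self.entry = f["entry_age"].to_numpy(dtype=float)
        self.delta = f["delta"].to_numpy(dtype=float)
        start = self.entry if delayed_entry else np.zeros(self.n)
        self.e = person_time_by_interval(start, self.y)
        self.ev_int = interval_index(self.y)
        x = f[["x_radon", "x_gamma", "x_dust"]].to_numpy(dtype=float).copy()
        self.x_raw = x.copy()

        any_pos = (x > 0).any(axis=1)
        all_pos = (x > 0).all(axis=1)
        partial = any_pos & ~all_pos
        if zero_policy == "impute_half_min" and partial.any():
            for q in range(3):
                pos = x[:, q] > 0
                if pos.any():
                    fill = 0.5 * x[pos, q].min()
                    col = x[:, q]
                    col[partial & ~pos] = fill
            self.exposed = any_pos
        elif zero_policy == "to_reference":
            x[partial] = 0.0
            self.exposed = all_pos
        else:
            self.exposed = any_pos
        self.x = x
        self.exposed_idx = np.flatnonzero(self.exposed)
        self.m = self.exposed_idx.size
        sub = self.exposed_idx
        age_first = f["age_first_exposure"].to_numpy(dtype=float)[sub]
        with np.errstate(divide="ignore"):
            self.logx = np.log(
                np.column_stack([x[sub, 0], x[sub, 1], x[sub, 2], age_first])
            )
        self.job0 = f["job"].to_numpy(dtype=int)[sub] - 1
        self.mine0 = f["mine"].to_numpy(dtype=int)[sub] - 1
        self.dur0 = f["duration_class"].to_numpy(dtype=int)[sub] - 1
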