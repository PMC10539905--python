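"""Panel-cohort construction: decimal ages, death timing, validation.

The multistate likelihood needs, for every subject, an ordered list of
(decimal age, state) observations with deaths carrying an exact age.
Survey interviews are recorded to year+month only, so interview dates
are placed at mid-month (day 15) and decimal ages computed as
(interview - birthday) in days / 365.25.  Deaths whose exact date was
not recorded are interval-censored between the last wave the subject
was seen alive and the wave at which the death was reported; their
death time is imputed as the midpoint of those two times.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .staging import SarcopeniaState

__all__ = [
    "Observation",
    "PanelDataset",
    "ValidationReport",
    "compute_age",
    "impute_death_age",
    "impute_death_ages",
    "validate_panel",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
_MID_MONTH_DAY = 15

#: Column dictionary for panel tables (long format, one row per
#: subject-observation):
#:
#: ============  ==========================================================
#: subject_id    unique subject identifier
#: age           decimal age at observation, years
#: state         1 no sarcopenia, 2 possible, 3 sarcopenia, 4 dead
#: death_exact   0/1; for state=4 rows, whether the age is an exact death
#:               age (1) or the reporting-wave age awaiting midpoint
#:               imputation (0).  Ignored for live rows.
#: <covariates>  any further columns, constant within subject
#: ============  ==========================================================
PANEL_COLUMNS = ("subject_id", "age", "state")


class Observation(NamedTuple):
    """One subject-wave observation."""

    age: float
    state: int
    death_exact: bool = True


def _parse_year_month(value) -> tuple[int, int]:
    if isinstance(value, str):
        year, month = value.split("-")[:2]
        return int(year), int(month)
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return int(value[0]), int(value[1])
    if isinstance(value, (_dt.date, _dt.datetime)):
        return value.year, value.month
    raise ValueError(f"cannot interpret interview year-month: {value!r}")


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    if isinstance(value, str):
        return _dt.date.fromisoformat(value)
    raise ValueError(f"cannot interpret date: {value!r}")


def compute_age(interview_year_month, birth_date) -> float:
    """Decimal age at interview.

    The interview is recorded to year and month; its day is fixed at
    mid-month (15th), an unbiased within-month convention.  The age is
    the day count from the exact birthday divided by 365.25.
    """
    year, month = _parse_year_month(interview_year_month)
    birth = _parse_date(birth_date)
    interview = _dt.date(year, month, _MID_MONTH_DAY)
    if interview < birth:
        raise ValueError(
            f"interview {interview} precedes birth {birth}"
        )
    return (interview - birth).days / DAYS_PER_YEAR


def impute_death_age(
    last_alive_time: float,
    ascertainment_time: float,
    exact_death_time: float | None = None,
) -> float:
    """Death time on the decimal-age scale.

    When an exact death time is recorded it is returned unchanged;
    otherwise the death is interval-censored between the last wave the
    subject was seen alive and the wave reporting the death, and the
    midpoint of the two times is used.
    """
    if exact_death_time is not None:
        return float(exact_death_time)
    if not ascertainment_time > last_alive_time:
        raise ValueError(
            "ascertainment time must exceed the last-alive time "
            f"({ascertainment_time} <= {last_alive_time})"
        )
    return 0.5 * (last_alive_time + ascertainment_time)


@dataclass
class PanelDataset:
    """Long-format panel: one row per subject-observation.

    ``data`` must hold the ``PANEL_COLUMNS``; ``covariates`` names the
    columns treated as (time-constant) covariates.
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    n_states: int = 4
    dead_state: int = 4

    def __post_init__(self):
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        for c in self.covariates:
            if c not in self.data.columns:
                raise ValueError(f"covariate column {c!r} not in panel table")
        self.data = self.data.sort_values(
            ["subject_id", "age"], kind="stable"
        ).reset_index(drop=True)

    @property
    def live_states(self) -> list[int]:
        return [s for s in range(1, self.n_states + 1) if s != self.dead_state]

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @classmethod
    def from_csv(cls, path, covariates: Sequence[str] = ()) -> "PanelDataset":
        return cls(pd.read_csv(path), covariates=list(covariates))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def baseline(self) -> pd.DataFrame:
        """First observation of each subject."""
        return self.data.groupby("subject_id", sort=False).head(1)

    def intervals(self) -> pd.DataFrame:
        """Consecutive-observation intervals for the likelihood.

        Columns: subject_id, from_state, to_state, age0, dt, plus the
        covariate columns (taken from the interval's first record).
        """
        df = self.data
        grp = df.groupby("subject_id", sort=False)
        out = pd.DataFrame(
            {
                "subject_id": df["subject_id"],
                "from_state": df["state"],
                "age0": df["age"],
                "to_state": grp["state"].shift(-1),
                "age1": grp["age"].shift(-1),
            }
        )
        for c in self.covariates:
            out[c] = df[c]
        out = out.dropna(subset=["to_state"]).copy()
        out["to_state"] = out["to_state"].astype(int)
        out["dt"] = out["age1"] - out["age0"]
        return out.drop(columns=["age1"]).reset_index(drop=True)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`."""

    n_subjects_in: int
    n_subjects_retained: int
    n_records_in: int
    n_records_retained: int
    dropped_subjects: dict[str, int]
    panel: PanelDataset

    def __str__(self) -> str:  # pragma: no cover - display only
        lines = [
            f"subjects: {self.n_subjects_in} in, {self.n_subjects_retained} retained",
            f"records:  {self.n_records_in} in, {self.n_records_retained} retained",
        ]
        for reason, n in self.dropped_subjects.items():
            lines.append(f"  dropped ({reason}): {n}")
        return "\n".join(lines)


def impute_death_ages(df: pd.DataFrame, dead_state: int = 4) -> pd.DataFrame:
    """Resolve interval-censored death ages in a panel table.

    Rows with ``state == dead_state`` and ``death_exact == 0`` carry the
    reporting-wave age; they are replaced by the midpoint of the previous
    (last-alive) age and the reporting age, and flagged exact afterwards
    (the likelihood treats imputed deaths as exactly timed).
    """
    df = df.sort_values(["subject_id", "age"], kind="stable").reset_index(drop=True)
    if "death_exact" not in df.columns:
        df["death_exact"] = True
        return df
    df["death_exact"] = df["death_exact"].fillna(1).astype(bool)
    prev_age = df.groupby("subject_id", sort=False)["age"].shift(1)
    needs = (df["state"] == dead_state) & ~df["death_exact"] & prev_age.notna()
    df.loc[needs, "age"] = 0.5 * (prev_age[needs] + df.loc[needs, "age"])
    df.loc[needs, "death_exact"] = True
    n = int(needs.sum())
    if n:
        logger.info("imputed %d interval-censored death ages (midpoint)", n)
    return df


def validate_panel(panel: PanelDataset, drop: bool = True) -> ValidationReport:
    """Check panel invariants and (optionally) drop violating subjects.

    Enforced per subject: strictly increasing ages; at most one death
    record, and it is last; at least two observations or a death record
    (single-wave survivors carry no transition information).  Retained
    records are never altered.
    """
    df = panel.data
    if df.empty:
        raise ValueError("empty panel dataset")
    dead = panel.dead_state
    dropped: dict[str, set] = {
        "non-monotone ages": set(),
        "records after death": set(),
        "multiple death records": set(),
        "single observation, no death": set(),
    }
    for sid, g in df.groupby("subject_id", sort=False):
        ages = g["age"].to_numpy()
        states = g["state"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            dropped["non-monotone ages"].add(sid)
        dead_pos = np.flatnonzero(states == dead)
        if dead_pos.size > 1:
            dropped["multiple death records"].add(sid)
        if dead_pos.size >= 1 and dead_pos[0] != len(states) - 1:
            dropped["records after death"].add(sid)
        if len(states) < 2 and dead_pos.size == 0:
            dropped["single observation, no death"].add(sid)

    bad = set().union(*dropped.values())
    for reason, sids in dropped.items():
        if sids:
            logger.info("panel validation: %d subject(s) %s", len(sids), reason)
    out_df = df[~df["subject_id"].isin(bad)].copy() if drop else df
    out = PanelDataset(
        out_df,
        covariates=list(panel.covariates),
        n_states=panel.n_states,
        dead_state=panel.dead_state,
    )
    return ValidationReport(
        n_subjects_in=df["subject_id"].nunique(),
        n_subjects_retained=out_df["subject_id"].nunique(),
        n_records_in=len(df),
        n_records_retained=len(out_df),
        dropped_subjects={k: len(v) for k, v in dropped.items() if v},
        panel=out,
    )
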