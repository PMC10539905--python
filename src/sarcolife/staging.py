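"""AWGS-2019 sarcopenia staging from anthropometric measurements.

Each subject-wave record carries handgrip strength (kg), the five-time
chair-stand time (seconds, or a flag that the test was attempted and
failed), body weight (kg), height (cm), age and sex.  Appendicular
skeletal muscle mass (ASM, kg) is estimated from the validated Chinese
anthropometric equation

    ASM = 0.193*weight + 0.107*height - 4.15*sex - 0.037*age - 2.631

with sex coded man=1 / woman=2, and converted to the height-adjusted
index ASM/Ht^2 (kg/m^2).  The three binary components are then

* low muscle strength  : grip < 28 kg (men), < 18 kg (women)
* low muscle mass      : ASM/Ht^2 < 7.0 (men), < 5.4 (women)
* low physical performance : chair-stand time >= 12 s, or test failed

and the stage is

* SARCOPENIA          if low mass and (low strength or low performance)
* POSSIBLE_SARCOPENIA else if low strength
* NO_SARCOPENIA       otherwise.

Low performance alone (normal strength, normal mass) is NO_SARCOPENIA by
default; the broader AWGS-2019 screening variant, in which low strength
OR low performance qualifies as possible sarcopenia, is available via
``possible_includes_low_performance=True``.

Boundary conventions: strength and mass comparisons are strict ``<`` (a
grip of exactly 28 kg in a man is *not* low); the chair-stand comparison
is ``>=`` (exactly 12 s *is* low).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MAN",
    "WOMAN",
    "SarcopeniaState",
    "SarcopeniaMeasurement",
    "StageCutoffs",
    "DEFAULT_CUTOFFS",
    "MissingDataError",
    "estimate_asm",
    "asm_index",
    "grip_max",
    "classify_state",
    "stage_table",
    "read_measurements",
]

MAN = 1
WOMAN = 2

# ASM anthropometric equation coefficients (kg scale).
_ASM_WEIGHT = 0.193
_ASM_HEIGHT = 0.107
_ASM_SEX = -4.15
_ASM_AGE = -0.037
_ASM_CONST = -2.631


class SarcopeniaState(enum.IntEnum):
    """Live sarcopenia stages plus the absorbing death state."""

    NO_SARCOPENIA = 1
    POSSIBLE_SARCOPENIA = 2
    SARCOPENIA = 3
    DEAD = 4


class MissingDataError(ValueError):
    """A staging component is missing without an explanatory flag."""


def _check_sex(sex) -> None:
    arr = np.asarray(sex)
    if not np.all(np.isin(arr, (MAN, WOMAN))):
        raise ValueError(f"sex must be coded man={MAN} / woman={WOMAN}, got {sex!r}")


@dataclass(frozen=True)
class StageCutoffs:
    """Staging thresholds, by sex where the consensus differentiates.

    Defaults are the AWGS-2019 values: grip < 28/18 kg (man/woman),
    ASM index < 7.0/5.4 kg/m^2, chair-stand >= 12 s.
    """

    grip_low: Mapping[int, float] = field(
        default_factory=lambda: {MAN: 28.0, WOMAN: 18.0}
    )
    asm_index_low: Mapping[int, float] = field(
        default_factory=lambda: {MAN: 7.0, WOMAN: 5.4}
    )
    chair_stand_low: float = 12.0

    def __post_init__(self):
        for sex in (MAN, WOMAN):
            if self.grip_low[sex] <= 0 or self.asm_index_low[sex] <= 0:
                raise ValueError("cutoffs must be strictly positive")
        if self.chair_stand_low <= 0:
            raise ValueError("chair_stand_low must be strictly positive")

    @classmethod
    def from_yaml(cls, path) -> "StageCutoffs":
        """Load cutoffs from a YAML mapping.

        Recognised keys (all optional, defaults retained otherwise)::

            grip_low:       {man: 28, woman: 18}
            asm_index_low:  {man: 7.0, woman: 5.4}
            chair_stand_low: 12
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("grip_low", "asm_index_low"):
            if key in raw:
                kwargs[key] = {MAN: float(raw[key]["man"]), WOMAN: float(raw[key]["woman"])}
        if "chair_stand_low" in raw:
            kwargs["chair_stand_low"] = float(raw["chair_stand_low"])
        return cls(**kwargs)


DEFAULT_CUTOFFS = StageCutoffs()


@dataclass
class SarcopeniaMeasurement:
    """Raw per-wave physical measures feeding the classifier.

    ``chair_stand_time`` may be ``None`` when ``chair_stand_failed`` is
    set (attempted but could not complete: counted as low performance).
    """

    grip_strength: float  # kg, max over recorded trials
    chair_stand_time: float | None  # seconds
    weight: float  # kg
    height: float  # cm
    age: float  # years
    sex: int  # man=1, woman=2
    chair_stand_failed: bool = False

    def __post_init__(self):
        _check_sex(self.sex)
        if self.grip_strength < 0:
            raise ValueError("grip_strength must be >= 0")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be > 0")


def grip_max(*trials: float) -> float:
    """Aggregate grip-strength trials (both hands) as their maximum.

    The AWGS convention when several dynamometer readings are recorded.
    Missing trials (NaN/None) are ignored; all-missing raises.
    """
    vals = [t for t in trials if t is not None and not math.isnan(t)]
    if not vals:
        raise MissingDataError("no grip-strength trial available")
    return max(vals)


def estimate_asm(weight, height, age, sex):
    """Appendicular skeletal muscle mass (kg) from the anthropometric equation.

    Accepts scalars or numpy arrays; weight in kg, height in cm, age in
    years, sex man=1 / woman=2.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be strictly positive")
    _check_sex(sex)
    out = (
        _ASM_WEIGHT * weight
        + _ASM_HEIGHT * height
        + _ASM_SEX * np.asarray(sex, dtype=float)
        + _ASM_AGE * np.asarray(age, dtype=float)
        + _ASM_CONST
    )
    return out if out.ndim else float(out)


def asm_index(asm, height):
    """Height-adjusted muscle mass ASM/Ht^2 in kg/m^2 (height in cm)."""
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be strictly positive")
    out = np.asarray(asm, dtype=float) / (height / 100.0) ** 2
    return out if out.ndim else float(out)


def classify_state(
    m: SarcopeniaMeasurement,
    cutoffs: StageCutoffs | None = None,
    possible_includes_low_performance: bool = False,
) -> SarcopeniaState:
    """Assign the AWGS-2019 stage to one measurement record."""
    c = cutoffs or DEFAULT_CUTOFFS
    if m.chair_stand_failed:
        low_perf = True
    else:
        if m.chair_stand_time is None or math.isnan(m.chair_stand_time):
            raise MissingDataError(
                "chair-stand time missing without a failure flag"
            )
        low_perf = m.chair_stand_time >= c.chair_stand_low
    if math.isnan(m.grip_strength):
        raise MissingDataError("grip strength missing")

    low_strength = m.grip_strength < c.grip_low[m.sex]
    idx = asm_index(estimate_asm(m.weight, m.height, m.age, m.sex), m.height)
    low_mass = idx < c.asm_index_low[m.sex]

    if low_mass and (low_strength or low_perf):
        return SarcopeniaState.SARCOPENIA
    if low_strength or (possible_includes_low_performance and low_perf):
        return SarcopeniaState.POSSIBLE_SARCOPENIA
    return SarcopeniaState.NO_SARCOPENIA


#: Column dictionary for measurement tables (long format, one row per
#: subject-wave):
#:
#: ==================  =======================================================
#: subject_id          unique subject identifier
#: wave                integer wave index (1-based)
#: age                 decimal age at interview, years
#: sex                 man=1 / woman=2
#: grip_strength       kg, already aggregated over trials (max)
#: chair_stand_time    seconds; may be empty if chair_stand_failed is 1
#: chair_stand_failed  0/1, attempted-but-failed flag (optional column)
#: weight              kg
#: height              cm
#: ==================  =======================================================
MEASUREMENT_COLUMNS = (
    "subject_id",
    "wave",
    "age",
    "sex",
    "grip_strength",
    "chair_stand_time",
    "weight",
    "height",
)


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV (see ``MEASUREMENT_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if "chair_stand_failed" not in df.columns:
        df["chair_stand_failed"] = False
    df["chair_stand_failed"] = df["chair_stand_failed"].fillna(0).astype(bool)
    return df


def stage_table(
    df: pd.DataFrame,
    cutoffs: StageCutoffs | None = None,
    possible_includes_low_performance: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every row of a measurement table.

    Returns ``(staged, excluded)``: ``staged`` is the input plus
    ``asm``, ``asm_index`` and integer ``state`` columns for rows with
    complete components; ``excluded`` holds the dropped rows with an
    ``exclusion_reason`` column (mirrors the study-flowchart role).
    """
    c = cutoffs or DEFAULT_CUTOFFS
    df = df.copy()
    if "chair_stand_failed" not in df.columns:
        df["chair_stand_failed"] = False
    df["chair_stand_failed"] = df["chair_stand_failed"].fillna(0).astype(bool)
    _check_sex(df["sex"].to_numpy())

    reasons = pd.Series("", index=df.index, dtype=object)
    bad_grip = df["grip_strength"].isna()
    bad_body = (
        df["weight"].isna() | df["height"].isna()
        | (df["weight"] <= 0) | (df["height"] <= 0)
    )
    bad_chair = df["chair_stand_time"].isna() & ~df["chair_stand_failed"]
    reasons[bad_chair] = "missing chair-stand time"
    reasons[bad_body] = "missing/invalid weight or height"
    reasons[bad_grip] = "missing grip strength"
    excluded_mask = bad_grip | bad_body | bad_chair

    excluded = df[excluded_mask].copy()
    excluded["exclusion_reason"] = reasons[excluded_mask]
    ok = df[~excluded_mask].copy()
    if len(ok):
        sex = ok["sex"].to_numpy()
        asm = estimate_asm(
            ok["weight"].to_numpy(), ok["height"].to_numpy(),
            ok["age"].to_numpy(), sex,
        )
        idx = asm_index(asm, ok["height"].to_numpy())
        grip_cut = np.where(sex == MAN, c.grip_low[MAN], c.grip_low[WOMAN])
        mass_cut = np.where(sex == MAN, c.asm_index_low[MAN], c.asm_index_low[WOMAN])
        low_strength = ok["grip_strength"].to_numpy() < grip_cut
        low_mass = idx < mass_cut
        chair = ok["chair_stand_time"].to_numpy(dtype=float)
        low_perf = ok["chair_stand_failed"].to_numpy() | (chair >= c.chair_stand_low)

        state = np.full(len(ok), int(SarcopeniaState.NO_SARCOPENIA))
        possible = low_strength | (possible_includes_low_performance & low_perf)
        state[possible] = int(SarcopeniaState.POSSIBLE_SARCOPENIA)
        state[low_mass & (low_strength | low_perf)] = int(SarcopeniaState.SARCOPENIA)
        ok["asm"] = asm
        ok["asm_index"] = idx
        ok["state"] = state
    else:
        ok["asm"] = pd.Series(dtype=float)
        ok["asm_index"] = pd.Series(dtype=float)
        ok["state"] = pd.Series(dtype=int)
    return ok, excluded
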