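"""Synthetic ageing-cohort generator with known ground truth.

Emulates a CHARLS-like panel so that every downstream stage — staging,
panel construction, model fitting, life tables — is testable without any
external download: baseline ages 60-90, three interview waves roughly
two years apart with per-wave jitter, three live sarcopenia stages plus
death, Gompertz-type age-increasing intensities, wave-on-wave dropout,
and a mix of exactly dated and interval-censored deaths.

The default generator parameters are illustrative, chosen so that
two-year transition frequencies resemble the qualitative pattern of an
ageing community cohort (onset moves more common than recovery from the
sarcopenia stage; death rates ordered q34 > q24 > q14); they are not a
fit to any survey.

Everything is deterministic under a master seed, with hierarchical
per-subject seeding so cohorts of different sizes share their common
prefix of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Observation, PanelDataset, impute_death_ages, validate_panel
from .lifetable import (
    LEConfig,
    LifeExpectancyTable,
    PrevalenceModel,
    life_expectancies,
)
from .msm import DEFAULT_STRUCTURE, IntensityModel
from .staging import (
    DEFAULT_CUTOFFS,
    MAN,
    WOMAN,
    SarcopeniaMeasurement,
    SarcopeniaState,
    StageCutoffs,
)

__all__ = [
    "SyntheticConfig",
    "SimulatedCohort",
    "default_true_model",
    "default_baseline_prevalence",
    "simulate_trajectory",
    "observe_panel",
    "emit_measurements",
    "simulate_cohort",
    "true_life_expectancy",
]


def default_true_model() -> IntensityModel:
    """Ground-truth intensities for the default synthetic cohort.

    Baseline (age-60) rates per year with Gompertz-type age slopes:
    onset and progression rise with age, recovery falls slightly, and
    mortality rises steeply and is ordered q34 > q24 > q14.
    """
    # transitions: 1->2, 2->1, 2->3, 3->2, 1->4, 2->4, 3->4
    alpha = np.log([0.16, 0.14, 0.085, 0.17, 0.006, 0.014, 0.032])
    beta = np.array([0.030, -0.020, 0.040, -0.020, 0.080, 0.075, 0.070])
    return IntensityModel(DEFAULT_STRUCTURE, alpha, beta)


def default_baseline_prevalence() -> PrevalenceModel:
    """Age-dependent baseline stage distribution (multinomial logit).

    Calibrated loosely so that around the cohort's mean baseline age the
    possible-sarcopenia stage is the most common and the sarcopenia
    share rises steeply with age.
    """
    coef = np.array(
        [
            [0.15, -1.50],  # intercepts: state 2, state 3 (vs state 1)
            [0.04, 0.13],  # age slopes
        ]
    )
    return PrevalenceModel(live_states=(1, 2, 3), coef=coef, age_center=60.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated survey design: n subjects with uniform
    baseline ages 60-90, three waves at 0/2/4 years with +-0.3 y uniform
    jitter, per-wave dropout, and half of between-wave deaths carrying
    an exact date (the rest interval-censored and midpoint-imputed).
    """

    n_subjects: int = 3000
    baseline_age_range: tuple[float, float] = (60.0, 90.0)
    wave_times: tuple[float, ...] = (0.0, 2.0, 4.0)
    wave_jitter: float = 0.3
    dropout_per_wave: float = 0.08
    exact_death_fraction: float = 0.5
    omega_max: float = 120.0
    segment: float = 0.25
    seed: int = 0
    true_model: IntensityModel = field(default_factory=default_true_model)
    baseline_prevalence: PrevalenceModel = field(
        default_factory=default_baseline_prevalence
    )

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if np.any(np.diff(self.wave_times) <= 0):
            raise ValueError("wave_times must be strictly increasing")
        for p in (self.dropout_per_wave, self.exact_death_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.segment <= 0 or self.wave_jitter < 0:
            raise ValueError("segment must be > 0 and wave_jitter >= 0")


def simulate_trajectory(
    true_model: IntensityModel,
    baseline_age: float,
    baseline_state: int,
    rng: np.random.Generator | int,
    omega_max: float = 120.0,
    segment: float = 0.25,
    covariates=None,
) -> list[tuple[float, int]]:
    """Exact continuous-time path until death or omega_max.

    Intensities are piecewise-constant on ``segment``-year age segments
    (frozen at each segment's start age); within a segment events are
    sampled by exponential competing risks, with the memoryless redraw
    at segment boundaries.  Returns the event list
    ``[(age, state), ...]`` starting at the baseline entry.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    dead = true_model.structure.dead_state
    state = int(baseline_state)
    age = float(baseline_age)
    path = [(age, state)]
    labels = true_model.structure.transitions
    seg_start = age
    while state != dead and age < omega_max:
        seg_end = min(seg_start + segment, omega_max)
        rates = true_model.rates(seg_start, covariates)[0]
        row = np.array(
            [rates[k] if r == state else 0.0 for k, (r, _s) in enumerate(labels)]
        )
        total = row.sum()
        if total > 0:
            wait = rng.exponential(1.0 / total)
            if age + wait < seg_end:
                age += wait
                dests = [s for (r, s), v in zip(labels, row) if r == state and v > 0]
                probs = row[row > 0] / total
                state = int(rng.choice(dests, p=probs))
                path.append((age, state))
                continue
        age = seg_end
        seg_start = seg_end
    return path


def _state_at(path: list[tuple[float, int]], age: float) -> int:
    state = path[0][1]
    for a, s in path:
        if a <= age:
            state = s
        else:
            break
    return state


def _death_age(path: list[tuple[float, int]], dead: int) -> float | None:
    for a, s in path:
        if s == dead:
            return a
    return None


def observe_panel(
    path: list[tuple[float, int]],
    wave_ages: Sequence[float],
    dropout_per_wave: float,
    exact_death_fraction: float,
    rng: np.random.Generator | int,
    dead_state: int = 4,
) -> list[Observation]:
    """Discretise a continuous path into wave observations.

    The state is read at each attended wave.  Dropout is checked before
    each post-baseline wave and is absorbing.  A death occurring before
    an attended wave is reported either at its exact age (with the
    configured probability) or as interval-censored at the wave age
    (``death_exact=False``), to be midpoint-imputed downstream.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    obs: list[Observation] = []
    death = _death_age(path, dead_state)
    for w, wave_age in enumerate(wave_ages):
        if w > 0 and rng.random() < dropout_per_wave:
            break
        if death is not None and death <= wave_age:
            exact = rng.random() < exact_death_fraction
            obs.append(
                Observation(
                    age=death if exact else wave_age,
                    state=dead_state,
                    death_exact=exact,
                )
            )
            break
        obs.append(Observation(age=wave_age, state=_state_at(path, wave_age)))
    return obs


def emit_measurements(
    state: int,
    sex: int,
    age: float,
    rng: np.random.Generator | int,
    cutoffs: StageCutoffs | None = None,
) -> SarcopeniaMeasurement:
    """Raw measurements that classify back to the intended live state.

    Component values are sampled uniformly inside the region the
    cutoffs carve out for the target stage, and the ASM equation is
    inverted for a body weight consistent with the target muscle-mass
    category — so the staging round trip is exact by construction.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    c = cutoffs or DEFAULT_CUTOFFS
    state = SarcopeniaState(state)
    if state == SarcopeniaState.DEAD:
        raise ValueError("measurements exist only for live states")
    grip_cut = c.grip_low[sex]
    mass_cut = c.asm_index_low[sex]
    height = float(
        np.clip(rng.normal(166.0 if sex == MAN else 155.0, 6.0), 145.0, 190.0)
    )

    def grip(low: bool) -> float:
        if low:
            return rng.uniform(max(1.0, grip_cut - 12.0), grip_cut - 0.05)
        return rng.uniform(grip_cut, grip_cut + 18.0)

    def chair(low: bool) -> tuple[float | None, bool]:
        if low:
            if rng.random() < 0.1:
                return None, True  # attempted but failed
            return rng.uniform(c.chair_stand_low, c.chair_stand_low + 12.0), False
        return rng.uniform(5.0, c.chair_stand_low - 0.1), False

    if state == SarcopeniaState.NO_SARCOPENIA:
        low_strength, low_mass, low_perf = False, False, False
    elif state == SarcopeniaState.POSSIBLE_SARCOPENIA:
        low_strength, low_mass = True, False
        low_perf = bool(rng.random() < 0.4)
    else:  # SARCOPENIA: low mass + (strength and/or performance)
        low_mass = True
        low_strength = bool(rng.random() < 0.8)
        low_perf = not low_strength or bool(rng.random() < 0.5)

    if low_mass:
        idx = rng.uniform(max(0.5, mass_cut - 1.5), mass_cut - 0.02)
    else:
        idx = rng.uniform(mass_cut, mass_cut + 2.5)
    asm = idx * (height / 100.0) ** 2
    weight = (asm + 4.15 * sex + 0.037 * age + 2.631 - 0.107 * height) / 0.193
    if weight <= 0:
        raise ValueError(
            "cutoff configuration implies a non-physical body weight"
        )
    chair_time, failed = chair(low_perf)
    return SarcopeniaMeasurement(
        grip_strength=grip(low_strength),
        chair_stand_time=chair_time,
        weight=weight,
        height=height,
        age=age,
        sex=sex,
        chair_stand_failed=failed,
    )


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`."""

    panel: PanelDataset  # analysis-ready (deaths midpoint-imputed, validated)
    raw: pd.DataFrame  # as-observed records incl. interval-censored deaths
    measurements: pd.DataFrame | None  # raw physical measures for live waves
    truth: dict  # true parameters and true analytic LEs


def true_life_expectancy(
    model: IntensityModel,
    prevalence: PrevalenceModel,
    x: float = 60.0,
    omega_max: float = 120.0,
    h: float = 0.05,
) -> LifeExpectancyTable:
    """Analytic (fine-grid midpoint quadrature) LE table for a true model."""
    cfg = LEConfig(x=x, omega_max=omega_max, h=h, method="middle_riemann")
    return life_expectancies(model, prevalence, cfg)


def simulate_cohort(
    cfg: SyntheticConfig | None = None,
    seed: int | None = None,
    emit_raw_measures: bool = False,
) -> SimulatedCohort:
    """Generate a full synthetic panel cohort.

    Per subject: draw sex, baseline age and baseline stage; simulate the
    continuous trajectory; observe it at jittered waves with dropout and
    mixed death dating; midpoint-impute interval-censored deaths and
    validate.  Optionally also emit raw physical measures for every live
    observation (for staging round trips).  The ``truth`` dict carries
    the generating parameters and the true analytic LE table at 60.
    """
    cfg = cfg or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    master = np.random.SeedSequence(cfg.seed)
    subject_seeds = master.spawn(cfg.n_subjects)
    model = cfg.true_model
    prev = cfg.baseline_prevalence
    rows = []
    meas_rows = [] if emit_raw_measures else None
    for i, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        sex = MAN if rng.random() < 0.5 else WOMAN
        a0 = rng.uniform(*cfg.baseline_age_range)
        probs = np.atleast_2d(prev.predict(a0))[0]
        s0 = int(rng.choice(prev.live_states, p=probs))
        path = simulate_trajectory(
            model, a0, s0, rng, omega_max=cfg.omega_max, segment=cfg.segment
        )
        wave_ages = [
            a0 + t + (rng.uniform(-cfg.wave_jitter, cfg.wave_jitter) if w else 0.0)
            for w, t in enumerate(cfg.wave_times)
        ]
        obs = observe_panel(
            path,
            wave_ages,
            cfg.dropout_per_wave,
            cfg.exact_death_fraction,
            rng,
            dead_state=model.structure.dead_state,
        )
        for w, o in enumerate(obs):
            rows.append(
                {
                    "subject_id": i,
                    "wave": w + 1,
                    "age": o.age,
                    "state": o.state,
                    "death_exact": o.death_exact,
                    "sex": sex,
                }
            )
            if meas_rows is not None and o.state != model.structure.dead_state:
                m = emit_measurements(o.state, sex, o.age, rng)
                meas_rows.append(
                    {
                        "subject_id": i,
                        "wave": w + 1,
                        "age": o.age,
                        "sex": sex,
                        "grip_strength": m.grip_strength,
                        "chair_stand_time": m.chair_stand_time,
                        "chair_stand_failed": m.chair_stand_failed,
                        "weight": m.weight,
                        "height": m.height,
                        "true_state": o.state,
                    }
                )
    raw = pd.DataFrame(rows)
    imputed = impute_death_ages(raw.copy(), dead_state=model.structure.dead_state)
    panel = PanelDataset(
        imputed,
        covariates=[],
        n_states=model.structure.n_states,
        dead_state=model.structure.dead_state,
    )
    panel = validate_panel(panel).panel
    truth = {
        "alpha": model.alpha.copy(),
        "beta": model.beta.copy(),
        "transitions": model.structure.transitions,
        "baseline_prevalence_coef": prev.coef.copy(),
        "true_le_at_60": true_life_expectancy(model, prev, omega_max=cfg.omega_max),
        "seed": cfg.seed,
    }
    measurements = pd.DataFrame(meas_rows) if meas_rows is not None else None
    return SimulatedCohort(panel=panel, raw=raw, measurements=measurements, truth=truth)
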