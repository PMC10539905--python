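import numpy as np
import pandas as pd
import pytest

import sarcolife as sl


def two_state_structure():
    """Alive(1) -> dead(2) only."""
    return sl.TransitionStructure(((1, 2),), n_states=2, dead_state=2)


def death_only_model(mu: float) -> sl.IntensityModel:
    """Constant-rate alive->dead model (closed forms available)."""
    return sl.IntensityModel(
        two_state_structure(), alpha=np.log([mu]), beta=np.zeros(1)
    )


@pytest.fixture(scope="session")
def small_cohort() -> sl.SimulatedCohort:
    """A small synthetic cohort for cheap structural tests."""
    return sl.simulate_cohort(
        sl.SyntheticConfig(n_subjects=250, seed=3), emit_raw_measures=True
    )


@pytest.fixture(scope="session")
def recovery_cohort() -> sl.SimulatedCohort:
    """The parameter-recovery study cohort: n=3000, three waves."""
    return sl.simulate_cohort(sl.SyntheticConfig(n_subjects=3000, seed=42))


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort) -> sl.FittedModel:
    return sl.fit_msm(recovery_cohort.panel)


@pytest.fixture(scope="session")
def recovery_prevalence(recovery_cohort) -> sl.PrevalenceModel:
    base = recovery_cohort.panel.baseline()
    return sl.fit_prevalence(base["state"], base["age"])


@pytest.fixture
def toy_panel() -> sl.PanelDataset:
    """Hand-written 3-live-state panel with live moves and both death kinds."""
    rows = [
        # id, age, state
        (1, 61.0, 1), (1, 63.1, 2), (1, 65.0, 2),
        (2, 70.0, 2), (2, 72.2, 3),
        (3, 65.5, 3), (3, 67.4, 2), (3, 69.6, 1),
        (4, 80.0, 1), (4, 82.5, 4),      # exactly timed death
        (5, 75.0, 3), (5, 76.9, 4),      # exactly timed death
        (6, 62.0, 2), (6, 64.0, 2), (6, 66.2, 3),
        (7, 68.0, 1), (7, 70.3, 1),
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "age", "state"])
    df["death_exact"] = True
    return sl.PanelDataset(df)
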