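"""Descriptive tables: baseline prevalence, chi-squared tests, transitions.

Mirrors the usual presentation of a staged ageing cohort: a
prevalence-by-characteristic contingency table with row percentages and
Pearson chi-squared tests, and an interval transition matrix with
per-origin percentages plus pooled deterioration / improvement shares
(severity order: no sarcopenia < possible < sarcopenia < death).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import PanelDataset

__all__ = [
    "Chi2Result",
    "TransitionSummary",
    "prevalence_table",
    "chi_squared",
    "transition_table",
    "pooled_transition_rates",
    "format_p",
]

_STATE_NAMES = {1: "No sarcopenia", 2: "Possible sarcopenia", 3: "Sarcopenia", 4: "Death"}


def prevalence_table(
    staged: pd.DataFrame,
    group: str,
    state_col: str = "state",
    states: tuple[int, ...] = (1, 2, 3),
    levels=None,
) -> pd.DataFrame:
    """Counts and row percentages of live stages by a grouping variable.

    Returns one row per group level with ``n_<state>`` counts and
    ``pct_<state>`` row percentages rounded to one decimal (display
    convention).  Levels absent from the data appear with zero counts
    when passed explicitly via ``levels``.
    """
    if group not in staged.columns:
        raise ValueError(f"grouping variable {group!r} not present")
    counts = pd.crosstab(staged[group], staged[state_col])
    counts = counts.reindex(columns=list(states), fill_value=0)
    if levels is not None:
        counts = counts.reindex(levels, fill_value=0)
    totals = counts.sum(axis=1)
    out = pd.DataFrame(index=counts.index)
    for s in states:
        out[f"n_{s}"] = counts[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"pct_{s}"] = np.round(100.0 * counts[s] / totals, 1)
    out["total"] = totals
    return out


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float

    def display_p(self) -> str:
        return format_p(self.p)


def chi_squared(counts) -> Chi2Result:
    """Pearson chi-squared test of homogeneity on a contingency table.

    ``counts`` is a 2-D array-like or DataFrame of nonnegative integer
    counts; a zero row or column margin is a hard error naming it.
    """
    if isinstance(counts, pd.DataFrame):
        arr = counts.to_numpy(dtype=float)
        row_names = list(counts.index)
        col_names = list(counts.columns)
    else:
        arr = np.asarray(counts, dtype=float)
        row_names = list(range(arr.shape[0]))
        col_names = list(range(arr.shape[1]))
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(arr < 0):
        raise ValueError("negative counts in contingency table")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    for name, total in zip(row_names, row_sums):
        if total == 0:
            raise ValueError(f"zero margin: row {name!r} has no observations")
    for name, total in zip(col_names, col_sums):
        if total == 0:
            raise ValueError(f"zero margin: column {name!r} has no observations")
    stat, p, df, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return Chi2Result(float(stat), int(df), float(p))


def format_p(p: float, threshold: float = 0.001) -> str:
    """Display p-values as '<0.001' below the threshold (table style)."""
    return f"<{threshold:g}" if p < threshold else f"{p:.3f}"


@dataclass
class TransitionSummary:
    """Interval transition counts between consecutive waves.

    Counting convention: every consecutive-wave observation pair is one
    subject-interval; subjects observed at three waves contribute two
    pairs.  ``counts``/``pct`` are origin-state rows by destination-state
    columns; ``deterioration``/``improvement`` pool all intervals whose
    destination is a worse (incl. death) / better stage.
    """

    counts: pd.DataFrame
    pct: pd.DataFrame
    deterioration: float  # proportion, 0-1
    improvement: float

    @property
    def deterioration_pct(self) -> float:
        return 100.0 * self.deterioration

    @property
    def improvement_pct(self) -> float:
        return 100.0 * self.improvement


def transition_table(panel: PanelDataset) -> TransitionSummary:
    """Observed interval transitions in a panel (see TransitionSummary)."""
    iv = panel.intervals()
    origins = panel.live_states
    dests = origins + [panel.dead_state]
    counts = pd.crosstab(iv["from_state"], iv["to_state"])
    counts = counts.reindex(index=origins, columns=dests, fill_value=0)
    counts.index.name = "from_state"
    counts.columns.name = "to_state"
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    total = counts.to_numpy().sum()
    worse = sum(
        counts.loc[r, s]
        for r in origins
        for s in dests
        if s > r
    )
    better = sum(counts.loc[r, s] for r in origins for s in dests if s < r)
    return TransitionSummary(
        counts=counts,
        pct=pct,
        deterioration=worse / total if total else 0.0,
        improvement=better / total if total else 0.0,
    )


def pooled_transition_rates(
    origin_totals: dict[int, float],
    pct: dict[tuple[int, int], float],
) -> tuple[float, float]:
    """Pooled deterioration/improvement from per-origin summary numbers.

    Reconstructs the pooled proportions from published per-origin
    denominators and destination percentages (as printed in a
    transition figure): deterioration counts every move to a
    higher-severity state or death, improvement every move to a
    lower-severity state, both over the pooled denominator.  Returns
    percentages on the 0-100 scale.
    """
    denom = sum(origin_totals.values())
    worse = sum(
        origin_totals[r] * v / 100.0 for (r, s), v in pct.items() if s > r
    )
    better = sum(
        origin_totals[r] * v / 100.0 for (r, s), v in pct.items() if s < r
    )
    return 100.0 * worse / denom, 100.0 * better / denom
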