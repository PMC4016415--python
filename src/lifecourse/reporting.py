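"""Aggregation arithmetic, report tables and convenience figures.

The helpers here perform the small but load-bearing arithmetic the reports
rely on: decomposing life expectancy into healthy/chronic years, comparing
the two simulation engines, and laying out the expectancy and lifetime-cost
tables.  Figures (occupancy areas, yearly cost lines, cost histograms) are
convenience outputs only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortOccupancy, CohortResult
from .montecarlo import LifetimeCostSummary, PathwayCollection
from .states import CHRONIC_STATES, Gender, HealthState, TRANSIENT_STATES

__all__ = [
    "aggregate_expectancy",
    "compare_engines",
    "expectancy_table",
    "cost_summary_table",
    "plot_occupancy",
    "plot_yearly_cost",
    "plot_cost_histogram",
]


def aggregate_expectancy(per_state: Mapping[HealthState | str, float]) -> dict[str, float]:
    """Aggregate per-state expected years into total / chronic / healthy.

    ``per_state`` must contain all six transient states (by enum or label).
    Values are returned at full precision; display rounding is the caller's
    concern.
    """
    values: dict[HealthState, float] = {}
    for key, v in per_state.items():
        state = HealthState[key] if isinstance(key, str) else key
        values[state] = float(v)
    missing = [s.name for s in TRANSIENT_STATES if s not in values]
    if missing:
        raise ValueError(f"missing expected-years values for states: {missing}")
    total = sum(values[s] for s in TRANSIENT_STATES)
    chronic = sum(values[s] for s in TRANSIENT_STATES if s in CHRONIC_STATES)
    return {
        "total": total,
        "chronic_years": chronic,
        "healthy_years": values[HealthState.E1],
    }


def compare_engines(cohort_value: float, mc_value: float) -> float:
    """Relative difference |cohort - mc| / cohort, in percent.

    The exact cohort value is the reference; the Monte-Carlo estimate
    carries the sampling bias being measured.
    """
    if not cohort_value > 0:
        raise ValueError(f"cohort reference value must be positive, got {cohort_value}")
    return abs(cohort_value - mc_value) / cohort_value * 100.0


def expectancy_table(cohort: CohortResult, mc_years: pd.DataFrame) -> pd.DataFrame:
    """Expected-years table: exact cohort mean plus MC mean/SD/min/max per gender."""
    rows = []
    for s in TRANSIENT_STATES:
        row = {"state": s.name}
        for g in Gender:
            mc = mc_years[(mc_years["gender"] == g.name) & (mc_years["state"] == s.name)]
            row[f"{g.name}_cohort_mean"] = cohort.expected_years.loc[s.name, g.name]
            row[f"{g.name}_mc_mean"] = float(mc["mean"].iloc[0]) if len(mc) else np.nan
            row[f"{g.name}_sd"] = float(mc["sd"].iloc[0]) if len(mc) else np.nan
            row[f"{g.name}_min"] = float(mc["min"].iloc[0]) if len(mc) else np.nan
            row[f"{g.name}_max"] = float(mc["max"].iloc[0]) if len(mc) else np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("state")
    totals = {c: df[c].sum() if c.endswith("mean") else np.nan for c in df.columns}
    chronic = {
        c: df.loc[[s.name for s in TRANSIENT_STATES if s in CHRONIC_STATES], c].sum()
        if c.endswith("mean")
        else np.nan
        for c in df.columns
    }
    df.loc["Total"] = totals
    df.loc["Chronic"] = chronic
    return df


def cost_summary_table(summaries: Mapping[str, LifetimeCostSummary]) -> pd.DataFrame:
    """Lifetime-cost distribution table, one column per gender."""
    return pd.DataFrame({g: s.to_series() for g, s in summaries.items()})


# ---------------------------------------------------------------------------
# figures (convenience only; nothing downstream reads pixels)
# ---------------------------------------------------------------------------


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_occupancy(occ: CohortOccupancy, gender: Gender, path: str | Path) -> Path:
    """Stacked occupancy area chart over age for one gender."""
    plt = _axes()
    frac = occ.mass[:, int(gender), :] / occ.initial_gender_mass()[int(gender)]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.stackplot(occ.ages, frac.T, labels=[s.name for s in HealthState])
    ax.set_xlabel("age")
    ax.set_ylabel("cohort share")
    ax.set_title(f"Cohort occupancy - {gender.name}")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_yearly_cost(yearly: pd.DataFrame, path: str | Path) -> Path:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(yearly.index, yearly["F"], label="F")
    ax.plot(yearly.index, yearly["M"], linestyle="--", label="M")
    ax.set_xlabel("age")
    ax.set_ylabel("mean annual cost per survivor (EUR)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cost_histogram(
    collection: PathwayCollection, gender: Gender, path: str | Path, bins: int = 60
) -> Path:
    plt = _axes()
    x = collection.lifetime_cost[collection.gender_mask(gender)]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.hist(x, bins=bins)
    ax.set_xlabel("lifetime healthcare cost (EUR)")
    ax.set_ylabel("pathways")
    ax.set_title(f"Lifetime cost distribution - {gender.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
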