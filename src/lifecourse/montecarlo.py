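"""Monte-Carlo microsimulation of individual birth-to-death pathways.

Each simulated individual starts at age 0 in a state drawn from the initial
(gender x state) mix and then moves through the stratified one-year
transition matrices by inverse-CDF sampling: a uniform draw is compared to
the cumulative row probabilities in the fixed state order, with half-open
cumulative intervals so every draw maps to exactly one destination.
Pathways end at DEAD, or with forced death after the year lived at the age
cap (default 110), mirroring the cohort engine.

The annual cost attached to a pathway year is the (gender, age band, state)
cell *mean* — there is no individual-level cost noise — so the spread of
the lifetime-cost distribution across pathways reflects the variability of
health-state histories, not cost sampling.

Summaries reproduce the usual lifetime-cost distribution table (n, mean,
SD, variance, skewness, kurtosis, min, max, quartiles) and per-state years
lived with mean/SD/min/max.  Skewness is the third standardised central
moment; kurtosis is reported in both the raw and the excess convention,
since published tables do not always declare which one they use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import InitialMix
from .estimation import CostTable, TransitionMatrixSet
from .states import (
    N_GENDERS,
    N_TRANSIENT,
    STATE_LABELS,
    Gender,
    HealthState,
    TRANSIENT_STATES,
)

__all__ = [
    "Pathway",
    "PathwayCollection",
    "LifetimeCostSummary",
    "simulate_pathway",
    "draw_initial_state",
    "simulate_collection",
    "summarize_costs",
    "summarize_years",
]

_DEAD = HealthState.DEAD.value
_NONE = -1  # sentinel in state arrays for ages not reached


def _pick(cdf_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF state pick: first j with u < cdf[j]; half-open intervals."""
    return np.minimum((cdf_rows <= u[..., None]).sum(axis=-1), cdf_rows.shape[-1] - 1)


@dataclass(frozen=True)
class Pathway:
    """One simulated life: states by age (ending at DEAD) and its lifetime cost."""

    gender: Gender
    states: tuple[HealthState, ...]
    lifetime_cost: float | None = None

    @property
    def years_lived(self) -> int:
        return sum(1 for s in self.states if s is not HealthState.DEAD)


def simulate_pathway(
    matrices: TransitionMatrixSet,
    gender: Gender,
    initial_state: HealthState,
    rng: np.random.Generator,
    costs: CostTable | None = None,
    max_age: int = 110,
) -> Pathway:
    """Simulate a single birth-to-death pathway (reference scalar implementation)."""
    if initial_state is HealthState.DEAD:
        raise ValueError("initial state must be transient")
    matrices.validate()
    scheme = matrices.scheme
    g = int(gender)
    state = int(initial_state)
    states = []
    total_cost = 0.0
    for age in range(max_age + 1):
        states.append(HealthState(state))
        if costs is not None:
            total_cost += costs.effective[g, scheme.group(age), state]
        if age == max_age:
            states.append(HealthState.DEAD)  # forced death at the cap
            break
        row = matrices.probs[g, scheme.group(age), state]
        state = int(_pick(np.cumsum(row), np.array(rng.random())))
        if state == _DEAD:
            states.append(HealthState.DEAD)
            break
    return Pathway(
        gender=gender,
        states=tuple(states),
        lifetime_cost=round(total_cost, 10) if costs is not None else None,
    )


def draw_initial_state(
    mix: InitialMix, rng: np.random.Generator
) -> tuple[Gender, HealthState]:
    """Draw a (gender, state) pair from the joint initial mix."""
    flat = mix.shares.ravel()
    k = int(_pick(np.cumsum(flat), np.array(rng.random())))
    return Gender(k // N_TRANSIENT), HealthState(k % N_TRANSIENT)


@dataclass
class PathwayCollection:
    """Vectorised store of simulated pathways.

    ``states`` is an int8 array (n, max_age + 2) with -1 for ages never
    reached; ``years_in_state`` counts transient person-years per pathway
    and state; ``lifetime_cost`` is NaN-free euros.
    """

    genders: np.ndarray  # int8 (n,)
    states: np.ndarray  # int8 (n, L)
    years_in_state: np.ndarray  # int64 (n, 6)
    lifetime_cost: np.ndarray  # float64 (n,)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.genders)

    @property
    def lengths(self) -> np.ndarray:
        return self.years_in_state.sum(axis=1)

    def gender_mask(self, gender: Gender) -> np.ndarray:
        return self.genders == int(gender)

    def pathway(self, i: int) -> Pathway:
        row = self.states[i]
        seq = tuple(HealthState(int(s)) for s in row[row != _NONE])
        return Pathway(
            gender=Gender(int(self.genders[i])),
            states=seq,
            lifetime_cost=float(self.lifetime_cost[i]),
        )

    def to_long_df(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self)):
            row = self.states[i]
            for age, s in enumerate(row):
                if s == _NONE:
                    break
                rows.append((i, Gender(int(self.genders[i])).name, age, STATE_LABELS[int(s)]))
        df = pd.DataFrame(rows, columns=["pathway_id", "gender", "age", "state"])
        df["lifetime_cost"] = self.lifetime_cost[df["pathway_id"].to_numpy()]
        return df


def simulate_collection(
    matrices: TransitionMatrixSet,
    mix: InitialMix,
    n_per_gender: int,
    costs: CostTable,
    seed: int,
    max_age: int = 110,
) -> PathwayCollection:
    """Simulate ``n_per_gender`` pathways for each gender (vectorised).

    Seeding is hierarchical (one child stream per gender), so the female
    pathways do not depend on how many male pathways are requested.
    """
    if n_per_gender < 1:
        raise ValueError("n_per_gender must be at least 1")
    matrices.validate()
    scheme = matrices.scheme
    streams = np.random.SeedSequence(seed).spawn(N_GENDERS)
    L = max_age + 2

    all_states = []
    all_yis = []
    all_cost = []
    for g in Gender:
        rng = np.random.default_rng(streams[int(g)])
        n = n_per_gender
        cdf0 = np.cumsum(mix.conditional_state(g))
        cur = _pick(cdf0[None, :], rng.random(n)).astype(np.int64)
        states = np.full((n, L), _NONE, dtype=np.int8)
        yis = np.zeros((n, N_TRANSIENT), dtype=np.int64)
        cost = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        lookup = costs.effective[int(g)]  # (n_bands, 6)
        for age in range(max_age + 1):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            s = cur[idx]
            states[idx, age] = s
            np.add.at(yis, (idx, s), 1)
            cost[idx] += lookup[scheme.group(age), s]
            u = rng.random(n)  # full-width draw keeps the stream layout fixed
            if age == max_age:
                states[idx, age + 1] = _DEAD
                break
            band = scheme.group(age)
            rows = matrices.probs[int(g), band][s]
            nxt = _pick(np.cumsum(rows, axis=1), u[idx])
            dying = idx[nxt == _DEAD]
            states[dying, age + 1] = _DEAD
            alive[dying] = False
            cur[idx] = nxt
        all_states.append(states)
        all_yis.append(yis)
        all_cost.append(cost)

    return PathwayCollection(
        genders=np.repeat(np.arange(N_GENDERS, dtype=np.int8), n_per_gender),
        states=np.concatenate(all_states),
        years_in_state=np.concatenate(all_yis),
        lifetime_cost=np.concatenate(all_cost),
        seed=seed,
    )


@dataclass(frozen=True)
class LifetimeCostSummary:
    """Distribution statistics of lifetime healthcare cost for one gender."""

    n_trials: int
    mean: float
    sd: float
    variance: float
    skewness: float  # third standardised central moment; NaN if degenerate
    kurtosis_excess: float  # fourth standardised moment minus 3
    kurtosis_raw: float
    minimum: float
    maximum: float
    p25: float
    p50: float
    p75: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def summarize_costs(collection: PathwayCollection, gender: Gender) -> LifetimeCostSummary:
    """Moment and quantile summary of lifetime cost for one gender.

    Quantiles use linear interpolation between order statistics; SD uses
    the n-1 denominator.  Shape statistics are undefined (NaN) when the
    costs are all identical.
    """
    x = collection.lifetime_cost[collection.gender_mask(gender)]
    if x.size == 0:
        raise ValueError(f"no pathways for gender {gender.name}")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    degenerate = not (sd > 0)
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    return LifetimeCostSummary(
        n_trials=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        variance=sd * sd,
        skewness=float("nan") if degenerate else float(stats.skew(x, bias=True)),
        kurtosis_excess=(
            float("nan") if degenerate else float(stats.kurtosis(x, fisher=True, bias=True))
        ),
        kurtosis_raw=(
            float("nan") if degenerate else float(stats.kurtosis(x, fisher=False, bias=True))
        ),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
    )


def summarize_years(collection: PathwayCollection) -> pd.DataFrame:
    """Mean/SD/min/max of years lived in each state, per gender.

    The per-gender means partition: summed over states they equal the mean
    pathway length.
    """
    rows = []
    for g in Gender:
        yis = collection.years_in_state[collection.gender_mask(g)]
        if yis.size == 0:
            continue
        for s in TRANSIENT_STATES:
            col = yis[:, int(s)]
            rows.append(
                {
                    "gender": g.name,
                    "state": s.name,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)) if col.size > 1 else float("nan"),
                    "min": int(col.min()),
                    "max": int(col.max()),
                }
            )
    return pd.DataFrame(rows)
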