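"""Exact (expected-value) propagation of a birth cohort through the chain.

A closed cohort starts at age 0 with a given (gender x state) composition
and is pushed through the stratified one-year transition matrices, one year
of age per cycle, until extinction.  Mass is real-valued: this is the exact
expectation of the microsimulation, not a random draw.

Occupancy follows a start-of-year convention: the state mass recorded at
age ``a`` counts one full person-year, including for people who die during
that year (their mass appears in DEAD at age ``a + 1``).  Expected years in
a state are therefore the occupancy sums divided by the initial gender
mass, and for an age-homogeneous chain they coincide with the row sums of
the fundamental matrix ``(I - Q)^{-1}`` applied to the initial mix.

Iteration stops when the surviving fraction drops below an extinction
tolerance or at a hard age cap (default 110), at which point all remaining
mass is moved to DEAD.  Because transition matrices switch at the band
boundaries {1, 15, 25, ..., 85}, occupancy curves show jumps there; these
are a property of the band construction, not smoothed away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import CostTable, TransitionMatrixSet
from .states import (
    CHRONIC_STATES,
    N_GENDERS,
    N_STATES,
    N_TRANSIENT,
    STATE_LABELS,
    Gender,
    HealthState,
    TRANSIENT_STATES,
)

__all__ = [
    "InitialMix",
    "CohortOccupancy",
    "CohortResult",
    "run_cohort",
    "expected_years",
    "yearly_mean_cost",
    "lifetime_mean_cost",
    "cohort_result",
]

_DEAD = HealthState.DEAD.value


@dataclass(frozen=True)
class InitialMix:
    """Joint probability over (gender, transient state) at age 0.

    ``shares`` has shape (2, 6) and sums to 1.  The default mirrors the
    composition of a contemporary under-1 population: about 96% healthy
    and a male share of 50.5%.
    """

    shares: np.ndarray

    def __post_init__(self) -> None:
        shares = np.asarray(self.shares, dtype=float)
        object.__setattr__(self, "shares", shares)
        if shares.shape != (N_GENDERS, N_TRANSIENT):
            raise ValueError(f"initial mix shape {shares.shape} != (2, 6)")
        if (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("initial mix must be non-negative and sum to 1")

    @classmethod
    def default(
        cls,
        male_share: float = 0.505,
        state_mix: np.ndarray | None = None,
    ) -> "InitialMix":
        if state_mix is None:
            # healthy newborn cohort; the residual mass covers neonatal acute
            # episodes and rare congenital chronic conditions
            state_mix = np.array([0.96, 0.03, 0.004, 0.005, 0.0007, 0.0003])
        state_mix = np.asarray(state_mix, dtype=float)
        state_mix = state_mix / state_mix.sum()
        shares = np.stack([(1 - male_share) * state_mix, male_share * state_mix])
        return cls(shares=shares)

    def gender_mass(self) -> np.ndarray:
        return self.shares.sum(axis=1)

    def conditional_state(self, gender: Gender) -> np.ndarray:
        row = self.shares[int(gender)]
        return row / row.sum()


@dataclass
class CohortOccupancy:
    """State mass per (age, gender, state incl. DEAD), start-of-year counts.

    ``mass`` has shape (n_ages, 2, 7); row 0 is age 0.  The final recorded
    row is followed by forced extinction (all mass in DEAD), which is not
    itself an occupancy row.
    """

    mass: np.ndarray
    size: float

    @property
    def n_ages(self) -> int:
        return self.mass.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.n_ages)

    def initial_gender_mass(self) -> np.ndarray:
        return self.mass[0].sum(axis=1)

    def survivors(self) -> np.ndarray:
        """Transient mass per (age, gender)."""
        return self.mass[:, :, :N_TRANSIENT].sum(axis=2)

    def to_long_df(self) -> pd.DataFrame:
        a, g, s = np.meshgrid(
            self.ages, np.arange(N_GENDERS), np.arange(N_STATES), indexing="ij"
        )
        return pd.DataFrame(
            {
                "age": a.ravel(),
                "gender": np.array(["F", "M"])[g.ravel()],
                "state": np.array(STATE_LABELS)[s.ravel()],
                "mass": self.mass.ravel(),
            }
        )


def run_cohort(
    matrices: TransitionMatrixSet,
    mix: InitialMix,
    size: float = 100_000,
    max_age: int = 110,
    extinction_tol: float = 1e-6,
) -> CohortOccupancy:
    """Propagate a birth cohort of ``size`` until extinction.

    ``extinction_tol`` is the surviving *fraction* of the cohort below which
    the run stops; remaining mass is then forced to DEAD.  The hard cap
    ``max_age`` bounds the run regardless (its year is still lived).
    """
    if max_age < 1:
        raise ValueError("max_age must be at least 1")
    matrices.validate()
    mass = np.zeros((N_GENDERS, N_STATES))
    mass[:, :N_TRANSIENT] = size * mix.shares
    rows = []
    age = 0
    while True:
        rows.append(mass.copy())
        alive = mass[:, :N_TRANSIENT].sum()
        if alive < extinction_tol * size or age >= max_age:
            break
        for g in range(N_GENDERS):
            band = matrices.scheme.group(age)
            mass[g] = mass[g] @ matrices.probs[g, band]
        age += 1
    return CohortOccupancy(mass=np.array(rows), size=float(size))


def expected_years(occ: CohortOccupancy) -> pd.DataFrame:
    """Expected years lived in each state, per gender (start-of-year counts).

    Returns a (state x gender) DataFrame in euros-free years; summing the
    six transient rows per gender gives total life expectancy at birth.
    """
    init = occ.initial_gender_mass()
    years = occ.mass[:, :, :N_TRANSIENT].sum(axis=0) / init[:, None]
    return pd.DataFrame(
        years.T, index=[s.name for s in TRANSIENT_STATES], columns=["F", "M"]
    )


def yearly_mean_cost(occ: CohortOccupancy, costs: CostTable) -> pd.DataFrame:
    """Mean annual cost per *survivor* at each age, per gender.

    Ages with no surviving mass yield NaN (undefined), not zero.
    """
    scheme = costs.scheme
    lookup = costs.effective  # (2, n_bands, 6)
    bands = np.array([scheme.group(a) for a in range(occ.n_ages)])
    per_state_cost = lookup[:, bands, :].transpose(1, 0, 2)  # (ages, 2, 6)
    transient = occ.mass[:, :, :N_TRANSIENT]
    total_cost = (transient * per_state_cost).sum(axis=2)
    survivors = transient.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(survivors > 0, total_cost / survivors, np.nan)
    return pd.DataFrame(mean, index=occ.ages, columns=["F", "M"])


def lifetime_mean_cost(occ: CohortOccupancy, costs: CostTable) -> pd.Series:
    """Expected lifetime healthcare cost per initial cohort member, by gender.

    With an age-invariant cost table this equals the dot product of expected
    years with the (gender, state) cost means.
    """
    scheme = costs.scheme
    lookup = costs.effective
    bands = np.array([scheme.group(a) for a in range(occ.n_ages)])
    per_state_cost = lookup[:, bands, :].transpose(1, 0, 2)
    total = (occ.mass[:, :, :N_TRANSIENT] * per_state_cost).sum(axis=(0, 2))
    return pd.Series(total / occ.initial_gender_mass(), index=["F", "M"])


@dataclass
class CohortResult:
    """Bundle of the cohort run and its derived summaries."""

    occupancy: CohortOccupancy
    expected_years: pd.DataFrame  # state x gender
    total_le: pd.Series  # per gender
    yearly_mean_cost: pd.DataFrame | None
    lifetime_mean_cost: pd.Series | None

    def chronic_years(self) -> pd.Series:
        chronic = [s.name for s in HealthState if s in CHRONIC_STATES]
        return self.expected_years.loc[chronic].sum()


def cohort_result(
    matrices: TransitionMatrixSet,
    mix: InitialMix,
    costs: CostTable | None = None,
    size: float = 100_000,
    max_age: int = 110,
    extinction_tol: float = 1e-6,
) -> CohortResult:
    occ = run_cohort(matrices, mix, size=size, max_age=max_age, extinction_tol=extinction_tol)
    ey = expected_years(occ)
    return CohortResult(
        occupancy=occ,
        expected_years=ey,
        total_le=ey.sum(axis=0),
        yearly_mean_cost=yearly_mean_cost(occ, costs) if costs is not None else None,
        lifetime_mean_cost=lifetime_mean_cost(occ, costs) if costs is not None else None,
    )
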