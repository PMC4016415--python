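"""Synthetic longitudinal registry generator.

No public person-year registry with aggregated CRG states exists, so this
module builds one with the statistical shape of an integrated-care
population database: ten age bands x two genders, first-order Markov yearly
state dynamics with an absorbing death state, mortality that increases with
both age band and morbidity severity, an elevated acute-episode probability
for women of childbearing age (pregnancy-related care), right-skewed annual
costs with gender x state means on the scale of published 2007 full-cost
figures, and in/out migration.

The generator is first-class, tested code: estimation and simulation are
validated against the *known* ground-truth matrices it produces.  Its
defaults were calibrated once, at design time, to a handful of population
anchors — roughly 65% of the cross-section healthy, ~96% of newborns
healthy, a 50.5% male share, and life expectancy at birth in the low 80s
for women and high 70s for men — and are not tuned beyond that.

One root seed drives independent per-purpose random streams (initial
population, state paths, migration, costs), so switching cost generation
on or off never perturbs the simulated health histories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import InitialMix, run_cohort
from .estimation import CostTable, TransitionMatrixSet
from .panel import PersonYearPanel
from .states import (
    DEFAULT_SCHEME,
    N_GENDERS,
    N_STATES,
    N_TRANSIENT,
    STATE_LABELS,
    AgeGroupScheme,
    Gender,
    HealthState,
)

__all__ = [
    "SynthConfig",
    "CostModel",
    "GroundTruth",
    "make_ground_truth",
    "generate_panel",
    "sample_annual_cost",
    "state_distribution_by_age",
    "cross_sectional_prevalence",
    "PYRAMID_SHARES",
    "DEFAULT_COST_MEANS",
]

_DEAD = HealthState.DEAD.value

# Population age-band shares of a 2007 reference cross-section (fractions).
PYRAMID_SHARES = np.array(
    [0.0108, 0.1435, 0.1117, 0.1778, 0.1686, 0.1290, 0.0976, 0.0791, 0.0612, 0.0207]
)
PYRAMID_SHARES = PYRAMID_SHARES / PYRAMID_SHARES.sum()

# Published 2007 mean annual full cost (euros) per gender x state, rows F, M.
DEFAULT_COST_MEANS = np.array(
    [
        [324.16, 1692.67, 1069.41, 2739.67, 11095.93, 5617.47],
        [227.42, 1195.57, 936.65, 2334.04, 10113.71, 5519.98],
    ]
)

# Baseline one-year death probability from the healthy state per age band
# (monotone by construction); genders and severities scale it below.
_BASE_MORTALITY = np.array(
    [1.5e-4, 1.5e-4, 2.0e-4, 3.0e-4, 5.0e-4, 1.0e-3, 2.5e-3, 9.0e-3, 4.2e-2, 1.6e-1]
)
_GENDER_MORTALITY = np.array([0.66, 1.16])  # F, M
# Severity multipliers relative to healthy, per transient state.
_SEVERITY_MULT = np.array([1.0, 1.3, 1.45, 1.55, 12.0, 22.0])
# Absolute yearly mortality floors: severe multi-system disease (E79) and
# metastatic malignancy (E8) are high-lethality at any age.
_SEVERITY_FLOOR = np.array([0.0, 0.0, 0.0, 0.0, 0.28, 0.33])
_MORTALITY_CAP = 0.6


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    ``severity_gradient`` and ``age_mortality_gradient`` are positive
    exponents applied to the baseline severity and age mortality ratios
    (1.0 reproduces the defaults; larger values steepen the gradient while
    preserving monotonicity).  ``female_acute_multiplier`` scales the
    healthy-to-acute probability for women in the 15-44 bands.
    """

    n_individuals: int = 20_000
    years: tuple[int, ...] = (2004, 2005, 2006, 2007)
    seed: int = 0
    severity_gradient: float = 1.0
    age_mortality_gradient: float = 1.0
    female_acute_multiplier: float = 1.8
    cost_cv: float = 1.2
    out_migration_rate: float = 0.01
    in_migration_rate: float = 0.01
    male_share: float = 0.505
    scheme: AgeGroupScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        years = tuple(sorted(self.years))
        object.__setattr__(self, "years", years)
        if len(years) < 2:
            raise ValueError("at least 2 calendar years are needed to observe transitions")
        for name in ("severity_gradient", "age_mortality_gradient", "female_acute_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cost_cv < 0:
            raise ValueError("cost_cv must be non-negative")
        for name in ("out_migration_rate", "in_migration_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.male_share < 1:
            raise ValueError("male_share must be in (0, 1)")


@dataclass(frozen=True)
class CostModel:
    """Right-skewed annual-cost family: gamma parameterised by mean and CV.

    With coefficient of variation ``cv`` the gamma shape is ``1/cv^2`` and
    the scale ``mean * cv^2``; skewness is ``2 cv > 0``.  ``cv = 0``
    degenerates to a point mass at the mean.
    """

    means: np.ndarray  # (2, 6) euros
    cv: float = 1.2

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        if means.shape != (N_GENDERS, N_TRANSIENT) or (means <= 0).any():
            raise ValueError("cost means must be positive with shape (2, 6)")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    def sample(self, gender: Gender, state: HealthState, rng: np.random.Generator, size=None):
        if state is HealthState.DEAD:
            raise ValueError("no annual cost is defined for the DEAD state")
        mean = self.means[int(gender), int(state)]
        if self.cv == 0:
            return mean if size is None else np.full(size, mean)
        shape = 1.0 / self.cv**2
        return rng.gamma(shape, mean / shape, size=size)

    def sample_by_index(self, g: np.ndarray, s: np.ndarray, rng: np.random.Generator):
        """Vectorised draw for index arrays of equal length (transient states)."""
        mean = self.means[g, s]
        if self.cv == 0:
            return mean.copy()
        shape = 1.0 / self.cv**2
        return rng.gamma(shape, mean / shape)

    def to_cost_table(self, scheme: AgeGroupScheme = DEFAULT_SCHEME) -> CostTable:
        return CostTable(base=self.means.copy(), scheme=scheme)


def sample_annual_cost(
    model: CostModel, gender: Gender, state: HealthState, rng: np.random.Generator, size=None
):
    """Draw annual cost(s) in euros for a (gender, state) cell."""
    return model.sample(gender, state, rng, size=size)


@dataclass(frozen=True)
class GroundTruth:
    """Known-true structures behind a synthetic registry."""

    matrices: TransitionMatrixSet
    initial_mix: InitialMix
    cost_model: CostModel
    out_migration_rate: float
    in_migration_rate: float
    scheme: AgeGroupScheme = DEFAULT_SCHEME


def _transient_weights(config: SynthConfig) -> np.ndarray:
    """Pre-mortality destination weights among transient states, (2, 10, 6, 6)."""
    a = np.arange(10, dtype=float)
    W = np.zeros((N_GENDERS, 10, N_TRANSIENT, N_TRANSIENT))

    acute = np.array([0.16, 0.07, 0.05, 0.05, 0.05, 0.05, 0.05, 0.055, 0.065, 0.075])
    onset34 = np.array([0.010, 0.014, 0.018, 0.022, 0.026, 0.030, 0.034, 0.038, 0.040, 0.040])
    onset56 = np.array([0.0005, 0.0008, 0.001, 0.002, 0.005, 0.015, 0.05, 0.10, 0.14, 0.16])
    onset79 = 0.008 * (a / 9) ** 3 + 0.0001
    onset8 = 0.004 * (a / 9) ** 3 + 0.00005

    for g in Gender:
        gi = int(g)
        e1_acute = acute.copy()
        if g is Gender.F:
            e1_acute[2:5] *= config.female_acute_multiplier  # bands 15-24, 25-34, 35-44
        # E1 healthy
        W[gi, :, 0, 1] = e1_acute
        W[gi, :, 0, 2] = onset34
        W[gi, :, 0, 3] = onset56
        W[gi, :, 0, 4] = onset79
        W[gi, :, 0, 5] = onset8
        # E2 acute: mostly resolves back to healthy, some chronification
        W[gi, :, 1, 0] = 0.60 - 0.02 * a
        W[gi, :, 1, 2] = 0.05
        W[gi, :, 1, 3] = 0.002 + 0.05 * (a / 9) ** 3
        W[gi, :, 1, 4] = 0.012 * (a / 9) ** 3 + 0.0002
        W[gi, :, 1, 5] = 0.006 * (a / 9) ** 3 + 0.0002
        # E34 minor chronic: partial remission, progression to E56
        W[gi, :, 2, 0] = 0.28 - 0.018 * a
        W[gi, :, 2, 1] = 0.03
        W[gi, :, 2, 3] = 0.004 + 0.11 * (a / 9) ** 3
        W[gi, :, 2, 4] = 0.014 * (a / 9) ** 3 + 0.0002
        W[gi, :, 2, 5] = 0.006 * (a / 9) ** 3 + 0.0002
        # E56 significant chronic: sticky, slow progression
        W[gi, :, 3, 0] = np.maximum(0.050 - 0.006 * a, 0.003)
        W[gi, :, 3, 1] = 0.015
        W[gi, :, 3, 2] = np.maximum(0.030 - 0.003 * a, 0.008)
        W[gi, :, 3, 4] = 0.016 * (a / 9) ** 3 + 0.0004
        W[gi, :, 3, 5] = 0.010 * (a / 9) ** 3 + 0.0004
        # E79 multi-system / catastrophic
        W[gi, :, 4, 3] = 0.40
        W[gi, :, 4, 5] = 0.006
        # E8 malignancies
        W[gi, :, 5, 3] = 0.30

    off = W.sum(axis=-1)
    if (off >= 1).any():
        raise ValueError("transient off-diagonal weights exceed 1; config too extreme")
    diag = 1.0 - off
    W[:, :, np.arange(N_TRANSIENT), np.arange(N_TRANSIENT)] = diag
    return W


def _mortality(config: SynthConfig) -> np.ndarray:
    """One-year death probability q[gender, band, state], capped and monotone."""
    age_ratio = (_BASE_MORTALITY / _BASE_MORTALITY[0]) ** config.age_mortality_gradient
    q_age = _BASE_MORTALITY[0] * age_ratio
    sev = _SEVERITY_MULT**config.severity_gradient
    q = _GENDER_MORTALITY[:, None, None] * q_age[None, :, None] * sev[None, None, :]
    q = np.maximum(q, _SEVERITY_FLOOR[None, None, :])
    return np.minimum(q, _MORTALITY_CAP)


def make_ground_truth(config: SynthConfig = SynthConfig()) -> GroundTruth:
    """Build the known-true transition matrices, initial mix and cost model."""
    W = _transient_weights(config)
    q = _mortality(config)
    probs = np.zeros((N_GENDERS, config.scheme.n_groups, N_STATES, N_STATES))
    probs[:, :, :N_TRANSIENT, :N_TRANSIENT] = (1.0 - q[..., None]) * W
    probs[:, :, :N_TRANSIENT, _DEAD] = q
    probs[:, :, _DEAD, _DEAD] = 1.0
    matrices = TransitionMatrixSet(probs=probs, scheme=config.scheme, provenance="synthetic")
    matrices.validate()
    return GroundTruth(
        matrices=matrices,
        initial_mix=InitialMix.default(male_share=config.male_share),
        cost_model=CostModel(means=DEFAULT_COST_MEANS.copy(), cv=config.cost_cv),
        out_migration_rate=config.out_migration_rate,
        in_migration_rate=config.in_migration_rate,
        scheme=config.scheme,
    )


def state_distribution_by_age(
    truth: GroundTruth, max_age: int = 110
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional state distribution of survivors at each age.

    Returns ``(dist, survival)``: ``dist[age, gender, state]`` sums to 1
    over the six transient states (uniform where no mass survives), and
    ``survival[age, gender]`` is the surviving fraction of the birth
    cohort.  Computed by exact cohort propagation of the ground truth.
    """
    occ = run_cohort(truth.matrices, truth.initial_mix, size=1.0, max_age=max_age,
                     extinction_tol=1e-12)
    transient = occ.mass[:, :, :N_TRANSIENT]
    surv = transient.sum(axis=2)
    n_ages = max_age + 1
    dist = np.full((n_ages, N_GENDERS, N_TRANSIENT), 1.0 / N_TRANSIENT)
    k = min(occ.n_ages, n_ages)
    with np.errstate(invalid="ignore"):
        d = transient[:k] / surv[:k, :, None]
    ok = surv[:k] > 0
    dist[:k][ok] = d[ok]
    survival = np.zeros((n_ages, N_GENDERS))
    survival[:k] = surv[:k] / occ.initial_gender_mass()[None, :]
    return dist, survival


def cross_sectional_prevalence(truth: GroundTruth, max_age: int = 99) -> np.ndarray:
    """Stationary cross-sectional state prevalence implied by the ground truth.

    Survivor state distributions by age are weighted by the reference
    population pyramid (uniform within bands, last band spanning 85 to
    ``max_age``) and by the configured gender split.
    """
    dist, _ = state_distribution_by_age(truth, max_age=max_age)
    edges = list(truth.scheme.boundaries) + [max_age + 1]
    weights = np.zeros(max_age + 1)
    for b in range(truth.scheme.n_groups):
        lo, hi = edges[b], edges[b + 1]
        weights[lo:hi] = PYRAMID_SHARES[b] / (hi - lo)
    weights = weights / weights.sum()
    gender_share = truth.initial_mix.gender_mass()
    return np.einsum("a,g,ags->s", weights, gender_share, dist)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------


def _draw_ages(n: int, rng: np.random.Generator, scheme: AgeGroupScheme) -> np.ndarray:
    """Ages from the reference pyramid, uniform within bands (85+ spans 85-99)."""
    edges = list(scheme.boundaries) + [100]
    bands = rng.choice(scheme.n_groups, size=n, p=PYRAMID_SHARES)
    lo = np.array(edges)[bands]
    hi = np.array(edges)[bands + 1]
    return lo + np.floor(rng.random(n) * (hi - lo)).astype(np.int64)


def _draw_states(
    dist: np.ndarray, genders: np.ndarray, ages: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw transient states from per-(age, gender) conditional distributions."""
    ages_c = np.minimum(ages, dist.shape[0] - 1)
    rows = dist[ages_c, genders]  # (n, 6)
    cdf = np.cumsum(rows, axis=1)
    u = rng.random(len(ages))
    return np.minimum((cdf <= u[:, None]).sum(axis=1), N_TRANSIENT - 1)


def generate_panel(truth: GroundTruth, config: SynthConfig) -> PersonYearPanel:
    """Simulate a person-year panel that follows the ground truth exactly.

    The initial cross-section is drawn from the reference pyramid with
    states from the truth's survivor distribution at each age; subsequent
    years evolve by the true first-order Markov dynamics.  Deaths produce
    an explicit DEAD record (cost 0); out-migrants are censored without
    one; in-migrants enter in later years with pyramid ages.  The same
    seed always yields a byte-identical panel.
    """
    scheme = config.scheme
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_states, rng_migr, rng_costs = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    dist, _ = state_distribution_by_age(truth)

    years = config.years
    n0 = config.n_individuals
    genders = (rng_init.random(n0) < config.male_share).astype(np.int64)
    ages = _draw_ages(n0, rng_init, scheme)
    states = _draw_states(dist, genders, ages, rng_init)
    ids = np.arange(n0, dtype=np.int64)
    next_id = n0

    rec_pid, rec_year, rec_gender, rec_age, rec_state = [], [], [], [], []

    def emit(pid, year, g, age, s):
        rec_pid.append(pid)
        rec_year.append(np.full(len(pid), year, dtype=np.int64))
        rec_gender.append(g)
        rec_age.append(age)
        rec_state.append(s)

    for k, year in enumerate(years):
        emit(ids, year, genders, ages, states)
        if k == len(years) - 1:
            break
        # out-migration: censored, no further records, no DEAD record
        stay = rng_migr.random(len(ids)) >= config.out_migration_rate
        ids, genders, ages, states = ids[stay], genders[stay], ages[stay], states[stay]
        # Markov step under the true matrices
        bands = np.searchsorted(scheme.boundaries, ages, side="right") - 1
        rows = truth.matrices.probs[genders, bands, states]  # (n, 7)
        cdf = np.cumsum(rows, axis=1)
        u = rng_states.random(len(ids))
        nxt = np.minimum((cdf <= u[:, None]).sum(axis=1), N_STATES - 1)
        ages = ages + 1
        died = nxt == _DEAD
        emit(ids[died], years[k + 1], genders[died], ages[died], np.full(died.sum(), _DEAD))
        ids, genders, ages, states = ids[~died], genders[~died], ages[~died], nxt[~died]
        # in-migration: new arrivals observable from the next year on
        n_new = int(rng_migr.binomial(n0, config.in_migration_rate))
        if n_new:
            g_new = (rng_migr.random(n_new) < config.male_share).astype(np.int64)
            a_new = _draw_ages(n_new, rng_migr, scheme)
            s_new = _draw_states(dist, g_new, a_new, rng_migr)
            id_new = np.arange(next_id, next_id + n_new, dtype=np.int64)
            next_id += n_new
            ids = np.concatenate([ids, id_new])
            genders = np.concatenate([genders, g_new])
            ages = np.concatenate([ages, a_new])
            states = np.concatenate([states, s_new])
            order = np.argsort(ids, kind="stable")
            ids, genders, ages, states = ids[order], genders[order], ages[order], states[order]

    pid = np.concatenate(rec_pid)
    year = np.concatenate(rec_year)
    g = np.concatenate(rec_gender)
    age = np.concatenate(rec_age)
    st = np.concatenate(rec_state)

    cost = np.zeros(len(pid))
    transient = st != _DEAD
    cost[transient] = truth.cost_model.sample_by_index(g[transient], st[transient], rng_costs)
    cost = np.round(cost, 2)

    width = max(7, len(str(max(next_id, 1))))
    df = pd.DataFrame(
        {
            "person_id": np.char.add("P", np.char.zfill(pid.astype(str), width)),
            "year": year,
            "gender": np.array(["F", "M"])[g],
            "age": age,
            "state": np.array(STATE_LABELS)[st],
            "cost": cost,
        }
    )
    return PersonYearPanel(df)
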