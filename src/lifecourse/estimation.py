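"""Stratified transition-matrix estimation, stationarity testing, cost table.

Given a person-year panel, transitions are counted per (gender, age band)
stratum and per period (pair of consecutive calendar years), with the
stratum assigned by the age at the *origin* year of each transition.  The
maximum-likelihood estimate of each one-year transition probability pools
the counts over periods:

    p_hat[i, j] = sum_t n[i, j](t) / sum_z sum_t n[i, z](t)

Whether pooling is legitimate — whether the chain is time-homogeneous over
the observation window — is checked with the Anderson–Goodman chi-squared
homogeneity test, which compares each period's matrix against the pool:

    X2 = sum_t sum_{i,j} n_i(t-1) * (p_hat[i,j](t) - p_hat[i,j])^2 / p_hat[i,j]

asymptotically chi-squared with m(m-1)(P-1) degrees of freedom for m states
and P period matrices.  Cells whose pooled probability is zero contribute
0/0 terms; they are skipped and the degrees of freedom reduced accordingly
(both the nominal and the adjusted df are reported).

The cost table attaches a mean annual euro cost to every (gender, state)
cell, optionally refined by age band with a small-cell fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PersonYearPanel
from .states import (
    DEFAULT_SCHEME,
    GENDER_LABELS,
    N_GENDERS,
    N_STATES,
    N_TRANSIENT,
    STATE_LABELS,
    AgeGroupScheme,
    Gender,
    HealthState,
    ages_to_groups,
)

__all__ = [
    "TransitionCounts",
    "TransitionMatrixSet",
    "StationarityResult",
    "CostTable",
    "count_transitions",
    "estimate_matrices",
    "estimate_matrices_per_period",
    "anderson_goodman",
    "stationarity_test",
    "stationarity_report",
    "estimate_cost_table",
    "write_matrices",
    "read_matrices",
]

_DEAD = HealthState.DEAD.value


# ---------------------------------------------------------------------------
# transition counts
# ---------------------------------------------------------------------------


@dataclass
class TransitionCounts:
    """Stratified transition counts ``counts[gender, band, period, i, j]``.

    ``periods`` lists the (origin year, destination year) pairs in order.
    Row totals ``n_i(t-1)`` are ``counts.sum(axis=-1)``.
    """

    counts: np.ndarray  # int64, shape (2, n_bands, P, m, m)
    periods: tuple[tuple[int, int], ...]
    scheme: AgeGroupScheme = DEFAULT_SCHEME

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def pooled(self) -> np.ndarray:
        """Counts summed over periods, shape (2, n_bands, m, m)."""
        return self.counts.sum(axis=2)

    def row_totals(self) -> np.ndarray:
        """``n_i(t-1)`` per stratum and period, shape (2, n_bands, P, m)."""
        return self.counts.sum(axis=-1)


def count_transitions(
    panel: PersonYearPanel, scheme: AgeGroupScheme = DEFAULT_SCHEME
) -> TransitionCounts:
    """Count one-year transitions per (gender, age band) stratum and period.

    Only consecutive-year record pairs of one person produce a transition;
    a gap (missing next year) is censoring and contributes nothing.  The
    stratum is determined by the age at the origin year.
    """
    years = panel.years
    if len(years) < 2:
        raise ValueError("no transitions observable: panel covers a single year")
    periods = tuple((y, y + 1) for y in years[:-1] if y + 1 in years)
    if not periods:
        raise ValueError("no transitions observable: no consecutive year pair in panel")
    period_of_origin = {p[0]: k for k, p in enumerate(periods)}

    df = panel.df
    pid = df["person_id"].to_numpy()
    year = df["year"].to_numpy()
    state = df["state"].map({s: i for i, s in enumerate(STATE_LABELS)}).to_numpy()
    gender = (df["gender"] == "M").to_numpy().astype(np.int64)
    band = ages_to_groups(df["age"].to_numpy(), scheme)

    nxt_same = np.concatenate((pid[1:] == pid[:-1], [False]))
    dyear = np.concatenate((year[1:] - year[:-1], [0]))
    origin = nxt_same & (dyear == 1) & (state != _DEAD)

    idx = np.flatnonzero(origin)
    p_idx = np.array([period_of_origin[y] for y in year[idx]], dtype=np.int64)
    counts = np.zeros(
        (N_GENDERS, scheme.n_groups, len(periods), N_STATES, N_STATES), dtype=np.int64
    )
    np.add.at(counts, (gender[idx], band[idx], p_idx, state[idx], state[idx + 1]), 1)
    return TransitionCounts(counts=counts, periods=periods, scheme=scheme)


# ---------------------------------------------------------------------------
# maximum-likelihood matrices
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrixSet:
    """Row-stochastic one-year transition matrices per (gender, age band).

    ``probs`` has shape ``(2, n_bands, m, m)`` in the fixed state order;
    the DEAD row of every matrix is the unit vector on DEAD.
    """

    probs: np.ndarray
    scheme: AgeGroupScheme = DEFAULT_SCHEME
    provenance: str = "pooled"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (N_GENDERS, self.scheme.n_groups, N_STATES, N_STATES)
        if self.probs.shape != expected:
            raise ValueError(f"matrix set shape {self.probs.shape} != {expected}")

    def validate(self, atol: float = 1e-10) -> None:
        p = self.probs
        if (p < -atol).any() or (p > 1 + atol).any():
            raise ValueError("transition probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=-1), 1.0, atol=atol):
            raise ValueError("transition matrix rows do not sum to 1")
        dead_row = np.zeros(N_STATES)
        dead_row[_DEAD] = 1.0
        if not np.allclose(p[:, :, _DEAD, :], dead_row, atol=atol):
            raise ValueError("DEAD row is not absorbing")

    def matrix(self, gender: Gender, band: int) -> np.ndarray:
        return self.probs[int(gender), band]

    def to_long_df(self) -> pd.DataFrame:
        g, b, i, j = np.meshgrid(
            np.arange(N_GENDERS),
            np.arange(self.scheme.n_groups),
            np.arange(N_STATES),
            np.arange(N_STATES),
            indexing="ij",
        )
        labels = self.scheme.labels
        return pd.DataFrame(
            {
                "gender": np.array(GENDER_LABELS)[g.ravel()],
                "age_group": np.array(labels)[b.ravel()],
                "from_state": np.array(STATE_LABELS)[i.ravel()],
                "to_state": np.array(STATE_LABELS)[j.ravel()],
                "probability": self.probs.ravel(),
            }
        )


def _rows_to_probs(pooled: np.ndarray) -> np.ndarray:
    """Turn stratified count blocks into row-stochastic matrices.

    Zero-count origin rows fall back to the identity row (stay in state),
    with a warning; the DEAD row is always forced absorbing.
    """
    pooled = pooled.astype(float)
    totals = pooled.sum(axis=-1, keepdims=True)
    probs = np.divide(pooled, totals, out=np.zeros_like(pooled), where=totals > 0)
    empty = totals[..., 0] == 0
    empty_transient = empty.copy()
    empty_transient[..., _DEAD] = False
    if empty_transient.any():
        warnings.warn(
            f"{int(empty_transient.sum())} origin rows with no observed transitions; "
            "falling back to identity (stay-in-state) rows",
            stacklevel=3,
        )
        idx = np.nonzero(empty_transient)
        probs[idx + (idx[-1],)] = 1.0  # stay-in-state: unit mass on the diagonal
    probs[..., _DEAD, :] = 0.0
    probs[..., _DEAD, _DEAD] = 1.0
    return probs


def estimate_matrices(counts: TransitionCounts) -> TransitionMatrixSet:
    """Pooled maximum-likelihood transition matrices (counts summed over periods)."""
    probs = _rows_to_probs(counts.pooled())
    mset = TransitionMatrixSet(probs=probs, scheme=counts.scheme, provenance="pooled")
    mset.validate()
    return mset


def estimate_matrices_per_period(counts: TransitionCounts) -> list[TransitionMatrixSet]:
    """One maximum-likelihood matrix set per period (no pooling over t)."""
    out = []
    for k, (y0, y1) in enumerate(counts.periods):
        probs = _rows_to_probs(counts.counts[:, :, k])
        mset = TransitionMatrixSet(
            probs=probs, scheme=counts.scheme, provenance=f"period {y0}-{y1}"
        )
        mset.validate()
        out.append(mset)
    return out


# ---------------------------------------------------------------------------
# Anderson–Goodman stationarity (homogeneity) test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationarityResult:
    gender: str
    age_group: str
    statistic: float
    df_nominal: int
    df_adjusted: int
    p_value: float
    stationary: bool
    alpha: float


def anderson_goodman(period_counts: np.ndarray) -> tuple[float, int, int, float]:
    """Chi-squared homogeneity test of P period count matrices against their pool.

    Parameters
    ----------
    period_counts
        Integer array of shape ``(P, m, m)``: transition counts per period.

    Returns
    -------
    (statistic, df_nominal, df_adjusted, p_value)
        ``df_nominal = m (m - 1) (P - 1)``.  Cells with pooled probability
        zero are skipped (their terms are 0/0) and each removes ``P - 1``
        degrees of freedom; an origin row with no observations at all drops
        its entire ``(m - 1)(P - 1)`` block.  The p-value is the upper tail
        of the chi-squared distribution at ``df_adjusted`` (1.0 if the
        adjusted df is zero).
    """
    c = np.asarray(period_counts, dtype=float)
    if c.ndim != 3 or c.shape[1] != c.shape[2]:
        raise ValueError(f"period counts must have shape (P, m, m), got {c.shape}")
    n_periods, m, _ = c.shape
    if n_periods < 2:
        raise ValueError("stationarity test undefined with a single period")

    pooled = c.sum(axis=0)
    row_tot = pooled.sum(axis=1, keepdims=True)
    p_pool = np.divide(pooled, row_tot, out=np.zeros_like(pooled), where=row_tot > 0)

    n_prev = c.sum(axis=2)  # (P, m)
    p_t = np.divide(c, n_prev[:, :, None], out=np.zeros_like(c), where=n_prev[:, :, None] > 0)

    live = p_pool > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_prev[:, :, None] * (p_t - p_pool[None]) ** 2 / p_pool[None]
    statistic = float(terms[:, live].sum())

    df_nominal = m * (m - 1) * (n_periods - 1)
    k_per_row = live.sum(axis=1)  # positive cells per origin row
    df_adjusted = int((np.maximum(k_per_row - 1, 0)).sum() * (n_periods - 1))
    p_value = float(stats.chi2.sf(statistic, df_adjusted)) if df_adjusted > 0 else 1.0
    return statistic, df_nominal, df_adjusted, p_value


def stationarity_test(
    counts: TransitionCounts, alpha: float = 0.05
) -> list[StationarityResult]:
    """Run the homogeneity test in every (gender, age band) stratum.

    The test informs but never blocks: non-stationary strata are flagged in
    the result, and downstream stages still use the pooled matrices.
    """
    if counts.n_periods < 2:
        raise ValueError("stationarity test requires at least two periods")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    results = []
    labels = counts.scheme.labels
    for g in Gender:
        for b in range(counts.scheme.n_groups):
            stat, df_nom, df_adj, p = anderson_goodman(counts.counts[int(g), b])
            results.append(
                StationarityResult(
                    gender=g.name,
                    age_group=labels[b],
                    statistic=stat,
                    df_nominal=df_nom,
                    df_adjusted=df_adj,
                    p_value=p,
                    stationary=p >= alpha,
                    alpha=alpha,
                )
            )
    return results


def stationarity_report(results: list[StationarityResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    df["decision"] = np.where(df["stationary"], "stationary", "non-stationary")
    return df[
        ["gender", "age_group", "statistic", "df_nominal", "df_adjusted", "p_value", "decision"]
    ]


# ---------------------------------------------------------------------------
# cost table
# ---------------------------------------------------------------------------


@dataclass
class CostTable:
    """Mean annual cost (euros) per (gender, transient state), optionally by age band.

    ``base`` has shape ``(2, 6)``; ``by_band`` (if present) has shape
    ``(2, n_bands, 6)`` with NaN marking cells that fall back to ``base``.
    ``effective`` resolves the fallback into a dense lookup array.
    """

    base: np.ndarray
    by_band: np.ndarray | None = None
    scheme: AgeGroupScheme = DEFAULT_SCHEME
    year_basis: int = 2007

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        if self.base.shape != (N_GENDERS, N_TRANSIENT):
            raise ValueError(f"cost table base shape {self.base.shape} != (2, 6)")
        if np.isnan(self.base).any() or (self.base < 0).any():
            raise ValueError("cost table must have a non-negative mean for every "
                             "(gender, state) cell")
        if self.by_band is not None:
            self.by_band = np.asarray(self.by_band, dtype=float)
            expected = (N_GENDERS, self.scheme.n_groups, N_TRANSIENT)
            if self.by_band.shape != expected:
                raise ValueError(f"by-band cost shape {self.by_band.shape} != {expected}")

    @property
    def effective(self) -> np.ndarray:
        """Dense lookup ``(2, n_bands, 6)`` with fallback cells filled from base."""
        full = np.broadcast_to(
            self.base[:, None, :], (N_GENDERS, self.scheme.n_groups, N_TRANSIENT)
        ).copy()
        if self.by_band is not None:
            mask = ~np.isnan(self.by_band)
            full[mask] = self.by_band[mask]
        return full

    def cost(self, gender: Gender, band: int, state: HealthState) -> float:
        if state is HealthState.DEAD:
            raise ValueError("no annual cost is defined for the DEAD state")
        return float(self.effective[int(gender), band, int(state)])

    def to_long_df(self) -> pd.DataFrame:
        rows = []
        labels = self.scheme.labels
        for g in Gender:
            for s in range(N_TRANSIENT):
                rows.append((g.name, "all", STATE_LABELS[s], self.base[int(g), s]))
            if self.by_band is not None:
                for b in range(self.scheme.n_groups):
                    for s in range(N_TRANSIENT):
                        v = self.by_band[int(g), b, s]
                        if not np.isnan(v):
                            rows.append((g.name, labels[b], STATE_LABELS[s], v))
        return pd.DataFrame(rows, columns=["gender", "age_group", "state", "mean_cost"])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long_df().to_csv(path, index=False, float_format="%.6f")
        return path

    @classmethod
    def read(cls, path: str | Path, scheme: AgeGroupScheme = DEFAULT_SCHEME) -> "CostTable":
        df = pd.read_csv(path)
        base = np.full((N_GENDERS, N_TRANSIENT), np.nan)
        by_band = np.full((N_GENDERS, scheme.n_groups, N_TRANSIENT), np.nan)
        band_of = {lab: i for i, lab in enumerate(scheme.labels)}
        any_band = False
        for row in df.itertuples(index=False):
            g = Gender[row.gender].value
            s = HealthState[row.state].value
            if row.age_group == "all":
                base[g, s] = row.mean_cost
            else:
                by_band[g, band_of[row.age_group], s] = row.mean_cost
                any_band = True
        return cls(base=base, by_band=by_band if any_band else None, scheme=scheme)


def estimate_cost_table(
    panel: PersonYearPanel,
    scheme: AgeGroupScheme | None = None,
    min_cell: int = 30,
) -> CostTable:
    """Arithmetic-mean annual cost per cell from an observed panel.

    With ``scheme`` given, (gender, band, state) cells with at least
    ``min_cell`` person-years refine the table; smaller cells fall back to
    the (gender, state) aggregate.  A (gender, state) cell with no
    person-years at all borrows the state's mean pooled over genders.
    """
    if not panel.has_cost:
        raise ValueError("panel has no cost column; cannot estimate a cost table")
    df = panel.df
    df = df[(df["state"] != HealthState.DEAD.name) & df["cost"].notna()]
    if df.empty:
        raise ValueError("panel has no costed transient person-years")

    g = (df["gender"] == "M").to_numpy().astype(int)
    s = df["state"].map({lab: i for i, lab in enumerate(STATE_LABELS)}).to_numpy()
    c = df["cost"].to_numpy(dtype=float)

    sums = np.zeros((N_GENDERS, N_TRANSIENT))
    ns = np.zeros((N_GENDERS, N_TRANSIENT))
    np.add.at(sums, (g, s), c)
    np.add.at(ns, (g, s), 1)
    with np.errstate(invalid="ignore"):
        base = sums / ns
    # empty (gender, state) cell: borrow the state mean pooled over genders
    state_mean = np.divide(
        sums.sum(0), ns.sum(0), out=np.zeros(N_TRANSIENT), where=ns.sum(0) > 0
    )
    missing = ns == 0
    if missing.any():
        if (ns.sum(0)[missing.any(0)] == 0).any():
            raise ValueError("some transient state has no costed person-years at all")
        warnings.warn(
            f"{int(missing.sum())} empty (gender, state) cost cells filled with the "
            "pooled state mean",
            stacklevel=2,
        )
        base[missing] = np.broadcast_to(state_mean, base.shape)[missing]

    by_band = None
    if scheme is not None:
        b = ages_to_groups(df["age"].to_numpy(), scheme)
        sums_b = np.zeros((N_GENDERS, scheme.n_groups, N_TRANSIENT))
        ns_b = np.zeros((N_GENDERS, scheme.n_groups, N_TRANSIENT))
        np.add.at(sums_b, (g, b, s), c)
        np.add.at(ns_b, (g, b, s), 1)
        with np.errstate(invalid="ignore"):
            by_band = np.where(ns_b >= min_cell, sums_b / np.maximum(ns_b, 1), np.nan)
    return CostTable(base=base, by_band=by_band, scheme=scheme or DEFAULT_SCHEME)


# ---------------------------------------------------------------------------
# matrix-set file I/O
# ---------------------------------------------------------------------------


def write_matrices(mset: TransitionMatrixSet, path: str | Path) -> Path:
    """Write a matrix set as long CSV (gender, age_group, from, to, probability)."""
    path = Path(path)
    mset.to_long_df().to_csv(path, index=False, float_format="%.12f")
    return path


def read_matrices(
    path: str | Path, scheme: AgeGroupScheme = DEFAULT_SCHEME
) -> TransitionMatrixSet:
    df = pd.read_csv(path)
    probs = np.zeros((N_GENDERS, scheme.n_groups, N_STATES, N_STATES))
    band_of = {lab: i for i, lab in enumerate(scheme.labels)}
    g = df["gender"].map({lab: i for i, lab in enumerate(GENDER_LABELS)}).to_numpy()
    b = df["age_group"].map(band_of).to_numpy()
    i = df["from_state"].map(lambda x: HealthState[x].value).to_numpy()
    j = df["to_state"].map(lambda x: HealthState[x].value).to_numpy()
    probs[g, b, i, j] = df["probability"].to_numpy()
    mset = TransitionMatrixSet(probs=probs, scheme=scheme, provenance=f"file:{path}")
    mset.validate(atol=1e-10)
    return mset
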