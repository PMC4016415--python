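"""Person-year panel: the longitudinal registry container and its file I/O.

A panel holds one health-state observation per person per calendar year,
plus gender, completed age and (optionally) the annual healthcare cost in
euros.  Death is an explicit record (state ``DEAD`` in the year of death);
a sequence that simply stops without a ``DEAD`` record is censoring
(out-migration).  Gaps in a person's year sequence are allowed — they are
reported by validation and contribute no transitions downstream — but age
must always track calendar time (equal increments).

The interchange format is a UTF-8 CSV with header
``person_id,year,gender,age,state[,cost]``; costs use ``.`` as the decimal
separator and are preserved to 2 decimals (euro cents).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

from .states import GENDER_LABELS, STATE_LABELS, Gender, HealthState

REQUIRED_COLUMNS = ("person_id", "year", "gender", "age", "state")
_DEAD = HealthState.DEAD.name


class PanelValidationError(ValueError):
    """A panel violates a structural invariant; the message names the culprit."""


class PersonYearRecord(NamedTuple):
    person_id: str
    year: int
    gender: Gender
    age: int
    state: HealthState
    cost: Optional[float] = None


@dataclass(frozen=True)
class ValidationReport:
    """Summary of a successful panel validation."""

    n_records: int
    n_persons: int
    years: tuple[int, ...]
    has_cost: bool
    n_gap_persons: int
    gap_person_ids: tuple[str, ...]  # sample, at most 10


class PersonYearPanel:
    """Validated longitudinal person-year panel.

    Wraps a :class:`pandas.DataFrame` sorted by ``(person_id, year)``.
    Construction validates all invariants (idempotently, without mutating
    the input) and stores a :class:`ValidationReport` under ``.report``.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"panel is missing required columns: {missing}")
        df["person_id"] = df["person_id"].astype(str)
        for col in ("year", "age"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        df = df.sort_values(["person_id", "year"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.report = self._validate() if validate else None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PersonYearRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[PersonYearRecord]:
        has_cost = self.has_cost
        out = []
        for row in self.df.itertuples(index=False):
            cost = float(row.cost) if has_cost and not pd.isna(row.cost) else None
            out.append(
                PersonYearRecord(
                    row.person_id,
                    int(row.year),
                    Gender[row.gender],
                    int(row.age),
                    HealthState[row.state],
                    cost,
                )
            )
        return out

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.df["year"].unique()))

    @property
    def has_cost(self) -> bool:
        return "cost" in self.df.columns

    def __eq__(self, other) -> bool:
        if not isinstance(other, PersonYearPanel):
            return NotImplemented
        a, b = self.df, other.df
        if self.has_cost != other.has_cost or len(a) != len(b):
            return False
        cols = list(REQUIRED_COLUMNS) + (["cost"] if self.has_cost else [])
        a = a[cols].reset_index(drop=True)
        b = b[cols].reset_index(drop=True)
        for c in cols:
            if c == "cost":
                if not np.allclose(
                    a[c].fillna(-1).round(2), b[c].fillna(-1).round(2), atol=5e-3
                ):
                    return False
            elif not a[c].equals(b[c]):
                return False
        return True

    # -- validation ----------------------------------------------------------
    def _validate(self) -> ValidationReport:
        df = self.df
        bad_state = ~df["state"].isin(STATE_LABELS)
        if bad_state.any():
            i = int(np.flatnonzero(bad_state)[0])
            raise PanelValidationError(
                f"unknown state label {df['state'].iat[i]!r} for person "
                f"{df['person_id'].iat[i]!r}, year {df['year'].iat[i]}"
            )
        bad_gender = ~df["gender"].isin(GENDER_LABELS)
        if bad_gender.any():
            i = int(np.flatnonzero(bad_gender)[0])
            raise PanelValidationError(
                f"unknown gender label {df['gender'].iat[i]!r} for person "
                f"{df['person_id'].iat[i]!r}"
            )
        if (df["age"] < 0).any():
            pid = df.loc[df["age"] < 0, "person_id"].iloc[0]
            raise PanelValidationError(f"negative age for person {pid!r}")
        if self.has_cost:
            cost = pd.to_numeric(df["cost"], errors="raise")
            if (cost.dropna() < 0).any():
                pid = df.loc[cost < 0, "person_id"].iloc[0]
                raise PanelValidationError(f"negative cost for person {pid!r}")

        dup = df.duplicated(["person_id", "year"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise PanelValidationError(
                f"duplicate record for person {row['person_id']!r}, year {row['year']}"
            )

        pid = df["person_id"].to_numpy()
        same = np.concatenate(([False], pid[1:] == pid[:-1]))
        year = df["year"].to_numpy()
        age = df["age"].to_numpy()
        dyear = np.diff(year, prepend=year[0] if len(year) else 0)
        dage = np.diff(age, prepend=age[0] if len(age) else 0)

        mismatch = same & (dyear != dage)
        if mismatch.any():
            i = int(np.flatnonzero(mismatch)[0])
            raise PanelValidationError(
                f"age/year inconsistency for person {pid[i]!r}: year advanced by "
                f"{dyear[i]} but age by {dage[i]} into year {year[i]}"
            )

        gender = df["gender"].to_numpy()
        flip = same & (gender != np.roll(gender, 1))
        if flip.any():
            i = int(np.flatnonzero(flip)[0])
            raise PanelValidationError(f"inconsistent gender for person {pid[i]!r}")

        dead = df["state"].to_numpy() == _DEAD
        prev_dead = same & np.roll(dead, 1)
        if prev_dead.any():
            i = int(np.flatnonzero(prev_dead)[0])
            raise PanelValidationError(
                f"record after death for person {pid[i]!r} in year {year[i]}"
            )

        gap = same & (dyear > 1)
        gap_persons = pd.unique(pd.Series(pid)[gap])
        return ValidationReport(
            n_records=len(df),
            n_persons=int(df["person_id"].nunique()),
            years=self.years,
            has_cost=self.has_cost,
            n_gap_persons=len(gap_persons),
            gap_person_ids=tuple(gap_persons[:10]),
        )


def read_panel(path: str | Path) -> PersonYearPanel:
    """Read and validate a person-year panel from a CSV file."""
    df = pd.read_csv(path, dtype={"person_id": str})
    if df.empty and not set(REQUIRED_COLUMNS) <= set(df.columns):
        raise PanelValidationError(f"{path}: missing header columns {REQUIRED_COLUMNS}")
    return PersonYearPanel(df)


def write_panel(panel: PersonYearPanel, path: str | Path) -> Path:
    """Write a panel to CSV; ``read_panel(write_panel(p)) == p`` exactly."""
    path = Path(path)
    cols = list(REQUIRED_COLUMNS) + (["cost"] if panel.has_cost else [])
    panel.df[cols].to_csv(path, index=False, float_format="%.2f")
    return path
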