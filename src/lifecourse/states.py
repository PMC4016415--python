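"""State space and stratification shared by every stage of the pipeline.

The yearly health-transition model classifies each person-year into one of
six aggregated Clinical Risk Group (CRG) core health statuses, with an
explicit absorbing death state appended:

=======  ==========================================================
label    meaning
=======  ==========================================================
``E1``   healthy
``E2``   significant acute disease
``E34``  minor chronic disease
``E56``  significant chronic disease in one or two organ systems
``E79``  significant chronic disease in three or more organ systems,
         or catastrophic conditions
``E8``   dominant and metastatic malignancies
``DEAD`` death (absorbing)
=======  ==========================================================

The ordinal positions above are fixed: every transition matrix, sampler and
report in the package indexes states in this order.  Transition dynamics are
stratified by gender and by ten age bands (``<1``, ``1-14``, ``15-24``, ...,
``75-84``, ``>=85``), encoded as half-open integer intervals so that every
completed age maps to exactly one band.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from enum import IntEnum


class HealthState(IntEnum):
    """One of the six aggregated CRG core statuses, or death."""

    E1 = 0
    E2 = 1
    E34 = 2
    E56 = 3
    E79 = 4
    E8 = 5
    DEAD = 6

    @property
    def is_transient(self) -> bool:
        return self is not HealthState.DEAD

    @property
    def is_chronic(self) -> bool:
        return self in CHRONIC_STATES


TRANSIENT_STATES: tuple[HealthState, ...] = tuple(
    s for s in HealthState if s is not HealthState.DEAD
)
CHRONIC_STATES: frozenset[HealthState] = frozenset(
    {HealthState.E34, HealthState.E56, HealthState.E79, HealthState.E8}
)

N_STATES: int = len(HealthState)  # 7, death included
N_TRANSIENT: int = len(TRANSIENT_STATES)

STATE_LABELS: tuple[str, ...] = tuple(s.name for s in HealthState)
STATE_INDEX: dict[str, int] = {s.name: s.value for s in HealthState}


class Gender(IntEnum):
    F = 0
    M = 1


GENDER_LABELS: tuple[str, ...] = tuple(g.name for g in Gender)
N_GENDERS: int = 2


@dataclass(frozen=True)
class AgeGroupScheme:
    """Half-open age bands ``[lo, hi)`` covering all non-negative ages.

    ``boundaries`` are the lower edges; the last band is open-ended.  The
    default is the ten-band scheme used throughout: ``[0,1), [1,15),
    [15,25), ..., [75,85), [85, inf)``.
    """

    boundaries: tuple[int, ...] = (0, 1, 15, 25, 35, 45, 55, 65, 75, 85)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 1 or b[0] != 0 or list(b) != sorted(set(b)):
            raise ValueError(f"age band boundaries must be strictly increasing from 0, got {b}")

    @property
    def n_groups(self) -> int:
        return len(self.boundaries)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        for i, lo in enumerate(self.boundaries):
            if i + 1 < len(self.boundaries):
                hi = self.boundaries[i + 1]
                out.append("<1" if (lo == 0 and hi == 1) else f"{lo}-{hi - 1}")
            else:
                out.append(f">={lo}")
        return tuple(out)

    def group(self, age: int) -> int:
        if age < 0:
            raise ValueError(f"age must be non-negative, got {age}")
        return bisect_right(self.boundaries, age) - 1


DEFAULT_SCHEME = AgeGroupScheme()


def age_to_group(age: int, scheme: AgeGroupScheme = DEFAULT_SCHEME) -> int:
    """Map a completed age in years to its band index under ``scheme``."""
    return scheme.group(age)


def ages_to_groups(ages, scheme: AgeGroupScheme = DEFAULT_SCHEME):
    """Vectorised :func:`age_to_group` for an integer array of ages."""
    import numpy as np

    ages = np.asarray(ages)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    return np.searchsorted(scheme.boundaries, ages, side="right") - 1
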