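"""Age x sex population grids.

The whole model is bookkept on a single-year-of-age grid from 18 to the
open-ended 100+ class, split by sex.  :class:`CohortGrid` is a thin,
validating wrapper around a ``(83, 2)`` float array; heavy numerics operate
on the underlying array directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_MIN = 18
AGE_MAX = 100  # index 100 is the open-ended 100+ class
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGE = AGES.size

FEMALE = 0
MALE = 1
SEXES = ("female", "male")
N_SEX = 2

GRID_SHAPE = (N_AGE, N_SEX)

#: tolerance below which a slightly negative entry (float round-off) is
#: silently clipped to zero rather than rejected
_NEG_TOL = 1e-9


def sex_index(sex) -> int:
    """Map ``"female"``/``"male"`` (or 0/1) to the sex axis index."""
    if isinstance(sex, str):
        try:
            return SEXES.index(sex.lower())
        except ValueError:
            raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}") from None
    i = int(sex)
    if i not in (FEMALE, MALE):
        raise ValueError(f"sex index must be 0 (female) or 1 (male), got {sex!r}")
    return i


def age_index(age) -> int:
    """Map an age in years to the age axis index (100+ caps at the top class)."""
    a = int(age)
    if a < AGE_MIN:
        raise ValueError(f"age {age!r} below modelled range ({AGE_MIN}+)")
    return min(a, AGE_MAX) - AGE_MIN


class CohortGrid:
    """Non-negative person counts indexed by single year of age (18..100+) and sex.

    Parameters
    ----------
    values : array-like, shape (83, 2)
        Persons per (age, sex) cell.  Column 0 is female, column 1 male.
        Entries more negative than ``-1e-9`` raise; tiny negative round-off
        is clipped to zero.
    """

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.shape != GRID_SHAPE:
            raise ValueError(f"CohortGrid expects shape {GRID_SHAPE}, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("CohortGrid entries must be finite")
        if arr.min() < -_NEG_TOL:
            raise ValueError(f"CohortGrid entries must be >= 0 (min {arr.min():g})")
        self.values = np.clip(arr, 0.0, None)

    # -- constructors -----------------------------------------------------
    @classmethod
    def zeros(cls) -> "CohortGrid":
        return cls(np.zeros(GRID_SHAPE))

    @classmethod
    def filled(cls, value: float) -> "CohortGrid":
        return cls(np.full(GRID_SHAPE, float(value)))

    @classmethod
    def single(cls, age, sex, persons: float) -> "CohortGrid":
        """A grid with one occupied cell (handy in tests)."""
        arr = np.zeros(GRID_SHAPE)
        arr[age_index(age), sex_index(sex)] = persons
        return cls(arr)

    # -- views ------------------------------------------------------------
    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def copy(self) -> "CohortGrid":
        return CohortGrid(self.values.copy())

    def total(self) -> float:
        return float(self.values.sum())

    def by_sex(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def by_age(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def __getitem__(self, key):
        return self.values[key]

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"CohortGrid(total={self.total():,.1f})"

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns age, sex, persons."""
        rows = []
        for si, sex in enumerate(SEXES):
            rows.append(
                pd.DataFrame(
                    {"age": AGES, "sex": sex, "persons": self.values[:, si]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "persons") -> "CohortGrid":
        arr = np.zeros(GRID_SHAPE)
        for _, row in df.iterrows():
            arr[age_index(row["age"]), sex_index(row["sex"])] += float(row[value_col])
        return cls(arr)


def as_grid_array(grid) -> np.ndarray:
    """Accept a CohortGrid, scalar or broadcastable array; return (83, 2) floats."""
    if isinstance(grid, CohortGrid):
        return grid.values
    arr = np.asarray(grid, dtype=float)
    return np.broadcast_to(arr, GRID_SHAPE).copy() if arr.shape != GRID_SHAPE else arr
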