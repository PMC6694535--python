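"""Age- and sex-structured population bookkeeping.

Annual difference equations (explicit Euler, dt = 1 year).  Within a step the
flow ordering is fixed and documented: deaths -> (state transitions, handled
by the sub-models) -> net migration -> aging shift -> age-18 entry.  The
open-ended 100+ class accumulates; anyone aging out of 99 joins it.

Rates are interpreted as annual fractions by default; ``hazard=True``
converts each rate r to 1 - exp(-r) for a hazard reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .grids import AGES, GRID_SHAPE, N_AGE, N_SEX, SEXES, CohortGrid, as_grid_array

FECUND_AGE_BAND = (15, 49)


@dataclass
class DemographyInputs:
    """Exogenous demographic series driving a simulation.

    Attributes
    ----------
    initial_population : CohortGrid
        Population at ``start_year``.
    start_year : int
        Calendar year of the first entries of every series.
    fertility_rate : ndarray, shape (n_years,)
        Births per fecund woman per year.
    mortality_rate : ndarray, shape (n_years, 83, 2)
        Annual death fraction per age/sex cell, in [0, 1].
    net_migration : ndarray, shape (n_years, 83, 2)
        Net migrants per year per cell (may be negative).
    entrants_18 : ndarray, shape (n_years, 2), optional
        Persons entering the age-18 cohort each year by sex.  When absent the
        age-18 cohort is replaced at its pre-step size (see
        :func:`step_demography`).
    fecund_correction : float
        Scale factor approximating fecund women aged 15-17 who fall below the
        modelled range; the fecund pool is women 18-49 times this factor.
    """

    initial_population: CohortGrid
    start_year: int
    fertility_rate: np.ndarray
    mortality_rate: np.ndarray
    net_migration: np.ndarray
    entrants_18: Optional[np.ndarray] = None
    fecund_age_band: tuple = FECUND_AGE_BAND
    fecund_correction: float = 1.0

    def __post_init__(self):
        self.fertility_rate = np.asarray(self.fertility_rate, dtype=float)
        self.mortality_rate = np.asarray(self.mortality_rate, dtype=float)
        self.net_migration = np.asarray(self.net_migration, dtype=float)
        n = self.fertility_rate.shape[0]
        if self.mortality_rate.shape != (n,) + GRID_SHAPE:
            raise ValueError("mortality_rate shape mismatch with fertility series")
        if self.net_migration.shape != (n,) + GRID_SHAPE:
            raise ValueError("net_migration shape mismatch with fertility series")
        if self.fertility_rate.min() < 0:
            raise ValueError("fertility_rate must be >= 0")
        if self.mortality_rate.min() < 0 or self.mortality_rate.max() > 1:
            raise ValueError("mortality_rate must lie in [0, 1]")
        if self.entrants_18 is not None:
            self.entrants_18 = np.asarray(self.entrants_18, dtype=float)
            if self.entrants_18.shape != (n, N_SEX):
                raise ValueError("entrants_18 must have shape (n_years, 2)")
        if tuple(self.fecund_age_band) != FECUND_AGE_BAND:
            raise ValueError(f"fecund_age_band is fixed to {FECUND_AGE_BAND}")

    @property
    def n_years(self) -> int:
        return self.fertility_rate.shape[0]

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    def _idx(self, year: int) -> int:
        i = int(year) - self.start_year
        if not 0 <= i < self.n_years:
            raise ValueError(
                f"year {year} outside input series range "
                f"[{self.start_year}, {self.end_year}]"
            )
        return i

    def mortality_at(self, year: int) -> np.ndarray:
        return self.mortality_rate[self._idx(year)]

    def migration_at(self, year: int) -> np.ndarray:
        return self.net_migration[self._idx(year)]

    def fertility_at(self, year: int) -> float:
        return float(self.fertility_rate[self._idx(year)])

    def entrants_at(self, year: int, pop: CohortGrid) -> np.ndarray:
        """Age-18 entrants by sex; defaults to replacing the current age-18 cohort."""
        if self.entrants_18 is not None:
            return self.entrants_18[self._idx(year)]
        return pop.values[0, :].copy()

    def fecund_women(self, pop: CohortGrid) -> float:
        """Women in the fecund band; ages 15-17 approximated via fecund_correction."""
        lo, hi = self.fecund_age_band
        lo = max(lo, AGES[0])
        mask = (AGES >= lo) & (AGES <= hi)
        return float(pop.values[mask, 0].sum()) * self.fecund_correction

    # ------------------------------------------------------------------ io
    def to_frame(self) -> pd.DataFrame:
        """Long CSV layout: year, age, sex, variable, value.

        Fertility rows use age/sex = 'all'; the initial population is stored
        under variable 'population' at start_year.
        """
        recs = []
        pop = self.initial_population.to_frame()
        for _, r in pop.iterrows():
            recs.append((self.start_year, int(r["age"]), r["sex"], "population", r["persons"]))
        for t in range(self.n_years):
            year = self.start_year + t
            recs.append((year, "all", "all", "fertility_rate", self.fertility_rate[t]))
            for si, sex in enumerate(SEXES):
                if self.entrants_18 is not None:
                    recs.append((year, 18, sex, "entrants_18", self.entrants_18[t, si]))
                for ai, age in enumerate(AGES):
                    recs.append((year, int(age), sex, "mortality_rate", self.mortality_rate[t, ai, si]))
                    recs.append((year, int(age), sex, "net_migration", self.net_migration[t, ai, si]))
        return pd.DataFrame(recs, columns=["year", "age", "sex", "variable", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "DemographyInputs":
        years = sorted(df.loc[df["variable"] == "fertility_rate", "year"].astype(int).unique())
        if not years:
            raise ValueError("no fertility_rate rows found")
        start_year, n = years[0], len(years)
        fert = np.zeros(n)
        mort = np.zeros((n,) + GRID_SHAPE)
        mig = np.zeros((n,) + GRID_SHAPE)
        ent = None
        pop = np.zeros(GRID_SHAPE)
        sex_i = {s: i for i, s in enumerate(SEXES)}
        for _, r in df.iterrows():
            var, val = r["variable"], float(r["value"])
            if var == "fertility_rate":
                fert[int(r["year"]) - start_year] = val
                continue
            si = sex_i[r["sex"]]
            ai = min(int(r["age"]), 100) - 18
            if var == "population":
                pop[ai, si] += val
            elif var == "mortality_rate":
                mort[int(r["year"]) - start_year, ai, si] = val
            elif var == "net_migration":
                mig[int(r["year"]) - start_year, ai, si] = val
            elif var == "entrants_18":
                if ent is None:
                    ent = np.zeros((n, N_SEX))
                ent[int(r["year"]) - start_year, si] = val
            else:
                raise ValueError(f"unknown variable {var!r}")
        return cls(CohortGrid(pop), start_year, fert, mort, mig, entrants_18=ent, **kwargs)


def births(fecund_women: float, fertility_rate: float) -> float:
    """Annual births from the fecund female population.

    Examples
    --------
    >>> births(100_000, 0.05)
    5000.0
    """
    if fecund_women < 0 or fertility_rate < 0:
        raise ValueError("fecund_women and fertility_rate must be >= 0")
    return float(fecund_women) * float(fertility_rate)


def effective_rate(rate, hazard: bool = False):
    """Annual-fraction reading (default) or hazard reading 1 - exp(-r)."""
    r = np.asarray(rate, dtype=float)
    out = 1.0 - np.exp(-r) if hazard else r
    return float(out) if np.isscalar(rate) or out.ndim == 0 else out


def age_shift(values: np.ndarray, entrants: np.ndarray | float = 0.0) -> np.ndarray:
    """Shift every cohort up one year of age; 100+ absorbs; entrants fill age 18."""
    out = np.empty_like(values)
    out[1:-1] = values[:-2]
    out[-1] = values[-2] + values[-1]
    out[0] = entrants
    return out


def step_demography(
    pop: CohortGrid,
    inputs: DemographyInputs,
    year: int,
    entrants: Optional[np.ndarray] = None,
    hazard: bool = False,
) -> CohortGrid:
    """Advance the population one year: deaths, migration, aging, age-18 entry.

    ``entrants`` overrides the input series / replacement default.  Negative
    cells created by out-migration exceeding the surviving cohort are clipped
    to zero with a warning.
    """
    m = effective_rate(inputs.mortality_at(year), hazard)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mortality outside [0, 1]")
    if entrants is None:
        entrants = inputs.entrants_at(year, pop)
    entrants = np.broadcast_to(np.asarray(entrants, dtype=float), (N_SEX,))
    if np.any(entrants < 0):
        raise ValueError("entrants must be >= 0")

    survivors = pop.values * (1.0 - m)
    migrated = survivors + inputs.migration_at(year)
    if migrated.min() < 0:
        warnings.warn(
            "net out-migration exceeded surviving cohort; clipping to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        migrated = np.clip(migrated, 0.0, None)
    return CohortGrid(age_shift(migrated, entrants))


def distribute_proportionally(total_grid: np.ndarray, parts: list[np.ndarray],
                              fallback: int = 0) -> list[np.ndarray]:
    """Split a per-cell flow (e.g. net migration) across state grids by share.

    Cells where all parts are empty route the whole flow to ``parts[fallback]``.
    """
    stacked = np.stack(parts)
    cell_tot = stacked.sum(axis=0)
    shares = np.zeros_like(stacked)
    nz = cell_tot > 0
    shares[:, nz] = stacked[:, nz] / cell_tot[nz]
    shares[fallback, ~nz] = 1.0
    return [total_grid * shares[k] for k in range(len(parts))]
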