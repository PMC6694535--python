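"""Parameter calibration: risk-group intercepts and transition-rate fitting.

Two distinct problems are solved here:

* :func:`calibrate_beta0` — for each risk group, the intercept of the
  logistic event equation is recovered from a target annual event count by a
  bracketed 1-D root find (the expected-events function is strictly monotone
  in the intercept);
* :func:`fit_rates` — free transition rates are fitted to prevalence/event
  time series by deterministic bounded least squares on (relative) residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import expit

from .cvd_engine import GROUPS, N_GROUPS, RiskEngineParams, linear_predictor
from .grids import AGES, GRID_SHAPE, N_SEX


@dataclass
class EventDistribution:
    """Fraction of total CVD events attributed to each of the 8 risk groups."""

    fraction: Mapping[str, float]

    def __post_init__(self):
        missing = set(GROUPS) - set(self.fraction)
        if missing:
            raise ValueError(f"event distribution missing groups: {sorted(missing)}")
        vals = np.array([float(self.fraction[g]) for g in GROUPS])
        if np.any(vals < 0):
            raise ValueError("event fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"event fractions must sum to 1 (got {vals.sum():g})")

    def __getitem__(self, group: str) -> float:
        return float(self.fraction[group])

    def as_array(self) -> np.ndarray:
        return np.array([float(self.fraction[g]) for g in GROUPS])


@dataclass
class CalibrationTargets:
    """Observed series the model is fitted against.

    ``series`` maps a series name (e.g. ``prevalence_diabetes``,
    ``cvd_events``) to values aligned with ``years``.
    """

    years: np.ndarray
    series: dict[str, np.ndarray]
    event_distribution: Optional[EventDistribution] = None
    total_events: Optional[float] = None  # base-year total, for beta0 calibration

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        for k, v in self.series.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != self.years.shape:
                raise ValueError(f"target series {k!r} length mismatch")
            self.series[k] = arr

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.series):
            for y, v in zip(self.years, self.series[name]):
                rows.append((int(y), name, float(v)))
        return pd.DataFrame(rows, columns=["year", "series", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "CalibrationTargets":
        years = np.sort(df["year"].astype(int).unique())
        series = {}
        for name, grp in df.groupby("series"):
            grp = grp.sort_values("year")
            if len(grp) != len(years):
                raise ValueError(f"series {name!r} does not cover all target years")
            series[name] = grp["value"].to_numpy(dtype=float)
        return cls(years, series, **kwargs)


def expected_events(beta0: float, group: str, population: np.ndarray,
                    params: RiskEngineParams) -> float:
    """Expected annual events in one group for a candidate intercept."""
    tot = 0.0
    for si in range(N_SEX):
        lin = linear_predictor(group, AGES, si, params, include_intercept=False)
        tot += float(np.sum(population[:, si] * expit(beta0 + lin)))
    return tot


def calibrate_beta0(
    targets: CalibrationTargets,
    population_by_group: np.ndarray,
    params: RiskEngineParams,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Solve each group's intercept so expected events hit the target split.

    The group target is ``total_events * fraction[group]``.  Requires
    ``targets.total_events`` and ``targets.event_distribution``.  A zero
    target with nonzero population yields ``-inf`` (flagged by warning); a
    target at or above the group population is infeasible.
    """
    if targets.event_distribution is None or targets.total_events is None:
        raise ValueError("targets must carry total_events and event_distribution")
    pop = np.asarray(population_by_group, dtype=float)
    if pop.shape != (N_GROUPS,) + GRID_SHAPE:
        raise ValueError(f"population_by_group must have shape {(N_GROUPS,) + GRID_SHAPE}")

    out: dict[str, float] = {}
    for gi, group in enumerate(GROUPS):
        target = float(targets.total_events) * targets.event_distribution[group]
        gpop = pop[gi]
        gtotal = gpop.sum()
        if target > 0 and gtotal <= 0:
            raise ValueError(f"group {group!r} has zero population but nonzero target")
        if target >= gtotal and target > 0:
            raise ValueError(
                f"group {group!r}: target events ({target:g}) >= group population "
                f"({gtotal:g}); infeasible"
            )
        if target == 0:
            if gtotal > 0:
                warnings.warn(f"group {group!r}: zero target events, beta0 -> -inf",
                              RuntimeWarning, stacklevel=2)
            out[group] = float("-inf")
            continue

        def mismatch(b0, group=group, gpop=gpop, target=target):
            return expected_events(b0, group, gpop, params) - target

        lo, hi = -60.0, 30.0
        # expected events are monotone increasing in beta0; expand if needed
        while mismatch(lo) > 0:
            lo -= 30.0
        while mismatch(hi) < 0:
            hi += 30.0
        b0 = brentq(mismatch, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
        if abs(mismatch(b0)) > max(tol, 1e-8 * target):
            warnings.warn(f"group {group!r}: residual event mismatch "
                          f"{mismatch(b0):.3g}", RuntimeWarning, stacklevel=2)
        out[group] = float(b0)
    return out


@dataclass
class FitResult:
    params: dict[str, float]
    residuals: np.ndarray
    cost: float
    converged: bool
    message: str = ""
    n_evaluations: int = 0

    def __post_init__(self):
        if not self.converged:
            warnings.warn(f"rate fit did not converge: {self.message}",
                          RuntimeWarning, stacklevel=2)


def fit_rates(
    free_params: Mapping[str, float],
    targets: CalibrationTargets,
    simulate_fn: Callable[[Mapping[str, float]], Mapping[str, np.ndarray]],
    bounds: Optional[Mapping[str, tuple]] = None,
    loss: str = "relative",
) -> FitResult:
    """Fit free rates to target series by deterministic bounded least squares.

    Parameters
    ----------
    free_params : mapping
        Parameter path -> starting value (the deterministic start point).
    targets : CalibrationTargets
        Must span at least two years.
    simulate_fn : callable
        Maps a {path: value} dict to predicted series (same keys and year
        alignment as ``targets.series``).
    bounds : mapping, optional
        path -> (lo, hi); defaults to (0, 1) per rate.
    loss : {"relative", "absolute"}
        Residual scaling; relative squared error is the default because the
        target series span orders of magnitude.
    """
    if not free_params:
        preds = simulate_fn({})
        res = _residuals(preds, targets, loss)
        return FitResult({}, res, 0.5 * float(res @ res), True, "no free parameters")
    if targets.years.size < 2:
        raise ValueError("targets must span at least two years")
    if loss not in ("relative", "absolute"):
        raise ValueError("loss must be 'relative' or 'absolute'")

    names = list(free_params)
    x0 = np.array([float(free_params[n]) for n in names])
    lo = np.array([(bounds or {}).get(n, (0.0, 1.0))[0] for n in names])
    hi = np.array([(bounds or {}).get(n, (0.0, 1.0))[1] for n in names])

    def fun(x):
        preds = simulate_fn(dict(zip(names, x)))
        return _residuals(preds, targets, loss)

    sol = least_squares(fun, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return FitResult(
        params=dict(zip(names, map(float, sol.x))),
        residuals=sol.fun,
        cost=float(sol.cost),
        converged=bool(sol.success),
        message=str(sol.message),
        n_evaluations=int(sol.nfev),
    )


def _residuals(preds: Mapping[str, np.ndarray], targets: CalibrationTargets,
               loss: str) -> np.ndarray:
    chunks = []
    for name in sorted(targets.series):
        if name not in preds:
            raise KeyError(f"simulate_fn did not return target series {name!r}")
        obs = targets.series[name]
        sim = np.asarray(preds[name], dtype=float)
        if sim.shape != obs.shape:
            raise ValueError(f"predicted series {name!r} length mismatch")
        if loss == "relative":
            denom = np.where(obs != 0, obs, 1.0)
            chunks.append((sim - obs) / denom)
        else:
            chunks.append(sim - obs)
    return np.concatenate(chunks)
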