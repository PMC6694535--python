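"""Stock-flow dynamics for the three risk-factor sub-models.

Two compartmental structures are provided:

* a generic two-stage disease model (healthy -> pre-stage -> disease, each
  non-healthy stage split into managed/unmanaged), used for both diabetes
  and hypertension;
* a three-state smoking model (never -> current <-> former).

All flows are explicit-Euler: within a step, deaths are applied first, then
every transition flow is computed simultaneously from the post-death stocks.
Oversized combined outflows are an error by default (``negative_stock =
"error"``); ``"clamp"`` rescales the offending cell's outflows and warns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .grids import GRID_SHAPE, N_SEX, CohortGrid, as_grid_array

_OVERSHOOT_TOL = 1e-12


def _per_sex(rate) -> np.ndarray:
    """Normalize a scalar, (2,) array or {'female','male'} dict to shape (2,)."""
    if isinstance(rate, dict):
        return np.array([float(rate["female"]), float(rate["male"])])
    arr = np.asarray(rate, dtype=float)
    if arr.ndim == 0:
        return np.full(N_SEX, float(arr))
    if arr.shape != (N_SEX,):
        raise ValueError(f"per-sex rate must be scalar or length-2, got {arr.shape}")
    return arr


@dataclass
class TwoStageParams:
    """Annual transition rates for a two-stage disease sub-model.

    Managed progression is given either explicitly
    (``progression_rate_managed``) or as ``progression_effect_multiplier``
    applied to the unmanaged rate; exactly one must be set.
    """

    incidence_rate: float
    regression_rate: float
    progression_rate_unmanaged: Union[float, dict, np.ndarray]
    progression_rate_managed: Optional[Union[float, dict, np.ndarray]] = None
    progression_effect_multiplier: Optional[float] = None
    uptake_rate: float = 0.0
    treatment_mortality_effect: float = 0.0
    uptake_applies_to: str = "both"  # "pre" | "disease" | "both"
    regression_applies: str = "both"  # "both" | "managed"
    managed_dropout_rate: float = 0.0

    def __post_init__(self):
        if (self.progression_rate_managed is None) == (self.progression_effect_multiplier is None):
            raise ValueError(
                "set exactly one of progression_rate_managed / progression_effect_multiplier"
            )
        for name in ("incidence_rate", "regression_rate", "uptake_rate", "managed_dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.progression_effect_multiplier is not None and not (
            0 <= self.progression_effect_multiplier <= 1
        ):
            raise ValueError("progression_effect_multiplier must lie in [0, 1]")
        if not 0 <= self.treatment_mortality_effect <= 1:
            raise ValueError("treatment_mortality_effect must lie in [0, 1]")
        if self.uptake_applies_to not in ("pre", "disease", "both"):
            raise ValueError("uptake_applies_to must be 'pre', 'disease' or 'both'")
        if self.regression_applies not in ("both", "managed"):
            raise ValueError("regression_applies must be 'both' or 'managed'")

    def progression_unmanaged(self) -> np.ndarray:
        return _per_sex(self.progression_rate_unmanaged)

    def progression_managed(self) -> np.ndarray:
        if self.progression_rate_managed is not None:
            return _per_sex(self.progression_rate_managed)
        return self.progression_unmanaged() * self.progression_effect_multiplier


@dataclass
class SmokingParams:
    initiation_rate: float
    cessation_rate: float
    relapse_rate: float

    def __post_init__(self):
        for name in ("initiation_rate", "cessation_rate", "relapse_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TwoStageStocks:
    """Five-compartment decomposition of a sub-model's population."""

    healthy: CohortGrid
    pre_unmanaged: CohortGrid
    pre_managed: CohortGrid
    disease_unmanaged: CohortGrid
    disease_managed: CohortGrid

    STATES = ("healthy", "pre_unmanaged", "pre_managed", "disease_unmanaged", "disease_managed")

    @classmethod
    def zeros(cls) -> "TwoStageStocks":
        return cls(*[CohortGrid.zeros() for _ in range(5)])

    def grids(self) -> list[np.ndarray]:
        return [getattr(self, s).values for s in self.STATES]

    def total_grid(self) -> np.ndarray:
        return sum(self.grids())

    def total(self) -> float:
        return float(self.total_grid().sum())

    def disease_grid(self) -> np.ndarray:
        return self.disease_unmanaged.values + self.disease_managed.values

    def managed_grid(self) -> np.ndarray:
        return self.pre_managed.values + self.disease_managed.values

    def disease_managed_share(self) -> float:
        """Aggregate share of the disease stock under management."""
        dis = self.disease_grid().sum()
        return float(self.disease_managed.total() / dis) if dis > 0 else float("nan")

    def copy(self) -> "TwoStageStocks":
        return TwoStageStocks(*[getattr(self, s).copy() for s in self.STATES])


@dataclass
class SmokingStocks:
    never: CohortGrid
    current: CohortGrid
    former: CohortGrid

    STATES = ("never", "current", "former")

    @classmethod
    def zeros(cls) -> "SmokingStocks":
        return cls(CohortGrid.zeros(), CohortGrid.zeros(), CohortGrid.zeros())

    def grids(self) -> list[np.ndarray]:
        return [getattr(self, s).values for s in self.STATES]

    def total_grid(self) -> np.ndarray:
        return sum(self.grids())

    def total(self) -> float:
        return float(self.total_grid().sum())

    def copy(self) -> "SmokingStocks":
        return SmokingStocks(*[getattr(self, s).copy() for s in self.STATES])


def _check_outflow(stock: np.ndarray, outflow: np.ndarray, label: str, mode: str) -> np.ndarray:
    """Guard against combined outflows exceeding a stock within one step."""
    over = outflow > stock + _OVERSHOOT_TOL
    if not np.any(over):
        return outflow
    if mode == "error":
        raise ValueError(
            f"combined outflow exceeds stock '{label}' in {int(over.sum())} cell(s); "
            "reduce rates/dt or set negative_stock='clamp'"
        )
    warnings.warn(f"clamping oversized outflow from '{label}'", RuntimeWarning, stacklevel=3)
    scale = np.ones_like(stock)
    scale[over] = stock[over] / outflow[over]
    return outflow * scale


def _scaled_flows(stock, rates, label, mode):
    """Flows stock*rate for each rate, jointly rescaled if they overdraw the stock."""
    flows = [stock * r for r in rates]
    tot = sum(flows)
    checked = _check_outflow(stock, tot, label, mode)
    if checked is not tot:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(tot > 0, checked / np.where(tot > 0, tot, 1.0), 0.0)
        flows = [f * ratio for f in flows]
    return flows


def step_two_stage(
    stocks: TwoStageStocks,
    params: TwoStageParams,
    mortality,
    dt: float = 1.0,
    negative_stock: str = "error",
) -> TwoStageStocks:
    """One annual step of the two-stage disease model (deaths then transitions).

    Mortality applies per cell; managed stocks face mortality scaled by
    ``(1 - treatment_mortality_effect)``.  All transition flows are computed
    from the post-death stocks simultaneously.
    """
    m = as_grid_array(mortality)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mortality outside [0, 1]")
    m_managed = m * (1.0 - params.treatment_mortality_effect)

    h = stocks.healthy.values * (1.0 - m * dt)
    pu = stocks.pre_unmanaged.values * (1.0 - m * dt)
    pm = stocks.pre_managed.values * (1.0 - m_managed * dt)
    du = stocks.disease_unmanaged.values * (1.0 - m * dt)
    dm = stocks.disease_managed.values * (1.0 - m_managed * dt)

    prog_u = params.progression_unmanaged()[np.newaxis, :] * dt
    prog_m = params.progression_managed()[np.newaxis, :] * dt
    reg = params.regression_rate * dt
    reg_u_rate = reg if params.regression_applies == "both" else 0.0
    up = params.uptake_rate * dt
    up_pre = up if params.uptake_applies_to in ("pre", "both") else 0.0
    up_dis = up if params.uptake_applies_to in ("disease", "both") else 0.0
    drop = params.managed_dropout_rate * dt

    inc = _scaled_flows(h, [params.incidence_rate * dt], "healthy", negative_stock)[0]
    reg_u, prog_u_flow, up_pre_flow = _scaled_flows(
        pu, [reg_u_rate, prog_u, up_pre], "pre_unmanaged", negative_stock
    )
    reg_m, prog_m_flow, drop_pre = _scaled_flows(
        pm, [reg, prog_m, drop], "pre_managed", negative_stock
    )
    (up_dis_flow,) = _scaled_flows(du, [up_dis], "disease_unmanaged", negative_stock)
    (drop_dis,) = _scaled_flows(dm, [drop], "disease_managed", negative_stock)

    return TwoStageStocks(
        healthy=CohortGrid(h - inc + reg_u + reg_m),
        pre_unmanaged=CohortGrid(pu + inc - reg_u - prog_u_flow - up_pre_flow + drop_pre),
        pre_managed=CohortGrid(pm - reg_m - prog_m_flow + up_pre_flow - drop_pre),
        disease_unmanaged=CohortGrid(du + prog_u_flow - up_dis_flow + drop_dis),
        disease_managed=CohortGrid(dm + prog_m_flow + up_dis_flow - drop_dis),
    )


def step_smoking(
    stocks: SmokingStocks,
    params: SmokingParams,
    mortality,
    new_18_entrants=0.0,
    dt: float = 1.0,
    negative_stock: str = "error",
) -> SmokingStocks:
    """One annual step of the smoking model.

    Deaths first, then initiation (never -> current), cessation (current ->
    former) and relapse (former -> current) from post-death stocks; age-18
    entrants join the never-smoker stock last.
    """
    m = as_grid_array(mortality)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mortality outside [0, 1]")

    nv = stocks.never.values * (1.0 - m * dt)
    cu = stocks.current.values * (1.0 - m * dt)
    fo = stocks.former.values * (1.0 - m * dt)

    (init,) = _scaled_flows(nv, [params.initiation_rate * dt], "never", negative_stock)
    (cess,) = _scaled_flows(cu, [params.cessation_rate * dt], "current", negative_stock)
    (rel,) = _scaled_flows(fo, [params.relapse_rate * dt], "former", negative_stock)

    nv = nv - init
    cu = cu + init - cess + rel
    fo = fo + cess - rel

    entrants = np.broadcast_to(np.asarray(new_18_entrants, dtype=float), (N_SEX,))
    if np.any(entrants < 0):
        raise ValueError("entrants must be >= 0")
    nv = nv.copy()
    nv[0, :] += entrants
    return SmokingStocks(CohortGrid(nv), CohortGrid(cu), CohortGrid(fo))


def prevalence(stocks, which: Optional[str] = None):
    """Per-cell and aggregate prevalence of the marker state of a sub-model.

    For :class:`TwoStageStocks` the marker is the disease stage (managed +
    unmanaged); for :class:`SmokingStocks` it is current smokers (pass
    ``which="current_plus_former"`` to count ever-smokers).  Empty cells get
    NaN in the per-cell grid; an entirely empty population yields aggregate
    NaN.

    Returns
    -------
    (ndarray, float)
        Per-(age, sex) fraction grid and the population-weighted aggregate.
    """
    if isinstance(stocks, TwoStageStocks):
        num = stocks.disease_grid()
    elif isinstance(stocks, SmokingStocks):
        if which == "current_plus_former":
            num = stocks.current.values + stocks.former.values
        else:
            num = stocks.current.values
    else:
        raise TypeError(f"unsupported stocks type {type(stocks)!r}")
    tot = stocks.total_grid()
    grid = np.full(GRID_SHAPE, np.nan)
    nz = tot > 0
    grid[nz] = num[nz] / tot[nz]
    agg = float(num.sum() / tot.sum()) if tot.sum() > 0 else float("nan")
    return grid, agg
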