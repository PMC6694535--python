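"""Composed annual simulation: demography + risk factors + CVD engine.

One model year proceeds as (fixed, documented ordering):

1. outcomes for the current year are measured from current stocks (risk-group
   partition, treatment-adjusted event probabilities, events, deaths,
   age-adjusted incidence);
2. the post-CVD stock absorbs event survivors and loses post-CVD deaths,
   then ages one year;
3. each risk-factor sub-model applies deaths and state transitions, then net
   migration (split across states proportionally within each age/sex cell),
   ages one year, and receives the age-18 entrant cohort into its entry
   state (healthy / never-smoker);
4. the treatment-free reference population advances by pure demography; it
   is the at-risk denominator for the event engine (minus the post-CVD
   stock) and the default standard for age adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import cvd_engine as ce
from .cli_io import ModelConfig, _SCHEMA
from .demography import DemographyInputs, age_shift, births, step_demography
from .grids import GRID_SHAPE, CohortGrid
from .risk_factors import (
    SmokingStocks,
    TwoStageStocks,
    prevalence,
    step_smoking,
    step_two_stage,
)

OUTCOME_KEYS = (
    "cvd_events",
    "cvd_event_deaths",
    "post_cvd_deaths",
    "cvd_deaths",
    "post_cvd_population",
    "age_adjusted_incidence",
    "prevalence_diabetes",
    "prevalence_hypertension",
    "prevalence_smoking",
    "count_diabetes",
    "count_hypertension",
    "count_smokers",
    "managed_share_diabetes",
    "managed_share_hypertension",
    "total_population",
)


@dataclass
class InitialState:
    """Full model state at the simulation start year."""

    diabetes: TwoStageStocks
    hypertension: TwoStageStocks
    smoking: SmokingStocks
    post_cvd: CohortGrid
    reference_pop: Optional[CohortGrid] = None

    def __post_init__(self):
        if self.reference_pop is None:
            self.reference_pop = CohortGrid(self.diabetes.total_grid())

    def copy(self) -> "InitialState":
        return InitialState(
            self.diabetes.copy(),
            self.hypertension.copy(),
            self.smoking.copy(),
            self.post_cvd.copy(),
            self.reference_pop.copy(),
        )


@dataclass
class SimulationResult:
    """Annual outcome trajectories of one scenario run."""

    years: np.ndarray
    series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)
    group_events: Optional[np.ndarray] = None  # (n_years, 8)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        for k, v in self.series.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != self.years.shape:
                raise ValueError(f"series {k!r} length mismatch")
            self.series[k] = arr

    def at(self, outcome: str, year: int) -> Optional[float]:
        idx = np.where(self.years == int(year))[0]
        if idx.size == 0:
            return None
        return float(self.series[outcome][idx[0]])

    def percent_change(self, outcome: str, year0: int, year1: int) -> Optional[float]:
        v0, v1 = self.at(outcome, year0), self.at(outcome, year1)
        if v0 is None or v1 is None or v0 == 0:
            return None
        return 100.0 * (v1 - v0) / v0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for year, i in zip(self.years, range(self.years.size)):
            for key in sorted(self.series):
                rows.append((int(year), key, "all", "all", float(self.series[key][i])))
        return pd.DataFrame(rows, columns=["year", "outcome", "age", "sex", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimulationResult":
        sub = df[(df["age"] == "all") | (df["age"].astype(str) == "all")]
        years = np.sort(sub["year"].astype(int).unique())
        series = {}
        for key, grp in sub.groupby("outcome"):
            grp = grp.sort_values("year")
            vals = np.full(years.shape, np.nan)
            for _, r in grp.iterrows():
                vals[np.where(years == int(r["year"]))[0][0]] = float(r["value"])
            series[key] = vals
        return cls(years, series)


def engine_inputs(
    diabetes: TwoStageStocks,
    hypertension: TwoStageStocks,
    smoking: SmokingStocks,
    post_cvd: CohortGrid,
    reference_pop: CohortGrid,
    config: ModelConfig,
):
    """Derive the event-engine inputs (shares, coverage, at-risk persons).

    Returns a dict with keys ``shares`` (RiskGroupShares), ``coverages``
    (per-factor grids), ``at_risk`` (83, 2) and ``pop_by_group`` (8, 83, 2).
    """
    prev_d, _ = prevalence(diabetes)
    prev_h, _ = prevalence(hypertension)
    smode = config["modes.smoking_group_mode"]
    prev_s, _ = prevalence(
        smoking, which="current_plus_former" if smode == "current_plus_former" else None
    )

    def cov(num, den):
        out = np.zeros(GRID_SHAPE)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        return np.clip(out, 0.0, 1.0)

    coverages = {
        "diabetes": cov(diabetes.disease_managed.values, diabetes.disease_grid()),
        "hypertension": cov(hypertension.disease_managed.values, hypertension.disease_grid()),
    }
    if smode == "current_plus_former":
        ever = smoking.current.values + smoking.former.values
        coverages["smoking"] = cov(smoking.former.values, ever)
    else:
        coverages["smoking"] = np.zeros(GRID_SHAPE)

    shares = ce.partition_risk_groups(
        np.nan_to_num(prev_d), np.nan_to_num(prev_h), np.nan_to_num(prev_s),
        mode=config["modes.partition_mode"],
    )
    at_risk = np.clip(reference_pop.values - post_cvd.values, 0.0, None)
    pop_by_group = shares.share * at_risk[np.newaxis]
    return {
        "shares": shares,
        "coverages": coverages,
        "at_risk": at_risk,
        "pop_by_group": pop_by_group,
    }


def _step_states_demography(grids, migration, entrants, entry_index):
    """Migration (proportional split), aging, and age-18 entry for a stock list."""
    from .demography import distribute_proportionally

    parts = distribute_proportionally(migration, grids, fallback=entry_index)
    out = []
    for k, g in enumerate(grids):
        moved = g + parts[k]
        if moved.min() < 0:
            warnings.warn("out-migration exceeded a state stock; clipping",
                          RuntimeWarning, stacklevel=2)
            moved = np.clip(moved, 0.0, None)
        ent = entrants if k == entry_index else 0.0
        out.append(age_shift(moved, ent))
    return out


def run_simulation(
    inputs: DemographyInputs,
    state: InitialState,
    config: ModelConfig,
    overrides: Sequence[tuple] = (),
    start_year: Optional[int] = None,
    end_year: Optional[int] = None,
    scenario: str = "base",
) -> SimulationResult:
    """Deterministic trajectory from ``start_year`` to ``end_year`` inclusive.

    ``overrides`` is a sequence of ``(config_path, value, effective_year)``
    triples; each is applied at the start of its effective year (a step
    change held constant thereafter).  Unknown paths fail before the run.
    """
    cfg = config.copy()
    start = int(start_year if start_year is not None else cfg["simulation.start_year"])
    end = int(end_year if end_year is not None else cfg["simulation.end_year"])
    if end < start:
        raise ValueError("end_year before start_year")
    for path, value, year in overrides:
        if path not in _SCHEMA:
            raise KeyError(f"unknown override parameter path {path!r}")
        if not start <= int(year) <= end:
            raise ValueError(f"override year {year} outside horizon [{start}, {end}]")

    hazard = cfg["modes.hazard_rates"]
    neg = cfg["modes.negative_stock"]
    dt = float(cfg["simulation.dt"])
    n_sub = max(int(round(1.0 / dt)), 1)
    if abs(n_sub * dt - 1.0) > 1e-9:
        raise ValueError("simulation.dt must divide one year evenly")

    def params_bundle():
        return (
            cfg.two_stage_params("diabetes"),
            cfg.two_stage_params("hypertension"),
            cfg.smoking_params(),
            cfg.risk_engine_params(),
            cfg["modes.eq10_literal"],
        )

    dia_p, hyp_p, smo_p, eng_p, literal = params_bundle()

    dia = state.diabetes.copy()
    hyp = state.hypertension.copy()
    smo = state.smoking.copy()
    post = state.post_cvd.copy()
    ref = state.reference_pop.copy()
    standard = ref.copy()  # age-adjustment standard: the start-year population

    years = np.arange(start, end + 1)
    series = {k: np.zeros(years.shape) for k in OUTCOME_KEYS}
    group_events = np.zeros((years.size, ce.N_GROUPS))
    p_grid = ce.probability_grid(eng_p)

    for t, year in enumerate(years):
        applied = [o for o in overrides if int(o[2]) == year]
        if applied:
            for path, value, _ in applied:
                cfg.set(path, value)
            dia_p, hyp_p, smo_p, eng_p, literal = params_bundle()
            p_grid = ce.probability_grid(eng_p)

        eng = engine_inputs(dia, hyp, smo, post, ref, cfg)
        mult = ce.group_risk_multiplier(eng["coverages"], eng_p, eq10_literal=literal)
        events_by_group = ce.compute_events(eng["pop_by_group"], p_grid * mult)
        events_grid = events_by_group.sum(axis=0)

        cvd_state = ce.update_post_cvd(
            ce.CvdState(post), events_grid, eng_p, inputs.mortality_at(year)
            if year <= inputs.end_year else inputs.mortality_at(inputs.end_year)
        )

        _, prev_d_agg = prevalence(dia)
        _, prev_h_agg = prevalence(hyp)
        _, prev_s_agg = prevalence(smo)  # reported smoking prevalence = current smokers
        series["cvd_events"][t] = cvd_state.annual_events
        series["cvd_event_deaths"][t] = cvd_state.annual_event_deaths
        series["post_cvd_deaths"][t] = cvd_state.annual_post_cvd_deaths
        series["cvd_deaths"][t] = (
            cvd_state.annual_event_deaths + cvd_state.annual_post_cvd_deaths
        )
        series["post_cvd_population"][t] = post.total()
        series["age_adjusted_incidence"][t] = ce.age_adjusted_incidence(
            events_grid, eng["at_risk"], standard
        )
        series["prevalence_diabetes"][t] = prev_d_agg
        series["prevalence_hypertension"][t] = prev_h_agg
        series["prevalence_smoking"][t] = prev_s_agg
        series["count_diabetes"][t] = dia.disease_grid().sum()
        series["count_hypertension"][t] = hyp.disease_grid().sum()
        series["count_smokers"][t] = smo.current.total()
        series["managed_share_diabetes"][t] = dia.disease_managed_share()
        series["managed_share_hypertension"][t] = hyp.disease_managed_share()
        series["total_population"][t] = ref.total()
        group_events[t] = events_by_group.sum(axis=(1, 2))

        if year == end:
            break

        # ---- advance state to the next year -----------------------------
        m = inputs.mortality_at(year)
        entrants = inputs.entrants_at(year, ref)
        migration = inputs.migration_at(year)

        post = CohortGrid(age_shift(cvd_state.post_cvd.values, 0.0))

        for _ in range(n_sub):
            dia = step_two_stage(dia, dia_p, m, dt=dt, negative_stock=neg)
            hyp = step_two_stage(hyp, hyp_p, m, dt=dt, negative_stock=neg)
            smo = step_smoking(smo, smo_p, m, dt=dt, negative_stock=neg)

        dia_grids = _step_states_demography(dia.grids(), migration, entrants, 0)
        dia = TwoStageStocks(*[CohortGrid(g) for g in dia_grids])
        hyp_grids = _step_states_demography(hyp.grids(), migration, entrants, 0)
        hyp = TwoStageStocks(*[CohortGrid(g) for g in hyp_grids])
        smo_grids = _step_states_demography(smo.grids(), migration, entrants, 0)
        smo = SmokingStocks(*[CohortGrid(g) for g in smo_grids])

        ref = step_demography(ref, inputs, year, entrants=entrants, hazard=hazard)

    meta = {
        "scenario": scenario,
        "start_year": start,
        "end_year": end,
        "overrides": [list(o) for o in overrides],
        "config_hash": config.config_hash(),
    }
    return SimulationResult(years, series, metadata=meta, group_events=group_events)
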