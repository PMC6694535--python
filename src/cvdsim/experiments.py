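"""Policy scenarios, scenario comparison and Monte-Carlo sensitivity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cli_io import ModelConfig, _SCHEMA
from .demography import DemographyInputs
from .simulate import InitialState, SimulationResult, run_simulation

#: outcomes reported by compare_scenarios / sensitivity summaries
COMPARISON_OUTCOMES = (
    "cvd_events",
    "cvd_deaths",
    "post_cvd_population",
    "age_adjusted_incidence",
)

#: rates varied in the +/-50% sensitivity analysis
DEFAULT_SENSITIVITY_PARAMS = (
    "diabetes.incidence_rate",
    "hypertension.incidence_rate",
    "smoking.initiation_rate",
)


@dataclass
class Override:
    path: str
    value: float
    year: int

    def as_tuple(self):
        return (self.path, self.value, self.year)


@dataclass
class ScenarioSpec:
    """A named policy experiment: timed step-change parameter overrides."""

    name: str
    overrides: Sequence[Override] = ()
    start_year: int = 2010
    end_year: int = 2040

    def __post_init__(self):
        self.overrides = [
            o if isinstance(o, Override) else Override(*o) for o in self.overrides
        ]
        for o in self.overrides:
            if o.path not in _SCHEMA:
                raise KeyError(f"scenario {self.name!r}: unknown parameter path {o.path!r}")
            if not self.start_year <= o.year <= self.end_year:
                raise ValueError(
                    f"scenario {self.name!r}: override year {o.year} outside horizon"
                )

    def override_tuples(self):
        return [o.as_tuple() for o in self.overrides]


def builtin_scenarios(config: ModelConfig, policy_year: int = 2020,
                      start_year: Optional[int] = None,
                      end_year: Optional[int] = None) -> dict[str, ScenarioSpec]:
    """The five standard experiments: base case plus four interventions.

    Interventions step in at ``policy_year`` and hold: diabetes management
    uptake 5% -> 15%, hypertension management uptake 3.5% -> 13.5%, smoking
    cessation 16.2% -> 25%, and all three combined.
    """
    y0 = int(start_year if start_year is not None else config["simulation.start_year"])
    y1 = int(end_year if end_year is not None else config["simulation.end_year"])
    d = Override("diabetes.uptake_rate", 0.15, policy_year)
    h = Override("hypertension.uptake_rate", 0.135, policy_year)
    s = Override("smoking.cessation_rate", 0.25, policy_year)
    mk = lambda name, ov: ScenarioSpec(name, ov, start_year=y0, end_year=y1)
    return {
        "base": mk("base", []),
        "diabetes_management": mk("diabetes_management", [d]),
        "hypertension_management": mk("hypertension_management", [h]),
        "smoking_cessation": mk("smoking_cessation", [s]),
        "combined": mk("combined", [d, h, s]),
    }


def run_scenario(
    spec: ScenarioSpec,
    inputs: DemographyInputs,
    state: InitialState,
    config: ModelConfig,
) -> SimulationResult:
    """Deterministic trajectory for one scenario (overrides validated upfront)."""
    return run_simulation(
        inputs,
        state,
        config,
        overrides=spec.override_tuples(),
        start_year=spec.start_year,
        end_year=spec.end_year,
        scenario=spec.name,
    )


def compare_scenarios(result: SimulationResult, base: SimulationResult, year: int,
                      outcomes: Sequence[str] = COMPARISON_OUTCOMES) -> dict:
    """Percent reduction vs base at ``year`` plus within-run percent change.

    ``reduction_pct[outcome]`` is ``100 * (base - scenario) / base``; ``None``
    flags an undefined comparison (base outcome zero).  ``change_pct`` holds
    each run's own percent change from its first to its last year.
    """
    if not np.array_equal(result.years, base.years):
        raise ValueError("scenario and base horizons do not match")
    reduction = {}
    for key in outcomes:
        b = base.at(key, year)
        s = result.at(key, year)
        if b is None or s is None or b == 0:
            if b == 0:
                warnings.warn(f"base outcome {key!r} is zero at {year}; "
                              "reduction undefined", RuntimeWarning, stacklevel=2)
            reduction[key] = None
        else:
            reduction[key] = 100.0 * (b - s) / b
    y0, y1 = int(result.years[0]), int(result.years[-1])
    change = {
        "scenario": {k: result.percent_change(k, y0, y1) for k in outcomes},
        "base": {k: base.percent_change(k, y0, y1) for k in outcomes},
    }
    return {"year": int(year), "reduction_pct": reduction, "change_pct": change}


@dataclass
class SensitivitySpec:
    """Monte-Carlo design: multiplicative +/-range draws on selected rates."""

    varied_params: Sequence[str] = DEFAULT_SENSITIVITY_PARAMS
    rel_range: float = 0.5
    n_runs: int = 500
    ci_level: float = 0.95
    rng_seed: int = 0
    mode: str = "joint"  # joint | one_at_a_time | pairwise

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.rel_range < 0:
            raise ValueError("rel_range must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.mode not in ("joint", "one_at_a_time", "pairwise"):
            raise ValueError("mode must be joint, one_at_a_time or pairwise")
        for p in self.varied_params:
            if p not in _SCHEMA:
                raise KeyError(f"unknown sensitivity parameter path {p!r}")
        if self.n_runs < 40 and self.ci_level >= 0.95:
            warnings.warn("fewer than 40 runs: 95% percentile interval is unstable",
                          RuntimeWarning, stacklevel=2)


@dataclass
class SensitivityResult:
    years: np.ndarray
    mean: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    runs: dict[str, np.ndarray]  # outcome -> (n_runs, n_years)
    draws: np.ndarray  # (n_runs, n_params) multipliers
    spec: SensitivitySpec = None

    def interval(self, outcome: str, year: int):
        idx = np.where(self.years == int(year))[0]
        if idx.size == 0 or outcome not in self.lower:
            return None
        return (float(self.lower[outcome][idx[0]]), float(self.upper[outcome][idx[0]]))

    def to_dict(self) -> dict:
        return {
            "years": [int(y) for y in self.years],
            "mean": {k: list(map(float, v)) for k, v in self.mean.items()},
            "lower": {k: list(map(float, v)) for k, v in self.lower.items()},
            "upper": {k: list(map(float, v)) for k, v in self.upper.items()},
        }


def _draw_multipliers(spec: SensitivitySpec, rng: np.random.Generator) -> np.ndarray:
    k = len(spec.varied_params)
    lo, hi = 1.0 - spec.rel_range, 1.0 + spec.rel_range
    if spec.mode == "joint":
        return rng.uniform(lo, hi, size=(spec.n_runs, k))
    draws = np.ones((spec.n_runs, k))
    if spec.mode == "one_at_a_time":
        active = [(i,) for i in range(k)]
    else:  # pairwise
        active = [(i, j) for i in range(k) for j in range(i + 1, k)] or [(0,)]
    for r in range(spec.n_runs):
        for i in active[r % len(active)]:
            draws[r, i] = rng.uniform(lo, hi)
    return draws


def run_sensitivity(
    spec: SensitivitySpec,
    scenario: ScenarioSpec,
    inputs: DemographyInputs,
    state: InitialState,
    config: ModelConfig,
    outcomes: Sequence[str] = COMPARISON_OUTCOMES,
) -> SensitivityResult:
    """Seeded Monte-Carlo over the varied rates; per-year mean and the
    empirical (1-ci)/2 and 1-(1-ci)/2 percentiles of each outcome."""
    rng = np.random.default_rng(spec.rng_seed)
    draws = _draw_multipliers(spec, rng)
    baseline = np.array([float(config[p]) for p in spec.varied_params])

    runs = None
    years = None
    for r in range(spec.n_runs):
        cfg = config.copy()
        for p, mult, base in zip(spec.varied_params, draws[r], baseline):
            cfg.set(p, float(base * mult))
        res = run_scenario(scenario, inputs, state, cfg)
        if runs is None:
            years = res.years
            runs = {k: np.zeros((spec.n_runs, years.size)) for k in outcomes}
        for k in outcomes:
            runs[k][r] = res.series[k]

    alpha = (1.0 - spec.ci_level) / 2.0
    mean = {k: v.mean(axis=0) for k, v in runs.items()}
    lower = {k: np.quantile(v, alpha, axis=0) for k, v in runs.items()}
    upper = {k: np.quantile(v, 1.0 - alpha, axis=0) for k, v in runs.items()}
    return SensitivityResult(years, mean, lower, upper, runs, draws, spec)
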