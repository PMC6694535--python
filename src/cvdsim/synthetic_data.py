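"""Synthetic inputs with known ground truth.

Everything the model would normally ingest from national statistics —
an age pyramid, life tables, fertility, migration, initial risk-factor
stocks, and calibration target series — is generated here so that every
other module is testable offline.  The generator emits the same structures
(and CSV layouts) the demography and calibration modules consume.

Mortality is Gompertz (``m = a * exp(b * age)``, capped at 1) and initial
prevalence curves are logistic in age; both are parametric and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit

from . import cvd_engine as ce
from .calibration import CalibrationTargets, EventDistribution, calibrate_beta0
from .cli_io import ModelConfig
from .demography import DemographyInputs
from .grids import AGES, GRID_SHAPE, N_AGE, N_SEX, CohortGrid
from .risk_factors import SmokingStocks, TwoStageStocks
from .simulate import InitialState, engine_inputs, run_simulation

# printed 2010 anchors used to initialize the Singapore-like fixture
DIABETICS_2010 = 369_133.0
HYPERTENSIVES_2010 = 659_958.0
SMOKERS_2010 = 414_789.0
CVD_EVENTS_2010 = 33_292.0
POST_CVD_2010 = 112_606.0
MANAGED_SHARE_DIABETES_2010 = 0.44
MANAGED_SHARE_HYPERTENSION_2010 = 0.43
#: adult (18+) resident population implied by the printed prevalence anchors
ADULT_POPULATION_2010 = 3_200_000.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic input generator."""

    population_scale: float = 1e6
    pyramid_shape: Mapping[str, float] = field(
        default_factory=lambda: {
            "midpoint": 60.0,
            "width": 8.0,
            "bulge_center": 45.0,
            "bulge_width": 15.0,
            "bulge_share": 0.6,
            "female_share": 0.51,
        }
    )
    mortality_model: Mapping[str, tuple] = field(
        default_factory=lambda: {"female": (2.0e-5, 0.095), "male": (3.2e-5, 0.095)}
    )
    fertility: float = 0.033
    horizon: int = 31
    migration_per_year: float = 0.0
    entrants_decay: float = 1.0  # annual shrink factor of the age-18 entrant cohort
    true_params: Optional[ModelConfig] = None
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.population_scale <= 0:
            raise ValueError("population_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for sex in ("female", "male"):
            a, b = self.mortality_model[sex]
            if a < 0:
                raise ValueError("Gompertz level must be >= 0")
            if a * np.exp(b * AGES[0]) > 1.0:
                raise ValueError("Gompertz mortality exceeds 1 at the youngest age")

    def config(self) -> ModelConfig:
        return (self.true_params or ModelConfig()).copy()


def gompertz_mortality(a: float, b: float, ages=AGES) -> np.ndarray:
    """Gompertz hazard a * exp(b * age), capped at 1."""
    return np.minimum(a * np.exp(b * np.asarray(ages, dtype=float)), 1.0)


def _pyramid(spec: SyntheticSpec) -> CohortGrid:
    p = spec.pyramid_shape
    shape = expit((p["midpoint"] - AGES) / p["width"])
    bshare = p.get("bulge_share", 0.0)
    if bshare:
        bulge = np.exp(-0.5 * ((AGES - p["bulge_center"]) / p["bulge_width"]) ** 2)
        shape = (1.0 - bshare) * shape + bshare * bulge
    fshare = p.get("female_share", 0.5)
    grid = np.empty(GRID_SHAPE)
    grid[:, 0] = shape * fshare
    grid[:, 1] = shape * (1.0 - fshare)
    return CohortGrid(grid / grid.sum() * spec.population_scale)


def make_demography(spec: SyntheticSpec, start_year: int = 2010) -> DemographyInputs:
    """Deterministic demographic inputs for ``spec.horizon`` years."""
    n = spec.horizon
    pop = _pyramid(spec)
    mort = np.empty((n,) + GRID_SHAPE)
    for si, sex in enumerate(("female", "male")):
        a, b = spec.mortality_model[sex]
        mort[:, :, si] = gompertz_mortality(a, b)[np.newaxis, :]
    mig = np.zeros((n,) + GRID_SHAPE)
    if spec.migration_per_year:
        band = (AGES >= 25) & (AGES <= 44)
        mig[:, band, :] = spec.migration_per_year / (band.sum() * N_SEX)
    fert = np.full(n, float(spec.fertility))
    entrants = None
    if spec.entrants_decay != 1.0:
        base = pop.values[0, :]
        entrants = base[np.newaxis, :] * (spec.entrants_decay ** np.arange(n))[:, np.newaxis]
    return DemographyInputs(pop, start_year, fert, mort, mig, entrants_18=entrants)


def _scaled_logistic_prevalence(pop: np.ndarray, target_count: float,
                                midpoint: float, width: float,
                                cap: float = 0.9) -> np.ndarray:
    """Logistic-in-age prevalence grid scaled so counts hit ``target_count``."""
    shape = expit((AGES - midpoint) / width)[:, np.newaxis] * np.ones(GRID_SHAPE)
    if target_count <= 0:
        return np.zeros(GRID_SHAPE)
    lo, hi = 0.0, 1.0
    while (np.minimum(shape * hi, cap) * pop).sum() < target_count:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("target count unreachable under prevalence cap")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (np.minimum(shape * mid, cap) * pop).sum() < target_count:
            lo = mid
        else:
            hi = mid
    return np.minimum(shape * 0.5 * (lo + hi), cap)


def build_initial_state(
    pop: CohortGrid,
    *,
    diabetics: float,
    hypertensives: float,
    smokers: float,
    post_cvd_total: float,
    managed_share_diabetes: float = MANAGED_SHARE_DIABETES_2010,
    managed_share_hypertension: float = MANAGED_SHARE_HYPERTENSION_2010,
    pre_diabetes_fraction: float = 0.14,
    prehypertension_fraction: float = 0.28,
    former_per_current: float = 1.62,
) -> InitialState:
    """Distribute aggregate counts over age/sex into valid initial stocks.

    Disease prevalence rises logistically with age; smoking declines with
    age; the former-smoker stock defaults to the cessation/relapse
    flow-balance ratio of the current-smoker stock.
    """
    P = pop.values
    total = P.sum()

    def two_stage(dis_count, pre_frac, managed, mid_d, wid_d, mid_p, wid_p):
        dis = _scaled_logistic_prevalence(P, dis_count, mid_d, wid_d) * P
        pre = _scaled_logistic_prevalence(P, pre_frac * total, mid_p, wid_p) * P
        # shrink the pre-stage (not the anchored disease count) where the two
        # stages would overfill a cell
        room = np.clip(P - dis, 0.0, None)
        pre = np.minimum(pre, room * (1 - 1e-12))
        return TwoStageStocks(
            healthy=CohortGrid(P - dis - pre),
            pre_unmanaged=CohortGrid(pre * (1 - managed)),
            pre_managed=CohortGrid(pre * managed),
            disease_unmanaged=CohortGrid(dis * (1 - managed)),
            disease_managed=CohortGrid(dis * managed),
        )

    dia = two_stage(diabetics, pre_diabetes_fraction, managed_share_diabetes,
                    52.0, 11.0, 45.0, 11.0)
    hyp = two_stage(hypertensives, prehypertension_fraction, managed_share_hypertension,
                    50.0, 9.0, 40.0, 10.0)

    cur = _scaled_logistic_prevalence(P, smokers, 60.0, -12.0, cap=0.6) * P
    fo = np.minimum(cur * former_per_current, np.clip(0.95 * P - cur, 0.0, None))
    smo = SmokingStocks(
        never=CohortGrid(P - cur - fo), current=CohortGrid(cur), former=CohortGrid(fo)
    )

    post = _scaled_logistic_prevalence(P, post_cvd_total, 68.0, 8.0, cap=0.5) * P
    return InitialState(dia, hyp, smo, CohortGrid(post), pop.copy())


@dataclass
class Fixture:
    inputs: DemographyInputs
    state: InitialState
    config: ModelConfig


def make_singapore_like_fixture(
    scale: float = 1.0,
    seed: int = 0,
    config: Optional[ModelConfig] = None,
    horizon: int = 31,
    migration_per_year: float = 18_000.0,
) -> Fixture:
    """A packaged fixture anchored to the printed 2010 aggregates.

    Aggregate 2010 prevalences (diabetes, hypertension, current smokers,
    post-CVD stock) match the printed national values scaled by ``scale``;
    parameters default to the packaged table.  The fixture config enables
    ``eq10_literal`` because that adjustment convention is the one consistent
    with the published scenario ordering.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    spec = SyntheticSpec(
        population_scale=ADULT_POPULATION_2010 * scale,
        horizon=horizon,
        migration_per_year=migration_per_year * scale,
        entrants_decay=0.99,
        rng_seed=seed,
    )
    inputs = make_demography(spec, start_year=2010)
    state = build_initial_state(
        inputs.initial_population,
        diabetics=DIABETICS_2010 * scale,
        hypertensives=HYPERTENSIVES_2010 * scale,
        smokers=SMOKERS_2010 * scale,
        post_cvd_total=POST_CVD_2010 * scale,
        former_per_current=1.0,
    )
    cfg = (config or ModelConfig()).copy()
    cfg.set("modes.eq10_literal", True)
    return Fixture(inputs, state, cfg)


def calibrated_fixture(
    seed: int = 0,
    scale: float = 1.0,
    config: Optional[ModelConfig] = None,
) -> tuple[Fixture, dict]:
    """Fixture with risk-group intercepts recalibrated to the 2010 anchors.

    The intercepts are solved so that treatment-adjusted expected events in
    2010 equal the printed national event count, split across groups by the
    packaged expert distribution.  (The treatment multiplier is folded into
    the group populations, which is exact because it does not depend on the
    intercept.)
    """
    fixture = make_singapore_like_fixture(scale=scale, seed=seed, config=config)
    cfg = fixture.config
    params = cfg.risk_engine_params()
    eng = engine_inputs(
        fixture.state.diabetes,
        fixture.state.hypertension,
        fixture.state.smoking,
        fixture.state.post_cvd,
        fixture.state.reference_pop,
        cfg,
    )
    mult = ce.group_risk_multiplier(
        eng["coverages"], params, eq10_literal=cfg["modes.eq10_literal"]
    )
    pop_eff = eng["pop_by_group"] * mult
    targets = CalibrationTargets(
        years=np.array([2010]),
        series={},
        event_distribution=cfg.event_distribution(),
        total_events=CVD_EVENTS_2010 * scale,
    )
    beta0 = calibrate_beta0(targets, pop_eff, params)
    for group, value in beta0.items():
        cfg.set(f"cvd.beta0.{group}", float(value))
    report = {
        "beta0": beta0,
        "target_events_2010": CVD_EVENTS_2010 * scale,
        "config_hash": cfg.config_hash(),
    }
    return fixture, report


TARGET_SERIES = (
    "prevalence_diabetes",
    "prevalence_hypertension",
    "prevalence_smoking",
    "cvd_events",
)


def synthetic_state(spec: SyntheticSpec, inputs: DemographyInputs) -> InitialState:
    """Generic (non-anchored) initial stocks for a synthetic population."""
    total = spec.population_scale
    return build_initial_state(
        inputs.initial_population,
        diabetics=0.113 * total,
        hypertensives=0.205 * total,
        smokers=0.13 * total,
        post_cvd_total=0.035 * total,
    )


def observation_simulator(spec: SyntheticSpec, start_year: int = 2010):
    """A closure mapping {config path: value} to noise-free target series.

    This is the forward model handed to :func:`cvdsim.calibration.fit_rates`
    in parameter-recovery settings; it shares inputs and initial state with
    :func:`make_observations`.
    """
    cfg0 = spec.config()
    inputs = make_demography(spec, start_year=start_year)
    state = synthetic_state(spec, inputs)
    end_year = start_year + spec.horizon - 1

    def simulate_fn(params: Mapping[str, float]):
        cfg = cfg0.copy()
        for path, value in params.items():
            cfg.set(path, float(value))
        res = run_simulation(inputs, state, cfg, start_year=start_year,
                             end_year=end_year, scenario="synthetic-fit")
        return {k: res.series[k] for k in TARGET_SERIES}

    return simulate_fn


def make_observations(spec: SyntheticSpec, start_year: int = 2010) -> CalibrationTargets:
    """Run the model under ``spec.true_params`` and emit noisy target series.

    Observation noise is multiplicative lognormal with log-sd ``noise_sd``;
    the attached event distribution is computed from the simulated
    group-level events (and is therefore exactly normalized).
    """
    cfg = spec.config()
    inputs = make_demography(spec, start_year=start_year)
    state = synthetic_state(spec, inputs)
    end_year = start_year + spec.horizon - 1
    res = run_simulation(inputs, state, cfg, start_year=start_year, end_year=end_year,
                         scenario="synthetic-truth")
    rng = np.random.default_rng(spec.rng_seed)
    series = {}
    for key in TARGET_SERIES:
        clean = res.series[key]
        noise = (
            np.exp(rng.normal(0.0, spec.noise_sd, size=clean.shape))
            if spec.noise_sd > 0
            else 1.0
        )
        series[key] = clean * noise
    group_tot = res.group_events.sum(axis=0)
    dist = EventDistribution(
        {g: float(v / group_tot.sum()) for g, v in zip(ce.GROUPS, group_tot)}
    )
    return CalibrationTargets(
        res.years, series, event_distribution=dist,
        total_events=float(res.series["cvd_events"][0]),
    )
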