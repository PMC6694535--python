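"""Eight-risk-group CVD event engine.

The adult population is partitioned into the 2^3 combinations of
{diabetes, hypertension, smoking}.  Each group g carries a logistic annual
event probability

    p(g, age, sex) = 1 / (1 + exp(-(b0[g] + b_age[sex]*age
                                    + b_d[sex]*1{D in g} + b_h[sex]*1{H in g}
                                    + b_s[sex]*1{S in g})))

which is then adjusted for the fraction of each constituent risk factor
under management.  Two adjustment conventions are supported (see
:func:`adjusted_probability`): the default multiplies the treated fraction's
risk by the relative risk RR; ``eq10_literal=True`` multiplies by (1 - RR)
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .grids import AGES, GRID_SHAPE, N_SEX, CohortGrid, as_grid_array, sex_index

GROUPS = ("none", "D", "H", "S", "DH", "DS", "HS", "DHS")
N_GROUPS = len(GROUPS)
#: factor membership indicators per group, order (diabetes, hypertension, smoking)
GROUP_FACTORS = {
    "none": (0, 0, 0),
    "D": (1, 0, 0),
    "H": (0, 1, 0),
    "S": (0, 0, 1),
    "DH": (1, 1, 0),
    "DS": (1, 0, 1),
    "HS": (0, 1, 1),
    "DHS": (1, 1, 1),
}
FACTORS = ("diabetes", "hypertension", "smoking")


def _per_sex(value) -> np.ndarray:
    if isinstance(value, Mapping):
        return np.array([float(value["female"]), float(value["male"])])
    arr = np.asarray(value, dtype=float)
    return np.full(N_SEX, float(arr)) if arr.ndim == 0 else arr


@dataclass
class RiskEngineParams:
    """Framingham-style coefficients plus treatment effects."""

    beta0: Mapping[str, float]
    beta_age: Mapping[str, float] | np.ndarray
    beta_diabetes: Mapping[str, float] | np.ndarray
    beta_hypertension: Mapping[str, float] | np.ndarray
    beta_smoking: Mapping[str, float] | np.ndarray
    rr_treated_diabetes: float = 0.8
    rr_treated_hypertension: float = 0.5
    rr_treated_smoking_cessation: float = 0.5
    event_death_rate: float = 0.2
    rr_death_post_cvd: float = 1.6
    treatment_mortality_effect: float = 0.13
    fraction_post_cvd_treated: float = 1.0

    def __post_init__(self):
        missing = set(GROUPS) - set(self.beta0)
        if missing:
            raise ValueError(f"beta0 missing groups: {sorted(missing)}")
        for name in ("rr_treated_diabetes", "rr_treated_hypertension",
                     "rr_treated_smoking_cessation"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.event_death_rate <= 1:
            raise ValueError("event_death_rate must lie in [0, 1]")
        if self.rr_death_post_cvd <= 0:
            raise ValueError("rr_death_post_cvd must be > 0")
        if not 0 <= self.fraction_post_cvd_treated <= 1:
            raise ValueError("fraction_post_cvd_treated must lie in [0, 1]")

    def slopes(self) -> dict[str, np.ndarray]:
        return {
            "age": _per_sex(self.beta_age),
            "diabetes": _per_sex(self.beta_diabetes),
            "hypertension": _per_sex(self.beta_hypertension),
            "smoking": _per_sex(self.beta_smoking),
        }

    def rr_for(self, factor: str) -> float:
        return {
            "diabetes": self.rr_treated_diabetes,
            "hypertension": self.rr_treated_hypertension,
            "smoking": self.rr_treated_smoking_cessation,
        }[factor]


@dataclass
class RiskGroupShares:
    """Fractions per (group, age, sex); sum over groups = 1 in every cell."""

    share: np.ndarray  # (8, 83, 2)

    def __post_init__(self):
        self.share = np.asarray(self.share, dtype=float)
        if self.share.shape != (N_GROUPS,) + GRID_SHAPE:
            raise ValueError(f"share must have shape {(N_GROUPS,) + GRID_SHAPE}")
        if self.share.min() < -1e-9:
            raise ValueError("shares must be >= 0")
        tot = self.share.sum(axis=0)
        if not np.allclose(tot, 1.0, atol=1e-6):
            raise ValueError("shares must sum to 1 per age/sex cell")

    def __getitem__(self, group: str) -> np.ndarray:
        return self.share[GROUPS.index(group)]


@dataclass
class CvdState:
    """Post-event stock plus the current year's event/death tallies."""

    post_cvd: CohortGrid
    annual_events: float = 0.0
    annual_event_deaths: float = 0.0
    annual_post_cvd_deaths: float = 0.0

    def __post_init__(self):
        for name in ("annual_events", "annual_event_deaths", "annual_post_cvd_deaths"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def partition_risk_groups(prev_d, prev_h, prev_s, mode: str = "independence") -> RiskGroupShares:
    """Allocate the population across the eight risk groups from marginal prevalences.

    ``independence`` (default) assumes the three factors are independent:
    share(DHS) = prev_d * prev_h * prev_s, share(none) = product of
    complements, and so on.  ``even_split`` seeds each factor's mass evenly
    across its four containing groups and reconciles to the exact marginals
    by iterative proportional fitting.
    """
    pd_, ph, ps = (as_grid_array(p) for p in (prev_d, prev_h, prev_s))
    for name, p in (("prev_d", pd_), ("prev_h", ph), ("prev_s", ps)):
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValueError(f"{name} must lie in [0, 1]")

    if mode == "independence":
        share = np.empty((N_GROUPS,) + GRID_SHAPE)
        for gi, g in enumerate(GROUPS):
            d, h, s = GROUP_FACTORS[g]
            share[gi] = (
                (pd_ if d else 1 - pd_) * (ph if h else 1 - ph) * (ps if s else 1 - ps)
            )
        return RiskGroupShares(share)
    if mode == "even_split":
        return RiskGroupShares(_even_split_ipf(pd_, ph, ps))
    raise ValueError(f"unknown partition mode {mode!r}")


def _even_split_ipf(pd_, ph, ps, iters: int = 400, eps: float = 1e-12) -> np.ndarray:
    # cells indexed (d, h, s) in a 2x2x2 table per age/sex cell
    x = np.full((2, 2, 2) + GRID_SHAPE, eps)
    for g, (d, h, s) in GROUP_FACTORS.items():
        x[d, h, s] += d * pd_ / 4 + h * ph / 4 + s * ps / 4
    x[0, 0, 0] += np.clip(1.0 - (pd_ + ph + ps), 0.0, None)
    margins = [np.stack([1 - pd_, pd_]), np.stack([1 - ph, ph]), np.stack([1 - ps, ps])]
    for _ in range(iters):
        for axis, target in enumerate(margins):
            cur = x.sum(axis=tuple(a for a in range(3) if a != axis))
            with np.errstate(invalid="ignore", divide="ignore"):
                fac = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            shape = [1, 1, 1] + list(GRID_SHAPE)
            shape[axis] = 2
            x = x * fac.reshape(shape)
        x = np.clip(x, 0.0, None)
    tot = x.sum(axis=(0, 1, 2))
    x = x / np.where(tot > 0, tot, 1.0)
    share = np.empty((N_GROUPS,) + GRID_SHAPE)
    for gi, g in enumerate(GROUPS):
        d, h, s = GROUP_FACTORS[g]
        share[gi] = x[d, h, s]
    return share


def linear_predictor(group: str, age, sex, params: RiskEngineParams,
                     include_intercept: bool = True):
    """The logit-scale score for a group at given age(s) and sex."""
    si = sex_index(sex)
    d, h, s = GROUP_FACTORS[group]
    slopes = params.slopes()
    lin = (
        slopes["age"][si] * np.asarray(age, dtype=float)
        + d * slopes["diabetes"][si]
        + h * slopes["hypertension"][si]
        + s * slopes["smoking"][si]
    )
    if include_intercept:
        lin = lin + float(params.beta0[group])
    return lin


def cvd_probability(group: str, age, sex, params: RiskEngineParams):
    """Annual CVD event probability for one risk group (logistic in age).

    Strictly inside (0, 1) and monotone increasing in age when the age slope
    is positive.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown risk group {group!r}")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 18) or np.any(age_arr > 100):
        raise ValueError("age must lie in [18, 100]")
    from scipy.special import expit

    out = expit(linear_predictor(group, age_arr, sex, params))
    return float(out) if out.ndim == 0 else out


def probability_grid(params: RiskEngineParams) -> np.ndarray:
    """Unadjusted event probabilities, shape (8, 83, 2)."""
    out = np.empty((N_GROUPS,) + GRID_SHAPE)
    for gi, g in enumerate(GROUPS):
        for si in range(N_SEX):
            out[gi, :, si] = cvd_probability(g, AGES, si, params)
    return out


def adjusted_probability(p, coverage, rr, eq10_literal: bool = False):
    """Treatment-adjusted event probability.

    The untreated fraction keeps risk ``p``; the treated fraction's risk is
    multiplied by ``rr`` (default convention, i.e. a 20% risk cut for
    rr = 0.8) or by ``(1 - rr)`` when ``eq10_literal`` is set, reproducing
    the alternative printed-formula convention.
    """
    p = np.asarray(p, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    if np.any(cov < 0) or np.any(cov > 1):
        raise ValueError("coverage must lie in [0, 1]")
    if not 0 < rr <= 1:
        raise ValueError("rr must lie in (0, 1]")
    mult = (1.0 - rr) if eq10_literal else rr
    out = p * (1.0 - cov) + p * cov * mult
    return float(out) if out.ndim == 0 else out


def group_risk_multiplier(coverages: Mapping[str, np.ndarray], params: RiskEngineParams,
                          eq10_literal: bool = False) -> np.ndarray:
    """Per-group multiplicative risk adjustment from per-factor coverage.

    Coverage is tracked per factor; management status is assumed independent
    across factors, so a group's multiplier is the product over its
    constituent factors of ``(1 - cov_f) + cov_f * m_f``.
    """
    mult = np.ones((N_GROUPS,) + GRID_SHAPE)
    for gi, g in enumerate(GROUPS):
        for fi, factor in enumerate(FACTORS):
            if GROUP_FACTORS[g][fi]:
                cov = as_grid_array(coverages.get(factor, 0.0))
                rr = params.rr_for(factor)
                m = (1.0 - rr) if eq10_literal else rr
                mult[gi] *= (1.0 - cov) + cov * m
    return mult


def compute_events(pop_by_group: np.ndarray, adjusted_p: np.ndarray) -> np.ndarray:
    """Annual events per group/age/sex: elementwise persons x probability."""
    pop = np.asarray(pop_by_group, dtype=float)
    p = np.asarray(adjusted_p, dtype=float)
    if pop.shape != p.shape:
        raise ValueError("pop_by_group and adjusted_p shapes must match")
    return pop * p


def update_post_cvd(state: CvdState, events, params: RiskEngineParams, mortality) -> CvdState:
    """Apply one year of event inflow and post-event mortality to the CVD stock.

    Event deaths are ``events * event_death_rate``; survivors join the
    post-CVD stock.  Post-CVD deaths use background mortality scaled by
    ``rr_death_post_cvd`` and reduced by treatment
    (``1 - treatment_mortality_effect * fraction_post_cvd_treated``), capped
    so no cell goes negative.
    """
    ev = as_grid_array(events)
    if np.any(ev < 0):
        raise ValueError("events must be >= 0")
    m = as_grid_array(mortality)
    event_deaths = ev * params.event_death_rate
    survivors = ev - event_deaths
    death_rate = np.clip(
        m * params.rr_death_post_cvd
        * (1.0 - params.treatment_mortality_effect * params.fraction_post_cvd_treated),
        0.0,
        1.0,
    )
    post_deaths = state.post_cvd.values * death_rate
    new_post = state.post_cvd.values - post_deaths + survivors
    return CvdState(
        post_cvd=CohortGrid(new_post),
        annual_events=float(ev.sum()),
        annual_event_deaths=float(event_deaths.sum()),
        annual_post_cvd_deaths=float(post_deaths.sum()),
    )


def age_adjusted_incidence(events, pop, standard_pop) -> float:
    """Directly standardized incidence: sum of cell rates weighted by a standard.

    Cells with zero population are excluded (with a warning) and the standard
    weights renormalized over the remaining cells.
    """
    ev = as_grid_array(events)
    po = as_grid_array(pop)
    st = as_grid_array(standard_pop)
    if st.sum() <= 0:
        raise ValueError("standard population total must be > 0")
    ok = po > 0
    if not np.all(ok[st > 0]):
        warnings.warn("empty population cells excluded from standardization",
                      RuntimeWarning, stacklevel=2)
    w = np.where(ok, st, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        return float("nan")
    rate = np.zeros_like(po)
    rate[ok] = ev[ok] / po[ok]
    return float((rate * w).sum() / wsum)
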