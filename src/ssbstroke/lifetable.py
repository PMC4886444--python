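"""Proportional multi-state life table for stroke.

Each 5-year age x sex cohort of the 2012 adult population is simulated by
single year of age until death or age 100, in a reference arm and an
intervention arm whose stroke incidence is scaled by (1 - PIF). The state
vector splits the living into healthy (S) and prevalent stroke cases (C);
28-day acute deaths leave directly from incident cases, prevalent cases die
at the case-fatality rate, and all-cause other mortality applies
proportionally to both living states. Outputs per cohort-year: incident
cases, mid-year prevalent cases, stroke and total deaths, life years,
health-adjusted life years and stroke health-care costs.

Annual transition probabilities are obtained from rates as p = 1 - exp(-r).
Closed cohorts only: no new entrants after baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NumericalError, StructuralError, ValidationError
from .scenario import TaxScenario
from .strata import MAX_AGE, SEXES, band_lowers, band_of_age

logger = logging.getLogger(__name__)

EPI_COLUMNS = (
    "population",
    "acm_rate",          # all-cause mortality rate /yr
    "incidence",         # stroke incidence rate /yr among the healthy
    "prevalence",        # baseline prevalent fraction
    "case_fatality",     # annual rate at which prevalent cases die of stroke
    "d28",               # proportion of incident cases fatal within 28 days
    "pyld_rate",         # total prevalent YLD per person-year (all causes)
    "cost_per_case_year",  # ZAR per prevalent case-year
)

STROKE_DISABILITY_WEIGHT = 0.28


@dataclass(frozen=True)
class CostInputs:
    """Sector-weighted stroke care cost: 18 % of the population uses private
    facilities and public-sector costs run at ~70 % of private costs."""

    private_cost: float
    private_share: float = 0.18
    public_ratio: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 <= self.private_share <= 1.0:
            raise ValidationError("private_share must be in [0, 1]")
        if self.public_ratio <= 0:
            raise ValidationError("public_ratio must be > 0")
        if self.private_cost < 0:
            raise ValidationError("private_cost must be >= 0")


def weighted_cost(c: CostInputs) -> float:
    """Population-weighted cost per prevalent case-year (ZAR)."""
    return c.private_share * c.private_cost + (1.0 - c.private_share) * (
        c.public_ratio * c.private_cost
    )


def discount_series(values, rate: float):
    """Discount a per-year series at `rate`/yr; model year t (0-indexed) is
    divided by (1 + rate)^t. Rate 0 returns the series unchanged."""
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[-1])
    return values / (1.0 + rate) ** t


def disease_step(S, C, incidence, case_fatality, d28, m_other, pif=0.0):
    """One annual cycle of the stroke sub-model.

    Returns (S_next, C_next, new_cases, acute_deaths, case_deaths,
    other_deaths). Effective incidence is incidence * (1 - pif). Other-cause
    mortality applies proportionally to both living states after the disease
    transitions, so persons_in == persons_out + deaths exactly.
    """
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    i_eff = np.asarray(incidence, dtype=float) * (1.0 - np.asarray(pif, dtype=float))
    if np.any(i_eff < 0):
        raise ValidationError("effective incidence went negative (pif > 1?)")

    new_cases = S * -np.expm1(-i_eff)
    acute_deaths = new_cases * d28
    entering = new_cases - acute_deaths
    case_deaths = C * -np.expm1(-np.asarray(case_fatality, dtype=float))

    S_mid = S - new_cases
    C_mid = C - case_deaths + entering

    p_other = -np.expm1(-np.asarray(m_other, dtype=float))
    other_S = S_mid * p_other
    other_C = C_mid * p_other
    S_next = S_mid - other_S
    C_next = C_mid - other_C

    if np.any(S_next < 0) or np.any(C_next < 0):
        raise NumericalError(
            "state occupancy went negative; annual rates too large for the "
            "difference equations (validate rates < ~2/yr)"
        )
    return S_next, C_next, new_cases, acute_deaths, case_deaths, other_S + other_C


@dataclass
class CohortResults:
    """Per-cohort per-year trajectories for one arm.

    Arrays have shape (n_bands, n_sexes, n_years); `entry_age[b]` is the
    lower bound of cohort b's age band at baseline. Cohort (b, s) is active
    while entry_age[b] + t < 100; inactive cells are zero.
    """

    age_groups: tuple
    sexes: tuple
    arrays: dict = field(repr=False)
    arm: str = "reference"

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def by_sex(self, key: str) -> pd.DataFrame:
        """Sum over cohorts -> DataFrame (year x sex)."""
        a = self.arrays[key].sum(axis=0)  # (n_sexes, n_years)
        return pd.DataFrame(a.T, columns=list(self.sexes)).rename_axis("year")

    def total(self, key: str) -> np.ndarray:
        return self.arrays[key].sum(axis=(0, 1))


_RESULT_KEYS = (
    "incident_cases", "prevalent_mid", "stroke_deaths", "other_deaths",
    "total_deaths", "life_years", "halys", "costs", "alive_start",
)


def run_cohort(
    epi: pd.DataFrame,
    pifs: pd.DataFrame | None,
    scenario: TaxScenario,
    arm: str = "reference",
    disability_weight: float = STROKE_DISABILITY_WEIGHT,
    sim_years: int | None = None,
) -> CohortResults:
    """Simulate every cohort for one arm.

    `epi` is indexed by (age_group, sex) with the columns in
    :data:`EPI_COLUMNS`. `pifs` (strata x year) scales incidence in the
    intervention arm; the reference arm passes None (PIF = 0). Rates are
    looked up by a cohort's *current* age band as it ages; ages beyond the
    last band reuse the last band's rates.

    `sim_years` caps the number of simulated years (default: until age 100).
    Every reported output over the scenario horizon is unchanged by a cap at
    >= horizon_years, since outputs are per-year functions of state.
    """
    missing = [c for c in EPI_COLUMNS if c not in epi.columns]
    if missing:
        raise StructuralError(f"epi table lacks columns {missing}")
    age_groups = tuple(epi.index.get_level_values("age_group").unique())
    sexes = tuple(epi.index.get_level_values("sex").unique())
    n_b, n_s = len(age_groups), len(sexes)

    full_idx = pd.MultiIndex.from_product(
        [list(age_groups), list(sexes)], names=["age_group", "sex"]
    )
    epi_full = epi if epi.index.equals(full_idx) else epi.reindex(full_idx)
    if epi_full[list(EPI_COLUMNS)].isna().any().any():
        raise StructuralError("epi table missing strata for the full age x sex grid")

    def grid(col):
        return epi_full[col].to_numpy().reshape(n_b, n_s)

    pop = grid("population")
    acm = grid("acm_rate")
    inc = grid("incidence")
    prev0 = grid("prevalence")
    cf = grid("case_fatality")
    d28 = grid("d28")
    pyld = grid("pyld_rate")
    unit_cost = grid("cost_per_case_year")

    # stroke's own pYLD contribution at baseline prevalence is removed from
    # the background so intervention-driven prevalence changes flow into HALYs
    pyld_bg = np.clip(pyld - prev0 * disability_weight, 0.0, None)
    pyld_bg = pyld_bg * scenario.pyld_scale

    pif_arr = None
    if pifs is not None:
        pif_arr = (
            pifs.reindex(pd.MultiIndex.from_product(
                [list(age_groups), list(sexes)], names=["age_group", "sex"]))
            .to_numpy()
            .reshape(n_b, n_s, -1)
        )
        if np.isnan(pif_arr).any():
            raise StructuralError("PIF table missing strata present in epi inputs")

    lowers = np.array(band_lowers(age_groups))
    total_years = int((MAX_AGE - lowers.min()))
    if sim_years is not None:
        total_years = min(total_years, int(sim_years))

    C = pop * prev0
    S = pop - C
    out = {k: np.zeros((n_b, n_s, total_years)) for k in _RESULT_KEYS}

    warned_overflow = False
    for t in range(total_years):
        age = lowers + t                      # (n_b,)
        active = age < MAX_AGE
        if not active.any():
            break
        cur = np.array([band_of_age(a, age_groups) for a in age])
        if not warned_overflow and np.any(age[active] > lowers[-1] + 4):
            logger.warning("ages beyond the last band use the last band's rates")
            warned_overflow = True

        a_mask = active[:, None]              # broadcast over sex
        pif_t = 0.0
        if pif_arr is not None:
            pif_t = pif_arr[cur, :, min(t, pif_arr.shape[2] - 1)]

        S_next, C_next, new_cases, acute, case_d, other_d = disease_step(
            S, C, inc[cur, :], cf[cur, :], d28[cur, :], acm[cur, :], pif_t
        )
        S_next = np.where(a_mask, S_next, 0.0)
        C_next = np.where(a_mask, C_next, 0.0)

        alive_start = S + C
        alive_end = S_next + C_next
        c_mid = np.where(a_mask, (C + C_next) / 2.0, 0.0)
        ly = np.where(a_mask, (alive_start + alive_end) / 2.0, 0.0)
        haly = ly * (1.0 - pyld_bg[cur, :]) - c_mid * disability_weight

        out["incident_cases"][:, :, t] = np.where(a_mask, new_cases, 0.0)
        out["prevalent_mid"][:, :, t] = c_mid
        out["stroke_deaths"][:, :, t] = np.where(a_mask, acute + case_d, 0.0)
        out["other_deaths"][:, :, t] = np.where(a_mask, other_d, 0.0)
        out["total_deaths"][:, :, t] = out["stroke_deaths"][:, :, t] + out["other_deaths"][:, :, t]
        out["life_years"][:, :, t] = ly
        out["halys"][:, :, t] = np.where(a_mask, haly, 0.0)
        out["costs"][:, :, t] = c_mid * unit_cost[cur, :] * scenario.cost_scale
        out["alive_start"][:, :, t] = np.where(a_mask, alive_start, 0.0)

        S, C = S_next, C_next

    return CohortResults(age_groups, sexes, out, arm)


def aggregate_results(
    ref: CohortResults,
    intervention: CohortResults,
    scenario: TaxScenario,
    detail: bool = True,
) -> dict:
    """Population totals and arm differences over the reporting horizon.

    Returns a dict with:

    - ``per_year``: DataFrame (year x [arm, sex, outcome]) over the horizon,
    - ``pct_reduction``: 100 x (ref - int)/ref for incidence, prevalence and
      stroke mortality by sex and year (NaN where the reference total is 0),
    - ``summary``: horizon totals of cases/deaths/HALYs/costs averted; HALYs
      and costs are discounted at the scenario rate, counts never are.

    With ``detail=False`` only the summary is computed (the per-year frames
    are None); the Monte Carlo driver uses this path.
    """
    h = scenario.horizon_years
    n_years = ref["incident_cases"].shape[2]
    if h > n_years:
        raise ValidationError(
            f"horizon {h} exceeds simulated span {n_years}; cohorts are "
            "simulated to age 100 from a youngest entry age"
        )

    def diff(key):
        return ref.total(key)[:h] - intervention.total(key)[:h]

    d_haly = discount_series(-diff("halys"), scenario.discount_rate)
    d_cost = discount_series(diff("costs"), scenario.discount_rate)
    prev_diff = diff("prevalent_mid")

    summary = {
        "incident_cases_averted": float(diff("incident_cases").sum()),
        "stroke_deaths_averted": float(diff("stroke_deaths").sum()),
        "total_deaths_averted": float(diff("total_deaths").sum()),
        "prevalent_cases_averted_final_year": float(prev_diff[h - 1]),
        "prevalent_case_years_averted": float(prev_diff.sum()),
        "halys_gained": float(d_haly.sum()),
        "costs_saved_zar": float(d_cost.sum()),
        "life_years_gained": float(
            (intervention.total("life_years")[:h] - ref.total("life_years")[:h]).sum()
        ),
        "horizon_years": h,
        "discount_rate": scenario.discount_rate,
    }
    if not detail:
        return {"per_year": None, "pct_reduction": None, "summary": summary}

    frames = {}
    for arm_name, res in (("reference", ref), ("intervention", intervention)):
        for key in ("incident_cases", "prevalent_mid", "stroke_deaths",
                    "total_deaths", "life_years", "halys", "costs"):
            df = res.by_sex(key).iloc[:h]
            for sex in res.sexes:
                frames[(arm_name, sex, key)] = df[sex]
    per_year = pd.DataFrame(frames)
    per_year.columns.names = ["arm", "sex", "outcome"]

    pct = {}
    for sex in ref.sexes:
        for key, name in (("incident_cases", "incidence"),
                          ("prevalent_mid", "prevalence"),
                          ("stroke_deaths", "mortality")):
            r = per_year[("reference", sex, key)].to_numpy()
            i = per_year[("intervention", sex, key)].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.where(r != 0.0, 100.0 * (r - i) / np.where(r == 0, 1, r), np.nan)
            pct[(sex, name)] = vals
    pct_reduction = pd.DataFrame(pct, index=per_year.index)
    pct_reduction.columns.names = ["sex", "outcome"]
    return {"per_year": per_year, "pct_reduction": pct_reduction, "summary": summary}
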