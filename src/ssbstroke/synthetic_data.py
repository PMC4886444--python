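"""Seeded synthetic input bundle.

The model's original inputs — a national nutrition survey (beverage intake),
a panel survey (BMI waves), GBD relative risks and disability rates, vital
registration mortality and medical-scheme claims — are restricted or
unpublished. This module generates a self-consistent synthetic bundle that
emulates their *structure*: plausible magnitudes, age and sex gradients, and
the stated uncertainty inputs. It makes no attempt to match the real joint
distributions; every generated table is a stand-in.

Structural features encoded by construction:

- SSB intake declines with age (young adults drink the most) and the
  population-weighted mean is calibrated exactly to a knob (default
  184 ml/day, the surveyed 2012 adult mean);
- all-cause mortality and stroke incidence rise ~exponentially with age;
- stroke relative risk per 5 BMI units attenuates toward 1 at older ages;
- baseline stroke prevalence is the quasi-steady state implied by incidence,
  case fatality and mortality, so it can never exceed the population;
- about one third of incident strokes are fatal within 28 days;
- BMI is log-normal per stratum with a recorded true (mu, sigma), and two
  synthetic survey "waves" identify the SD-mean slope used to co-move the
  SD with the mean.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bmi_model import (
    SWINBURN_KJ_PER_KG,
    SWINBURN_KJ_PER_KG_SD,
    SDMeanRelation,
    estimate_sd_mean_slope,
    fit_lognormal,
)
from .demand import ElasticityMatrix, default_energy_density_table
from .errors import ValidationError
from .lifetable import STROKE_DISABILITY_WEIGHT, CostInputs, weighted_cost
from .pif import DEFAULT_TMREB, RRSpec
from .strata import (
    BEVERAGES,
    DEFAULT_AGE_GROUPS,
    SEXES,
    band_midpoints,
    consumption_index,
    strata_index,
    validate_age_groups,
)

# Stand-in elasticities of demand with respect to the SSB price, from the
# meta-analysis of LMIC beverage price elasticities (own SSB, cross for
# substitutes). The real model's point values/SDs are in an unavailable
# supplement; these are configurable defaults, not constants.
DEFAULT_ELASTICITIES = {
    "ssb": (-1.299, 0.32),
    "milk": (0.129, 0.085),
    "diet": (0.423, 0.25),
    "juice": (0.388, 0.34),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic bundle. All scale knobs must be >= 0."""

    seed: int = 0
    n_bmi_samples_per_stratum: int = 0
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    sexes: tuple[str, ...] = SEXES

    # population
    total_population: float = 35e6          # adults 15+, 2012-ish
    population_age_decay: float = 0.045     # /yr of age: young pyramid

    # consumption (ml/day)
    ssb_mean_overall: float = 184.0         # calibrated pop-weighted SSB mean
    consumption_age_decay: float = 0.03
    ssb_male_ratio: float = 1.15
    milk_mean: float = 90.0
    juice_mean: float = 25.0
    diet_mean: float = 20.0
    consumption_se_frac: float = 0.06
    consumption_noise: float = 0.05

    # BMI (kg/m^2)
    bmi_base: float = 22.0
    bmi_age_amp_male: float = 4.0
    bmi_age_amp_female: float = 7.5
    bmi_peak_age: float = 55.0
    bmi_sd_at_ref: float = 5.5
    bmi_sd_ref_mean: float = 27.0
    sd_mean_slope: float = 0.25             # true slope recovered from waves
    bmi_noise: float = 0.3
    bmi_mean_override: float | None = None  # force one mean for all strata
    bmi_sd_override: float | None = None

    # heights (m)
    height_male: float = 1.68
    height_female: float = 1.58

    # epidemiology (rates /yr unless noted)
    acm_base: float = 0.004
    acm_age_slope: float = 0.065
    incidence_base: float = 3.5e-4
    incidence_age_slope: float = 0.085
    case_fatality_base: float = 0.10
    case_fatality_age_slope: float = 0.012
    d28_mean: float = 1.0 / 3.0             # ~a third fatal within 28 days
    pyld_background_base: float = 0.02
    pyld_age_slope: float = 0.025
    female_epi_ratio: float = 0.85          # female rates relative to male

    # relative risk per 5 BMI units
    rr_amplitude: float = 0.40
    rr_age_decay: float = 0.02
    rr_log_sd: float = 0.05
    tmreb: float = DEFAULT_TMREB

    # costs (ZAR per prevalent case-year, private sector)
    private_cost: float = 35000.0
    private_share: float = 0.18
    public_ratio: float = 0.70

    disability_weight: float = STROKE_DISABILITY_WEIGHT
    elasticities: dict = field(
        default_factory=lambda: dict(DEFAULT_ELASTICITIES)
    )

    def __post_init__(self) -> None:
        validate_age_groups(self.age_groups)
        scale_knobs = (
            "total_population", "ssb_mean_overall", "milk_mean", "juice_mean",
            "diet_mean", "consumption_se_frac", "consumption_noise",
            "bmi_sd_at_ref", "bmi_noise", "acm_base", "incidence_base",
            "case_fatality_base", "pyld_background_base", "rr_amplitude",
            "rr_log_sd", "private_cost",
        )
        for name in scale_knobs:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.d28_mean <= 1.0:
            raise ValidationError("d28_mean must be in [0, 1]")
        if self.n_bmi_samples_per_stratum < 0:
            raise ValidationError("n_bmi_samples_per_stratum must be >= 0")


@dataclass
class InputBundle:
    """Everything the pipeline needs for one run."""

    consumption: pd.DataFrame        # (age_group, sex, beverage) x [mean, se]
    bmi: pd.DataFrame                # (age_group, sex) x [mean, sd]
    heights: pd.Series               # (age_group, sex) -> m
    epi: pd.DataFrame                # (age_group, sex) x EPI_COLUMNS
    rr: RRSpec
    elasticities: ElasticityMatrix
    energy_density: pd.DataFrame
    costs: CostInputs
    sd_mean_relation: SDMeanRelation
    disability_weight: float = STROKE_DISABILITY_WEIGHT
    k_kj_per_kg: float = SWINBURN_KJ_PER_KG
    k_sd: float = SWINBURN_KJ_PER_KG_SD
    manifest: dict = field(default_factory=dict)
    bmi_samples: dict | None = field(default=None, repr=False)

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(self.epi.index.get_level_values("age_group").unique())

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self.epi.index.get_level_values("sex").unique())

    def copy(self) -> "InputBundle":
        return dataclasses.replace(
            self,
            consumption=self.consumption.copy(),
            bmi=self.bmi.copy(),
            heights=self.heights.copy(),
            epi=self.epi.copy(),
            rr=RRSpec(self.rr.table.copy(), self.rr.tmreb,
                      self.rr.unit_width, self.rr.upper),
            elasticities=ElasticityMatrix(self.elasticities.table.copy(),
                                          validate=False),
            energy_density=self.energy_density.copy(),
            manifest=dict(self.manifest),
        )


def _age_profile(mids: np.ndarray, base: float, slope: float) -> np.ndarray:
    return base * np.exp(slope * (mids - mids[0]))


def generate_bundle(config: SyntheticConfig) -> InputBundle:
    """Generate a deterministic, self-consistent bundle for `config.seed`."""
    rng = np.random.default_rng(config.seed)
    groups = config.age_groups
    sexes = config.sexes
    mids = np.array(band_midpoints(groups))
    x = mids - mids[0]
    n_b = len(groups)
    idx = strata_index(groups, sexes)

    # --- population: young pyramid, slight female excess
    w = np.exp(-config.population_age_decay * x)
    sex_share = {"male": 0.49, "female": 0.51}
    pop = {
        s: config.total_population * sex_share.get(s, 1.0 / len(sexes)) * w / w.sum()
        for s in sexes
    }

    # --- consumption
    cons_rows = {}
    shape = np.exp(-config.consumption_age_decay * x)
    for s in sexes:
        sex_mult = config.ssb_male_ratio if s == "male" else 1.0
        noise = np.exp(rng.normal(0.0, config.consumption_noise, n_b))
        cons_rows[("ssb", s)] = shape * sex_mult * noise
        cons_rows[("milk", s)] = (
            config.milk_mean * np.exp(rng.normal(0.0, config.consumption_noise, n_b))
        )
        cons_rows[("juice", s)] = (
            config.juice_mean
            * np.exp(-0.01 * x)
            * np.exp(rng.normal(0.0, config.consumption_noise, n_b))
        )
        cons_rows[("diet", s)] = (
            config.diet_mean
            * np.exp(-0.02 * x)
            * np.exp(rng.normal(0.0, config.consumption_noise, n_b))
        )
    # calibrate the population-weighted SSB mean exactly to the knob
    ssb_weighted = sum(
        (cons_rows[("ssb", s)] * pop[s]).sum() for s in sexes
    ) / sum(pop[s].sum() for s in sexes)
    if config.ssb_mean_overall > 0 and ssb_weighted > 0:
        scale = config.ssb_mean_overall / ssb_weighted
        for s in sexes:
            cons_rows[("ssb", s)] = cons_rows[("ssb", s)] * scale

    cidx = consumption_index(groups, sexes)
    mean_col = np.empty(len(cidx))
    for j, (g, s, b) in enumerate(cidx):
        mean_col[j] = cons_rows[(b, s)][groups.index(g)]
    consumption = pd.DataFrame(
        {
            "mean_ml_day": mean_col,
            "se_ml_day": mean_col * config.consumption_se_frac,
        },
        index=cidx,
    )

    # --- BMI moments per stratum (+ optional samples with recorded truth)
    bmi_profile = np.exp(-((mids - config.bmi_peak_age) ** 2) / (2.0 * 25.0**2))
    bmi_rows = {}
    for s in sexes:
        amp = config.bmi_age_amp_male if s == "male" else config.bmi_age_amp_female
        mean = config.bmi_base + amp * bmi_profile + rng.normal(0.0, config.bmi_noise, n_b)
        if config.bmi_mean_override is not None:
            mean = np.full(n_b, float(config.bmi_mean_override))
        sd = (
            config.bmi_sd_at_ref
            + config.sd_mean_slope * (mean - config.bmi_sd_ref_mean)
            + rng.normal(0.0, 0.1, n_b)
        )
        if config.bmi_sd_override is not None:
            sd = np.full(n_b, float(config.bmi_sd_override))
        bmi_rows[s] = (mean, np.clip(sd, 0.5, None))
    bmi = pd.DataFrame(
        {
            "mean": [bmi_rows[s][0][groups.index(g)] for g, s in idx],
            "sd": [bmi_rows[s][1][groups.index(g)] for g, s in idx],
        },
        index=idx,
    )

    bmi_samples = None
    true_lognormal = {}
    if config.n_bmi_samples_per_stratum > 0:
        bmi_samples = {}
        for stratum in idx:
            m, s_ = bmi.loc[stratum, "mean"], bmi.loc[stratum, "sd"]
            mu, sigma = fit_lognormal(m, s_)
            true_lognormal[str(stratum)] = {"mu": mu, "sigma": sigma,
                                            "mean": float(m), "sd": float(s_)}
            bmi_samples[stratum] = rng.lognormal(
                mu, sigma, config.n_bmi_samples_per_stratum
            )

    # --- two synthetic waves identify the SD-mean slope
    d_mean = rng.normal(0.8, 0.3, len(idx))
    d_sd = config.sd_mean_slope * d_mean + rng.normal(0.0, 0.05, len(idx))
    slope_hat = estimate_sd_mean_slope(d_mean, d_sd)
    rel = SDMeanRelation(slope=slope_hat)

    # --- heights
    h_base = {"male": config.height_male, "female": config.height_female}
    heights = pd.Series(
        [
            h_base.get(s, 1.63) - 0.0006 * x[groups.index(g)]
            + rng.normal(0.0, 0.004)
            for g, s in idx
        ],
        index=idx,
        name="height_m",
    )

    # --- epidemiology (female rates scaled from male)
    acm_m = _age_profile(mids, config.acm_base, config.acm_age_slope)
    inc_m = _age_profile(mids, config.incidence_base, config.incidence_age_slope)
    cf_m = _age_profile(mids, config.case_fatality_base, config.case_fatality_age_slope)
    epi_rows = {}
    for s in sexes:
        r = 1.0 if s == "male" else config.female_epi_ratio
        acm = acm_m * r * np.exp(rng.normal(0.0, 0.03, n_b))
        inc = inc_m * r * np.exp(rng.normal(0.0, 0.05, n_b))
        cf = cf_m * np.exp(rng.normal(0.0, 0.03, n_b))
        d28 = np.clip(config.d28_mean + rng.normal(0.0, 0.015, n_b), 0.0, 1.0)
        # quasi-steady-state prevalence implied by the flows; bounded < 1
        prev = np.clip(inc * (1.0 - d28) / (cf + acm + inc), 0.0, 0.5)
        pyld_bg = _age_profile(mids, config.pyld_background_base, config.pyld_age_slope)
        pyld = np.clip(pyld_bg + prev * config.disability_weight, 0.0, 0.95)
        epi_rows[s] = dict(acm_rate=acm, incidence=inc, case_fatality=cf,
                           d28=d28, prevalence=prev, pyld_rate=pyld)

    unit_cost = weighted_cost(
        CostInputs(config.private_cost, config.private_share, config.public_ratio)
    )
    epi = pd.DataFrame(
        {
            "population": [pop[s][groups.index(g)] for g, s in idx],
            "acm_rate": [epi_rows[s]["acm_rate"][groups.index(g)] for g, s in idx],
            "incidence": [epi_rows[s]["incidence"][groups.index(g)] for g, s in idx],
            "prevalence": [epi_rows[s]["prevalence"][groups.index(g)] for g, s in idx],
            "case_fatality": [epi_rows[s]["case_fatality"][groups.index(g)] for g, s in idx],
            "d28": [epi_rows[s]["d28"][groups.index(g)] for g, s in idx],
            "pyld_rate": [epi_rows[s]["pyld_rate"][groups.index(g)] for g, s in idx],
            "cost_per_case_year": unit_cost,
        },
        index=idx,
    )

    # --- relative risks, attenuating with age
    rr_curve = 1.0 + config.rr_amplitude * np.exp(-config.rr_age_decay * x)
    rr_table = pd.DataFrame(
        {
            "rr_per_unit": [rr_curve[groups.index(g)] for g, s in idx],
            "log_sd": config.rr_log_sd,
        },
        index=idx,
    )
    rr = RRSpec(rr_table, tmreb=config.tmreb)

    elast_table = pd.DataFrame(
        {
            "elasticity": [config.elasticities[b][0] for b in BEVERAGES],
            "sd": [config.elasticities[b][1] for b in BEVERAGES],
        },
        index=pd.Index(BEVERAGES, name="beverage"),
    )

    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "true_sd_mean_slope": config.sd_mean_slope,
        "estimated_sd_mean_slope": slope_hat,
        "true_bmi_lognormal": true_lognormal,
        "synthetic": True,
        "note": "synthetic stand-in inputs; structural emulation only",
    }

    return InputBundle(
        consumption=consumption,
        bmi=bmi,
        heights=heights,
        epi=epi,
        rr=rr,
        elasticities=ElasticityMatrix(elast_table),
        energy_density=default_energy_density_table(),
        costs=CostInputs(config.private_cost, config.private_share, config.public_ratio),
        sd_mean_relation=rel,
        disability_weight=config.disability_weight,
        manifest=manifest,
        bmi_samples=bmi_samples,
    )
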