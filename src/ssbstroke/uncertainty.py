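"""Monte Carlo uncertainty intervals and the deterministic sensitivity grid.

The Monte Carlo varies exactly the uncertain inputs the model declares:
own/cross price elasticities (normal), baseline consumption means by age,
sex and beverage (normal around the mean with the survey SE, truncated at
zero), the energy-to-weight equilibrium factor (normal, 94 kJ/day per kg,
SD 2.96, truncated positive), and the stroke relative risks (log-normal on
the log-RR scale). Outcomes are collected as horizon totals and summarised
by their 2.5th and 97.5th percentiles around the all-parameters-at-mean
point estimate.

The sensitivity grid reruns the deterministic model over the scenario rows
of the published sensitivity analysis: tax rate, discount rate, portion
size, cost scale, pYLD scale, BMI trend, pass-on rate, and a lower own-price
elasticity bound (-0.85).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import RunResult, run_model
from .scenario import TaxScenario, portion_scale_for
from .synthetic_data import InputBundle

OUTCOME_KEYS = (
    "incident_cases_averted",
    "stroke_deaths_averted",
    "prevalent_cases_averted_final_year",
    "halys_gained",
    "costs_saved_zar",
)

_MAX_RESAMPLES = 1000


@dataclass(frozen=True)
class MCConfig:
    n_draws: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValidationError(f"n_draws must be >= 1, got {self.n_draws}")


@dataclass(frozen=True)
class UIResult:
    """Point estimate plus the 95 % uncertainty interval of one outcome."""

    point: float
    mean: float
    lo: float
    hi: float


def _truncated_normal(rng, mean, sd, lower, strict: bool = False):
    """Normal draws truncated by resampling at a physical bound."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = rng.normal(mean, sd)
    out = np.atleast_1d(np.asarray(out, dtype=float))
    bad = (out <= lower) if strict else (out < lower)
    tries = 0
    while bad.any():
        tries += 1
        if tries > _MAX_RESAMPLES:
            raise ValidationError(
                "over 1000 rejected resamples for one parameter; the mean/SD "
                "configuration puts almost all mass outside the physical bound"
            )
        redraw = rng.normal(np.broadcast_to(mean, out.shape)[bad],
                            np.broadcast_to(sd, out.shape)[bad])
        out[bad] = redraw
        bad = (out <= lower) if strict else (out < lower)
    return out


def draw_parameters(
    bundle: InputBundle, mc: MCConfig, draw_index: int
) -> tuple[InputBundle, float]:
    """One reproducible parameter draw: returns a perturbed bundle copy and
    the drawn energy-to-weight factor. Identical for identical
    (seed, draw_index)."""
    rng = np.random.default_rng(np.random.SeedSequence([mc.seed, draw_index]))
    out = bundle.copy()

    el = out.elasticities.table
    el["elasticity"] = rng.normal(el["elasticity"].to_numpy(), el["sd"].to_numpy())

    cons = out.consumption
    cons["mean_ml_day"] = _truncated_normal(
        rng, cons["mean_ml_day"].to_numpy(), cons["se_ml_day"].to_numpy(), 0.0
    )

    k = float(_truncated_normal(rng, bundle.k_kj_per_kg, bundle.k_sd, 0.0,
                                strict=True)[0])

    rr_t = out.rr.table
    log_rr = np.log(rr_t["rr_per_unit"].to_numpy())
    rr_t["rr_per_unit"] = np.exp(rng.normal(log_rr, rr_t["log_sd"].to_numpy()))

    return out, k


def run_monte_carlo(
    bundle: InputBundle,
    scenario: TaxScenario,
    mc: MCConfig,
    sim_years: int | None = None,
) -> dict:
    """95 % uncertainty intervals of the horizon totals across parameter
    draws. Returns ``{"ui": {outcome: UIResult}, "draws": DataFrame,
    "n_excluded": int}``; draws producing invalid model states are excluded
    and counted."""
    point = run_model(bundle, scenario, sim_years=sim_years, detail=False).summary

    rows = []
    n_excluded = 0
    for j in range(mc.n_draws):
        b_j, k_j = draw_parameters(bundle, mc, j)
        try:
            s = run_model(b_j, scenario, k_kj_per_kg=k_j, sim_years=sim_years,
                          detail=False).summary
        except (ValidationError, FloatingPointError) as exc:  # pragma: no cover
            n_excluded += 1
            rows.append({k: np.nan for k in OUTCOME_KEYS})
            continue
        rows.append({k: s[k] for k in OUTCOME_KEYS})
    draws = pd.DataFrame(rows)
    draws.index.name = "draw"

    ui = {}
    for key in OUTCOME_KEYS:
        vals = draws[key].dropna().to_numpy()
        ui[key] = UIResult(
            point=float(point[key]),
            mean=float(vals.mean()),
            lo=float(np.percentile(vals, 2.5)),
            hi=float(np.percentile(vals, 97.5)),
        )
    return {"ui": ui, "draws": draws, "n_excluded": n_excluded}


def grid_scenarios(base: TaxScenario) -> list[tuple[str, str, TaxScenario]]:
    """(block, label, scenario) triples mirroring the published grid rows."""
    rows: list[tuple[str, str, TaxScenario]] = []
    for pct in (10, 20, 30):
        rows.append(("tax_rate", f"{pct}%",
                     base.replace(tax_rate=pct / 100, label=f"tax_{pct}")))
    for pct in (0, 1, 2, 3):
        rows.append(("discount_rate", f"{pct}%",
                     base.replace(discount_rate=pct / 100, label=f"disc_{pct}")))
    for ml in (200, 250, 330, 500):
        rows.append(("portion_size", f"{ml} ml",
                     base.replace(portion_scale=portion_scale_for(ml),
                                  label=f"portion_{ml}")))
    for pct in (120, 110, 100, 90, 80):
        rows.append(("health_care_costs", f"{pct}%",
                     base.replace(cost_scale=pct / 100, label=f"cost_{pct}")))
    for pct in (100, 105, 110):
        rows.append(("pyld", f"{pct}%",
                     base.replace(pyld_scale=pct / 100, label=f"pyld_{pct}")))
    for trend in (0.0, 0.1, 0.2, 0.3):
        rows.append(("bmi_trend", f"{trend}",
                     base.replace(bmi_trend=trend, label=f"trend_{trend}")))
    for pct in (80, 90, 100):
        rows.append(("pass_on_rate", f"{pct}%",
                     base.replace(pass_on_rate=pct / 100, label=f"pass_{pct}")))
    rows.append(("own_price_elasticity", "-0.85", base.replace(label="low_elast")))
    return rows


def sensitivity_grid(
    bundle: InputBundle,
    base_scenario: TaxScenario | None = None,
    lower_elasticity: float = -0.85,
) -> pd.DataFrame:
    """One row per scenario; columns are signed horizon totals
    (intervention minus reference): change in incident cases, HALYs/DALYs
    averted, change in prevalent cases at the final year, and the cost
    change in billion ZAR."""
    base = base_scenario or TaxScenario()
    cache: dict[TaxScenario, dict] = {}

    def summary_for(b: InputBundle, scen: TaxScenario) -> dict:
        key = scen.replace(label="")
        if b is bundle and key in cache:
            return cache[key]
        s = run_model(b, scen, detail=False).summary
        if b is bundle:
            cache[key] = s
        return s

    records = []
    for block, label, scen in grid_scenarios(base):
        if block == "own_price_elasticity":
            b = bundle.copy()
            b.elasticities = b.elasticities.with_values({"ssb": lower_elasticity})
            s = summary_for(b, scen)
        else:
            s = summary_for(bundle, scen)
        records.append(
            {
                "block": block,
                "label": label,
                "incidence_change": -s["incident_cases_averted"],
                "dalys_averted": s["halys_gained"],
                "prevalence_change": -s["prevalent_cases_averted_final_year"],
                "cost_change_billion_zar": -s["costs_saved_zar"] / 1e9,
            }
        )
    return pd.DataFrame.from_records(records).set_index(["block", "label"])
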