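"""End-to-end orchestration: demand -> BMI shift -> PIF -> life table.

`run_model` executes one scenario in memory and returns the per-stage
intermediates plus the aggregated results; `run_scenario` wraps it with
input loading, validation and on-disk artifacts (per-year CSV, percentage
reduction CSV, JSON summary with a full config echo). Reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmi_model, demand, lifetable, pif
from .errors import StructuralError, ValidationError
from .io import read_bundle, write_bundle
from .lifetable import EPI_COLUMNS
from .scenario import TaxScenario
from .strata import MAX_AGE, band_lowers, validate_age_groups
from .synthetic_data import InputBundle, SyntheticConfig, generate_bundle

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """One run: either a bundle directory or a synthetic seed (exactly one)."""

    input_dir: str | None = None
    synthetic_seed: int | None = None
    scenario: TaxScenario = field(default_factory=TaxScenario)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic_seed is None):
            raise ValidationError(
                "exactly one of input_dir or synthetic_seed is required"
            )

    def load_bundle(self) -> InputBundle:
        if self.input_dir is not None:
            return read_bundle(self.input_dir)
        return generate_bundle(SyntheticConfig(seed=self.synthetic_seed))


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, row, fld: str, message: str) -> None:
        self.violations.append(
            {"table": table, "row": row, "field": fld, "message": message}
        )


def validate_bundle(bundle: InputBundle) -> ValidationReport:
    """Check every declared input invariant; structural problems raise,
    value problems are collected into the report with row coordinates."""
    rep = ValidationReport()
    validate_age_groups(bundle.age_groups)

    strata = set(bundle.epi.index)
    for name, idx in (
        ("bmi", bundle.bmi.index),
        ("heights", bundle.heights.index),
        ("rr", bundle.rr.table.index),
    ):
        missing = strata - set(idx)
        if missing:
            raise StructuralError(f"{name} table missing strata {sorted(missing)}")
    cons_strata = {
        (g, s) for g, s, _ in bundle.consumption.index
    }
    if strata - cons_strata:
        raise StructuralError(
            f"consumption table missing strata {sorted(strata - cons_strata)}"
        )
    missing_cols = [c for c in EPI_COLUMNS if c not in bundle.epi.columns]
    if missing_cols:
        raise StructuralError(f"epi table lacks columns {missing_cols}")

    def check(table: str, df, col: str, ok_mask, message: str) -> None:
        bad = df.index[~np.asarray(ok_mask)]
        for row in bad:
            rep.add(table, row, col, message)

    e = bundle.epi
    for col in ("population", "acm_rate", "incidence", "case_fatality",
                "pyld_rate", "cost_per_case_year"):
        check("epi", e, col, e[col].to_numpy() >= 0, f"{col} must be >= 0")
    check("epi", e, "d28", (e["d28"] >= 0) & (e["d28"] <= 1),
          "28-day fatality proportion must be in [0, 1]")
    check("epi", e, "prevalence", (e["prevalence"] >= 0) & (e["prevalence"] < 1),
          "prevalence must be in [0, 1)")
    for col, msg in (("acm_rate", "all-cause mortality"),
                     ("incidence", "incidence"), ("case_fatality", "case fatality")):
        big = e[col].to_numpy() > 2.0
        for row in e.index[big]:
            rep.warnings.append(
                f"epi[{row}].{col}: {msg} rate > 2/yr strains the annual cycle"
            )

    c = bundle.consumption
    check("consumption", c, "mean_ml_day", c["mean_ml_day"] >= 0, "intake must be >= 0")
    check("consumption", c, "se_ml_day", c["se_ml_day"] >= 0, "SE must be >= 0")

    b = bundle.bmi
    check("bmi", b, "mean", b["mean"] > 0, "BMI mean must be > 0")
    check("bmi", b, "sd", b["sd"] > 0, "BMI sd must be > 0")
    check("heights", bundle.heights.to_frame(), "height_m",
          bundle.heights > 0, "height must be > 0")

    r = bundle.rr.table
    check("rr", r, "rr_per_unit", r["rr_per_unit"] > 0, "RR must be > 0")
    check("rr", r, "log_sd", r["log_sd"] >= 0, "RR log SD must be >= 0")

    el = bundle.elasticities.table
    check("elasticities", el, "sd", el["sd"] >= 0, "elasticity SD must be >= 0")
    if el.loc["ssb", "elasticity"] > 0:
        rep.warnings.append("own-price elasticity of SSBs is positive")

    d = bundle.energy_density
    check("energy_density", d, "kj_per_litre", d["kj_per_litre"] >= 0,
          "energy density must be >= 0")

    # prevalent cases can never exceed the stratum population
    prev_cases = e["prevalence"] * e["population"]
    check("epi", e, "prevalence", prev_cases <= e["population"],
          "prevalent cases exceed population")
    return rep


@dataclass
class RunResult:
    scenario: TaxScenario
    summary: dict
    per_year: pd.DataFrame
    pct_reduction: pd.DataFrame
    delta_e: pd.Series
    delta_bmi: pd.Series
    pifs: pd.DataFrame


def run_model(
    bundle: InputBundle,
    scenario: TaxScenario,
    k_kj_per_kg: float | None = None,
    sim_years: int | None = None,
    detail: bool = True,
) -> RunResult:
    """Execute the full chain for one scenario on an in-memory bundle.

    ``detail=False`` skips the per-year/percentage frames and returns only
    the horizon summary (used inside Monte Carlo loops)."""
    dpp = demand.effective_price_change(scenario)
    dq = demand.consumption_change(
        bundle.consumption, bundle.elasticities, dpp,
        portion_scale=scenario.portion_scale, iso_elastic=scenario.iso_elastic,
    )
    delta_e = demand.net_energy_change(dq, bundle.energy_density)

    k = bundle.k_kj_per_kg if k_kj_per_kg is None else k_kj_per_kg
    delta_w = bmi_model.equilibrium_weight_change(delta_e.to_numpy(), k)
    heights = bundle.heights.reindex(delta_e.index)
    delta_bmi = pd.Series(
        bmi_model.weight_to_bmi_change(delta_w, heights.to_numpy()),
        index=delta_e.index,
        name="delta_bmi",
    )

    pifs = pif.pif_table(
        bundle.bmi.reindex(delta_bmi.index),
        delta_bmi,
        bundle.rr,
        rel=bundle.sd_mean_relation,
        trend=scenario.bmi_trend,
        n_years=scenario.horizon_years,
    )

    ref = lifetable.run_cohort(
        bundle.epi, None, scenario, arm="reference",
        disability_weight=bundle.disability_weight, sim_years=sim_years,
    )
    intervention = lifetable.run_cohort(
        bundle.epi, pifs, scenario, arm="intervention",
        disability_weight=bundle.disability_weight, sim_years=sim_years,
    )
    agg = lifetable.aggregate_results(ref, intervention, scenario, detail=detail)
    return RunResult(
        scenario=scenario,
        summary=agg["summary"],
        per_year=agg["per_year"],
        pct_reduction=agg["pct_reduction"],
        delta_e=delta_e,
        delta_bmi=delta_bmi,
        pifs=pifs,
    )


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_scenario(config: RunConfig) -> dict:
    """Load inputs, validate, run, and write artifacts to the output
    directory. Returns the summary dict (also written as JSON)."""
    bundle = config.load_bundle()
    report = validate_bundle(bundle)
    if not report.ok:
        raise ValidationError(
            f"bundle failed validation with {len(report.violations)} violations; "
            f"first: {report.violations[0]}"
        )
    result = run_model(bundle, config.scenario)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_year.to_csv(out / "per_year.csv")
    result.pct_reduction.to_csv(out / "pct_reduction.csv")
    result.pifs.to_csv(out / "pif.csv")
    result.delta_e.rename("de_kj_day").to_csv(out / "energy_change.csv")

    echo = {
        "scenario": config.scenario.to_dict(),
        "input_dir": config.input_dir,
        "synthetic_seed": config.synthetic_seed,
        "bundle_seed": bundle.manifest.get("seed"),
        "version": __version__,
    }
    payload = {
        "summary": result.summary,
        "config": echo,
        "config_hash": _config_hash(echo),
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "run.log").write_text(
        "\n".join(
            [
                f"config_hash={payload['config_hash']}",
                f"version={__version__}",
                f"seed={config.synthetic_seed}",
                f"strata={len(bundle.epi)}",
                f"warnings={len(report.warnings)}",
            ]
        )
        + "\n"
    )
    return payload


def max_simulated_years(bundle: InputBundle) -> int:
    return MAX_AGE - min(band_lowers(bundle.age_groups))
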