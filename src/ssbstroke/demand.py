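"""Tax -> price -> consumption -> energy stage.

Converts a tax scenario into per-stratum changes in beverage intake via own
and cross price elasticities, then into a net daily energy change using
beverage energy densities.

Demand response is linear at the margin by default,
``dQ = portion_scale * Q * eps * dp/p``; an iso-elastic form
``dQ = portion_scale * Q * ((1 + dp/p)^eps - 1)`` is available behind a
flag (at dp/p = 0.2 the two differ by roughly a fifth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError
from .scenario import TaxScenario
from .strata import BEVERAGES

DEFAULT_ENERGY_DENSITY = {  # kJ per litre
    "ssb": 1800.0,
    "juice": 1340.0,
    "milk": 2540.0,
    "diet": 0.0,
}


@dataclass
class ElasticityMatrix:
    """Demand elasticities of each beverage with respect to the SSB price.

    ``table`` is indexed by beverage with columns ``elasticity`` and ``sd``
    (the SD feeds Monte Carlo sampling). The SSB row is the own-price
    elasticity; the rest are cross-price elasticities that capture
    substitution toward (positive) or away from (negative) each beverage.
    """

    table: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        missing = [b for b in BEVERAGES if b not in self.table.index]
        if missing:
            raise StructuralError(f"elasticity rows missing for {missing}")
        for col in ("elasticity", "sd"):
            if col not in self.table.columns:
                raise StructuralError(f"elasticity table lacks column {col!r}")
        if (self.table["sd"] < 0).any():
            raise ValidationError("elasticity SDs must be >= 0")
        if self.validate and self.table.loc["ssb", "elasticity"] > 0:
            warnings.warn(
                "own-price elasticity of SSBs is positive; a normal good "
                "should have elasticity <= 0",
                stacklevel=2,
            )

    def __getitem__(self, beverage: str) -> float:
        try:
            return float(self.table.loc[beverage, "elasticity"])
        except KeyError as exc:
            raise StructuralError(f"no elasticity for beverage {beverage!r}") from exc

    def sd(self, beverage: str) -> float:
        return float(self.table.loc[beverage, "sd"])

    def with_values(self, values: dict[str, float]) -> "ElasticityMatrix":
        t = self.table.copy()
        for b, v in values.items():
            t.loc[b, "elasticity"] = v
        return ElasticityMatrix(t, validate=False)


def effective_price_change(scenario: TaxScenario) -> float:
    """Proportional retail price increase dp/p = tax rate x pass-on rate."""
    return scenario.tax_rate * scenario.pass_on_rate


def consumption_change(
    consumption: pd.DataFrame,
    elasticities: ElasticityMatrix,
    dpp: float,
    portion_scale: float = 1.0,
    iso_elastic: bool = False,
) -> pd.Series:
    """Per-stratum, per-beverage change in intake (ml/day).

    `consumption` is indexed by (age_group, sex, beverage) with a
    ``mean_ml_day`` column.
    """
    if dpp < 0:
        raise ValidationError(f"price change must be >= 0, got {dpp}")
    if "mean_ml_day" not in consumption.columns:
        raise StructuralError("consumption table lacks column 'mean_ml_day'")
    bev = consumption.index.get_level_values("beverage")
    eps = np.array([elasticities[b] for b in bev])
    if iso_elastic:
        factor = (1.0 + dpp) ** eps - 1.0
    else:
        factor = eps * dpp
    dq = portion_scale * consumption["mean_ml_day"].to_numpy() * factor
    return pd.Series(dq, index=consumption.index, name="dq_ml_day")


def net_energy_change(dq: pd.Series, densities: pd.DataFrame) -> pd.Series:
    """Net change in daily energy intake (kJ/day) per age group x sex.

    Each beverage's volume change (ml/day) is multiplied by its energy
    density (kJ/litre, hence /1000) and summed across beverages.
    """
    if "kj_per_litre" not in densities.columns:
        raise StructuralError("energy-density table lacks column 'kj_per_litre'")
    bev = dq.index.get_level_values("beverage")
    missing = sorted(set(bev) - set(densities.index))
    if missing:
        raise StructuralError(f"energy density missing for {missing}")
    dens = densities["kj_per_litre"].reindex(bev).to_numpy()
    de = dq.to_numpy() * dens / 1000.0
    out = (
        pd.Series(de, index=dq.index, name="de_kj_day")
        .groupby(level=["age_group", "sex"], sort=False)
        .sum()
    )
    return out


def default_energy_density_table(ssb_sd: float = 400.0) -> pd.DataFrame:
    """Energy densities (kJ/l): SSB 1800, juice 1340, whole milk 2540, diet 0.

    The SSB SD covers the label-survey alternative (mean 1880, SD 400).
    """
    t = pd.DataFrame(
        {
            "kj_per_litre": [DEFAULT_ENERGY_DENSITY[b] for b in BEVERAGES],
            "sd": [ssb_sd if b == "ssb" else 0.0 for b in BEVERAGES],
        },
        index=pd.Index(BEVERAGES, name="beverage"),
    )
    return t
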