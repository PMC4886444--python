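"""Tax scenario definition and TOML loading.

A :class:`TaxScenario` bundles every policy/reporting lever the deterministic
sensitivity analysis varies: the tax rate, the fraction passed through to
retail prices, the reporting horizon and discount rate, a portion-size
rescaling of baseline consumption volumes, a secular BMI trend applied to
both arms, and cost / disability (pYLD) scaling factors.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError


@dataclass(frozen=True)
class TaxScenario:
    """One scenario row: the base case is a 20 % tax with full pass-through
    over a 20-year horizon with no discounting."""

    tax_rate: float = 0.20
    pass_on_rate: float = 1.0
    horizon_years: int = 20
    discount_rate: float = 0.0
    portion_scale: float = 1.0
    bmi_trend: float = 0.0        # BMI units/year added to the mean, both arms
    cost_scale: float = 1.0
    pyld_scale: float = 1.0
    iso_elastic: bool = False     # use (1+dp/p)^eps - 1 instead of eps * dp/p
    label: str = "base"

    def __post_init__(self) -> None:
        if self.tax_rate < 0:
            raise ValidationError(f"tax_rate must be >= 0, got {self.tax_rate}")
        if not 0.0 <= self.pass_on_rate <= 1.0:
            raise ValidationError(
                f"pass_on_rate must be in [0, 1], got {self.pass_on_rate}"
            )
        if self.horizon_years < 1:
            raise ValidationError(
                f"horizon_years must be >= 1, got {self.horizon_years}"
            )
        if self.discount_rate < 0:
            raise ValidationError(
                f"discount_rate must be >= 0, got {self.discount_rate}"
            )
        for name in ("portion_scale", "cost_scale", "pyld_scale"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    def replace(self, **changes) -> "TaxScenario":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Serving volume (ml) whose portion_scale is 1.0; the portion-size scenarios
# rescale consumption volumes by portion_ml / 330.
REFERENCE_PORTION_ML = 330.0


def portion_scale_for(portion_ml: float) -> float:
    if portion_ml <= 0:
        raise ValidationError(f"portion size must be > 0, got {portion_ml}")
    return portion_ml / REFERENCE_PORTION_ML


def load_scenario(path: str | Path) -> TaxScenario:
    """Read a scenario from a TOML file; keys match TaxScenario fields.

    Unknown keys raise so a typo cannot silently run the base case.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("scenario", data)
    known = {f.name for f in dataclasses.fields(TaxScenario)}
    unknown = set(table) - known
    if unknown:
        raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
    return TaxScenario(**table)
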