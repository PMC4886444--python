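"""Age-band / sex stratification helpers.

The model works on 5-year age bands (15-19 ... 95-99) crossed with sex.
Band rates apply uniformly to the single years of age inside the band;
internally cohorts are aged by single years up to 100.
"""

from __future__ import annotations

import pandas as pd

from .errors import StructuralError

DEFAULT_AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(15, 100, 5)
)
SEXES: tuple[str, str] = ("male", "female")
BEVERAGES: tuple[str, ...] = ("ssb", "milk", "diet", "juice")

MAX_AGE = 100  # cohorts are simulated until death or this age


def band_bounds(label: str) -> tuple[int, int]:
    """Parse an age-band label like ``"15-19"`` into (lower, upper)."""
    try:
        lo_s, hi_s = label.split("-")
        lo, hi = int(lo_s), int(hi_s)
    except (ValueError, AttributeError) as exc:
        raise StructuralError(f"malformed age-band label {label!r}") from exc
    if hi != lo + 4:
        raise StructuralError(f"age band {label!r} is not a 5-year band")
    return lo, hi


def validate_age_groups(groups) -> tuple[str, ...]:
    """Check bands are contiguous ascending 5-year bands; return as tuple."""
    groups = tuple(groups)
    if not groups:
        raise StructuralError("no age groups supplied")
    bounds = [band_bounds(g) for g in groups]
    for (lo_a, hi_a), (lo_b, _) in zip(bounds, bounds[1:]):
        if lo_b != hi_a + 1:
            raise StructuralError(
                f"age bands not contiguous: {lo_a}-{hi_a} followed by {lo_b}-..."
            )
    return groups


def band_lowers(groups) -> list[int]:
    return [band_bounds(g)[0] for g in groups]


def band_midpoints(groups) -> list[float]:
    return [band_bounds(g)[0] + 2.0 for g in groups]


def band_of_age(age: float, groups) -> int:
    """Index of the band containing `age`; ages beyond the last band use the
    last band's rates (callers may warn)."""
    lo0 = band_bounds(groups[0])[0]
    idx = int((age - lo0) // 5)
    return max(0, min(idx, len(groups) - 1))


def strata_index(groups=DEFAULT_AGE_GROUPS, sexes=SEXES) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(groups), list(sexes)], names=["age_group", "sex"]
    )


def consumption_index(groups=DEFAULT_AGE_GROUPS, sexes=SEXES,
                      beverages=BEVERAGES) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(groups), list(sexes), list(beverages)],
        names=["age_group", "sex", "beverage"],
    )
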