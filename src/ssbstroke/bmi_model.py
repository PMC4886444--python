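"""Energy change -> weight change -> shifted log-normal BMI distribution.

The equilibrium energy-balance relation (94 kJ/day of sustained intake change
per kg of body weight at the new equilibrium, SD 2.96) converts a daily
energy change into a weight change; stratum mean height converts kg into BMI
units; and the population BMI distribution, modelled as log-normal via moment
matching, is shifted additively on the natural scale. The standard deviation
co-moves with the mean through a linear SD-mean relation estimated from
repeated survey waves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

SWINBURN_KJ_PER_KG = 94.0      # kJ/day sustained change per kg equilibrium weight change
SWINBURN_KJ_PER_KG_SD = 2.96


def equilibrium_weight_change(delta_e: float, k: float = SWINBURN_KJ_PER_KG):
    """Equilibrium body-weight change (kg) for a sustained daily energy
    change `delta_e` (kJ/day): dw = delta_e / k."""
    if k <= 0:
        raise ValidationError(f"energy-to-weight factor must be > 0, got {k}")
    return delta_e / k


def weight_to_bmi_change(delta_w, height):
    """BMI change (kg/m^2) for a weight change (kg) at a given height (m)."""
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValidationError("height must be > 0")
    return delta_w / height**2


def fit_lognormal(mean, sd):
    """Method-of-moments log-normal fit: returns (mu, sigma) such that a
    LogNormal(mu, sigma) has the given arithmetic mean and SD.

    sigma^2 = ln(1 + (sd/mean)^2);  mu = ln(mean) - sigma^2 / 2.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mean <= 0) or np.any(sd <= 0):
        raise ValidationError("log-normal moments require mean > 0 and sd > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    if mu.ndim == 0:
        return float(mu), float(sigma)
    return mu, sigma


def lognormal_moments(mu, sigma):
    """Inverse of :func:`fit_lognormal`: (mean, sd) of LogNormal(mu, sigma)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    mean = np.exp(mu + sigma**2 / 2.0)
    sd = mean * np.sqrt(np.expm1(sigma**2))
    if mean.ndim == 0:
        return float(mean), float(sd)
    return mean, sd


@dataclass(frozen=True)
class BMIDistribution:
    """Log-normal BMI distribution for one stratum, stored by its moments."""

    mean: float
    sd: float
    stratum: tuple | None = None

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValidationError(
                f"BMI distribution needs mean > 0 and sd > 0, got "
                f"mean={self.mean}, sd={self.sd}"
            )

    @property
    def mu(self) -> float:
        return fit_lognormal(self.mean, self.sd)[0]

    @property
    def sigma(self) -> float:
        return fit_lognormal(self.mean, self.sd)[1]

    @classmethod
    def from_lognormal(cls, mu: float, sigma: float, stratum=None) -> "BMIDistribution":
        mean, sd = lognormal_moments(mu, sigma)
        return cls(mean, sd, stratum)


@dataclass(frozen=True)
class SDMeanRelation:
    """Linear co-movement of the BMI SD with the BMI mean.

    `slope` is d(sd)/d(mean), dimensionless; the optional reference mean and
    intercept document the line the slope was read from. A slope of 0 keeps
    the SD fixed as the mean shifts.
    """

    slope: float
    reference_mean: float | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        # the relation must keep sd positive over plausible adult BMI means
        if self.reference_mean is not None:
            for m in (15.0, 45.0):
                sd = self.sd_at(m)
                if sd is not None and sd <= 0:
                    raise ValidationError(
                        f"SD-mean relation yields sd={sd:.3f} <= 0 at mean {m}"
                    )

    def sd_at(self, mean: float) -> float | None:
        if self.reference_mean is None:
            return None
        return self.intercept + self.slope * (mean - self.reference_mean)

    def shifted_sd(self, sd: float, delta_mean: float) -> float:
        return sd + self.slope * delta_mean


def shift_distribution(
    dist: BMIDistribution,
    delta_bmi: float,
    rel: SDMeanRelation | None = None,
    trend: float = 0.0,
    year: int = 0,
) -> BMIDistribution:
    """Shift a stratum BMI distribution by an intervention effect plus a
    secular trend, adjusting the SD through the SD-mean relation, and refit
    the log-normal from the new moments."""
    new_mean = dist.mean + delta_bmi + trend * year
    d_mean = new_mean - dist.mean
    new_sd = rel.shifted_sd(dist.sd, d_mean) if rel is not None else dist.sd
    if new_mean <= 0 or new_sd <= 0:
        raise ValidationError(
            f"degenerate shifted distribution: mean={new_mean:.4f}, sd={new_sd:.4f}"
        )
    return BMIDistribution(new_mean, new_sd, dist.stratum)


def estimate_sd_mean_slope(delta_mean, delta_sd) -> float:
    """Least-squares slope of SD change on mean change across strata
    (two survey waves); used to parameterise :class:`SDMeanRelation`."""
    delta_mean = np.asarray(delta_mean, dtype=float)
    delta_sd = np.asarray(delta_sd, dtype=float)
    if delta_mean.size < 2:
        raise ValidationError("need at least two strata to estimate the slope")
    if math.isclose(float(np.var(delta_mean)), 0.0):
        raise ValidationError("mean changes are constant; slope not identifiable")
    return float(np.polyfit(delta_mean, delta_sd, 1)[0])
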