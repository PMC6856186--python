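"""Per-capita methylmercury intake and dose-response health impacts.

The probable weekly intake (PWI, μg per kg body weight per week) converts a
country's food-supply mercury flux to a per-person dose; contaminated-site
exposure converts a local rice concentration and the national consumption
rate directly.  Health endpoints follow the hair-blood-intake slope chain of
Rice et al. (2010): fetal IQ decrement is linear in the daily dose, and
fatal heart attacks scale the national baseline by a saturating exponential
risk term, gated by a Bernoulli indicator for whether the cardiovascular
association is treated as causal (probability one-third) and lagged 6
(2-12) years between intake and response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "CONTINENT_BODY_WEIGHT_KG",
    "Demographics",
    "HealthCoefficients",
    "HealthBaseline",
    "pwi",
    "global_pwi",
    "site_pwi",
    "iq_decrement",
    "heart_attack_deaths",
]

#: Average adult body weight by continent (kg).
CONTINENT_BODY_WEIGHT_KG: dict[str, float] = {
    "Africa": 61.0,
    "Asia": 58.0,
    "Europe": 71.0,
    "North America": 81.0,
    "Oceania": 74.0,
    "South America": 68.0,
}


@dataclass(frozen=True)
class Demographics:
    """Country population and the continental average body weight."""

    country: str
    continent: str
    population: float  # persons
    body_weight_kg: float | None = None  # defaults from the continent table

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be > 0")
        if self.body_weight_kg is None:
            try:
                bw = CONTINENT_BODY_WEIGHT_KG[self.continent]
            except KeyError:
                raise ValueError(
                    f"unknown continent {self.continent!r} and no explicit body weight"
                ) from None
            object.__setattr__(self, "body_weight_kg", bw)
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")


@dataclass(frozen=True)
class HealthCoefficients:
    """Dose-response slope chain and cardiovascular protocol parameters.

    gamma: IQ points per μg Hg/g hair; lam: μg/g hair per μg/L blood;
    beta: μg/L blood per μg/day intake; phi: heart-attack risk per μg/g hair.
    Central values follow Rice et al. (2010); all are configuration inputs.
    omega_prob is the probability that the cardiovascular association is
    treated as causal in a Monte Carlo draw; lag_years offsets intake year
    against the baseline-mortality year.
    """

    gamma: float = 0.3
    lam: float = 0.2
    beta: float = 0.06
    phi: float = 0.066
    omega_prob: float = 1.0 / 3.0
    lag_years: int = 6
    lag_range: tuple[int, int] = (2, 12)
    gamma_se: float = 0.0
    lam_se: float = 0.0
    beta_se: float = 0.0
    phi_se: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma", "lam", "beta", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.omega_prob <= 1:
            raise ValueError("omega_prob must lie in [0, 1]")
        lo, hi = self.lag_range
        if not lo <= self.lag_years <= hi:
            raise ValueError("lag_years outside lag_range")


@dataclass(frozen=True)
class HealthBaseline:
    """National annual deaths from fatal heart attacks among people aged >= 30."""

    country: str
    fatal_heart_attacks_ge30: float

    def __post_init__(self) -> None:
        if self.fatal_heart_attacks_ge30 < 0:
            raise ValueError("baseline deaths must be >= 0")


def pwi(food_hg: float, demo: Demographics) -> float:
    """Probable weekly intake (μg kg^-1 week^-1) from a food mercury flux (kg/yr)."""
    if food_hg < 0:
        raise ValueError("food mercury flux must be >= 0")
    if demo.population <= 0 or demo.body_weight_kg <= 0:
        raise ValueError("population and body weight must be > 0")
    return food_hg / demo.population / demo.body_weight_kg / 52.0 * 1e9


def global_pwi(countries: Iterable[tuple[float, Demographics]]) -> float:
    """Population-weighted mean PWI over countries of (pwi_value, demographics)."""
    num = 0.0
    den = 0.0
    for pwi_value, demo in countries:
        num += demo.population * pwi_value
        den += demo.population
    if den == 0:
        raise ValueError("no countries supplied")
    return num / den


def site_pwi(conc: float, intake_g_day: float, body_weight_kg: float) -> float:
    """Weekly intake from locally consumed rice at a contaminated site.

    conc ng/g x intake g/day x 7 days -> ng/week; /1000 -> μg; per kg body weight.
    """
    if conc < 0 or intake_g_day < 0 or body_weight_kg <= 0:
        raise ValueError("inputs must be nonnegative with positive body weight")
    return conc * intake_g_day * 7.0 / body_weight_kg / 1000.0


def _daily_dose(delta_pwi: float, body_weight_kg: float) -> float:
    """μg/day dose from a weekly per-kg intake."""
    return delta_pwi * body_weight_kg / 7.0


def iq_decrement(delta_pwi: float, body_weight_kg: float, coeffs: HealthCoefficients) -> float:
    """Per-fetus IQ-point decrement for a rice-derived MeHg intake increment."""
    if delta_pwi < 0:
        raise ValueError("delta_pwi must be >= 0")
    return coeffs.gamma * coeffs.lam * coeffs.beta * _daily_dose(delta_pwi, body_weight_kg)


def heart_attack_deaths(
    delta_pwi: float,
    body_weight_kg: float,
    baseline: HealthBaseline,
    coeffs: HealthCoefficients,
    omega: int = 1,
) -> float:
    """Annual fatal-heart-attack deaths attributable to the MeHg intake increment.

    ``omega`` is the 0/1 causal-association draw; the expected value over the
    omega distribution is omega_prob times the omega=1 branch.  The result is
    bounded by the national baseline and saturates for large doses.
    """
    if delta_pwi < 0:
        raise ValueError("delta_pwi must be >= 0")
    if omega not in (0, 1):
        raise ValueError("omega must be 0 or 1")
    if omega == 0:
        return 0.0
    exponent = coeffs.phi * coeffs.lam * coeffs.beta * _daily_dose(delta_pwi, body_weight_kg)
    return baseline.fatal_heart_attacks_ge30 * (1.0 - math.exp(-exponent))


def expected_heart_attack_deaths(
    delta_pwi: float,
    body_weight_kg: float,
    baseline: HealthBaseline,
    coeffs: HealthCoefficients,
) -> float:
    """Expectation over the causal-association indicator."""
    return coeffs.omega_prob * heart_attack_deaths(
        delta_pwi, body_weight_kg, baseline, coeffs, omega=1
    )
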