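"""Residue management fates and field-burning mercury emissions.

Residue-borne mercury is split among management fates (field burning, feed,
fertilizer, domestic fuel, industrial fuel, thatching, left/other); the
burned fraction releases THg to the atmosphere as the dry residue mass times
the residue concentration times a combustion efficiency.  The divisor M
converts fresh to dry residue mass (M = 1/(1 - moisture fraction) under the
default interpretation; a raw-percent divisor is selectable for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FATES",
    "EmissionParams",
    "FateFractions",
    "burning_emission",
    "partition_fates",
]

FATES = (
    "burned_field",
    "feed",
    "fertilizer",
    "domestic_fuel",
    "industrial_fuel",
    "thatching",
    "other_left",
)

_SUM_TOL = 1e-9


def moisture_divisor(moisture_fraction: float = 0.125, as_percent: bool = False) -> float:
    """Fresh-to-dry divisor M from a residue moisture fraction.

    Default reading: M = 1/(1 - moisture).  The ``as_percent`` reading divides
    by the moisture fraction itself, which inflates emissions roughly 8-fold
    at 12.5% moisture; it is provided only so the two conventions can be
    compared explicitly.
    """
    if not 0 <= moisture_fraction < 1:
        raise ValueError("moisture fraction must lie in [0, 1)")
    if as_percent:
        if moisture_fraction <= 0:
            raise ValueError("percent-divisor reading needs moisture > 0")
        return 1.0 / moisture_fraction
    return 1.0 / (1.0 - moisture_fraction)


@dataclass(frozen=True)
class EmissionParams:
    """Burning-emission parameters: fresh-to-dry divisor M and combustion efficiency E."""

    m: float = 1.0 / (1.0 - 0.125)  # default 12.5% moisture
    e: float = 0.85

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("fresh-to-dry divisor M must be >= 1")
        if not 0 <= self.e <= 1:
            raise ValueError("combustion efficiency E must lie in [0, 1]")


def burning_emission(r: float, params: EmissionParams, c: float) -> float:
    """THg emitted (kg/yr) by burning *r* Mg/yr of fresh residue at *c* ng/g."""
    if r < 0:
        raise ValueError("burned residue mass must be >= 0")
    if c < 0:
        raise ValueError("residue concentration must be >= 0")
    return (r / params.m) * c * params.e * 1e-6


@dataclass(frozen=True)
class FateFractions:
    """Residue management shares; any remainder is assigned to other_left."""

    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = 0.0
        for fate, frac in self.fractions.items():
            if fate not in FATES:
                raise ValueError(f"unknown fate {fate!r}; one of {FATES}")
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction for {fate!r} must lie in [0, 1]")
            if fate != "other_left":
                total += frac
        if total > 1 + _SUM_TOL:
            raise ValueError(f"fate fractions sum to {total:.6g} > 1")

    def complete(self) -> dict[str, float]:
        """All seven fates with the remainder folded into other_left."""
        out = {fate: float(self.fractions.get(fate, 0.0)) for fate in FATES}
        assigned = sum(v for k, v in out.items() if k != "other_left")
        out["other_left"] = max(1.0 - assigned, 0.0)
        return out


def partition_fates(residue_hg: float, fractions: FateFractions) -> dict[str, float]:
    """Split residue-borne mercury (kg/yr) across management fates; conserves mass."""
    if residue_hg < 0:
        raise ValueError("residue mercury must be >= 0")
    shares = fractions.complete()
    ledger = {fate: residue_hg * share for fate, share in shares.items()}
    # exact conservation: absorb float crumbs into the remainder fate
    ledger["other_left"] += residue_hg - sum(ledger.values())
    return ledger
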