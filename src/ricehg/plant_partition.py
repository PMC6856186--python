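"""Grain-to-organ mercury partitioning and residue mass estimation.

Residue, stem and leaf concentrations follow fitted relations on the grain
(or stem) concentration — mostly power laws, with two linear exceptions —
and bulk residue concentration combines stem and leaf at the canonical 3:1
dry-mass ratio.  Residue masses come from national residue nitrogen totals
divided by the mean nitrogen content of rice residues, and historical fluxes
are rescaled by regional soil-mercury enrichment factors relative to the
2010s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "OrganRelation",
    "ORGAN_RELATIONS",
    "ResidueParams",
    "EnrichmentSeries",
    "organ_concentration",
    "bulk_residue_from_organs",
    "residue_mass_from_nitrogen",
    "other_crop_residue_thg",
    "apply_enrichment",
]


@dataclass(frozen=True)
class OrganRelation:
    """One fitted organ-to-organ relation: linear a*x + b or power a*x**b."""

    relation_id: str
    form: str  # "linear" | "power"
    a: float
    a_se: float
    b: float
    b_se: float
    r2: float

    def __post_init__(self) -> None:
        if self.form not in {"linear", "power"}:
            raise ValueError(f"unknown form {self.form!r}")
        if self.a <= 0:
            raise ValueError("coefficient a must be > 0")

    def predict(self, x: float, a: float | None = None, b: float | None = None) -> float:
        """Evaluate at x >= 0, optionally with perturbed coefficients."""
        if x < 0:
            raise ValueError("negative concentration")
        aa = self.a if a is None else a
        bb = self.b if b is None else b
        if self.form == "linear":
            return aa * x + bb
        return 0.0 if x == 0 else aa * x**bb


#: Fitted relations between grain, stem, leaf and bulk-residue concentrations
#: (ng/g on both sides).  Two are linear; the rest are power laws.
ORGAN_RELATIONS: dict[str, OrganRelation] = {
    rel.relation_id: rel
    for rel in (
        OrganRelation("residues_thg", "linear", 7.5, 0.34, 34.0, 38.0, 0.84),
        OrganRelation("stem_thg", "power", 4.3, 1.3, 0.92, 0.063, 0.83),
        OrganRelation("leaf_thg_from_grain", "linear", 20.0, 1.0, 18.0, 160.0, 0.91),
        OrganRelation("leaf_thg_from_stem", "power", 2.1, 1.4, 1.2, 0.067, 0.88),
        OrganRelation("residues_mehg", "power", 0.27, 1.3, 1.1, 0.10, 0.80),
        OrganRelation("stem_mehg", "power", 0.31, 1.3, 0.85, 0.12, 0.76),
        OrganRelation("leaf_mehg_from_grain", "power", 0.23, 1.3, 0.82, 0.13, 0.71),
        OrganRelation("leaf_mehg_from_stem", "power", 0.73, 1.1, 0.95, 0.079, 0.90),
    )
}


def organ_concentration(input_conc: float, relation_id: str) -> float:
    """Predicted organ concentration (ng/g) from a grain or stem concentration."""
    rel = ORGAN_RELATIONS.get(relation_id)
    if rel is None:
        raise ValueError(
            f"unknown relation {relation_id!r}; one of {sorted(ORGAN_RELATIONS)}"
        )
    return rel.predict(input_conc)


def bulk_residue_from_organs(stem: float, leaf: float) -> float:
    """Bulk residue concentration at the 3:1 stem:leaf dry-mass ratio."""
    if stem < 0 or leaf < 0:
        raise ValueError("organ concentrations must be >= 0")
    return (3.0 * stem + leaf) / 4.0


@dataclass(frozen=True)
class ResidueParams:
    """Residue mass and other-crop parameters.

    nitrogen_content: mean total-N fraction of residue dry mass (6.5 +/- 1.1 per mille).
    straw_grain_ratio: residue-to-grain mass ratio; rice averages 1.5 (0.75-2.5).
    default_other_crop_thg: THg for crops without measurements, 42 (1.0-180) ng/g.
    """

    nitrogen_content: float = 0.0065
    nitrogen_content_sd: float = 0.0011
    straw_grain_ratio: float = 1.5
    straw_grain_range: tuple[float, float] = (0.75, 2.5)
    default_other_crop_thg: float = 42.0
    other_crop_thg_range: tuple[float, float] = (1.0, 180.0)

    def __post_init__(self) -> None:
        for name in ("nitrogen_content", "straw_grain_ratio", "default_other_crop_thg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def residue_mass_from_nitrogen(total_n: float, nitrogen_content: float = 0.0065) -> float:
    """Residue dry mass (Mg/yr) from the national residue-nitrogen total (Mg N/yr)."""
    if total_n < 0:
        raise ValueError("total nitrogen must be >= 0")
    if nitrogen_content <= 0 or nitrogen_content >= 1:
        raise ValueError("nitrogen_content must lie in (0, 1)")
    return total_n / nitrogen_content


def other_crop_residue_thg(
    production: float, straw_grain_ratio: float = 1.5, conc: float = 42.0
) -> float:
    """THg sequestered in another crop's residues (kg/yr).

    production (Mg/yr) x straw/grain ratio gives residue mass; Mg x ng/g x 1e-6
    converts to kg of mercury.
    """
    if production < 0 or straw_grain_ratio < 0 or conc < 0:
        raise ValueError("inputs must be >= 0")
    return production * straw_grain_ratio * conc * 1e-6


@dataclass(frozen=True)
class EnrichmentSeries:
    """Region-specific soil-Hg enrichment factors by year, relative to the 2010s."""

    region: str
    factors: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, ef in self.factors.items():
            if ef <= 0:
                raise ValueError(f"enrichment factor for {year} must be > 0")

    def factor(self, year: int) -> float:
        try:
            return float(self.factors[year])
        except KeyError:
            lo, hi = (min(self.factors), max(self.factors)) if self.factors else (None, None)
            raise ValueError(
                f"year {year} outside enrichment support [{lo}, {hi}] for {self.region!r}"
            ) from None


def apply_enrichment(
    flux_reference: float,
    series: EnrichmentSeries | Mapping[str, EnrichmentSeries],
    region: str,
    year: int,
) -> float:
    """Scale a 2010s-reference flux (kg/yr) to *year* by the regional factor."""
    if isinstance(series, EnrichmentSeries):
        if series.region != region:
            raise ValueError(f"series covers {series.region!r}, not {region!r}")
        s = series
    else:
        try:
            s = series[region]
        except KeyError:
            raise ValueError(f"no enrichment series for region {region!r}") from None
    return flux_reference * s.factor(year)
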