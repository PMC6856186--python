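"""Mass-balance material flow of grain mercury through national supply chains.

Each country-year carries a commodity balance sheet: sources (production,
import, signed stock variation) equal sinks (export, feed, seed, processing,
other uses, food, losses).  Concentration-weighting turns the Mg/yr mass
terms into kg/yr mercury fluxes, with every import priced at the exporting
partner's concentration, which is what makes trade attribution possible:
the embodied-trade share of food-supply MeHg and the per-country deviation
from an autarky counterfactual both fall out of the ledger.

Unit bridge throughout: Mg (1e6 g) x ng/g x 1e-6 = kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "SOURCE_TERMS",
    "SINK_TERMS",
    "BALANCE_TERMS",
    "BalanceSheet",
    "TradeMatrix",
    "FlowLedger",
    "hg_flux",
    "build_ledger",
    "check_balance",
    "trade_embodied_share",
    "trade_delta",
]

SOURCE_TERMS = ("production", "import", "stock_variation")
SINK_TERMS = ("export", "feed", "seed", "processing", "other_uses", "food", "losses")
BALANCE_TERMS = SOURCE_TERMS + SINK_TERMS

_DEFAULT_CLOSURE_TOL = 1e-6  # relative to gross turnover


@dataclass
class BalanceSheet:
    """Per country-year rice mass terms (Mg/yr, milled equivalent).

    ``stock_variation`` is signed: positive means a stock drawdown that adds
    to the supply side.  Every other term is nonnegative.
    """

    country: str
    year: int
    production: float = 0.0
    import_: float = 0.0
    stock_variation: float = 0.0
    export: float = 0.0
    feed: float = 0.0
    seed: float = 0.0
    processing: float = 0.0
    other_uses: float = 0.0
    food: float = 0.0
    losses: float = 0.0

    _ATTR = {t: ("import_" if t == "import" else t) for t in BALANCE_TERMS}

    def __post_init__(self) -> None:
        for term in BALANCE_TERMS:
            if term == "stock_variation":
                continue
            if self.term(term) < 0:
                raise ValueError(f"{self.country} {self.year}: negative {term}")

    def term(self, name: str) -> float:
        try:
            return float(getattr(self, self._ATTR[name]))
        except KeyError:
            raise ValueError(f"unknown balance term {name!r}; one of {BALANCE_TERMS}") from None

    def set_term(self, name: str, value: float) -> None:
        if name not in self._ATTR:
            raise ValueError(f"unknown balance term {name!r}; one of {BALANCE_TERMS}")
        setattr(self, self._ATTR[name], float(value))

    @property
    def supply(self) -> float:
        """Domestic supply mass: production - export + stock variation + import."""
        return self.production - self.export + self.stock_variation + self.import_

    @property
    def sink_total(self) -> float:
        return self.feed + self.seed + self.processing + self.other_uses + self.food + self.losses

    @property
    def turnover(self) -> float:
        return sum(abs(self.term(t)) for t in BALANCE_TERMS)

    def closure_residual(self) -> float:
        """Signed sources-minus-sinks residual (Mg/yr)."""
        return self.supply - self.sink_total

    def is_closed(self, tol: float = _DEFAULT_CLOSURE_TOL) -> bool:
        scale = max(self.turnover, 1.0)
        return abs(self.closure_residual()) <= tol * scale


class TradeMatrix:
    """Sparse bilateral grain trade: (reporter/exporter, partner/importer) -> Mg/yr."""

    def __init__(self, flows: Mapping[tuple[str, str], float] | None = None):
        self._flows: dict[tuple[str, str], float] = {}
        if flows:
            for (rep, par), qty in flows.items():
                self.add_flow(rep, par, qty)

    def add_flow(self, reporter: str, partner: str, quantity: float) -> None:
        if reporter == partner:
            raise ValueError(f"self-trade row {reporter!r} -> {partner!r} rejected")
        if quantity < 0:
            raise ValueError(f"negative trade quantity {reporter}->{partner}")
        key = (reporter, partner)
        if key in self._flows:
            raise ValueError(f"duplicate trade row {reporter}->{partner}")
        self._flows[key] = float(quantity)

    def flow(self, reporter: str, partner: str) -> float:
        return self._flows.get((reporter, partner), 0.0)

    def items(self):
        return self._flows.items()

    def __len__(self) -> int:
        return len(self._flows)

    def __eq__(self, other) -> bool:
        return isinstance(other, TradeMatrix) and self._flows == other._flows

    def countries(self) -> set[str]:
        out: set[str] = set()
        for rep, par in self._flows:
            out.add(rep)
            out.add(par)
        return out

    def exports_of(self, reporter: str) -> float:
        return sum(q for (rep, _), q in self._flows.items() if rep == reporter)

    def imports_of(self, partner: str) -> float:
        return sum(q for (_, par), q in self._flows.items() if par == partner)

    def partners_of(self, importer: str) -> dict[str, float]:
        return {rep: q for (rep, par), q in self._flows.items() if par == importer}

    def scale_exports_to(self, targets: Mapping[str, float], warn: bool = True) -> "TradeMatrix":
        """Proportionally rescale each reporter's rows to match its export term."""
        factors: dict[str, float] = {}
        for rep, target in targets.items():
            rowsum = self.exports_of(rep)
            if rowsum > 0:
                if warn and abs(rowsum - target) > 1e-9 * max(rowsum, 1.0):
                    warnings.warn(
                        f"rescaling {rep} bilateral rows by {target / rowsum:.4g} "
                        "to match the export term",
                        stacklevel=2,
                    )
                factors[rep] = target / rowsum
        scaled = {
            (rep, par): q * factors.get(rep, 1.0) for (rep, par), q in self._flows.items()
        }
        return TradeMatrix(scaled)


def hg_flux(mass: float, conc: float) -> float:
    """Mercury flux (kg/yr) carried by *mass* Mg/yr at *conc* ng/g."""
    if mass < 0:
        raise ValueError("mass must be >= 0 (use signed wrappers for stock variation)")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return mass * conc * 1e-6


@dataclass
class FlowLedger:
    """Concentration-weighted mercury fluxes (kg/yr) for one country-year-species."""

    country: str
    year: int
    species: str  # "THg" | "MeHg"
    fluxes: dict[str, float] = field(default_factory=dict)  # per balance term
    bilateral_imports: dict[str, float] = field(default_factory=dict)  # exporter -> kg/yr
    food_import_origin: float = 0.0  # import-origin share of the food flux, kg/yr
    pool_concentration: float = 0.0  # mass-weighted supply concentration, ng/g
    domestic_concentration: float = 0.0  # producer's own concentration, ng/g
    food_mass: float = 0.0  # Mg/yr

    def flux(self, term: str) -> float:
        return self.fluxes.get(term, 0.0)

    @property
    def food_domestic_origin(self) -> float:
        return self.flux("food") - self.food_import_origin

    @property
    def import_origin_share(self) -> float:
        total = self.flux("food")
        return self.food_import_origin / total if total > 0 else 0.0


def build_ledger(
    sheet: BalanceSheet,
    conc: Mapping[str, tuple[float, float]] | Mapping[str, float],
    trade: TradeMatrix,
    species: str = "MeHg",
    closure_tol: float = _DEFAULT_CLOSURE_TOL,
) -> FlowLedger:
    """Concentration-weight one balance sheet into a mercury flow ledger.

    ``conc`` maps country -> concentration ng/g for *species* (a (THg, MeHg)
    pair is accepted and indexed by species).  Domestic terms (production,
    export, stock variation) are priced at the producer's own concentration;
    each bilateral import is priced at the exporting partner's concentration;
    sink terms are priced at the mass-weighted supply-pool concentration, so
    ledger closure inherits mass closure exactly.
    """
    if species not in {"THg", "MeHg"}:
        raise ValueError("species must be 'THg' or 'MeHg'")
    if not sheet.is_closed(closure_tol):
        raise ValueError(
            f"{sheet.country} {sheet.year}: balance sheet not closed "
            f"(residual {sheet.closure_residual():.6g} Mg)"
        )

    def _c(country: str) -> float:
        try:
            val = conc[country]
        except KeyError:
            raise ValueError(f"no concentration for country {country!r}") from None
        if isinstance(val, tuple):
            val = val[0] if species == "THg" else val[1]
        if val < 0:
            raise ValueError(f"negative concentration for {country!r}")
        return float(val)

    own = _c(sheet.country)
    partners = trade.partners_of(sheet.country)
    for partner in partners:
        _c(partner)  # unknown partner -> error before any arithmetic

    partner_flows = trade.partners_of(sheet.country)
    matrix_import = sum(partner_flows.values())
    # Bilateral import mercury, priced at each exporter's concentration; any
    # unattributed remainder of the import term is priced at the pool of partners
    # (or own concentration when there are no partners at all).
    bilateral = {rep: hg_flux(q, _c(rep)) for rep, q in partner_flows.items()}
    import_hg = sum(bilateral.values())
    residual_mass = sheet.import_ - matrix_import
    if residual_mass > 1e-9 * max(sheet.import_, 1.0):
        fallback = import_hg / matrix_import * 1e6 if matrix_import > 0 else own
        import_hg += hg_flux(residual_mass, fallback)

    domestic_mass = sheet.production - sheet.export + sheet.stock_variation
    domestic_hg = domestic_mass * own * 1e-6  # signed on purpose
    supply = sheet.supply
    pool = (domestic_hg + import_hg) / supply * 1e6 if supply > 0 else own

    ledger = FlowLedger(
        country=sheet.country,
        year=sheet.year,
        species=species,
        bilateral_imports=bilateral,
        pool_concentration=pool,
        domestic_concentration=own,
        food_mass=sheet.food,
    )
    ledger.fluxes["production"] = hg_flux(sheet.production, own)
    ledger.fluxes["export"] = hg_flux(sheet.export, own)
    ledger.fluxes["stock_variation"] = sheet.stock_variation * own * 1e-6
    ledger.fluxes["import"] = import_hg
    for term in ("feed", "seed", "processing", "other_uses", "food", "losses"):
        ledger.fluxes[term] = hg_flux(sheet.term(term), pool)
    import_share = import_hg / (domestic_hg + import_hg) if (domestic_hg + import_hg) > 0 else 0.0
    ledger.food_import_origin = ledger.fluxes["food"] * import_share
    return ledger


@dataclass(frozen=True)
class BalanceReport:
    country: str
    year: int
    species: str
    residual_kg: float
    relative: float
    passed: bool


def check_balance(ledger: FlowLedger, tol: float = 1e-9) -> BalanceReport:
    """Signed sources-minus-sinks mercury residual of a built ledger."""
    sources = (
        ledger.flux("production")
        - ledger.flux("export")
        + ledger.flux("stock_variation")
        + ledger.flux("import")
    )
    sinks = sum(
        ledger.flux(t) for t in ("feed", "seed", "processing", "other_uses", "food", "losses")
    )
    residual = sources - sinks
    scale = max(abs(sources) + abs(sinks), 1e-30)
    rel = residual / scale
    return BalanceReport(
        ledger.country, ledger.year, ledger.species, residual, rel, abs(rel) <= tol
    )


def trade_embodied_share(ledgers: Iterable[FlowLedger]) -> float:
    """Fraction of food-supply mercury that originated abroad (0 with a warning
    when no food mercury exists at all)."""
    num = 0.0
    den = 0.0
    for led in ledgers:
        num += led.food_import_origin
        den += led.flux("food")
    if den == 0:
        warnings.warn("no food-supply mercury anywhere; embodied share defined as 0", stacklevel=2)
        return 0.0
    return num / den


def trade_delta(
    ledger: FlowLedger,
    regional_fallback_conc: float | None = None,
) -> float:
    """Relative change in food mercury versus an autarky counterfactual.

    The counterfactual keeps the food mass fixed and prices it at the
    domestic production concentration; countries with no domestic production
    use ``regional_fallback_conc`` (the region's production-weighted mean).
    Returns (actual - counterfactual) / counterfactual.
    """
    cf_conc = ledger.domestic_concentration
    if ledger.flux("production") == 0 and cf_conc == 0:
        if regional_fallback_conc is None:
            raise ValueError(
                f"{ledger.country}: no domestic production and no regional fallback; "
                "trade delta undefined"
            )
        cf_conc = regional_fallback_conc
    counterfactual = hg_flux(ledger.food_mass, cf_conc)
    actual = ledger.flux("food")
    if counterfactual == 0:
        return 0.0 if actual == 0 else float("inf")
    return actual / counterfactual - 1.0
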