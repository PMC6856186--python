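"""Synthetic world generator: internally consistent inputs for the whole pipeline.

Real inputs to this analysis are FAO-style commodity balance sheets, a
bilateral trade matrix, WHO-style demographics and mortality baselines, and
a literature compilation of grain mercury measurements.  None of those ship
with the package; this module fabricates a world with the same statistical
structure — a spatially autocorrelated log-normal grain THg field, a
power-law THg-MeHg relation, gravity-style sparse trade with exact row-sum
consistency, and balance sheets that close exactly — plus the generator's
own ground-truth latent values so analyses can be verified against a known
answer.  Ground truth is written to a separate file the pipeline never reads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .concentrations import (
    CONTAMINATED_CLASSES,
    BACKGROUND_MEHG_POWER_LAW,
    CONTAMINATED_MEHG_POWER_LAW,
    ConcentrationRecord,
    great_circle_km,
)
from .exposure_health import CONTINENT_BODY_WEIGHT_KG, Demographics, HealthBaseline
from .material_flow import BalanceSheet, TradeMatrix
from .plant_partition import EnrichmentSeries
from .residue_fate import FateFractions
from . import dataio

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "calibrate_to_paper",
    "generate_contaminated_survey",
    "PAPER_GLOBAL_GRAIN_THG_KG",
]

#: Calibration target: global grain THg harvested in the reference year, kg/yr.
PAPER_GLOBAL_GRAIN_THG_KG = 5300.0

_CONTINENTS = list(CONTINENT_BODY_WEIGHT_KG)


@dataclass(frozen=True)
class WorldConfig:
    """Statistical structure of the synthetic world.

    The grain THg field is log-normal (median ``thg_median_ng_g``, geometric
    SD ``thg_gsd``) with exponential spatial autocorrelation of range
    ``spatial_range_km``; contaminated sites multiply the background level by
    a log-uniform 10-100x factor; a ``trade_intensity`` fraction of each
    producer's output is exported and a ``food_share`` fraction of domestic
    supply is eaten.  Populations are log-uniform between 1e5 and 1e9.
    """

    n_countries: int = 60
    n_regions: int = 9
    thg_median_ng_g: float = 7.0
    thg_gsd: float = 2.0
    spatial_range_km: float = 3000.0
    contaminated_multiplier: tuple[float, float] = (10.0, 100.0)
    trade_intensity: float = 0.1
    food_share: float = 0.8
    population_range: tuple[float, float] = (1e5, 1e9)
    measured_fraction: float = 0.7
    per_person_supply_mg: tuple[float, float] = (0.05, 0.2)
    year: int = 2013
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        if not 0 <= self.trade_intensity < 1:
            raise ValueError("trade_intensity must lie in [0, 1); exporting everything "
                             "while retaining a domestic food supply is infeasible")
        if not 0 <= self.food_share <= 1:
            raise ValueError("food_share must lie in [0, 1]")
        if not 0 < self.measured_fraction <= 1:
            raise ValueError("measured_fraction must lie in (0, 1]")
        if self.thg_median_ng_g <= 0 or self.thg_gsd < 1:
            raise ValueError("invalid grain THg field parameters")


@dataclass
class SyntheticWorld:
    """All pipeline inputs plus the generator's latent ground truth."""

    config: WorldConfig
    countries: list[str]
    regions: dict[str, str]
    continents: dict[str, str]
    centroids: dict[str, tuple[float, float]]
    records: list[ConcentrationRecord]
    sheets: list[BalanceSheet]
    trade: TradeMatrix
    demographics: dict[str, Demographics]
    baselines: dict[str, HealthBaseline]
    fates: dict[str, FateFractions]
    enrichment: dict[str, EnrichmentSeries]
    nitrogen_mg: dict[str, float]  # residue nitrogen totals, Mg N/yr
    ground_truth: dict = field(default_factory=dict)

    def sheet_for(self, country: str) -> BalanceSheet:
        for s in self.sheets:
            if s.country == country:
                return s
        raise KeyError(country)

    def write(self, outdir: str | Path) -> None:
        """Write the full input file set plus ground_truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dataio.write_balance_sheets(self.sheets, outdir / "balance_sheets.csv")
        dataio.write_trade_matrix(self.trade, outdir / "trade_matrix.csv")
        dataio.write_concentration_records(self.records, outdir / "concentrations.csv")
        dataio.write_demographics(self.demographics, outdir / "demographics.csv")
        dataio.write_baselines(self.baselines, outdir / "baselines.csv")
        dataio.write_fate_fractions(self.fates, outdir / "fates.csv")
        dataio.write_enrichment_series(self.enrichment, outdir / "enrichment.csv")
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "country": c,
                    "region": self.regions[c],
                    "lat": self.centroids[c][0],
                    "lon": self.centroids[c][1],
                    "nitrogen_Mg": self.nitrogen_mg[c],
                }
                for c in self.countries
            ]
        ).to_csv(outdir / "countries.csv", index=False, float_format="%.17g")
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )

    @classmethod
    def read(cls, indir: str | Path, config: WorldConfig | None = None) -> "SyntheticWorld":
        import pandas as pd

        indir = Path(indir)
        meta = pd.read_csv(indir / "countries.csv", float_precision="round_trip")
        countries = [str(c) for c in meta["country"]]
        demographics = dataio.read_demographics(indir / "demographics.csv")
        world = cls(
            config=config or WorldConfig(),
            countries=countries,
            regions={str(r["country"]): str(r["region"]) for _, r in meta.iterrows()},
            continents={c: demographics[c].continent for c in countries},
            centroids={
                str(r["country"]): (float(r["lat"]), float(r["lon"]))
                for _, r in meta.iterrows()
            },
            records=dataio.read_concentration_records(indir / "concentrations.csv"),
            sheets=dataio.read_balance_sheets(indir / "balance_sheets.csv"),
            trade=dataio.read_trade_matrix(indir / "trade_matrix.csv"),
            demographics=demographics,
            baselines=dataio.read_baselines(indir / "baselines.csv"),
            fates=dataio.read_fate_fractions(indir / "fates.csv"),
            enrichment=dataio.read_enrichment_series(indir / "enrichment.csv"),
            nitrogen_mg={
                str(r["country"]): float(r["nitrogen_Mg"]) for _, r in meta.iterrows()
            },
        )
        gt = indir / "ground_truth.json"
        if gt.exists():
            world.ground_truth = json.loads(gt.read_text())
        return world


def _country_ids(n: int) -> list[str]:
    """Opaque ISO-alpha-3-style identifiers: AAA, AAB, ..."""
    out = []
    for i in range(n):
        a, rem = divmod(i, 26 * 26)
        b, c = divmod(rem, 26)
        out.append(chr(65 + a) + chr(65 + b) + chr(65 + c))
    return out


def _spatial_lognormal_field(
    lats: np.ndarray,
    lons: np.ndarray,
    median: float,
    gsd: float,
    range_km: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-normal field with exponential spatial covariance on log scale."""
    n = lats.size
    d = great_circle_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    sigma2 = math.log(gsd) ** 2
    cov = sigma2 * np.exp(-d / range_km) + 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    return median * np.exp(chol @ rng.standard_normal(n))


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    countries = _country_ids(n)

    lats = rng.uniform(-45.0, 55.0, n)
    lons = rng.uniform(-180.0, 180.0, n)
    centroids = {c: (float(la), float(lo)) for c, la, lo in zip(countries, lats, lons)}
    # contiguous-ish regions: sort by longitude, slice into n_regions bands
    order = np.argsort(lons)
    regions: dict[str, str] = {}
    continents: dict[str, str] = {}
    for rank, idx in enumerate(order):
        r = min(rank * config.n_regions // n, config.n_regions - 1)
        regions[countries[idx]] = f"R{r}"
        continents[countries[idx]] = _CONTINENTS[r % len(_CONTINENTS)]

    true_thg = _spatial_lognormal_field(
        lats, lons, config.thg_median_ng_g, config.thg_gsd, config.spatial_range_km, rng
    )
    true_mehg = np.array([BACKGROUND_MEHG_POWER_LAW.predict(t) for t in true_thg])

    # literature-style measurement records for a subset of countries
    records: list[ConcentrationRecord] = []
    n_measured = max(2, int(round(config.measured_fraction * n)))
    measured_idx = rng.choice(n, size=n_measured, replace=False)
    rid = 0
    for idx in measured_idx:
        c = countries[idx]
        for _ in range(int(rng.integers(1, 4))):
            jitter = math.exp(rng.normal(0.0, 0.08))
            gsd = float(rng.uniform(1.5, 2.5))
            n_samples = int(rng.integers(3, 60))
            year = int(rng.integers(2000, 2017))
            lat, lon = centroids[c]
            records.append(
                ConcentrationRecord(
                    record_id=f"rec{rid:04d}",
                    country=c,
                    lat=float(np.clip(lat + rng.normal(0, 1.5), -90, 90)),
                    lon=float(((lon + rng.normal(0, 1.5) + 180) % 360) - 180),
                    site_class="background",
                    organ="grain",
                    species="THg",
                    median=float(true_thg[idx] * jitter),
                    gsd=gsd,
                    n=n_samples,
                    year=year,
                )
            )
            rid += 1
            if rng.random() < 0.5:  # paired MeHg measurement
                records.append(
                    ConcentrationRecord(
                        record_id=f"rec{rid:04d}",
                        country=c,
                        lat=records[-1].lat,
                        lon=records[-1].lon,
                        site_class="background",
                        organ="grain",
                        species="MeHg",
                        median=float(true_mehg[idx] * math.exp(rng.normal(0.0, 0.08))),
                        gsd=gsd,
                        n=n_samples,
                        year=year,
                    )
                )
                rid += 1

    populations = np.exp(
        rng.uniform(math.log(config.population_range[0]), math.log(config.population_range[1]), n)
    )
    demographics = {
        c: Demographics(country=c, continent=continents[c], population=float(p))
        for c, p in zip(countries, populations)
    }
    baselines = {
        c: HealthBaseline(c, float(0.002 * populations[i] * rng.uniform(0.5, 1.5)))
        for i, c in enumerate(countries)
    }

    # production and trade
    production = populations * rng.uniform(*config.per_person_supply_mg, n)
    exports = config.trade_intensity * production * rng.uniform(0.5, 1.5, n)
    exports = np.minimum(exports, 0.9 * production)

    # gravity-style sparse allocation: each exporter serves a few partners,
    # weighted by the partners' populations, then rows sum to exports exactly
    flows: dict[tuple[str, str], float] = {}
    for i in range(n):
        if exports[i] <= 0:
            continue
        k = int(min(8, n - 1))
        partners = rng.choice([j for j in range(n) if j != i], size=k, replace=False)
        weights = populations[partners] * rng.uniform(0.5, 1.5, k)
        weights = weights / weights.sum()
        running = 0.0
        for m, j in enumerate(partners):
            if m == k - 1:
                q = exports[i] - running  # exact row-sum repair
            else:
                q = exports[i] * weights[m]
                running += q
            if q > 0:
                flows[(countries[i], countries[int(j)])] = float(q)
    trade = TradeMatrix(flows)

    imports = np.array([trade.imports_of(c) for c in countries])
    stock = rng.uniform(-0.02, 0.05, n) * production
    supply = production - exports + stock + imports
    # guarantee a nonnegative supply by drawing down stocks where needed
    for i in range(n):
        if supply[i] < 0:
            stock[i] -= supply[i]
            supply[i] = 0.0

    sheets = []
    other_sinks = ("feed", "seed", "processing", "other_uses", "losses")
    for i, c in enumerate(countries):
        food = config.food_share * supply[i]
        rest = supply[i] - food
        shares = rng.dirichlet(np.ones(len(other_sinks)))
        sheet = BalanceSheet(
            country=c,
            year=config.year,
            production=float(production[i]),
            import_=float(imports[i]),
            stock_variation=float(stock[i]),
            export=float(exports[i]),
            food=float(food),
        )
        running = 0.0
        for m, term in enumerate(other_sinks):
            if m == len(other_sinks) - 1:
                q = rest - running  # exact closure
            else:
                q = rest * shares[m]
                running += q
            sheet.set_term(term, float(max(q, 0.0)))
        sheets.append(sheet)

    fates = {}
    for c in countries:
        burned = float(rng.uniform(0.04, 0.15))
        feed = float(rng.uniform(0.15, 0.35))
        fert = float(rng.uniform(0.10, 0.30))
        dom = float(rng.uniform(0.05, 0.15))
        ind = float(rng.uniform(0.01, 0.08))
        thatch = float(rng.uniform(0.01, 0.06))
        fates[c] = FateFractions(
            {
                "burned_field": burned,
                "feed": feed,
                "fertilizer": fert,
                "domestic_fuel": dom,
                "industrial_fuel": ind,
                "thatching": thatch,
            }
        )

    enrichment = {}
    for r in range(config.n_regions):
        start = float(rng.uniform(0.2, 0.5))
        factors = {}
        for year in range(1961, 2017):
            if year >= 2010:
                factors[year] = 1.0
            else:
                frac = (year - 1961) / (2010 - 1961)
                factors[year] = start + (1.0 - start) * frac
        enrichment[f"R{r}"] = EnrichmentSeries(f"R{r}", factors)

    # residue nitrogen totals consistent with a 1.5 straw/grain ratio and
    # 6.5 per-mille nitrogen content
    nitrogen = {c: float(production[i] * 1.5 * 0.0065) for i, c in enumerate(countries)}

    world = SyntheticWorld(
        config=config,
        countries=countries,
        regions=regions,
        continents=continents,
        centroids=centroids,
        records=records,
        sheets=sheets,
        trade=trade,
        demographics=demographics,
        baselines=baselines,
        fates=fates,
        enrichment=enrichment,
        nitrogen_mg=nitrogen,
    )
    world.ground_truth = _ground_truth(world, true_thg, true_mehg)
    return world


def _ground_truth(
    world: SyntheticWorld, true_thg: np.ndarray, true_mehg: np.ndarray
) -> dict:
    """Latent values, computed by the generator's own arithmetic.

    The embodied-trade share below is intentionally written from the
    algebraic identity food_flux = (food/supply) * (domestic_hg + import_hg),
    not by calling the material-flow ledger, so recovering it through the
    analysis modules is a genuine two-route check.
    """
    conc = {c: float(true_mehg[i]) for i, c in enumerate(world.countries)}
    num = 0.0
    den = 0.0
    for i, c in enumerate(world.countries):
        sheet = world.sheet_for(c)
        supply = sheet.supply
        if supply <= 0:
            continue
        dom_hg = (sheet.production - sheet.export + sheet.stock_variation) * conc[c] * 1e-6
        imp_hg = sum(
            q * conc[rep] * 1e-6 for rep, q in world.trade.partners_of(c).items()
        )
        ratio = sheet.food / supply
        num += ratio * imp_hg
        den += ratio * (dom_hg + imp_hg)
    share = num / den if den > 0 else 0.0
    grain_thg = sum(
        world.sheet_for(c).production * float(true_thg[i]) * 1e-6
        for i, c in enumerate(world.countries)
    )
    grain_mehg = sum(
        world.sheet_for(c).production * float(true_mehg[i]) * 1e-6
        for i, c in enumerate(world.countries)
    )
    return {
        "true_thg_ng_g": {c: float(true_thg[i]) for i, c in enumerate(world.countries)},
        "true_mehg_ng_g": {c: float(true_mehg[i]) for i, c in enumerate(world.countries)},
        "trade_embodied_share_mehg": share,
        "global_grain_thg_kg": grain_thg,
        "global_grain_mehg_kg": grain_mehg,
    }


def calibrate_to_paper(
    world: SyntheticWorld, target_grain_thg_kg: float = PAPER_GLOBAL_GRAIN_THG_KG
) -> SyntheticWorld:
    """Scale every mass so the deterministic global grain THg hits the target.

    All balance terms, trade flows and nitrogen totals scale by one factor,
    preserving closure, trade consistency and the embodied-trade share.
    """
    current = world.ground_truth.get("global_grain_thg_kg", 0.0)
    if current <= 0:
        raise ValueError("world has zero global grain THg flux; cannot calibrate")
    factor = target_grain_thg_kg / current
    for sheet in world.sheets:
        for term in (
            "production",
            "import",
            "stock_variation",
            "export",
            "feed",
            "seed",
            "processing",
            "other_uses",
            "food",
            "losses",
        ):
            sheet.set_term(term, sheet.term(term) * factor)
    world.trade = TradeMatrix({k: q * factor for k, q in world.trade.items()})
    world.nitrogen_mg = {c: v * factor for c, v in world.nitrogen_mg.items()}
    gt = dict(world.ground_truth)
    gt["global_grain_thg_kg"] = gt["global_grain_thg_kg"] * factor
    gt["global_grain_mehg_kg"] = gt["global_grain_mehg_kg"] * factor
    world.ground_truth = gt
    return world


def generate_contaminated_survey(
    site_class: str,
    n: int,
    seed: int,
    background_median: float = 7.0,
    multiplier_range: tuple[float, float] = (10.0, 100.0),
) -> list[ConcentrationRecord]:
    """Records from a mercury-contaminated area: background x log-uniform 10-100x
    multiplier for THg, MeHg consistent with the contaminated-site power law
    plus multiplicative noise."""
    if site_class not in CONTAMINATED_CLASSES:
        raise ValueError(f"site_class must be contaminated; one of {sorted(CONTAMINATED_CLASSES)}")
    if n < 3:
        raise ValueError("surveys need n >= 3 records (inclusion rule)")
    rng = np.random.default_rng(seed)
    lat0, lon0 = float(rng.uniform(-30, 45)), float(rng.uniform(-180, 180))
    records = []
    for i in range(n):
        mult = math.exp(rng.uniform(*(math.log(m) for m in multiplier_range)))
        thg = background_median * math.exp(rng.normal(0.0, math.log(2.0))) * mult
        mehg = CONTAMINATED_MEHG_POWER_LAW.predict(thg) * math.exp(rng.normal(0.0, 0.3))
        shared = dict(
            country="XXX",
            lat=float(np.clip(lat0 + rng.normal(0, 0.3), -90, 90)),
            lon=float(((lon0 + rng.normal(0, 0.3) + 180) % 360) - 180),
            site_class=site_class,
            organ="grain",
            gsd=float(rng.uniform(1.5, 2.5)),
            n=int(rng.integers(3, 30)),
            year=int(rng.integers(2000, 2017)),
        )
        records.append(
            ConcentrationRecord(record_id=f"site{i:03d}t", species="THg", median=thg, **shared)
        )
        records.append(
            ConcentrationRecord(record_id=f"site{i:03d}m", species="MeHg", median=mehg, **shared)
        )
    return records
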