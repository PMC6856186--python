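"""Tabular input/output and run configuration.

All interchange is plain CSV (long format, one fact per row) plus JSON for
configuration and Monte Carlo envelopes.  Country identifiers are opaque
ISO-3166-alpha-3-style strings.  Masses are Mg/yr milled equivalent,
concentrations ng/g, fluxes kg/yr, and PWI μg kg^-1 week^-1 throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .concentrations import ConcentrationRecord
from .exposure_health import Demographics, HealthBaseline
from .material_flow import BALANCE_TERMS, BalanceSheet, TradeMatrix
from .plant_partition import EnrichmentSeries
from .residue_fate import FateFractions

logger = logging.getLogger("ricehg")

__all__ = [
    "RunConfig",
    "read_balance_sheets",
    "write_balance_sheets",
    "read_trade_matrix",
    "write_trade_matrix",
    "read_concentration_records",
    "write_concentration_records",
    "read_demographics",
    "write_demographics",
    "read_baselines",
    "write_baselines",
    "read_fate_fractions",
    "write_fate_fractions",
    "read_enrichment_series",
    "write_enrichment_series",
    "write_envelopes",
    "read_envelopes",
]

UNITS = {
    "mass": "Mg/yr",
    "concentration": "ng/g",
    "flux": "kg/yr",
    "pwi": "ug/kg/week",
}


@dataclass
class RunConfig:
    """Run-level configuration: draws, seed, year, quantile band, file paths."""

    n_draws: int = 10_000
    seed: int = 0
    year: int = 2013
    iqr_bounds: tuple[float, float] = (0.25, 0.75)
    units: Mapping[str, str] = field(default_factory=lambda: dict(UNITS))
    paths: dict[str, str] = field(default_factory=dict)
    health_coefficients: str = "rice2010"
    mass_half_width: float = 0.3  # uniform deviation of statistical masses

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        lo, hi = self.iqr_bounds
        if not 0 <= lo < hi <= 1:
            raise ValueError("iqr_bounds must be strictly ordered probabilities")

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["iqr_bounds"] = list(self.iqr_bounds)
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "iqr_bounds" in data:
            data["iqr_bounds"] = tuple(data["iqr_bounds"])
        return cls(**data)


# --------------------------------------------------------------------------
# balance sheets
# --------------------------------------------------------------------------


def read_balance_sheets(path: str | Path) -> list[BalanceSheet]:
    """Read long-format balance sheets: country, year, term, quantity_Mg.

    Missing terms default to zero (logged); unknown terms and negative
    quantities for any term other than stock variation are errors.
    """
    df = _read_csv(path, ["country", "year", "term", "quantity_Mg"])
    if df.empty:
        return []
    bad = sorted(set(df["term"]) - set(BALANCE_TERMS))
    if bad:
        raise ValueError(f"unknown balance term(s) {bad}; valid terms are {list(BALANCE_TERMS)}")
    neg = df[(df["quantity_Mg"] < 0) & (df["term"] != "stock_variation")]
    if not neg.empty:
        row = neg.iloc[0]
        raise ValueError(
            f"negative quantity for term {row['term']!r} in {row['country']} {row['year']}"
        )
    sheets = []
    for (country, year), grp in df.groupby(["country", "year"], sort=True):
        sheet = BalanceSheet(country=str(country), year=int(year))
        present = set()
        for _, row in grp.iterrows():
            sheet.set_term(row["term"], row["quantity_Mg"])
            present.add(row["term"])
        missing = set(BALANCE_TERMS) - present
        if missing:
            logger.warning(
                "%s %s: terms %s missing, defaulting to zero", country, year, sorted(missing)
            )
        sheets.append(sheet)
    return sheets


def write_balance_sheets(sheets: Iterable[BalanceSheet], path: str | Path) -> None:
    rows = [
        {"country": s.country, "year": s.year, "term": t, "quantity_Mg": s.term(t)}
        for s in sheets
        for t in BALANCE_TERMS
    ]
    pd.DataFrame(rows, columns=["country", "year", "term", "quantity_Mg"]).to_csv(
        path, index=False, float_format="%.17g"
    )


# --------------------------------------------------------------------------
# trade matrix
# --------------------------------------------------------------------------


def read_trade_matrix(path: str | Path) -> TradeMatrix:
    """Read long-format bilateral trade: reporter, partner, quantity_Mg."""
    df = _read_csv(path, ["reporter", "partner", "quantity_Mg"])
    matrix = TradeMatrix()
    for _, row in df.iterrows():
        matrix.add_flow(str(row["reporter"]), str(row["partner"]), float(row["quantity_Mg"]))
    return matrix


def write_trade_matrix(matrix: TradeMatrix, path: str | Path) -> None:
    rows = [
        {"reporter": rep, "partner": par, "quantity_Mg": qty}
        for (rep, par), qty in sorted(matrix.items())
    ]
    pd.DataFrame(rows, columns=["reporter", "partner", "quantity_Mg"]).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# concentrations, demographics, baselines, fates, enrichment
# --------------------------------------------------------------------------

_CONC_COLS = [
    "record_id",
    "country",
    "lat",
    "lon",
    "site_class",
    "organ",
    "species",
    "median_ng_g",
    "gsd",
    "n",
    "year",
]


def read_concentration_records(path: str | Path) -> list[ConcentrationRecord]:
    df = _read_csv(path, _CONC_COLS)
    records = []
    for _, row in df.iterrows():
        gsd = row["gsd"]
        year = row["year"]
        records.append(
            ConcentrationRecord(
                record_id=str(row["record_id"]),
                country=str(row["country"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                site_class=str(row["site_class"]),
                organ=str(row["organ"]),
                species=str(row["species"]),
                median=float(row["median_ng_g"]),
                gsd=None if pd.isna(gsd) else float(gsd),
                n=int(row["n"]),
                year=None if pd.isna(year) else int(year),
            )
        )
    return records


def write_concentration_records(records: Iterable[ConcentrationRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "country": r.country,
            "lat": r.lat,
            "lon": r.lon,
            "site_class": r.site_class,
            "organ": r.organ,
            "species": r.species,
            "median_ng_g": r.median,
            "gsd": r.gsd,
            "n": r.n,
            "year": r.year,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CONC_COLS).to_csv(path, index=False, float_format="%.17g")


def read_demographics(path: str | Path) -> dict[str, Demographics]:
    df = _read_csv(path, ["country", "continent", "population", "body_weight_kg"])
    out = {}
    for _, row in df.iterrows():
        bw = row["body_weight_kg"]
        out[str(row["country"])] = Demographics(
            country=str(row["country"]),
            continent=str(row["continent"]),
            population=float(row["population"]),
            body_weight_kg=None if pd.isna(bw) else float(bw),
        )
    return out


def write_demographics(demos: Mapping[str, Demographics], path: str | Path) -> None:
    rows = [
        {
            "country": d.country,
            "continent": d.continent,
            "population": d.population,
            "body_weight_kg": d.body_weight_kg,
        }
        for d in demos.values()
    ]
    pd.DataFrame(rows, columns=["country", "continent", "population", "body_weight_kg"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_baselines(path: str | Path) -> dict[str, HealthBaseline]:
    df = _read_csv(path, ["country", "fatal_heart_attacks_ge30"])
    return {
        str(row["country"]): HealthBaseline(
            str(row["country"]), float(row["fatal_heart_attacks_ge30"])
        )
        for _, row in df.iterrows()
    }


def write_baselines(baselines: Mapping[str, HealthBaseline], path: str | Path) -> None:
    rows = [
        {"country": b.country, "fatal_heart_attacks_ge30": b.fatal_heart_attacks_ge30}
        for b in baselines.values()
    ]
    pd.DataFrame(rows, columns=["country", "fatal_heart_attacks_ge30"]).to_csv(path, index=False, float_format="%.17g")


def read_fate_fractions(path: str | Path, scenario: str = "fao") -> dict[str, FateFractions]:
    df = _read_csv(path, ["country", "fate", "fraction", "scenario"])
    df = df[df["scenario"] == scenario]
    out: dict[str, FateFractions] = {}
    for country, grp in df.groupby("country", sort=True):
        out[str(country)] = FateFractions(
            {str(r["fate"]): float(r["fraction"]) for _, r in grp.iterrows()}
        )
    return out


def write_fate_fractions(
    fates: Mapping[str, FateFractions], path: str | Path, scenario: str = "fao"
) -> None:
    rows = [
        {"country": country, "fate": fate, "fraction": frac, "scenario": scenario}
        for country, ff in fates.items()
        for fate, frac in ff.fractions.items()
    ]
    pd.DataFrame(rows, columns=["country", "fate", "fraction", "scenario"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_enrichment_series(path: str | Path) -> dict[str, EnrichmentSeries]:
    df = _read_csv(path, ["region", "year", "ef"])
    out = {}
    for region, grp in df.groupby("region", sort=True):
        out[str(region)] = EnrichmentSeries(
            str(region), {int(r["year"]): float(r["ef"]) for _, r in grp.iterrows()}
        )
    return out


def write_enrichment_series(series: Mapping[str, EnrichmentSeries], path: str | Path) -> None:
    rows = [
        {"region": s.region, "year": year, "ef": ef}
        for s in series.values()
        for year, ef in sorted(s.factors.items())
    ]
    pd.DataFrame(rows, columns=["region", "year", "ef"]).to_csv(path, index=False, float_format="%.17g")


def write_envelopes(envelopes: Mapping[str, object], path: str | Path) -> None:
    """Write {output_name: {median, q25, q75, n_draws, seed}} as JSON."""
    data = {
        name: env.as_dict() if hasattr(env, "as_dict") else env
        for name, env in envelopes.items()
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def read_envelopes(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    return df
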