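"""Grain mercury concentration modelling.

National grain THg/MeHg concentrations are built from literature-style
measurement summaries: log-normal Monte Carlo sampling of record medians, a
fitted power law to impute MeHg from THg (and its analytic inverse for the
rare opposite case), and ordinary kriging of log-concentrations to countries
without measurements.  Rice from mercury-contaminated sites is kept out of
national surfaces — it is consumed locally and handled by the site-exposure
path instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .uncertainty import lognormal

__all__ = [
    "SITE_CLASSES",
    "CONTAMINATED_CLASSES",
    "ORGANS",
    "SPECIES",
    "DEFAULT_GSD_65PCT",
    "BACKGROUND_MEHG_POWER_LAW",
    "CONTAMINATED_MEHG_POWER_LAW",
    "ConcentrationRecord",
    "PowerLawCoefficients",
    "VariogramSpec",
    "sample_median",
    "impute_mehg_from_thg",
    "invert_mehg_to_thg",
    "fit_power_law",
    "fit_variogram",
    "krige",
    "krige_country_surface",
    "country_grain_concentration",
    "great_circle_km",
]

SITE_CLASSES = frozenset(
    {"background", "gold_mining", "hg_mining", "smelting", "chloralkali", "other_industrial"}
)
CONTAMINATED_CLASSES = SITE_CLASSES - {"background"}
ORGANS = frozenset({"grain", "stem", "leaf", "residue_bulk"})
SPECIES = frozenset({"THg", "MeHg"})

#: Geometric SD implied by a 65% relative uncertainty read as a log-normal whose
#: 95% interval is median x [1/1.65, 1.65]: ln(1.65)/1.96.
DEFAULT_GSD_65PCT = math.exp(math.log(1.65) / 1.96)

#: Year before which literature records are excluded (configurable at call sites).
DEFAULT_YEAR_CUTOFF = 2000


@dataclass(frozen=True)
class ConcentrationRecord:
    """One literature-style measurement summary (median, dispersion, n)."""

    record_id: str
    country: str
    lat: float
    lon: float
    site_class: str
    organ: str
    species: str
    median: float  # ng/g
    gsd: float | None = None  # geometric SD, > 1; None -> 65% default
    n: int = 3
    year: int | None = None

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.median <= 0:
            raise ValueError("median concentration must be > 0")
        if self.gsd is not None and self.gsd <= 1:
            raise ValueError("gsd must be > 1 when present")
        if not -90 <= self.lat <= 90 or not -180 <= self.lon <= 180:
            raise ValueError("coordinates out of range")

    @property
    def included(self) -> bool:
        """Inclusion filter: at least three samples per summary."""
        return self.n >= 3

    @property
    def contaminated(self) -> bool:
        return self.site_class in CONTAMINATED_CLASSES

    def effective_gsd(self, default_gsd: float = DEFAULT_GSD_65PCT) -> float:
        return self.gsd if self.gsd is not None else default_gsd


def sample_median(
    record: ConcentrationRecord,
    rng: np.random.Generator,
    default_gsd: float = DEFAULT_GSD_65PCT,
) -> float:
    """Draw one plausible median from a record's log-normal uncertainty."""
    if record.median <= 0:
        raise ValueError("median must be positive")
    return lognormal(record.median, record.effective_gsd(default_gsd)).sample(rng)


@dataclass(frozen=True)
class PowerLawCoefficients:
    """y = a * x**b with fit standard errors, on concentration (ng/g) scale."""

    a: float
    b: float
    a_se: float = 0.0
    b_se: float = 0.0
    r2: float = float("nan")
    p: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("power-law coefficient a must be > 0")

    def predict(self, x: float) -> float:
        if x < 0:
            raise ValueError("negative concentration")
        if x == 0:
            return 0.0
        return self.a * x**self.b

    def invert(self, y: float) -> float:
        if y < 0:
            raise ValueError("negative concentration")
        if y == 0:
            return 0.0
        return (y / self.a) ** (1.0 / self.b)


# Fitted grain THg -> MeHg relations: background and Hg-contaminated sites.
BACKGROUND_MEHG_POWER_LAW = PowerLawCoefficients(a=0.80, b=0.65, a_se=1.1, b_se=0.072, r2=0.46, p=0.01)
CONTAMINATED_MEHG_POWER_LAW = PowerLawCoefficients(a=0.74, b=0.67, a_se=1.4, b_se=0.091, r2=0.61, p=0.01)


def _law_for_site(site_class: str) -> PowerLawCoefficients:
    if site_class == "background":
        return BACKGROUND_MEHG_POWER_LAW
    if site_class in CONTAMINATED_CLASSES:
        return CONTAMINATED_MEHG_POWER_LAW
    raise ValueError(f"unknown site_class {site_class!r}")


def impute_mehg_from_thg(thg: float, site_class: str = "background") -> float:
    """MeHg (ng/g) from THg via the fitted power law for the site class."""
    return _law_for_site(site_class).predict(thg)


def invert_mehg_to_thg(mehg: float, site_class: str = "background") -> float:
    """Analytic inverse of :func:`impute_mehg_from_thg` (MeHg measured, THg not)."""
    return _law_for_site(site_class).invert(mehg)


def fit_power_law(pairs: Iterable[tuple[float, float]]) -> PowerLawCoefficients:
    """Least-squares fit of log y on log x, back-transformed to y = a x^b.

    Reports the delta-method SE of a, the slope SE, r-squared and the slope
    t-test p-value.  Requires at least three strictly positive pairs.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    if np.any(arr <= 0):
        raise ValueError("all concentrations must be positive for a log-log fit")
    lx, ly = np.log(arr[:, 0]), np.log(arr[:, 1])
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in regressor")
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    intercept, slope = res.params
    a = math.exp(intercept)
    return PowerLawCoefficients(
        a=a,
        b=float(slope),
        a_se=a * float(res.bse[0]),
        b_se=float(res.bse[1]),
        r2=float(res.rsquared),
        p=float(res.pvalues[1]),
    )


# --------------------------------------------------------------------------
# Ordinary kriging on great-circle distances
# --------------------------------------------------------------------------

_EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (array-broadcasting)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass(frozen=True)
class VariogramSpec:
    """Variogram of log-concentration: gamma(h) = nugget + psill*(1 - exp(-h/range))."""

    model: str = "exponential"
    nugget: float = 0.0
    sill: float = 1.0  # total sill (nugget + partial sill)
    range_km: float = 2000.0

    def __post_init__(self) -> None:
        if self.model not in {"exponential", "spherical", "gaussian"}:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill <= 0:
            raise ValueError("sill must be > 0")
        if self.range_km <= 0:
            raise ValueError("range must be > 0")

    @property
    def psill(self) -> float:
        return max(self.sill - self.nugget, 0.0)

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag h (km); gamma(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        r = self.range_km
        if self.model == "exponential":
            struct = 1.0 - np.exp(-h / r)
        elif self.model == "gaussian":
            struct = 1.0 - np.exp(-((h / r) ** 2))
        else:  # spherical
            hr = np.clip(h / r, 0.0, 1.0)
            struct = 1.5 * hr - 0.5 * hr**3
        out = self.nugget + self.psill * struct
        return np.where(h == 0, 0.0, out)


def fit_variogram(
    lats: Sequence[float],
    lons: Sequence[float],
    values: Sequence[float],
    n_bins: int = 12,
    model: str = "exponential",
) -> VariogramSpec:
    """Fit a variogram to the empirical semivariogram by weighted least squares.

    Weights are pair counts per lag bin.  Falls back to a default spec (range =
    one-third of the domain diameter, sill = sample variance) when fitting fails
    or the field is degenerate.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    d = great_circle_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    iu = np.triu_indices(n, k=1)
    h = d[iu]
    sv = 0.5 * (vals[:, None] - vals[None, :])[iu] ** 2
    diameter = float(h.max()) if h.size else 1.0
    fallback = VariogramSpec(
        model=model,
        nugget=0.0,
        sill=max(float(np.var(vals)), 1e-12),
        range_km=max(diameter / 3.0, 1e-6),
    )
    if h.size < n_bins or np.var(vals) == 0:
        return fallback
    edges = np.linspace(0, diameter, n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    gamma_emp = np.array(
        [sv[idx == i].mean() if counts[i] else np.nan for i in range(n_bins)]
    )[keep]
    h_mid = (0.5 * (edges[:-1] + edges[1:]))[keep]
    w = counts[keep].astype(float)

    def _exp_model(hh, nugget, psill, rng_km):
        return nugget + psill * (1.0 - np.exp(-hh / rng_km))

    try:
        p0 = [0.0, max(gamma_emp.max(), 1e-9), max(diameter / 3.0, 1e-3)]
        popt, _ = curve_fit(
            _exp_model,
            h_mid,
            gamma_emp,
            p0=p0,
            sigma=1.0 / np.sqrt(w),
            bounds=([0, 1e-12, 1e-6], [np.inf, np.inf, 10 * diameter]),
            maxfev=10000,
        )
        nugget, psill, rng_km = map(float, popt)
        return VariogramSpec(model=model, nugget=nugget, sill=nugget + psill, range_km=rng_km)
    except Exception:  # noqa: BLE001 - fitting failure falls back by design
        return fallback


def krige(
    sample_lats: Sequence[float],
    sample_lons: Sequence[float],
    sample_values: Sequence[float],
    target_lats: Sequence[float],
    target_lons: Sequence[float],
    spec: VariogramSpec,
    return_weights: bool = False,
):
    """Ordinary kriging of *sample_values* (any scale) to target points.

    Solves, per target, the variogram-based linear system with the
    unbiasedness constraint (weights sum to one).  With a zero nugget the
    predictor is exact at sample locations.  Returns (predictions,
    kriging standard errors[, weights]).
    """
    slat = np.asarray(sample_lats, dtype=float)
    slon = np.asarray(sample_lons, dtype=float)
    z = np.asarray(sample_values, dtype=float)
    tlat = np.asarray(target_lats, dtype=float)
    tlon = np.asarray(target_lons, dtype=float)
    n = z.size
    if n < 1:
        raise ValueError("need at least one sample")
    d_ss = great_circle_km(slat[:, None], slon[:, None], slat[None, :], slon[None, :])
    if n > 1 and np.any(d_ss[np.triu_indices(n, k=1)] < 1e-9):
        raise ValueError("duplicate sample coordinates make the kriging system singular")

    if n == 1:
        # A single datum: the OK predictor collapses to that datum everywhere.
        preds = np.full(tlat.size, z[0])
        ses = np.sqrt(spec.gamma(great_circle_km(slat[0], slon[0], tlat, tlon)))
        if return_weights:
            return preds, ses, np.ones((tlat.size, 1))
        return preds, ses

    a = np.empty((n + 1, n + 1))
    a[:n, :n] = spec.gamma(d_ss)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    d_st = great_circle_km(slat[:, None], slon[:, None], tlat[None, :], tlon[None, :])
    b = np.empty((n + 1, tlat.size))
    b[:n, :] = spec.gamma(d_st)
    b[n, :] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging system") from exc
    weights = sol[:n, :]
    mu = sol[n, :]
    preds = weights.T @ z
    var = np.sum(weights * b[:n, :], axis=0) + mu
    ses = np.sqrt(np.clip(var, 0.0, None))
    if return_weights:
        return preds, ses, weights.T
    return preds, ses


def krige_country_surface(
    samples: Sequence[tuple[float, float, float]],
    targets: Sequence[tuple[float, float]],
    spec: VariogramSpec,
    log_scale: bool = True,
):
    """Interpolate georeferenced concentrations to country centroids.

    ``samples`` are (lat, lon, concentration ng/g); kriging runs on the log
    scale by default and predictions are back-transformed (median-unbiased
    for log-normal fields).  Returns (predictions ng/g, SE of log prediction).
    """
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    slat, slon, sval = (np.asarray(c, dtype=float) for c in zip(*samples))
    tlat, tlon = (np.asarray(c, dtype=float) for c in zip(*targets))
    if log_scale:
        if np.any(sval <= 0):
            raise ValueError("concentrations must be positive for log-scale kriging")
        preds, ses = krige(slat, slon, np.log(sval), tlat, tlon, spec)
        return np.exp(preds), ses
    return krige(slat, slon, sval, tlat, tlon, spec)


# --------------------------------------------------------------------------
# National surfaces
# --------------------------------------------------------------------------


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cut = 0.5 * cum[-1]
    return float(v[np.searchsorted(cum, cut)])


def pool_country_records(records: Sequence[ConcentrationRecord]) -> float:
    """Pool several records for one (country, species): n-weighted median of medians."""
    vals = np.array([r.median for r in records], dtype=float)
    wts = np.array([r.n for r in records], dtype=float)
    return _weighted_median(vals, wts)


def country_grain_concentration(
    records: Iterable[ConcentrationRecord],
    countries: Sequence[str],
    centroids: dict[str, tuple[float, float]],
    spec: VariogramSpec | None = None,
    year_cutoff: int | None = DEFAULT_YEAR_CUTOFF,
) -> dict[str, tuple[float, float]]:
    """Grain (THg, MeHg) central concentrations (ng/g) for every listed country.

    Measured countries pool their own background grain records; a missing
    species is imputed through the fitted power law (or its inverse).
    Countries without usable records get ordinary-kriging predictions from
    the measured countries' pooled log-concentrations.  Contaminated-site
    records never enter national surfaces.
    """
    usable: dict[str, dict[str, list[ConcentrationRecord]]] = {}
    for rec in records:
        if rec.organ != "grain" or rec.contaminated or not rec.included:
            continue
        if year_cutoff is not None and rec.year is not None and rec.year < year_cutoff:
            continue
        usable.setdefault(rec.country, {}).setdefault(rec.species, []).append(rec)
    if not usable:
        raise ValueError("no usable background grain records")

    measured: dict[str, tuple[float, float]] = {}
    for country, by_species in usable.items():
        thg = pool_country_records(by_species["THg"]) if "THg" in by_species else None
        mehg = pool_country_records(by_species["MeHg"]) if "MeHg" in by_species else None
        if thg is None and mehg is not None:
            thg = invert_mehg_to_thg(mehg)
        if mehg is None and thg is not None:
            mehg = impute_mehg_from_thg(thg)
        measured[country] = (float(thg), float(mehg))

    missing = [c for c in countries if c not in measured]
    out = {c: measured[c] for c in countries if c in measured}
    if missing:
        sample_pts = []
        log_thg, log_mehg = [], []
        for country, (thg, mehg) in measured.items():
            lat, lon = centroids[country]
            sample_pts.append((lat, lon))
            log_thg.append(math.log(thg))
            log_mehg.append(math.log(mehg))
        slat, slon = (np.asarray(c, dtype=float) for c in zip(*sample_pts))
        if spec is None:
            spec = fit_variogram(slat, slon, log_thg)
        tlat = np.array([centroids[c][0] for c in missing])
        tlon = np.array([centroids[c][1] for c in missing])
        thg_pred, _ = krige(slat, slon, np.asarray(log_thg), tlat, tlon, spec)
        mehg_pred, _ = krige(slat, slon, np.asarray(log_mehg), tlat, tlon, spec)
        # negative kriging weights can push predictions past the data range;
        # clip to the measured span so national surfaces never extrapolate
        # beyond the background observations
        thg_pred = np.clip(thg_pred, min(log_thg), max(log_thg))
        mehg_pred = np.clip(mehg_pred, min(log_mehg), max(log_mehg))
        for c, lt, lm in zip(missing, thg_pred, mehg_pred):
            out[c] = (math.exp(lt), math.exp(lm))
    return out
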