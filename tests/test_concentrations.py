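"""Concentration modelling: log-normal medians, power-law imputation, kriging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricehg.concentrations import (
    DEFAULT_GSD_65PCT,
    ConcentrationRecord,
    VariogramSpec,
    country_grain_concentration,
    fit_power_law,
    fit_variogram,
    great_circle_km,
    impute_mehg_from_thg,
    invert_mehg_to_thg,
    krige,
    krige_country_surface,
    sample_median,
)


def _record(**kw):
    base = dict(
        record_id="r0", country="AAA", lat=10.0, lon=20.0, site_class="background",
        organ="grain", species="THg", median=10.0, gsd=2.0, n=10, year=2010,
    )
    base.update(kw)
    return ConcentrationRecord(**base)


class TestRecords:
    def test_small_sample_flagged_excluded(self):
        assert not _record(n=2).included
        assert _record(n=3).included

    @pytest.mark.parametrize(
        "kw", [dict(median=0.0), dict(median=-1.0), dict(gsd=1.0), dict(gsd=0.5),
               dict(site_class="mine"), dict(organ="root"), dict(species="EtHg")]
    )
    def test_invalid_records_rejected(self, kw):
        with pytest.raises(ValueError):
            _record(**kw)


class TestSampleMedian:
    def test_degenerate_gsd_returns_median_exactly(self):
        rng = np.random.default_rng(0)
        draws = [sample_median(_record(gsd=1.0 + 1e-15), rng) for _ in range(50)]
        assert np.allclose(draws, 10.0, rtol=1e-6)

    def test_empirical_median_matches_record_median(self):
        # oracle: the median of lognormal(median=10, gsd=2) is 10 by construction
        rng = np.random.default_rng(1)
        rec = _record(median=10.0, gsd=2.0)
        draws = np.array([sample_median(rec, rng) for _ in range(100_000)])
        assert np.median(draws) == pytest.approx(10.0, rel=0.02)
        assert np.all(draws > 0)

    def test_missing_gsd_uses_65pct_default_dispersion(self):
        # 65% rule: 95% interval is median x [1/1.65, 1.65]
        rng = np.random.default_rng(2)
        rec = _record(gsd=None)
        draws = np.array([sample_median(rec, rng) for _ in range(100_000)])
        q = np.quantile(draws, [0.025, 0.975])
        assert q[0] == pytest.approx(10.0 / 1.65, rel=0.03)
        assert q[1] == pytest.approx(10.0 * 1.65, rel=0.03)
        assert DEFAULT_GSD_65PCT == pytest.approx(math.exp(math.log(1.65) / 1.96))


class TestImputation:
    @pytest.mark.parametrize(
        "thg,site,expected",
        [
            (1.0, "background", 0.80),  # unit THg exposes the coefficient
            (0.0, "background", 0.0),
            (10.0, "background", 0.80 * 10**0.65),
            (1.0, "gold_mining", 0.74),
            (1.0, "hg_mining", 0.74),
        ],
    )
    def test_power_law_values(self, thg, site, expected):
        assert impute_mehg_from_thg(thg, site) == pytest.approx(expected, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            impute_mehg_from_thg(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=1e4))
    def test_strictly_increasing_and_continuous_at_zero(self, thg):
        lo = impute_mehg_from_thg(thg)
        hi = impute_mehg_from_thg(thg * 1.01)
        assert hi > lo > 0
        assert impute_mehg_from_thg(1e-12) < 1e-6  # continuity at the origin

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_inverse_round_trips(self, mehg):
        assert invert_mehg_to_thg(impute_mehg_from_thg(
            invert_mehg_to_thg(mehg))) == pytest.approx(invert_mehg_to_thg(mehg), rel=1e-10)


class TestFitPowerLaw:
    @settings(derandomize=True, max_examples=20)
    @given(
        a=st.floats(min_value=0.05, max_value=20.0),
        b=st.floats(min_value=0.1, max_value=2.0),
    )
    def test_noise_free_recovery_any_coefficients(self, a, b):
        x = np.linspace(1.0, 50.0, 30)
        fit = fit_power_law(zip(x, a * x**b))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)

    def test_degenerate_regressor_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])

    def test_too_few_or_nonpositive_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError):
            fit_power_law([(1.0, 1.0), (2.0, -2.0), (3.0, 3.0)])

    def test_noisy_exponent_within_reported_se_most_seeds(self):
        # simulation oracle: with sigma_log=0.6 and n=200 the fitted exponent
        # should land within its own reported SE of the truth well over half
        # the time (the SE is an honest dispersion estimate)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.exp(rng.uniform(0.0, np.log(100.0), 200))
            y = 0.8 * x**0.65 * np.exp(rng.normal(0, 0.6, 200))
            fit = fit_power_law(zip(x, y))
            hits += abs(fit.b - 0.65) <= fit.b_se
        assert hits >= 60


class TestKriging:
    def test_constant_field_predicts_constant(self):
        spec = VariogramSpec(nugget=0.0, sill=1.0, range_km=1000.0)
        lats, lons = [0.0, 10.0, 20.0], [0.0, 10.0, 20.0]
        preds, ses = krige(lats, lons, [5.0, 5.0, 5.0], [5.0, 40.0], [5.0, 40.0], spec)
        assert np.allclose(preds, 5.0, atol=1e-9)

    def test_zero_nugget_is_exact_at_sample_locations(self):
        spec = VariogramSpec(nugget=0.0, sill=2.0, range_km=800.0)
        lats, lons, vals = [0.0, 15.0, -20.0], [0.0, 30.0, -40.0], [1.0, 4.0, 9.0]
        preds, ses = krige(lats, lons, vals, lats, lons, spec)
        assert np.allclose(preds, vals, atol=1e-8)
        assert np.allclose(ses, 0.0, atol=1e-6)

    def test_two_point_weights_match_hand_solved_system(self):
        # closed-form oracle for ordinary kriging with two samples:
        # w1 = (g(d2t) - g(d1t) + g(d12)) / (2 g(d12)), w2 = 1 - w1
        spec = VariogramSpec(nugget=0.1, sill=1.0, range_km=1000.0)
        s_lat, s_lon = [0.0, 0.0], [0.0, 20.0]
        t_lat, t_lon = [0.0], [5.0]
        g12 = spec.gamma(great_circle_km(0.0, 0.0, 0.0, 20.0))
        g1t = spec.gamma(great_circle_km(0.0, 0.0, 0.0, 5.0))
        g2t = spec.gamma(great_circle_km(0.0, 20.0, 0.0, 5.0))
        w1 = (g2t - g1t + g12) / (2 * g12)
        preds, ses, weights = krige(
            s_lat, s_lon, [3.0, 7.0], t_lat, t_lon, spec, return_weights=True
        )
        assert weights[0, 0] == pytest.approx(w1, abs=1e-10)
        assert weights[0, 1] == pytest.approx(1 - w1, abs=1e-10)
        assert preds[0] == pytest.approx(w1 * 3.0 + (1 - w1) * 7.0, abs=1e-10)

    def test_weights_sum_to_one_for_every_target(self):
        rng = np.random.default_rng(3)
        spec = VariogramSpec(nugget=0.2, sill=1.5, range_km=1500.0)
        slat, slon = rng.uniform(-60, 60, 15), rng.uniform(-170, 170, 15)
        vals = rng.normal(0, 1, 15)
        tlat, tlon = rng.uniform(-60, 60, 25), rng.uniform(-170, 170, 25)
        _, _, weights = krige(slat, slon, vals, tlat, tlon, spec, return_weights=True)
        assert np.allclose(weights.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicate_sample_coordinates_rejected(self):
        spec = VariogramSpec()
        with pytest.raises(ValueError, match="duplicate|singular"):
            krige([0.0, 0.0], [10.0, 10.0], [1.0, 2.0], [5.0], [5.0], spec)

    def test_single_datum_collapses_to_that_datum(self):
        spec = VariogramSpec(nugget=0.0, sill=1.0, range_km=500.0)
        preds, _ = krige_country_surface([(0.0, 0.0, 8.0)], [(30.0, 40.0)], spec)
        assert preds[0] == pytest.approx(8.0)

    def test_variogram_fit_recovers_range_scale(self):
        # field generated with a known exponential structure; the fitted range
        # should land within a factor-of-2 band (coarse but structural)
        rng = np.random.default_rng(11)
        n = 200
        lats, lons = rng.uniform(-40, 40, n), rng.uniform(-90, 90, n)
        d = great_circle_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
        cov = np.exp(-d / 2000.0) + 1e-8 * np.eye(n)
        vals = np.linalg.cholesky(cov) @ rng.standard_normal(n)
        spec = fit_variogram(lats, lons, vals)
        assert 500.0 < spec.range_km < 8000.0


class TestCountrySurface:
    def _records(self):
        return [
            _record(record_id="a", country="AAA", lat=0, lon=0, median=10.0, n=20),
            _record(record_id="b", country="AAA", lat=0, lon=1, median=30.0, n=5),
            _record(record_id="c", country="BBB", lat=0, lon=40, median=5.0,
                    species="THg"),
        ]

    def test_measured_country_uses_n_weighted_pooled_median(self):
        cents = {"AAA": (0.0, 0.0), "BBB": (0.0, 40.0)}
        out = country_grain_concentration(self._records(), ["AAA", "BBB"], cents)
        assert out["AAA"][0] == pytest.approx(10.0)  # n=20 dominates the pooling

    def test_thg_only_country_gets_power_law_mehg(self):
        cents = {"BBB": (0.0, 40.0)}
        out = country_grain_concentration(self._records(), ["BBB"], cents)
        assert out["BBB"][1] == pytest.approx(impute_mehg_from_thg(5.0))

    def test_unmeasured_country_with_single_neighbour_equals_neighbour(self):
        recs = [_record(country="AAA", lat=0, lon=0, median=12.0)]
        cents = {"AAA": (0.0, 0.0), "ZZZ": (10.0, 10.0)}
        out = country_grain_concentration(recs, ["AAA", "ZZZ"], cents,
                                          spec=VariogramSpec())
        assert out["ZZZ"][0] == pytest.approx(12.0)

    def test_contaminated_and_small_n_records_excluded(self):
        recs = [
            _record(country="AAA", median=10.0),
            _record(record_id="x", country="AAA", median=1e4, site_class="gold_mining"),
            _record(record_id="y", country="AAA", median=1e4, n=2),
            _record(record_id="z", country="AAA", median=1e4, year=1995),
        ]
        out = country_grain_concentration(recs, ["AAA"], {"AAA": (10.0, 20.0)})
        assert out["AAA"][0] == pytest.approx(10.0)

    def test_no_usable_records_is_an_error(self):
        with pytest.raises(ValueError):
            country_grain_concentration([], ["AAA"], {"AAA": (0.0, 0.0)})

    def test_national_surface_bounded_by_background_records(self, small_world):
        # with contaminated records excluded, no national value can exceed the
        # largest background record under exact (zero-nugget) interpolation
        recs = list(small_world.records)
        cents = small_world.centroids
        out = country_grain_concentration(
            recs, small_world.countries, cents,
            spec=VariogramSpec(nugget=0.0, sill=0.5, range_km=3000.0),
        )
        max_bg = max(r.median for r in recs if r.species == "THg")
        assert max(v[0] for v in out.values()) <= max_bg * (1 + 1e-9)
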