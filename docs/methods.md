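# Methods

This note documents the model, its parameters and defaults, the synthetic
data the tests run against, and the numerical and design choices a
maintainer would want to know about.

## Model overview

The pipeline is a chain of deterministic maps evaluated under a Monte Carlo
draw protocol:

1. **Concentration surfaces.** Each country gets a central grain (THg, MeHg)
   pair. Measured countries pool their background grain records by the
   n-weighted median of record medians; a missing species is imputed through
   the fitted speciation power law (MeHg = a·THg^b with a = 0.80, b = 0.65 at
   background sites, a = 0.74, b = 0.67 near contamination; the inverse is
   applied analytically in the rare MeHg-only case). Countries with no
   usable records receive ordinary-kriging predictions of the measured
   countries' log-concentrations at their centroids, back-transformed.
   Records with n < 3, records from contaminated sites, and records dated
   before 2000 never enter national surfaces; contaminated-site rice is
   treated as locally consumed and handled by the separate site-exposure
   path (`site_pwi`), whose health output is limited to IQ decrement.
2. **Material flow.** A country-year balance sheet must close:
   production − export + stock variation + import = Σ sinks (feed, seed,
   processing, other uses, food, losses), all in Mg/yr milled equivalent.
   Positive stock variation is a drawdown and adds to the supply side.
   Fluxes are mass × concentration × 10⁻⁶ (Mg × ng/g → kg). Domestic terms
   (production, export, stock) are priced at the producer's own
   concentration; each bilateral import at the exporting partner's; sink
   terms at the mass-weighted supply-pool concentration. This mixing rule
   makes mercury closure inherit mass closure exactly and attributes an
   import-origin fraction to the food flux, from which the global
   trade-embodied share and the per-country autarky delta follow. The
   autarky counterfactual keeps the food mass fixed and prices it at the
   domestic production concentration (regional production-weighted fallback
   for non-producers); this is the single largest interpretive decision in
   the trade attribution and sits behind one function argument. Trade
   attribution is one-hop: re-exports are not traced through intermediate
   countries.
3. **Plant partition and residues.** Eight fitted organ relations (two
   linear — residues and leaf from grain THg — and six power laws) map grain
   to stem/leaf/residue concentrations; when only stem and leaf are known,
   bulk residue is their 3:1 dry-mass combination. Residue mass is the
   national residue-nitrogen total divided by the nitrogen content
   (6.5 ± 1.1 ‰ of dry mass), avoiding the wide straw/grain ratio range
   (0.75–2.5, mean 1.5); the ratio and the 42 (1.0–180) ng/g default
   concentration are still used for other crops' residues. Historical
   fluxes scale by regional soil-mercury enrichment factors (an input
   series, = 1 in the 2010s; no extrapolation outside the series support).
4. **Residue fate and burning.** Residue mercury is split across seven
   management fates (field burning, feed, fertilizer, domestic fuel,
   industrial fuel, thatching, left/other; any unassigned remainder goes to
   the last). Burning emits (R/M) · C · E · 10⁻⁶ kg/yr. The printed form
   divides by a "moisture content (%)" M, which read literally (M = 0.125)
   would inflate emissions eightfold; the default here reinterprets M as the
   fresh-to-dry divisor 1/(1 − moisture) ≈ 1.143 at the 12.5% default
   moisture, preserving the algebra at sane magnitudes. The raw-percent
   divisor remains selectable (`moisture_divisor(..., as_percent=True)`) so
   the two conventions can be compared. Combustion efficiency defaults to
   E = 0.85 (configurable). Only THg is emitted; MeHg survival through
   combustion is not modelled.
5. **Exposure and health.** PWI = Food_Hg/P/BW/52 × 10⁹ with continental
   body weights (Africa 61, Asia 58, Europe 71, North America 81, Oceania
   74, South America 68 kg); the global value is population-weighted.
   ΔIQ = γλβ · (ΔPWI·BW/7); ΔCF = Pf · ω · (1 − exp(−φλβ·ΔPWI·BW/7)). The
   dose increment for health impacts is the full rice-derived MeHg PWI (a
   zero-rice-MeHg counterfactual), and health endpoints use MeHg only. The
   slope chain γ = 0.3 IQ points per μg/g hair, λ = 0.2 (μg/g hair)/(μg/L
   blood), β = 0.06 (μg/L blood)/(μg/day), φ = 0.066 risk per μg/g hair
   follows the central estimates of Rice et al. (2010, Environ. Sci.
   Technol. 44:216) and is entirely configuration-driven — no verification
   quantity depends on these values. Intake in year Y is matched against
   baseline mortality of year Y + lag, lag 6 years central, sampled
   uniformly on 2–12 in the Monte Carlo.

## Uncertainty protocol

- Concentrations: log-normal, parameterised by (median, geometric SD);
  log-mean = ln(median), log-SD = ln(gsd). A record without a reported
  dispersion uses the 65%-uncertainty default, mapped to a log-normal whose
  95% interval is median × [1/1.65, 1.65], i.e. gsd = exp(ln 1.65 / 1.96)
  ≈ 1.291. Countries filled by kriging also use this default.
- Statistical masses: uniform with a fixed 30% deviation. The phrase is
  ambiguous between a half-width and a strict coefficient of variation; the
  default reads it as half-width (support [0.7μ, 1.3μ]), and the strict-CV
  reading (half-width 0.3√3·μ) is available via `half_width_factor`. The
  choice changes envelope widths materially and is therefore exposed.
- Per-draw mass closure: sampling every balance term independently would
  break the mass balance in every draw. Source terms are sampled freely;
  sink terms are sampled and then proportionally rescaled to the sampled
  supply; bilateral trade rows are rescaled to the sampled export term and
  the import term is recomputed from the rescaled matrix. Every draw's
  ledger therefore closes and global export/import-origin conservation holds
  draw by draw.
- Regression coefficients (speciation and organ relations): normal
  perturbation of the fitted (a, b) by their standard errors, truncated to
  keep a > 0. The a–b correlation within one fit is not reported and is
  ignored. Linear-relation predictions are floored at zero, since a
  perturbed negative intercept can otherwise produce negative
  concentrations at very low grain levels.
- Cardiovascular causal indicator ω: Bernoulli(1/3) per draw. The gated
  output's envelope has median zero by construction; the ω-probability-
  weighted expectation is reported alongside it.
- Draws: n = 10,000 by default (`RunConfig`); the test suite and examples
  run 2,000 with correspondingly widened statistical tolerances. Each
  (seed, draw index, stream name) triple seeds an independent
  `numpy.random.Generator`, so model components draw from separate streams
  and adding an output does not perturb existing ones under the same seed.
  Identical (config, seed) reruns are bit-identical. Envelopes report the
  median and the 25th–75th percentiles.

## Kriging

Ordinary kriging with an exponential variogram
γ(h) = nugget + psill·(1 − e^(−h/range)) on great-circle (haversine)
distances, solved per target with the unbiasedness constraint; weights sum
to one to 1e-9 and the predictor is exact at sample locations when the
nugget is zero. The variogram is fitted to the empirical semivariogram by
pair-count-weighted least squares; if fitting fails or the field is
degenerate, the fallback is nugget 0, sill = sample variance, range =
one-third of the domain diameter. Duplicate sample coordinates are rejected
(singular system). Kriged national predictions are clipped to the span of
the measured pooled values: negative kriging weights can otherwise
extrapolate beyond the data range, and a national surface above every
background observation would not be physically defensible. Interpolation
runs on the log scale (median-unbiased back-transform for log-normal
fields).

## Synthetic world

The generator emulates the statistical structure of the real inputs:

- Grain THg: log-normal with median 7 ng/g and geometric SD 2 — the level
  at which ~7.4 × 10⁸ Mg of global milled production carries ~5.3 Mg of
  grain THg — with exponential spatial autocorrelation (range 3,000 km) via
  a Cholesky factor over country centroids. MeHg follows the background
  power law exactly, so speciation imputation is verifiable against truth.
- Measurement records: ~70% of countries carry 1–3 grain THg records
  (medians jittered ~8% around truth, gsd 1.5–2.5, n 3–60, years
  2000–2016), half with paired MeHg records; the rest are left for kriging.
- Trade: each exporter ships a `trade_intensity` (default 0.1) fraction of
  production to up to 8 partners, allocated gravity-style by partner
  population and repaired to exact row sums. Balance sheets close exactly:
  food takes `food_share` (default 0.8) of supply, the remainder is split
  by a Dirichlet draw over the other sinks with the last term absorbing
  rounding.
- Demographics: populations log-uniform 1e5–1e9; continental body weights;
  baseline fatal-heart-attack counts ~0.2% of population. Residue nitrogen
  totals equal production × 1.5 × 0.0065, consistent with the mean
  straw/grain ratio and nitrogen content. Default world size is 60
  countries in 9 regions — large enough to exercise every code path
  (kriging, trade attribution, regional fallbacks) while keeping the full
  Monte Carlo in seconds; reproducing the real 281-territory geography is
  explicitly out of scope.
- Ground truth (latent concentrations, the trade-embodied share computed by
  the generator's own algebra, global grain fluxes) is written to
  `ground_truth.json`, which the pipeline never reads; the share is
  recovered by the material-flow ledger to 1e-12 under deterministic
  concentrations, keeping generator and analyser honestly independent.
- `calibrate_to_paper` rescales all masses by one factor so the
  deterministic global grain THg equals a target (default 5,300 kg); the
  scaling preserves closure, trade consistency and the embodied share.
  Under calibration the residue THg inventory lands in a 30–600 Mg band —
  the consequence of the ~8–13× residue/grain concentration ratio implied
  by the linear residue relation at typical grain levels and the 1.5
  residue/grain mass ratio.

What passing tests do **not** show about real data: the synthetic world has
no reporting gaps or inconsistent bilateral mirrors (real FAO matrices
disagree with export terms; the proportional row-rescaling repair is
implemented and logged but exercised only lightly), no multi-commodity
processing chains, no within-country concentration heterogeneity beyond the
record jitter, and concentration records are unbiased around truth whereas
literature compilations oversample contaminated regions.

## Numerical choices and degenerate inputs

- Unit bridge throughout: Mg × ng/g × 10⁻⁶ = kg; PWI in μg kg⁻¹ week⁻¹.
- Closure tolerances: balance sheets 1e-6 relative to turnover on read;
  ledger residuals reported against 1e-9 by default; fate partitioning
  conserves mass to machine precision by absorbing float crumbs into the
  remainder fate.
- Zero denominators: the embodied share of a world without food mercury is
  defined as 0 with a warning; a country with neither domestic production
  nor a regional fallback has an undefined trade delta and raises.
- Truncated-normal sampling uses rejection with a 1,000-iteration cap and a
  clamp fallback; a Monte Carlo run aborts with diagnostics if more than 1%
  of draws fail.
- CSV round trips are exact: floats are written with `%.17g` and parsed
  with round-trip precision.

## Known limitations

- One-hop trade attribution; Leontief-style tracing through re-exports is
  not implemented, and processed-commodity mercury is reported as a sink
  only, not fed back into intake.
- Health endpoints ignore age, sex and socio-economic stratification and
  non-rice dietary sources.
- The enrichment-factor series is an input, not computed; no atmospheric
  transport of emitted mercury; no raster/map outputs or co-kriging.
- With a single-year world the intake–response lag only shifts the baseline
  year label; multi-year worlds would exercise it fully.
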