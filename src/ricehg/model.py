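"""Model/Results facade over the full rice-mercury pipeline.

``RiceHgModel`` bundles a world's inputs (balance sheets, trade, measurement
records, demographics, mortality baselines, residue fates) with a run
configuration; ``fit()`` propagates the uncertainty protocol — log-normal
concentrations, uniform ±30% statistical masses, truncated-normal regression
coefficients, the Bernoulli causal-association indicator — through the
deterministic pipeline and returns a ``RiceHgResults`` holding interquartile
envelopes for every output, a ``summary()`` table, and writers for the
standard result files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import dataio
from .concentrations import (
    DEFAULT_GSD_65PCT,
    country_grain_concentration,
)
from .exposure_health import (
    Demographics,
    HealthBaseline,
    HealthCoefficients,
    global_pwi,
    heart_attack_deaths,
    iq_decrement,
    pwi,
)
from .material_flow import (
    BalanceSheet,
    TradeMatrix,
    build_ledger,
    trade_embodied_share,
)
from .plant_partition import ORGAN_RELATIONS
from .residue_fate import EmissionParams, FateFractions, burning_emission, partition_fates
from .synthetic_world import SyntheticWorld
from .uncertainty import DrawContext, McResult, run_mc

__all__ = ["RiceHgModel", "RiceHgResults"]

_GLOBAL_OUTPUTS = (
    "grain_thg_kg",
    "grain_mehg_kg",
    "residue_thg_kg",
    "residue_mehg_kg",
    "burning_thg_kg",
    "food_thg_kg",
    "food_mehg_kg",
    "pwi_thg",
    "pwi_mehg",
    "iq_points",
    "heart_deaths",
    "heart_deaths_expected",
    "trade_share_mehg",
)


class RiceHgModel:
    """Rice life-cycle mercury biotransport and MeHg exposure model.

    Parameters
    ----------
    sheets, trade, records, demographics, baselines, fates, nitrogen_mg, centroids :
        The world's inputs; see :mod:`ricehg.dataio` for file formats.
    config :
        Run configuration (draw count, seed, quantile band, mass deviation).
    health :
        Dose-response coefficient set; defaults to the Rice et al. (2010)
        central values.
    """

    def __init__(
        self,
        sheets: list[BalanceSheet],
        trade: TradeMatrix,
        records,
        demographics: Mapping[str, Demographics],
        baselines: Mapping[str, HealthBaseline],
        fates: Mapping[str, FateFractions],
        nitrogen_mg: Mapping[str, float],
        centroids: Mapping[str, tuple[float, float]],
        config: dataio.RunConfig | None = None,
        health: HealthCoefficients | None = None,
        emission: EmissionParams | None = None,
        concentrations: Mapping[str, tuple[float, float]] | None = None,
    ):
        self.config = config or dataio.RunConfig()
        self.health = health or HealthCoefficients()
        self.emission = emission or EmissionParams()
        self.sheets = list(sheets)
        self.trade = trade
        self.records = list(records)
        self.demographics = dict(demographics)
        self.baselines = dict(baselines)
        self.fates = dict(fates)
        self.nitrogen_mg = dict(nitrogen_mg)
        self.countries = [s.country for s in self.sheets]
        if concentrations is not None:
            self.central_conc = dict(concentrations)
        else:
            self.central_conc = country_grain_concentration(
                self.records, self.countries, dict(centroids)
            )
        self._conc_gsd = self._per_country_gsd()

    @classmethod
    def from_world(
        cls,
        world: SyntheticWorld,
        config: dataio.RunConfig | None = None,
        use_ground_truth_conc: bool = False,
        **kwargs,
    ) -> "RiceHgModel":
        """Build from a :class:`SyntheticWorld` (optionally bypassing the
        concentration surface with the generator's latent truth, for
        dual-route verification)."""
        conc = None
        if use_ground_truth_conc:
            thg = world.ground_truth["true_thg_ng_g"]
            mehg = world.ground_truth["true_mehg_ng_g"]
            conc = {c: (thg[c], mehg[c]) for c in world.countries}
        return cls(
            sheets=world.sheets,
            trade=world.trade,
            records=world.records,
            demographics=world.demographics,
            baselines=world.baselines,
            fates=world.fates,
            nitrogen_mg=world.nitrogen_mg,
            centroids=world.centroids,
            config=config,
            concentrations=conc,
            **kwargs,
        )

    @classmethod
    def from_directory(cls, indir: str | Path, config: dataio.RunConfig | None = None) -> "RiceHgModel":
        """Build from a directory written by ``SyntheticWorld.write`` / the CLI."""
        world = SyntheticWorld.read(indir)
        return cls.from_world(world, config=config)

    # ------------------------------------------------------------------
    def _per_country_gsd(self) -> dict[str, float]:
        """Sampling dispersion per country: n-weighted mean record gsd, else the
        65% default for kriged (unmeasured) countries."""
        acc: dict[str, list[tuple[float, float]]] = {}
        for rec in self.records:
            if rec.organ != "grain" or rec.contaminated or not rec.included:
                continue
            acc.setdefault(rec.country, []).append((rec.effective_gsd(), float(rec.n)))
        out = {}
        for c in self.countries:
            if c in acc:
                g = np.array([g for g, _ in acc[c]])
                w = np.array([w for _, w in acc[c]])
                out[c] = float(np.exp(np.average(np.log(g), weights=w)))
            else:
                out[c] = DEFAULT_GSD_65PCT
        return out

    # ------------------------------------------------------------------
    def _draw_masses(self, ctx: DrawContext | None):
        """Sampled balance sheets and trade matrix with per-draw closure.

        Source terms get independent uniform factors; sink terms are sampled
        then proportionally rescaled so each country's sinks equal its
        sampled supply.  Trade rows are rescaled to the sampled export term.
        """
        if ctx is None:
            return self.sheets, self.trade
        rng = ctx.rng("masses")
        w = self.config.mass_half_width
        sheets = []
        export_targets = {}
        for s in self.sheets:
            f = lambda: rng.uniform(1 - w, 1 + w)  # noqa: E731
            prod = s.production * f()
            imp = s.import_ * f()
            stock = s.stock_variation * f()
            exp = min(s.export * f(), prod + max(stock, 0.0))
            supply = prod - exp + stock + imp
            if supply < 0:
                stock -= supply
                supply = 0.0
            sink_draws = {
                t: s.term(t) * f()
                for t in ("feed", "seed", "processing", "other_uses", "food", "losses")
            }
            total = sum(sink_draws.values())
            scale = supply / total if total > 0 else 0.0
            new = BalanceSheet(
                country=s.country,
                year=s.year,
                production=prod,
                import_=imp,
                stock_variation=stock,
                export=exp,
                **{("other_uses" if t == "other_uses" else t): v * scale for t, v in sink_draws.items()},
            )
            sheets.append(new)
            export_targets[s.country] = exp
        trade = self.trade.scale_exports_to(export_targets, warn=False)
        # imports must match the rescaled matrix for per-draw conservation
        for sheet in sheets:
            sheet.import_ = trade.imports_of(sheet.country)
            supply = sheet.supply
            total = sheet.sink_total
            if total > 0 and supply >= 0:
                k = supply / total
                for t in ("feed", "seed", "processing", "other_uses", "food", "losses"):
                    sheet.set_term(t, sheet.term(t) * k)
            elif supply < 0:
                sheet.stock_variation -= supply
        return sheets, trade

    def _draw_concentrations(self, ctx: DrawContext | None) -> dict[str, tuple[float, float]]:
        if ctx is None:
            return dict(self.central_conc)
        rng = ctx.rng("concentrations")
        out = {}
        for c, (thg, mehg) in self.central_conc.items():
            g = math.log(self._conc_gsd[c])
            out[c] = (
                thg * math.exp(rng.normal(0.0, g)),
                mehg * math.exp(rng.normal(0.0, g)),
            )
        return out

    def _draw_relations(self, ctx: DrawContext | None) -> dict[str, tuple[float, float]]:
        """Perturbed (a, b) per organ relation; a truncated positive."""
        if ctx is None:
            return {rid: (rel.a, rel.b) for rid, rel in ORGAN_RELATIONS.items()}
        rng = ctx.rng("organ_relations")
        out = {}
        for rid, rel in ORGAN_RELATIONS.items():
            for _ in range(1000):
                a = rng.normal(rel.a, rel.a_se)
                if a > 0:
                    break
            else:
                a = rel.a
            b = rng.normal(rel.b, rel.b_se)
            out[rid] = (a, b)
        return out

    def _draw_health(self, ctx: DrawContext | None) -> tuple[HealthCoefficients, int]:
        h = self.health
        if ctx is None:
            return h, 1
        rng = ctx.rng("health")

        def trunc(mean, se):
            if se == 0:
                return mean
            for _ in range(1000):
                x = rng.normal(mean, se)
                if x >= 0:
                    return x
            return 0.0

        coeffs = HealthCoefficients(
            gamma=trunc(h.gamma, h.gamma_se),
            lam=trunc(h.lam, h.lam_se),
            beta=trunc(h.beta, h.beta_se),
            phi=trunc(h.phi, h.phi_se),
            omega_prob=h.omega_prob,
            lag_years=int(rng.integers(h.lag_range[0], h.lag_range[1] + 1)),
            lag_range=h.lag_range,
        )
        omega = int(rng.random() < h.omega_prob)
        return coeffs, omega

    def _draw_residue_params(self, ctx: DrawContext | None) -> float:
        """Sampled residue nitrogen content (fraction of dry mass)."""
        if ctx is None:
            return 0.0065
        rng = ctx.rng("residue")
        for _ in range(1000):
            x = rng.normal(0.0065, 0.0011)
            if x > 0:
                return x
        return 0.0065

    # ------------------------------------------------------------------
    def evaluate(self, ctx: DrawContext | None = None, per_country: bool = True) -> dict[str, float]:
        """One pipeline evaluation: deterministic when ``ctx`` is None."""
        sheets, trade = self._draw_masses(ctx)
        conc = self._draw_concentrations(ctx)
        rel = self._draw_relations(ctx)
        coeffs, omega = self._draw_health(ctx)
        n_content = self._draw_residue_params(ctx)
        w = self.config.mass_half_width
        res_rng = ctx.rng("residue_mass") if ctx is not None else None

        out: dict[str, float] = {}
        grain_thg = grain_mehg = 0.0
        residue_thg = residue_mehg = burning = 0.0
        food_thg = food_mehg = 0.0
        mehg_ledgers = []
        pwi_pairs_thg = []
        pwi_pairs_mehg = []
        iq_total_weight = 0.0
        iq_weighted = 0.0
        heart_total = 0.0
        heart_expected = 0.0

        a_res_t, b_res_t = rel["residues_thg"]
        a_res_m, b_res_m = rel["residues_mehg"]

        for sheet in sheets:
            c = sheet.country
            c_thg, c_mehg = conc[c]
            grain_thg += sheet.production * c_thg * 1e-6
            grain_mehg += sheet.production * c_mehg * 1e-6

            # residues: linear THg relation, power MeHg relation, mass from nitrogen
            res_conc_thg = max(a_res_t * c_thg + b_res_t, 0.0)
            res_conc_mehg = a_res_m * c_mehg**b_res_m if c_mehg > 0 else 0.0
            n_total = self.nitrogen_mg.get(c, 0.0)
            if res_rng is not None:
                n_total *= res_rng.uniform(1 - w, 1 + w)
            res_mass = n_total / n_content
            res_hg_thg = res_mass * res_conc_thg * 1e-6
            residue_thg += res_hg_thg
            residue_mehg += res_mass * res_conc_mehg * 1e-6

            fates = self.fates.get(c, FateFractions({}))
            fate_ledger = partition_fates(res_hg_thg, fates)
            burned_mass = fates.complete()["burned_field"] * res_mass
            burning += burning_emission(burned_mass, self.emission, res_conc_thg)

            led_t = build_ledger(sheet, conc, trade, species="THg")
            led_m = build_ledger(sheet, conc, trade, species="MeHg")
            mehg_ledgers.append(led_m)
            food_thg += led_t.flux("food")
            food_mehg += led_m.flux("food")

            demo = self.demographics[c]
            pwi_t = pwi(led_t.flux("food"), demo)
            pwi_m = pwi(led_m.flux("food"), demo)
            pwi_pairs_thg.append((pwi_t, demo))
            pwi_pairs_mehg.append((pwi_m, demo))
            iq = iq_decrement(pwi_m, demo.body_weight_kg, coeffs)
            iq_weighted += iq * demo.population
            iq_total_weight += demo.population
            base = self.baselines.get(c)
            if base is not None:
                branch = heart_attack_deaths(pwi_m, demo.body_weight_kg, base, coeffs, omega=1)
                heart_total += omega * branch
                heart_expected += coeffs.omega_prob * branch
            if per_country:
                out[f"pwi_mehg:{c}"] = pwi_m
                out[f"pwi_thg:{c}"] = pwi_t
                out[f"iq:{c}"] = iq
                out[f"heart:{c}"] = (
                    heart_attack_deaths(pwi_m, demo.body_weight_kg, base, coeffs, omega=omega)
                    if base is not None
                    else 0.0
                )
                out[f"fate_burned:{c}"] = fate_ledger["burned_field"]

        out.update(
            grain_thg_kg=grain_thg,
            grain_mehg_kg=grain_mehg,
            residue_thg_kg=residue_thg,
            residue_mehg_kg=residue_mehg,
            burning_thg_kg=burning,
            food_thg_kg=food_thg,
            food_mehg_kg=food_mehg,
            pwi_thg=global_pwi(pwi_pairs_thg),
            pwi_mehg=global_pwi(pwi_pairs_mehg),
            iq_points=iq_weighted / iq_total_weight if iq_total_weight else 0.0,
            heart_deaths=heart_total,
            heart_deaths_expected=heart_expected,
            trade_share_mehg=trade_embodied_share(mehg_ledgers),
        )
        return out

    def deterministic(self) -> dict[str, float]:
        """Central (no-uncertainty) pipeline outputs."""
        return self.evaluate(None)

    def fit(
        self,
        n_draws: int | None = None,
        seed: int | None = None,
        per_country: bool = True,
    ) -> "RiceHgResults":
        """Propagate the uncertainty protocol and summarise as envelopes."""
        n = n_draws if n_draws is not None else self.config.n_draws
        s = seed if seed is not None else self.config.seed
        mc = run_mc(
            lambda ctx: self.evaluate(ctx, per_country=per_country),
            n_draws=n,
            seed=s,
            iqr_bounds=self.config.iqr_bounds,
        )
        return RiceHgResults(model=self, mc=mc)


@dataclass
class RiceHgResults:
    """Fitted results: interquartile envelopes per output plus summary/report."""

    model: RiceHgModel
    mc: McResult
    _deterministic: dict[str, float] | None = field(default=None, repr=False)

    @property
    def envelopes(self):
        return self.mc.envelopes

    def envelope(self, name: str):
        return self.mc.envelopes[name]

    def summary(self, global_only: bool = True) -> pd.DataFrame:
        """Tidy table of output, median, q25, q75 (global outputs by default)."""
        rows = []
        for name, env in self.mc.envelopes.items():
            if global_only and ":" in name:
                continue
            rows.append(
                {"output": name, "median": env.median, "q25": env.q25, "q75": env.q75}
            )
        df = pd.DataFrame(rows, columns=["output", "median", "q25", "q75"])
        if global_only:
            order = {name: i for i, name in enumerate(_GLOBAL_OUTPUTS)}
            df = df.sort_values("output", key=lambda s: s.map(lambda v: order.get(v, 99)))
            df = df.reset_index(drop=True)
        return df

    def country_table(self, prefix: str) -> pd.DataFrame:
        """Per-country envelope table for one output family (e.g. 'pwi_mehg')."""
        rows = []
        for name, env in self.mc.envelopes.items():
            if not name.startswith(prefix + ":"):
                continue
            rows.append(
                {
                    "country": name.split(":", 1)[1],
                    "median": env.median,
                    "q25": env.q25,
                    "q75": env.q75,
                }
            )
        return pd.DataFrame(rows, columns=["country", "median", "q25", "q75"])

    def save(self, outdir: str | Path) -> None:
        """Write envelopes.json, exposure.csv and health.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dataio.write_envelopes(self.mc.envelopes, outdir / "envelopes.json")
        year = self.model.config.year
        exposure = []
        health = []
        for c in self.model.countries:
            for species, key in (("THg", f"pwi_thg:{c}"), ("MeHg", f"pwi_mehg:{c}")):
                if key in self.mc.envelopes:
                    env = self.mc.envelopes[key]
                    exposure.append(
                        {
                            "country": c,
                            "year": year,
                            "species": species,
                            "pwi_median": env.median,
                            "pwi_q25": env.q25,
                            "pwi_q75": env.q75,
                        }
                    )
            iq_key, heart_key = f"iq:{c}", f"heart:{c}"
            if iq_key in self.mc.envelopes:
                iq_env = self.mc.envelopes[iq_key]
                heart_env = self.mc.envelopes.get(heart_key)
                health.append(
                    {
                        "country": c,
                        "iq_points": iq_env.median,
                        "iq_q25": iq_env.q25,
                        "iq_q75": iq_env.q75,
                        "heart_deaths": heart_env.median if heart_env else 0.0,
                        "heart_q25": heart_env.q25 if heart_env else 0.0,
                        "heart_q75": heart_env.q75 if heart_env else 0.0,
                    }
                )
        pd.DataFrame(exposure).to_csv(outdir / "exposure.csv", index=False)
        pd.DataFrame(health).to_csv(outdir / "health.csv", index=False)

    def plot_envelopes(self, outputs=None, ax=None):
        """Horizontal interquartile-bar chart of the global outputs."""
        import matplotlib.pyplot as plt

        names = list(outputs) if outputs else [n for n in _GLOBAL_OUTPUTS if n in self.mc.envelopes]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(names) + 1))
        y = np.arange(len(names))
        med = [self.mc.envelopes[n].median for n in names]
        lo = [med[i] - self.mc.envelopes[n].q25 for i, n in enumerate(names)]
        hi = [self.mc.envelopes[n].q75 - med[i] for i, n in enumerate(names)]
        ax.errorbar(med, y, xerr=[lo, hi], fmt="o", capsize=3)
        ax.set_yticks(y)
        ax.set_yticklabels(names)
        ax.set_xlabel("median and interquartile envelope")
        return ax
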