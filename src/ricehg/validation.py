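"""Parameter-recovery studies for the fitted organ and speciation relations.

The grain THg-MeHg power law and the grain-residue relations are the load-
bearing regressions of the whole analysis; these studies generate synthetic
surveys from known coefficients at realistic noise levels and check that the
package's fitting routines recover them.  They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .concentrations import fit_power_law

__all__ = [
    "PowerLawRecovery",
    "LinearRecovery",
    "recover_power_law",
    "recover_linear",
]


@dataclass(frozen=True)
class PowerLawRecovery:
    """Summary of a multi-seed power-law recovery study."""

    mean_exponent: float
    geomean_coefficient: float
    exponents: np.ndarray
    coefficients: np.ndarray
    n_pairs: int
    n_seeds: int


@dataclass(frozen=True)
class LinearRecovery:
    mean_slope: float
    mean_intercept: float
    slopes: np.ndarray
    intercepts: np.ndarray
    n_pairs: int
    n_seeds: int


def recover_power_law(
    a: float,
    b: float,
    n_pairs: int = 200,
    x_range: tuple[float, float] = (1.0, 100.0),
    sigma_log: float = 0.6,
    n_seeds: int = 100,
    seed: int = 0,
) -> PowerLawRecovery:
    """Fit ``fit_power_law`` to surveys drawn from y = a x^b with multiplicative
    log-normal noise; x is log-uniform over ``x_range``."""
    root = np.random.SeedSequence(seed)
    exps = np.empty(n_seeds)
    coefs = np.empty(n_seeds)
    for i, child in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        x = np.exp(rng.uniform(np.log(x_range[0]), np.log(x_range[1]), n_pairs))
        y = a * x**b * np.exp(rng.normal(0.0, sigma_log, n_pairs))
        fit = fit_power_law(zip(x, y))
        exps[i] = fit.b
        coefs[i] = fit.a
    return PowerLawRecovery(
        mean_exponent=float(exps.mean()),
        geomean_coefficient=float(np.exp(np.log(coefs).mean())),
        exponents=exps,
        coefficients=coefs,
        n_pairs=n_pairs,
        n_seeds=n_seeds,
    )


def recover_linear(
    slope: float,
    intercept: float,
    n_pairs: int = 200,
    x_range: tuple[float, float] = (1.0, 200.0),
    noise_sd: float = 30.0,
    n_seeds: int = 100,
    seed: int = 0,
) -> LinearRecovery:
    """Ordinary least squares on surveys from y = slope*x + intercept with
    additive normal noise; x uniform over ``x_range``."""
    root = np.random.SeedSequence(seed)
    slopes = np.empty(n_seeds)
    intercepts = np.empty(n_seeds)
    for i, child in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        x = rng.uniform(x_range[0], x_range[1], n_pairs)
        y = slope * x + intercept + rng.normal(0.0, noise_sd, n_pairs)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercepts[i], slopes[i] = res.params
    return LinearRecovery(
        mean_slope=float(slopes.mean()),
        mean_intercept=float(intercepts.mean()),
        slopes=slopes,
        intercepts=intercepts,
        n_pairs=n_pairs,
        n_seeds=n_seeds,
    )
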