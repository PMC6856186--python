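"""Monte Carlo engine: distribution specs, named sub-streams, interquartile envelopes.

The uncertainty protocol mirrors common practice in contaminant flux accounting:
measured concentrations are log-normal (median, geometric SD), statistical masses
are uniform with a fixed 30% relative deviation, fitted regression coefficients are
normal perturbations truncated to admissible ranges, and a Bernoulli indicator
switches causal epidemiological associations on or off per draw.  Results are
summarised as the median and the 25th–75th percentile band of the draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "DistributionSpec",
    "lognormal",
    "uniform_cv30",
    "normal_trunc",
    "bernoulli",
    "point",
    "Envelope",
    "DrawContext",
    "run_mc",
    "McFailure",
]

_VALID_KINDS = {"lognormal", "uniform_cv30", "normal_trunc", "bernoulli", "point"}


@dataclass(frozen=True)
class DistributionSpec:
    """A validated univariate sampling recipe.

    kind:
        ``lognormal``      params (median, gsd); log-mean = ln(median), log-sd = ln(gsd)
        ``uniform_cv30``   params (mean,); uniform on [0.7*mean, 1.3*mean] (half-width
                           reading of "fixed coefficient of deviation of 30%"); a
                           strict-CV reading is available via ``half_width_factor``
        ``normal_trunc``   params (mean, se, lower); redrawn until >= lower
        ``bernoulli``      params (p,)
        ``point``          params (value,)
    """

    kind: str
    params: tuple[float, ...]
    half_width_factor: float = 0.3  # uniform_cv30 only; 0.3*sqrt(3) for strict CV

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}; one of {sorted(_VALID_KINDS)}")
        p = self.params
        if self.kind == "lognormal":
            median, gsd = p
            if median <= 0:
                raise ValueError("lognormal median must be > 0")
            if gsd < 1:
                raise ValueError("lognormal gsd must be >= 1")
        elif self.kind == "uniform_cv30":
            (mean,) = p
            if mean < 0:
                raise ValueError("uniform_cv30 mean must be >= 0")
            if not 0 < self.half_width_factor < 1:
                raise ValueError("half_width_factor must be in (0, 1)")
        elif self.kind == "normal_trunc":
            mean, se, lower = p
            if se < 0:
                raise ValueError("normal_trunc se must be >= 0")
            if mean < lower:
                raise ValueError("normal_trunc mean below truncation bound")
        elif self.kind == "bernoulli":
            (prob,) = p
            if not 0 <= prob <= 1:
                raise ValueError("bernoulli p must lie in [0, 1]")
        # point: any finite value
        elif not math.isfinite(p[0]):
            raise ValueError("point value must be finite")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return float(self.params[0])
        if self.kind == "lognormal":
            median, gsd = self.params
            if gsd == 1.0:
                return float(median)
            return float(median * math.exp(rng.normal(0.0, math.log(gsd))))
        if self.kind == "uniform_cv30":
            (mean,) = self.params
            w = self.half_width_factor
            return float(rng.uniform((1 - w) * mean, (1 + w) * mean))
        if self.kind == "normal_trunc":
            mean, se, lower = self.params
            if se == 0.0:
                return float(mean)
            for _ in range(1000):
                x = rng.normal(mean, se)
                if x >= lower:
                    return float(x)
            return float(lower)  # pathological spec; clamp rather than loop forever
        # bernoulli
        return float(rng.random() < self.params[0])


def lognormal(median: float, gsd: float) -> DistributionSpec:
    return DistributionSpec("lognormal", (median, gsd))


def uniform_cv30(mean: float, half_width_factor: float = 0.3) -> DistributionSpec:
    return DistributionSpec("uniform_cv30", (mean,), half_width_factor)


def normal_trunc(mean: float, se: float, lower: float = -math.inf) -> DistributionSpec:
    return DistributionSpec("normal_trunc", (mean, se, lower))


def bernoulli(p: float) -> DistributionSpec:
    return DistributionSpec("bernoulli", (p,))


def point(value: float) -> DistributionSpec:
    return DistributionSpec("point", (value,))


def draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Sample one value from *spec* using *rng*."""
    return spec.sample(rng)


@dataclass(frozen=True)
class Envelope:
    """Monte Carlo summary: median and interquartile band of one scalar output."""

    median: float
    q25: float
    q75: float
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError("envelope quantiles out of order")

    def as_dict(self) -> dict:
        return {
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


class DrawContext:
    """Per-draw bundle of independent, named random sub-streams.

    Each (seed, draw index, stream name) triple maps to its own
    ``numpy.random.Generator``, so a model component that pulls from stream
    ``"concentrations"`` is unaffected by another component adding draws on
    stream ``"masses"`` — outputs stay stable under the same seed when new
    outputs are added.
    """

    def __init__(self, seed: int, index: int):
        self.seed = int(seed)
        self.index = int(index)
        self._streams: dict[str, np.random.Generator] = {}

    def rng(self, name: str = "default") -> np.random.Generator:
        gen = self._streams.get(name)
        if gen is None:
            key = zlib.crc32(name.encode("utf-8"))
            ss = np.random.SeedSequence([self.seed & 0x7FFFFFFF, self.index, key])
            gen = np.random.default_rng(ss)
            self._streams[name] = gen
        return gen

    def sample(self, spec: DistributionSpec, stream: str = "default") -> float:
        return spec.sample(self.rng(stream))


class McFailure(RuntimeError):
    """Raised when more than the tolerated fraction of draws error out."""


@dataclass
class McResult:
    """Envelopes for every scalar output of a Monte Carlo run."""

    envelopes: dict[str, Envelope]
    n_draws: int
    seed: int
    n_failed: int = 0
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __getitem__(self, key: str) -> Envelope:
        return self.envelopes[key]

    def as_dict(self) -> dict:
        return {k: v.as_dict() for k, v in self.envelopes.items()}


def run_mc(
    model: Callable[[DrawContext], Mapping[str, float]],
    n_draws: int,
    seed: int,
    iqr_bounds: tuple[float, float] = (0.25, 0.75),
    max_failure_fraction: float = 0.01,
    keep_draws: bool = False,
) -> McResult:
    """Run *model* over ``n_draws`` independent draw contexts and summarise.

    The model must be a pure function of its :class:`DrawContext`; identical
    (model, n_draws, seed) yields bit-identical envelopes.  Draws on which the
    model raises are recorded as failed; more than ``max_failure_fraction``
    failures aborts with diagnostics.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    lo, hi = iqr_bounds
    if not 0 <= lo < hi <= 1:
        raise ValueError("iqr_bounds must be ordered probabilities")

    samples: dict[str, list[float]] = {}
    failures: list[tuple[int, str]] = []
    for i in range(n_draws):
        ctx = DrawContext(seed, i)
        try:
            out = model(ctx)
        except Exception as exc:  # noqa: BLE001 - failed draws are data
            failures.append((i, repr(exc)))
            continue
        for key, val in out.items():
            samples.setdefault(key, []).append(float(val))

    if failures and len(failures) > max_failure_fraction * n_draws:
        head = "; ".join(f"draw {i}: {msg}" for i, msg in failures[:5])
        raise McFailure(f"{len(failures)}/{n_draws} draws failed: {head}")

    envelopes = {}
    kept = {}
    for key, vals in samples.items():
        arr = np.asarray(vals)
        q25, med, q75 = np.quantile(arr, [lo, 0.5, hi])
        envelopes[key] = Envelope(float(med), float(q25), float(q75), n_draws, int(seed))
        if keep_draws:
            kept[key] = arr
    return McResult(envelopes, n_draws, int(seed), len(failures), kept)
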