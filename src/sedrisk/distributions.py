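"""Distribution families, moment fitting, Anderson-Darling selection, sampling.

Summary tables in sediment studies report a mean and standard deviation per
element (plus min/max and a best-fit family name), not raw data or fitted
parameters. Every location-scale family here is therefore parameterized so
that a (mean, sd) pair can be inverted analytically into distribution
parameters, and a triangular spec can be built from a (mode, min, max)
triple. Family selection among candidates uses the fully-specified
Anderson-Darling statistic A² on moment-fitted candidates, which is stable
at the tiny sample sizes (n ≈ 15) typical of sediment surveys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "FitResult",
    "fit_moments",
    "triangular_from_table",
    "ad_statistic",
    "select_best",
    "sample",
]

EULER_GAMMA = 0.5772156649015329

#: Recognized families, in tie-breaking order.
FAMILIES = (
    "normal",
    "lognormal",
    "logistic",
    "gumbel_max",
    "gumbel_min",
    "triangular",
    "uniform",
    "point",
)

# Families whose moment fit is infeasible for non-positive means.
_POSITIVE_MEAN_FAMILIES = frozenset({"lognormal"})


class DistributionError(ValueError):
    """Invalid distribution specification or infeasible fit."""


@dataclass(frozen=True)
class DistributionSpec:
    """A named distribution family with parameters and optional truncation.

    Parameter conventions by family:

    - ``normal``, ``logistic``, ``gumbel_max``, ``gumbel_min``: ``(loc, scale)``
    - ``lognormal``: ``(mu, sigma)`` in log space
    - ``triangular``: ``(low, mode, high)``
    - ``uniform``: ``(low, high)``
    - ``point``: ``(value,)``

    ``truncation`` is an inclusive ``(low, high)`` support restriction applied
    at sampling time by rejection; either bound may be ``None``.
    """

    family: str
    params: tuple[float, ...]
    truncation: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family in ("normal", "lognormal", "logistic", "gumbel_max", "gumbel_min"):
            if len(self.params) != 2:
                raise DistributionError(f"{self.family} needs (loc, scale) parameters")
            if self.params[1] <= 0:
                raise DistributionError(f"{self.family} scale must be > 0, got {self.params[1]}")
        elif self.family == "triangular":
            if len(self.params) != 3:
                raise DistributionError("triangular needs (low, mode, high)")
            low, mode, high = self.params
            if not (low <= mode <= high):
                raise DistributionError(f"triangular requires low <= mode <= high, got {self.params}")
        elif self.family == "uniform":
            if len(self.params) != 2 or self.params[0] > self.params[1]:
                raise DistributionError("uniform needs ordered (low, high)")
        elif self.family == "point":
            if len(self.params) != 1:
                raise DistributionError("point needs a single value")
        if self.truncation is not None:
            low, high = self.truncation
            if low is not None and high is not None and low > high:
                raise DistributionError("truncation bounds must be ordered")
            object.__setattr__(self, "truncation", (low, high))

    # -- analytic moments (untruncated) ------------------------------------

    def frozen(self):
        """The scipy frozen distribution behind this spec (None for point)."""
        f, p = self.family, self.params
        if f == "normal":
            return stats.norm(loc=p[0], scale=p[1])
        if f == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if f == "logistic":
            return stats.logistic(loc=p[0], scale=p[1])
        if f == "gumbel_max":
            return stats.gumbel_r(loc=p[0], scale=p[1])
        if f == "gumbel_min":
            return stats.gumbel_l(loc=p[0], scale=p[1])
        if f == "triangular":
            low, mode, high = p
            if high == low:
                return None  # degenerate triangle == point mass
            return stats.triang(c=(mode - low) / (high - low), loc=low, scale=high - low)
        if f == "uniform":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        return None  # point

    def mean(self) -> float:
        if self.family == "point":
            return self.params[0]
        if self.family == "triangular":
            low, mode, high = self.params
            return (low + mode + high) / 3.0
        return float(self.frozen().mean())

    def sd(self) -> float:
        if self.family == "point":
            return 0.0
        if self.family == "triangular":
            low, mode, high = self.params
            if high == low:
                return 0.0
            var = (low**2 + mode**2 + high**2 - low * mode - low * high - mode * high) / 18.0
            return math.sqrt(var)
        return float(self.frozen().std())

    def cdf(self, x):
        if self.family == "point":
            return np.where(np.asarray(x, dtype=float) >= self.params[0], 1.0, 0.0)
        if self.family == "triangular" and self.params[2] == self.params[0]:
            return np.where(np.asarray(x, dtype=float) >= self.params[0], 1.0, 0.0)
        return self.frozen().cdf(x)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        named = {
            "normal": ("loc", "scale"),
            "lognormal": ("mu", "sigma"),
            "logistic": ("loc", "scale"),
            "gumbel_max": ("loc", "scale"),
            "gumbel_min": ("loc", "scale"),
            "triangular": ("min", "mode", "max"),
            "uniform": ("min", "max"),
            "point": ("value",),
        }[self.family]
        d: dict = {"family": self.family}
        if self.family == "triangular":
            # serialized as mode/min/max for readability
            d.update({"mode": self.params[1], "min": self.params[0], "max": self.params[2]})
        else:
            d.update(dict(zip(named, self.params)))
        if self.truncation is not None:
            d["truncation"] = list(self.truncation)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        """Build a spec from a config mapping.

        Location-scale families accept either raw parameters (``loc``/``scale``
        or ``mu``/``sigma``) or a ``mean``/``sd`` pair, which is moment-fitted.
        Triangular accepts ``mode``/``min``/``max``; point accepts ``value``.
        """
        d = dict(d)
        family = d.pop("family")
        trunc = d.pop("truncation", None)
        if trunc is not None:
            trunc = tuple(trunc)
        if family == "point":
            spec = cls("point", (d["value"],))
        elif family == "triangular":
            spec = triangular_from_table(d["mode"], d["min"], d["max"])
        elif family == "uniform" and "min" in d:
            spec = cls("uniform", (d["min"], d["max"]))
        elif "mean" in d:
            spec = fit_moments(family, d["mean"], d["sd"])
        elif family == "lognormal":
            spec = cls("lognormal", (d["mu"], d["sigma"]))
        else:
            spec = cls(family, (d["loc"], d["scale"]))
        if trunc is not None:
            spec = replace(spec, truncation=trunc)
        return spec


@dataclass(frozen=True)
class FitResult:
    """Outcome of best-family selection: the winning spec and its A²."""

    spec: DistributionSpec
    ad_statistic: float
    n: int
    candidates: tuple[tuple[str, float], ...] = field(default=())


def fit_moments(
    family: str,
    mean: float,
    sd: float,
    truncation: tuple[float | None, float | None] | None = None,
) -> DistributionSpec:
    """Invert a (mean, sd) pair into distribution parameters analytically.

    The returned spec's untruncated analytic mean and sd equal the inputs.
    """
    if family == "point":
        return DistributionSpec("point", (mean,), truncation)
    if sd <= 0:
        raise DistributionError(f"sd must be > 0 for family {family!r}, got {sd}")
    if family == "normal":
        params = (mean, sd)
    elif family == "logistic":
        params = (mean, sd * math.sqrt(3.0) / math.pi)
    elif family == "gumbel_max":
        beta = sd * math.sqrt(6.0) / math.pi
        params = (mean - EULER_GAMMA * beta, beta)
    elif family == "gumbel_min":
        beta = sd * math.sqrt(6.0) / math.pi
        params = (mean + EULER_GAMMA * beta, beta)
    elif family == "lognormal":
        if mean <= 0:
            raise DistributionError("lognormal moment fit needs mean > 0")
        sigma2 = math.log1p((sd / mean) ** 2)
        params = (math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2))
    elif family == "uniform":
        h = sd * math.sqrt(3.0)
        params = (mean - h, mean + h)
    elif family == "triangular":
        # symmetric triangle matching the two moments: var = h^2 / 6
        h = sd * math.sqrt(6.0)
        params = (mean - h, mean, mean + h)
    else:
        raise DistributionError(f"unknown family {family!r}")
    return DistributionSpec(family, params, truncation)


def triangular_from_table(mode: float, low: float, high: float) -> DistributionSpec:
    """Triangular spec from the 'most probable value (minimum, maximum)' form."""
    if not (low <= mode <= high):
        raise DistributionError(f"triangular requires min <= mode <= max, got mode={mode}, min={low}, max={high}")
    return DistributionSpec("triangular", (low, mode, high))


def sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` values from ``spec``; truncation is applied by resampling.

    ``seed`` may be an int, SeedSequence, or Generator; results are
    reproducible for a given (spec, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frozen = spec.frozen()
    if frozen is None:  # point mass (or degenerate triangle)
        return np.full(n, spec.params[0], dtype=float)
    draws = np.asarray(frozen.rvs(size=n, random_state=rng), dtype=float)
    if spec.truncation is not None:
        low, high = spec.truncation
        for _ in range(1000):
            bad = np.zeros(n, dtype=bool)
            if low is not None:
                bad |= draws < low
            if high is not None:
                bad |= draws > high
            k = int(bad.sum())
            if k == 0:
                break
            draws[bad] = frozen.rvs(size=k, random_state=rng)
        else:
            raise DistributionError(f"truncation {spec.truncation} rejects virtually all draws of {spec}")
    return draws


def ad_statistic(samples: Sequence[float], spec: DistributionSpec) -> float:
    """Anderson-Darling A² of a sample against a fully specified distribution.

    A² = -n - (1/n) Σ_{i=1..n} (2i-1) [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))].

    The fitted CDF is clipped into (0, 1) at 1e-12 so that samples at or
    beyond the candidate's support boundary contribute a large but finite
    penalty rather than an infinity.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("ad_statistic needs at least 3 samples")
    f = np.clip(np.asarray(spec.cdf(x), dtype=float), 1e-12, 1.0 - 1e-12)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("CDF not finite at a sample value")
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(f) + np.log1p(-f[::-1])))
    return float(-n - s / n)


def select_best(
    samples: Sequence[float],
    families: Iterable[str] = ("normal", "lognormal", "logistic", "gumbel_max", "gumbel_min", "triangular"),
) -> FitResult:
    """Fit each candidate family by moments and keep the minimal-A² spec.

    Location-scale families are moment-fitted from the sample mean and the
    n-1 standard deviation; the triangular candidate takes its support from
    the sample extremes and its mode from 3·median - 2·mean clamped into
    [min, max]. A constant sample short-circuits to a point spec with A² = 0.
    Ties break by the order families are listed.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("select_best needs at least 3 samples")
    families = list(families)
    if not families:
        raise ValueError("select_best needs at least one candidate family")
    if np.ptp(x) == 0.0:
        return FitResult(DistributionSpec("point", (float(x[0]),)), 0.0, int(x.size))
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    results: list[tuple[str, float, DistributionSpec]] = []
    errors: list[str] = []
    for fam in families:
        try:
            if fam == "triangular":
                low, high = float(x.min()), float(x.max())
                mode = min(max(3.0 * float(np.median(x)) - 2.0 * m, low), high)
                spec = DistributionSpec("triangular", (low, mode, high))
            else:
                spec = fit_moments(fam, m, s)
            results.append((fam, ad_statistic(x, spec), spec))
        except (DistributionError, FloatingPointError) as exc:
            errors.append(f"{fam}: {exc}")
    if not results:
        raise DistributionError("all candidate fits failed: " + "; ".join(errors))
    fam, a2, spec = min(results, key=lambda r: r[1])
    return FitResult(spec, a2, int(x.size), tuple((f, a) for f, a, _ in results))
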