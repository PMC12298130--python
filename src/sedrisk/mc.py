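"""Monte Carlo propagation engine.

Draws seeded samples from per-input distribution specs, pushes them through
a deterministic index function, and summarizes the output draws as mean,
sd, percentiles, threshold exceedance fractions, and empirical category
probabilities under a classification scheme. Plain Monte Carlo only — no
variance reduction — and per-input sampling is independent (no correlation
structure is imposed on the inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .config import RunConfig
from .distributions import DistributionSpec, sample
from .indices import ClassificationScheme

__all__ = ["MCSummary", "MCError", "propagate", "category_probability", "percentile", "summarize"]

log = logging.getLogger(__name__)

#: Percentile levels always reported, bracketing the 90% and 95% bands.
PERCENTILE_LEVELS = (2.5, 5.0, 50.0, 95.0, 97.5)

#: Hard failure threshold for the fraction of non-finite output draws.
MAX_NONFINITE_FRACTION = 0.01


class MCError(RuntimeError):
    """Monte Carlo propagation failed (e.g. too many non-finite draws)."""


@dataclass(frozen=True)
class MCSummary:
    """Summary of one simulated quantity."""

    quantity: str
    mean: float
    sd: float
    percentiles: dict[float, float]
    iterations: int
    seed: int | None = None
    category_probabilities: dict[str, float] | None = None
    exceedance: dict[str, float] | None = None
    n_nonfinite: int = 0

    def to_dict(self) -> dict:
        d = {
            "quantity": self.quantity,
            "mean": self.mean,
            "sd": self.sd,
            "percentiles": {str(k): v for k, v in self.percentiles.items()},
            "iterations": self.iterations,
            "seed": self.seed,
            "n_nonfinite": self.n_nonfinite,
        }
        if self.category_probabilities is not None:
            d["category_probabilities"] = dict(self.category_probabilities)
        if self.exceedance is not None:
            d["exceedance"] = dict(self.exceedance)
        return d


def percentile(draws, level: float) -> float:
    """Linear-interpolation empirical quantile at ``level`` (percent)."""
    if not (0.0 < level < 100.0):
        raise ValueError("percentile level must lie strictly between 0 and 100")
    return float(np.percentile(np.asarray(draws, dtype=float), level, method="linear"))


def category_probability(draws, scheme: ClassificationScheme) -> dict[str, float]:
    """Empirical fraction of draws falling in each category of ``scheme``.

    Invariant to draw order; the fractions sum to 1 over the scheme labels.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("category_probability needs at least one draw")
    idx = np.searchsorted(scheme.breakpoints, x, side="left")
    counts = np.bincount(idx, minlength=len(scheme.labels))
    return {label: float(c) / x.size for label, c in zip(scheme.labels, counts)}


def summarize(
    draws,
    quantity: str,
    *,
    seed: int | None = None,
    scheme: ClassificationScheme | None = None,
    thresholds: Mapping[str, float] | None = None,
    n_nonfinite: int = 0,
) -> MCSummary:
    """Summarize finite output draws; ``thresholds`` maps labels to levels
    reported as exceedance fractions P(draw > level)."""
    x = np.asarray(draws, dtype=float)
    pcts = {lv: percentile(x, lv) for lv in PERCENTILE_LEVELS} if x.size > 0 else {}
    return MCSummary(
        quantity=quantity,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        percentiles=pcts,
        iterations=int(x.size),
        seed=seed,
        category_probabilities=category_probability(x, scheme) if scheme is not None else None,
        exceedance={k: float(np.mean(x > v)) for k, v in thresholds.items()} if thresholds else None,
        n_nonfinite=n_nonfinite,
    )


def propagate(
    specs: Mapping[str, DistributionSpec],
    func: Callable[[str, np.ndarray], np.ndarray],
    config: RunConfig,
    scheme: ClassificationScheme | None = None,
    return_draws: bool = False,
):
    """Propagate sampled inputs through a deterministic index function.

    For every key in ``specs``, ``config.iterations`` draws are taken from
    its spec (each key gets an independent stream derived from
    ``config.seed``, keyed by sorted position, so results do not depend on
    mapping order) and ``func(key, draws)`` is evaluated elementwise.

    Non-finite outputs are excluded with a logged count; if more than 1% of
    draws are non-finite the propagation fails hard.

    Returns a dict key -> MCSummary, plus ``(input_draws, output_draws)``
    dicts when ``return_draws`` is set.
    """
    keys = list(specs)
    streams = dict(zip(sorted(keys), np.random.SeedSequence(config.seed).spawn(len(keys))))
    summaries: dict[str, MCSummary] = {}
    in_draws: dict[str, np.ndarray] = {}
    out_draws: dict[str, np.ndarray] = {}
    for key in keys:
        rng = np.random.default_rng(streams[key])
        x = sample(specs[key], config.iterations, rng)
        y = np.asarray(func(key, x), dtype=float)
        finite = np.isfinite(y)
        n_bad = int((~finite).sum())
        if n_bad > MAX_NONFINITE_FRACTION * y.size:
            raise MCError(f"{key}: {n_bad}/{y.size} non-finite draws exceeds the {MAX_NONFINITE_FRACTION:.0%} limit")
        if n_bad:
            log.warning("%s: excluded %d non-finite draws", key, n_bad)
        summaries[key] = summarize(y[finite], key, seed=config.seed, scheme=scheme, n_nonfinite=n_bad)
        if return_draws:
            in_draws[key] = x
            out_draws[key] = y[finite]
    if return_draws:
        return summaries, in_draws, out_draws
    return summaries
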