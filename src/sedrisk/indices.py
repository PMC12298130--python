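"""Deterministic sediment pollution and ecological-risk indices.

Implements the geo-accumulation index I_geo, the enrichment factor EF
against a conservative reference element, the contamination factor C_f, the
single-element potential ecological risk index E_i, and the composite risk
index RI, together with their interval classification schemes.

The E_i index is exposed in two modes. ``paper`` mode follows the formula
used by the source study, E_i = Tr / C_f = Tr · background / c, which
inverts the conventional concentration dependence; ``standard`` mode is the
classical Hakanson product Tr · C_f. The two are reciprocal up to Tr², i.e.
paper(c) · standard(c) = Tr² for every concentration.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClassificationScheme",
    "IGEO_SCHEME",
    "EF_SCHEME",
    "RI_SCHEME",
    "igeo",
    "classify",
    "enrichment_factor",
    "contamination_factor",
    "single_ecological_risk",
    "risk_index",
    "summary_stats",
    "DEFAULT_RI_ELEMENTS",
]

#: Element subset summed into RI by default (the composite index as reported
#: excludes Mn and Ni).
DEFAULT_RI_ELEMENTS = ("As", "Cd", "Cr", "Cu", "Pb", "Zn")

EI_MODES = ("paper", "standard")


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered breakpoints with left-open right-closed intervals.

    ``labels`` has one more entry than ``breakpoints``: value v falls in
    category i where breakpoints[i-1] < v <= breakpoints[i].
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one label per interval")
        if any(b >= a for a, b in zip(self.breakpoints[1:], self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")

    def classify(self, value: float) -> str:
        return self.labels[bisect_left(self.breakpoints, value)]

    def classify_many(self, values) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, np.asarray(values, dtype=float), side="left")
        return np.asarray(self.labels, dtype=object)[idx]


IGEO_SCHEME = ClassificationScheme(
    "Igeo",
    (0.0, 1.0, 2.0, 3.0, 4.0),
    ("Uncontaminated", "Slightly", "Moderately", "Moderately/Heavily", "Heavily", "Extremely"),
)

EF_SCHEME = ClassificationScheme(
    "EF",
    (1.0, 2.0, 5.0, 20.0, 40.0),
    ("Uncontaminated", "Slightly", "Moderately", "Moderately/Heavily", "Heavily", "Extremely"),
)

RI_SCHEME = ClassificationScheme(
    "RI",
    (150.0, 300.0, 600.0, 1200.0),
    ("Slight risk", "Moderate risk", "Higher risk", "High risk", "Extremely high risk"),
)

SCHEMES = {"Igeo": IGEO_SCHEME, "EF": EF_SCHEME, "RI": RI_SCHEME}


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value, dtype=float) <= 0):
            raise ValueError(f"{name} must be strictly positive")


def igeo(c, background):
    """Geo-accumulation index log2(c / (1.5 · background)).

    The factor 1.5 absorbs lithogenic variability of the background. Accepts
    scalars or arrays (broadcast); all inputs must be strictly positive.
    """
    _require_positive(c=c, background=background)
    out = np.log2(np.asarray(c, dtype=float) / (1.5 * np.asarray(background, dtype=float)))
    return float(out) if out.ndim == 0 else out


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Category label of ``value`` under a left-open right-closed scheme."""
    return scheme.classify(float(value))


def enrichment_factor(c_i, c_ref, bg_i, bg_ref):
    """EF = (c_i / c_ref)_sample / (bg_i / bg_ref)_background.

    Invariant under common rescaling of the sample columns (units cancel).
    """
    _require_positive(c_i=c_i, c_ref=c_ref, bg_i=bg_i, bg_ref=bg_ref)
    out = (np.asarray(c_i, dtype=float) / np.asarray(c_ref, dtype=float)) / (
        np.asarray(bg_i, dtype=float) / np.asarray(bg_ref, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


def contamination_factor(c, background):
    """Contamination factor C_f = c / background."""
    _require_positive(c=c, background=background)
    out = np.asarray(c, dtype=float) / np.asarray(background, dtype=float)
    return float(out) if out.ndim == 0 else out


def single_ecological_risk(c, background, tf, mode: str = "paper"):
    """Single-element potential ecological risk index E_i.

    ``paper`` mode: Tr / C_f = tf · background / c (as used by the source
    study); ``standard`` mode: the conventional Hakanson product tf · c /
    background.
    """
    if mode not in EI_MODES:
        raise ValueError(f"unknown E_i mode {mode!r}; expected one of {EI_MODES}")
    _require_positive(c=c, background=background, tf=tf)
    cf = np.asarray(c, dtype=float) / np.asarray(background, dtype=float)
    tf = np.asarray(tf, dtype=float)
    out = tf / cf if mode == "paper" else tf * cf
    return float(out) if out.ndim == 0 else out


def risk_index(ei_values: Mapping[str, float], elements: Sequence[str] | None = None) -> float:
    """Composite potential ecological risk RI = Σ E_i over an element subset."""
    if elements is None:
        elements = DEFAULT_RI_ELEMENTS
    missing = [e for e in elements if e not in ei_values]
    if missing:
        raise KeyError(f"missing E_i values for elements: {', '.join(missing)}")
    # exact summation keeps RI invariant to element order
    return math.fsum(float(ei_values[e]) for e in elements)


def summary_stats(values: Sequence[float]) -> dict[str, float]:
    """Min/max/median/mean/sd/CV% of a sample; sd uses the n-1 denominator."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("summary_stats needs at least 2 values")
    mean = float(np.mean(x))
    # a constant sample has exactly zero spread; avoid fp cancellation noise
    sd = 0.0 if np.ptp(x) == 0.0 else float(np.std(x, ddof=1))
    return {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
        "mean": mean,
        "sd": sd,
        "cv_percent": 100.0 * sd / mean if mean != 0 else float("nan"),
    }
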