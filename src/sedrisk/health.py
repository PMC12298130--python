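"""USEPA-style human health risk from sediment heavy metals.

Chronic daily doses (CDD, mg/(kg·day)) via incidental ingestion and dermal
contact, hazard quotients/indices (HQ, HI = Σ HQ) against reference doses,
and carcinogenic risk (CR = CDD · SF, TCR = Σ CR) for three population
groups. Both point-estimate and probabilistic (Monte Carlo) modes are
provided; the respiratory pathway is out of scope.

Conventions:

- Non-carcinogenic averaging time is AT = 365·ED days, so ED cancels out of
  non-carcinogenic doses; carcinogenic AT is 365·70 days for every group.
- Skin surface area SA is configured in m² and converted to cm² (×10⁴)
  internally, matching the mg/(cm²·day) units of the adherence factor AF.
- Elements without an RfD or SF for a pathway are skipped with a logged
  notice — "pathway not evaluated", never imputed as zero.
- Point-estimate mode collapses each exposure distribution to its nominal
  value: the mode of a triangular spec, the mean of a lognormal spec, the
  value of a point spec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .distributions import DistributionSpec, sample
from .mc import MCSummary, summarize

__all__ = [
    "GROUPS",
    "PATHWAYS",
    "ExposureProfile",
    "ElementToxicity",
    "ToxicityTable",
    "HazardResult",
    "CancerRiskResult",
    "point_estimate",
    "cdd_ingestion",
    "cdd_dermal",
    "hazard",
    "cancer_risk",
    "probabilistic_health_risk",
    "classify_cancer_risk",
]

log = logging.getLogger(__name__)

GROUPS = ("adult_male", "adult_female", "child")
PATHWAYS = ("ingestion", "dermal")

#: CR below this level is considered negligible; above the upper level,
#: unacceptable; the band in between is the acceptable range.
CR_NEGLIGIBLE = 1e-6
CR_UNACCEPTABLE = 1e-4

_M2_TO_CM2 = 1e4
_LIFETIME_YEARS = 70.0


@dataclass(frozen=True)
class ExposureProfile:
    """One population group's exposure parameters.

    ``ir_ing`` (mg/day), ``ed`` (years) and ``cf`` (kg/mg) are point values;
    ``ef`` (days/year), ``bw`` (kg), ``sa`` (m²) and ``af`` (mg/(cm²·day))
    are distribution specs so the probabilistic mode can sample them.
    """

    group: str
    ir_ing: float
    ed: float
    ef: DistributionSpec
    bw: DistributionSpec
    sa: DistributionSpec
    af: DistributionSpec
    cf: float = 1e-6

    def __post_init__(self) -> None:
        if self.ir_ing <= 0 or self.ed <= 0 or self.cf <= 0:
            raise ValueError("IR, ED and CF must be strictly positive")

    @property
    def at_noncarc(self) -> float:
        """Averaging time for non-carcinogenic risk, days."""
        return 365.0 * self.ed

    @property
    def at_carc(self) -> float:
        """Averaging time for carcinogenic risk, days (70-year lifetime)."""
        return 365.0 * _LIFETIME_YEARS


@dataclass(frozen=True)
class ElementToxicity:
    """Per-element toxicological constants; absent entries mean the
    element-pathway combination is not evaluated."""

    rfd_ing: float | None = None
    rfd_derm: float | None = None
    sf_ing: float | None = None
    sf_derm: float | None = None
    abs_frac: float | None = None

    def rfd(self, pathway: str) -> float | None:
        return self.rfd_ing if pathway == "ingestion" else self.rfd_derm

    def sf(self, pathway: str) -> float | None:
        return self.sf_ing if pathway == "ingestion" else self.sf_derm


class ToxicityTable(dict):
    """Mapping element -> ElementToxicity."""


def point_estimate(spec: DistributionSpec) -> float:
    """Nominal single value of an exposure spec (triangular mode, lognormal
    or other-family mean, point value)."""
    if spec.family == "point":
        return spec.params[0]
    if spec.family == "triangular":
        return spec.params[1]
    return spec.mean()


def _at(profile: ExposureProfile, carcinogenic: bool) -> float:
    return profile.at_carc if carcinogenic else profile.at_noncarc


def cdd_ingestion(c, profile: ExposureProfile, carcinogenic: bool = False, *, ef=None, bw=None):
    """CDD_ing = c · IR_ing · ED · EF · CF / (BW · AT), mg/(kg·day).

    ``ef``/``bw`` default to the profile's point estimates; pass arrays of
    sampled values for the probabilistic mode. With AT = 365·ED the
    non-carcinogenic dose is independent of ED.
    """
    ef = point_estimate(profile.ef) if ef is None else ef
    bw = point_estimate(profile.bw) if bw is None else bw
    c = np.asarray(c, dtype=float)
    out = c * profile.ir_ing * profile.ed * np.asarray(ef, dtype=float) * profile.cf / (
        np.asarray(bw, dtype=float) * _at(profile, carcinogenic)
    )
    return float(out) if np.ndim(out) == 0 else out


def cdd_dermal(
    c,
    profile: ExposureProfile,
    abs_frac: float,
    carcinogenic: bool = False,
    *,
    ef=None,
    bw=None,
    sa=None,
    af=None,
):
    """CDD_derm = c · SA · AF · ABS · ED · EF · CF / (BW · AT), mg/(kg·day).

    SA is held in m² and converted to cm² here.
    """
    ef = point_estimate(profile.ef) if ef is None else ef
    bw = point_estimate(profile.bw) if bw is None else bw
    sa = point_estimate(profile.sa) if sa is None else sa
    af = point_estimate(profile.af) if af is None else af
    c = np.asarray(c, dtype=float)
    out = (
        c
        * np.asarray(sa, dtype=float)
        * _M2_TO_CM2
        * np.asarray(af, dtype=float)
        * abs_frac
        * profile.ed
        * np.asarray(ef, dtype=float)
        * profile.cf
        / (np.asarray(bw, dtype=float) * _at(profile, carcinogenic))
    )
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class HazardResult:
    """Per element-pathway HQ table plus the HI aggregate per pathway."""

    group: str
    table: pd.DataFrame  # columns: group, pathway, element, cdd, hq
    hi: dict[str, float]

    def exceeds(self, pathway: str) -> bool:
        return self.hi[pathway] > 1.0


@dataclass(frozen=True)
class CancerRiskResult:
    """Per element-pathway CR table plus the TCR aggregate per pathway."""

    group: str
    table: pd.DataFrame  # columns: group, pathway, element, cdd, cr, category
    tcr: dict[str, float]


def classify_cancer_risk(cr: float) -> str:
    if cr < CR_NEGLIGIBLE:
        return "no carcinogenic risk"
    if cr < CR_UNACCEPTABLE:
        return "acceptable"
    return "unacceptable"


def hazard(
    concentrations: Mapping[str, float],
    profile: ExposureProfile,
    tox: Mapping[str, ElementToxicity],
    elements: Sequence[str] | None = None,
) -> HazardResult:
    """Point-estimate non-carcinogenic risk: HQ per element-pathway, HI = Σ HQ."""
    elements = list(concentrations) if elements is None else list(elements)
    rows = []
    for pathway in PATHWAYS:
        for el in elements:
            t = tox.get(el)
            rfd = t.rfd(pathway) if t is not None else None
            if rfd is None or (pathway == "dermal" and t.abs_frac is None):
                log.info("HQ skipped for %s/%s: pathway not evaluated", el, pathway)
                continue
            if pathway == "ingestion":
                dose = cdd_ingestion(concentrations[el], profile)
            else:
                dose = cdd_dermal(concentrations[el], profile, t.abs_frac)
            rows.append((profile.group, pathway, el, dose, dose / rfd))
    table = pd.DataFrame(rows, columns=["group", "pathway", "element", "cdd", "hq"])
    hi = {p: float(table.loc[table.pathway == p, "hq"].sum()) for p in PATHWAYS}
    return HazardResult(profile.group, table, hi)


def cancer_risk(
    concentrations: Mapping[str, float],
    profile: ExposureProfile,
    tox: Mapping[str, ElementToxicity],
    elements: Sequence[str] | None = None,
) -> CancerRiskResult:
    """Point-estimate carcinogenic risk: CR per element-pathway, TCR = Σ CR.

    Elements lacking a slope factor for a pathway are excluded from that
    pathway's TCR with a logged notice.
    """
    elements = list(concentrations) if elements is None else list(elements)
    rows = []
    for pathway in PATHWAYS:
        for el in elements:
            t = tox.get(el)
            sf = t.sf(pathway) if t is not None else None
            if sf is None or (pathway == "dermal" and t.abs_frac is None):
                log.info("CR skipped for %s/%s: no slope factor", el, pathway)
                continue
            if pathway == "ingestion":
                dose = cdd_ingestion(concentrations[el], profile, carcinogenic=True)
            else:
                dose = cdd_dermal(concentrations[el], profile, t.abs_frac, carcinogenic=True)
            cr = dose * sf
            rows.append((profile.group, pathway, el, dose, cr, classify_cancer_risk(cr)))
    table = pd.DataFrame(rows, columns=["group", "pathway", "element", "cdd", "cr", "category"])
    tcr = {p: float(table.loc[table.pathway == p, "cr"].sum()) for p in PATHWAYS}
    return CancerRiskResult(profile.group, table, tcr)


def probabilistic_health_risk(
    conc_specs: Mapping[str, DistributionSpec],
    profile: ExposureProfile,
    tox: Mapping[str, ElementToxicity],
    config: RunConfig,
    return_draws: bool = False,
):
    """Joint Monte Carlo of concentrations and exposure parameters.

    Exposure parameter draws (EF, BW, SA, AF) are shared across elements
    within an iteration — one simulated individual per draw — while element
    concentrations are sampled independently. Returns a dict with MCSummary
    entries for per-pathway HI and TCR (with exceedance fractions at HI > 1
    and CR > 1e-6 / 1e-4) and per element-pathway HQ and CR summaries.

    With ``return_draws``, also returns (input_draws, output_draws) dicts
    keyed by parameter/quantity name, for sensitivity analysis.
    """
    n = config.iterations
    root = np.random.SeedSequence(config.seed)
    exp_seq, conc_seq = root.spawn(2)
    ef_s, bw_s, sa_s, af_s = exp_seq.spawn(4)
    ef_d = sample(profile.ef, n, np.random.default_rng(ef_s))
    bw_d = sample(profile.bw, n, np.random.default_rng(bw_s))
    sa_d = sample(profile.sa, n, np.random.default_rng(sa_s))
    af_d = sample(profile.af, n, np.random.default_rng(af_s))

    elements = sorted(conc_specs)
    conc_draws = {
        el: sample(conc_specs[el], n, np.random.default_rng(s))
        for el, s in zip(elements, conc_seq.spawn(len(elements)))
    }

    summaries: dict[str, MCSummary] = {}
    outputs: dict[str, np.ndarray] = {}
    for pathway in PATHWAYS:
        hi_draws = np.zeros(n)
        tcr_draws = np.zeros(n)
        any_sf = False
        for el in elements:
            t = tox.get(el)
            if t is None:
                continue
            rfd, sf = t.rfd(pathway), t.sf(pathway)
            kw = dict(ef=ef_d, bw=bw_d)
            if pathway == "ingestion":
                dose_nc = cdd_ingestion(conc_draws[el], profile, **kw)
                dose_c = cdd_ingestion(conc_draws[el], profile, carcinogenic=True, **kw)
            else:
                if t.abs_frac is None:
                    continue
                kw.update(sa=sa_d, af=af_d)
                dose_nc = cdd_dermal(conc_draws[el], profile, t.abs_frac, **kw)
                dose_c = cdd_dermal(conc_draws[el], profile, t.abs_frac, carcinogenic=True, **kw)
            if rfd is not None:
                hq = dose_nc / rfd
                hi_draws += hq
                summaries[f"hq_{pathway}_{el}"] = summarize(
                    hq, f"hq_{pathway}_{el}", seed=config.seed, thresholds={"hq>1": 1.0}
                )
            if sf is not None:
                cr = dose_c * sf
                tcr_draws += cr
                any_sf = True
                summaries[f"cr_{pathway}_{el}"] = summarize(
                    cr, f"cr_{pathway}_{el}", seed=config.seed,
                    thresholds={"cr>1e-6": CR_NEGLIGIBLE, "cr>1e-4": CR_UNACCEPTABLE},
                )
        summaries[f"hi_{pathway}"] = summarize(
            hi_draws, f"hi_{pathway}", seed=config.seed, thresholds={"hi>1": 1.0}
        )
        outputs[f"hi_{pathway}"] = hi_draws
        if any_sf:
            summaries[f"tcr_{pathway}"] = summarize(
                tcr_draws, f"tcr_{pathway}", seed=config.seed,
                thresholds={"tcr>1e-6": CR_NEGLIGIBLE, "tcr>1e-4": CR_UNACCEPTABLE},
            )
            outputs[f"tcr_{pathway}"] = tcr_draws

    if return_draws:
        inputs = {"EF": ef_d, "BW": bw_d, "SA": sa_d, "AF": af_d}
        inputs.update({f"C_{el}": d for el, d in conc_draws.items()})
        return summaries, inputs, outputs
    return summaries
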