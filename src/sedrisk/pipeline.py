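"""High-level drivers combining the index, distribution and MC modules.

These functions are the substance behind the CLI subcommands and the
reproduction scripts: deterministic per-site index tables, Monte Carlo
index/risk summaries driven by the fitted concentration families, and
contribution-to-variance sensitivity reports.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import indices
from .config import RunConfig
from .distributions import DistributionSpec
from .health import probabilistic_health_risk
from .mc import MCSummary, propagate, summarize
from .params import Params
from .sensitivity import SensitivityReport, contribution_to_variance
from .synthetic import concentration_spec

__all__ = [
    "site_indices",
    "mean_indices",
    "mc_concentration_specs",
    "mc_igeo",
    "mc_enrichment_factor",
    "mc_ecological_risk",
    "ri_sensitivity",
    "health_sensitivity",
]


def site_indices(samples: pd.DataFrame, params: Params, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-site, per-element index table in long format.

    Columns: site_id, element, index_name, value, category. EF rows are
    emitted only when the reference-element column is present.
    """
    config = config or RunConfig()
    ref = params.reference_element
    have_ref = ref in samples.columns
    elements = [e for e in params.elements if e in samples.columns]
    rows = []
    for el in elements:
        c = samples[el].to_numpy()
        bg = params.background[el]
        ig = indices.igeo(c, bg)
        cf = indices.contamination_factor(c, bg)
        ei = indices.single_ecological_risk(c, bg, params.toxicity_factor[el], mode=config.ei_mode)
        per_site = {"Igeo": ig, "Cf": cf, "Ei": ei}
        if have_ref:
            per_site["EF"] = indices.enrichment_factor(c, samples[ref].to_numpy(), bg, params.background[ref])
        for name, values in per_site.items():
            scheme = indices.SCHEMES.get(name)
            for site, v in zip(samples.index, values):
                rows.append(
                    (site, el, name, float(v), scheme.classify(float(v)) if scheme else "")
                )
    return pd.DataFrame(rows, columns=["site_id", "element", "index_name", "value", "category"])


def mean_indices(site_table: pd.DataFrame) -> pd.DataFrame:
    """Per-element means of the site-level indices, with categories."""
    g = site_table.groupby(["element", "index_name"], sort=True)["value"].mean().reset_index()
    g["category"] = [
        indices.SCHEMES[n].classify(v) if n in indices.SCHEMES else ""
        for n, v in zip(g.index_name, g.value)
    ]
    return g


def mc_concentration_specs(params: Params) -> dict[str, DistributionSpec]:
    """Fitted concentration specs (truncated at zero) for the MC pipelines."""
    return {el: concentration_spec(t, truncate=False) for el, t in params.concentration_summary.items()}


def mc_igeo(params: Params, config: RunConfig) -> dict[str, MCSummary]:
    """Monte Carlo geo-accumulation index per element, with category
    probabilities under the I_geo scheme."""
    specs = mc_concentration_specs(params)
    return propagate(
        specs,
        lambda el, c: indices.igeo(c, params.background[el]),
        config,
        scheme=indices.IGEO_SCHEME,
    )


def mc_enrichment_factor(params: Params, config: RunConfig) -> dict[str, MCSummary]:
    """Monte Carlo enrichment factor per element.

    The reference-element concentration is held at background times the
    configured enrichment ratio (no measured reference data).
    """
    specs = mc_concentration_specs(params)
    ref_bg = params.background[params.reference_element]
    c_ref = ref_bg * params.al_enrichment_ratio
    return propagate(
        specs,
        lambda el, c: indices.enrichment_factor(c, c_ref, params.background[el], ref_bg),
        config,
        scheme=indices.EF_SCHEME,
    )


def mc_ecological_risk(
    params: Params, config: RunConfig, return_draws: bool = False
):
    """Monte Carlo single-element risk E_i per element plus the composite RI.

    RI draws are the iteration-wise sum of the per-element E_i draws over
    ``config.ri_elements``; its summary is keyed ``"RI"`` and classified
    under the RI scheme.
    """
    specs = mc_concentration_specs(params)
    summaries, in_draws, out_draws = propagate(
        specs,
        lambda el, c: indices.single_ecological_risk(
            c, params.background[el], params.toxicity_factor[el], mode=config.ei_mode
        ),
        config,
        return_draws=True,
    )
    missing = [el for el in config.ri_elements if el not in out_draws]
    if missing:
        raise KeyError(f"RI subset needs E_i draws for: {', '.join(missing)}")
    ri_draws = np.sum([out_draws[el] for el in config.ri_elements], axis=0)
    summaries["RI"] = summarize(ri_draws, "RI", seed=config.seed, scheme=indices.RI_SCHEME)
    if return_draws:
        out_draws["RI"] = ri_draws
        return summaries, in_draws, out_draws
    return summaries


def ri_sensitivity(params: Params, config: RunConfig) -> SensitivityReport:
    """Contribution of each element's concentration to the composite RI."""
    _, in_draws, out_draws = mc_ecological_risk(params, config, return_draws=True)
    inputs = {el: in_draws[el] for el in config.ri_elements}
    return contribution_to_variance(inputs, out_draws["RI"], output_name="RI", seed=config.seed)


def health_sensitivity(
    params: Params, config: RunConfig, group: str, output: str = "hi_ingestion"
) -> SensitivityReport:
    """Contribution of exposure parameters and concentrations to a health
    risk output (``hi_ingestion``, ``hi_dermal``, ``tcr_ingestion``, ...)."""
    profile = params.exposure_profiles[group]
    _, inputs, outputs = probabilistic_health_risk(
        mc_concentration_specs(params), profile, params.toxicity, config, return_draws=True
    )
    if output not in outputs:
        raise KeyError(f"unknown output {output!r}; available: {sorted(outputs)}")
    return contribution_to_variance(inputs, outputs[output], output_name=f"{group}:{output}", seed=config.seed)
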