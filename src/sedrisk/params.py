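"""Parameter tables: backgrounds, toxicity factors, RfD/SF/ABS, exposure
profiles, and observed concentration summaries, with YAML/JSON loading.

The packaged default parameter file carries the Dongting-basin background
values, Hakanson toxicity factors, USEPA toxicological constants and the
per-group exposure distributions used throughout the pipeline; any value
can be overridden by pointing the loaders at a user file of the same shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .distributions import DistributionSpec
from .health import ElementToxicity, ExposureProfile, ToxicityTable
from .indices import DEFAULT_RI_ELEMENTS

__all__ = [
    "ELEMENTS",
    "REFERENCE_ELEMENT",
    "ElementTarget",
    "Params",
    "ValidationError",
    "read_params",
    "load_default_params",
]

#: Closed-by-default element registry: the eight assessed metals plus the
#: conservative reference element. Extensible via the params file.
ELEMENTS = ("As", "Cd", "Cr", "Cu", "Mn", "Ni", "Pb", "Zn")
REFERENCE_ELEMENT = "Al"

_REQUIRED_SECTIONS = ("background", "toxicity_factor", "rfd", "sf", "abs", "exposure_profiles")


class ValidationError(ValueError):
    """A parameter or sample file failed validation."""


@dataclass(frozen=True)
class ElementTarget:
    """Observed summary of one element's concentrations: best-fit family,
    sample mean/sd and the observed extremes (all mg/kg)."""

    family: str
    mean: float
    sd: float
    min: float
    max: float
    median: float | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValidationError(f"mean {self.mean} outside observed range [{self.min}, {self.max}]")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")


@dataclass(frozen=True)
class Params:
    """Everything the pipeline needs besides the per-site sample table."""

    elements: tuple[str, ...]
    background: dict[str, float]
    toxicity_factor: dict[str, float]
    toxicity: ToxicityTable
    exposure_profiles: dict[str, ExposureProfile]
    concentration_summary: dict[str, ElementTarget]
    al_enrichment_ratio: float
    ri_elements: tuple[str, ...] = DEFAULT_RI_ELEMENTS
    reference_element: str = REFERENCE_ELEMENT
    n_samples: int = 15


def _parse_spec(value) -> DistributionSpec:
    if isinstance(value, Mapping):
        return DistributionSpec.from_dict(value)
    return DistributionSpec("point", (float(value),))


def _parse_profile(group: str, d: Mapping) -> ExposureProfile:
    try:
        return ExposureProfile(
            group=group,
            ir_ing=float(d["ir_ing"]),
            ed=float(d["ed"]),
            ef=_parse_spec(d["ef"]),
            bw=_parse_spec(d["bw"]),
            sa=_parse_spec(d["sa"]),
            af=_parse_spec(d["af"]),
            cf=float(d.get("cf", 1e-6)),
        )
    except KeyError as exc:
        raise ValidationError(f"exposure profile {group!r} is missing {exc}") from None


def _parse(raw: Mapping, source: str) -> Params:
    for section in _REQUIRED_SECTIONS:
        if section not in raw:
            raise ValidationError(f"{source}: missing required section {section!r}")
    elements = tuple(raw.get("elements", ELEMENTS))
    background = {k: float(v) for k, v in raw["background"].items()}
    for el, v in background.items():
        if v <= 0:
            raise ValidationError(f"{source}: background[{el}] must be > 0, got {v}")
    tf = {k: float(v) for k, v in raw["toxicity_factor"].items()}
    for el in elements:
        if el not in background:
            raise ValidationError(f"{source}: element {el} has no background value")
        if el not in tf:
            raise ValidationError(f"{source}: element {el} has no toxicity factor")
        if tf[el] <= 0:
            raise ValidationError(f"{source}: toxicity_factor[{el}] must be > 0")

    rfd, sf, abs_ = raw["rfd"], raw["sf"], raw["abs"]
    for pathway in ("ingestion", "dermal"):
        for el, v in rfd.get(pathway, {}).items():
            if v is not None and float(v) <= 0:
                raise ValidationError(f"{source}: rfd.{pathway}[{el}] must be positive, got {v}")
    tox_elements = set(elements) | set(rfd.get("ingestion", {})) | set(sf.get("ingestion", {}))

    def _get(table: Mapping, pathway: str, el: str) -> float | None:
        v = table.get(pathway, {}).get(el)
        return None if v is None else float(v)

    toxicity = ToxicityTable(
        {
            el: ElementToxicity(
                rfd_ing=_get(rfd, "ingestion", el),
                rfd_derm=_get(rfd, "dermal", el),
                sf_ing=_get(sf, "ingestion", el),
                sf_derm=_get(sf, "dermal", el),
                abs_frac=None if abs_.get(el) is None else float(abs_[el]),
            )
            for el in sorted(tox_elements)
        }
    )

    profiles = {g: _parse_profile(g, d) for g, d in raw["exposure_profiles"].items()}

    summary = {
        el: ElementTarget(
            family=d["family"],
            mean=float(d["mean"]),
            sd=float(d["sd"]),
            min=float(d["min"]),
            max=float(d["max"]),
            median=None if d.get("median") is None else float(d["median"]),
        )
        for el, d in raw.get("concentration_summary", {}).items()
    }

    return Params(
        elements=elements,
        background=background,
        toxicity_factor=tf,
        toxicity=toxicity,
        exposure_profiles=profiles,
        concentration_summary=summary,
        al_enrichment_ratio=float(raw.get("al_enrichment_ratio", 1.0)),
        ri_elements=tuple(raw.get("ri_elements", DEFAULT_RI_ELEMENTS)),
        reference_element=str(raw.get("reference_element", REFERENCE_ELEMENT)),
        n_samples=int(raw.get("n_samples", 15)),
    )


def read_params(path) -> Params:
    """Load and validate a YAML or JSON parameter file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: expected a mapping at the top level")
    return _parse(raw, str(path))


def load_default_params() -> Params:
    """The packaged default parameter set."""
    text = resources.files("sedrisk").joinpath("data/default_params.yaml").read_text()
    return _parse(yaml.safe_load(text), "default_params.yaml")
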