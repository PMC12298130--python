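"""Run configuration shared by the Monte Carlo pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .indices import DEFAULT_RI_ELEMENTS, EI_MODES

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a Monte Carlo run.

    iterations: number of random draws per input (default 10,000).
    seed: master seed; all per-input streams derive from it.
    confidence_level: central band width reported alongside percentiles.
    ei_mode: 'paper' (Tr/C_f) or 'standard' (Tr·C_f) single-risk formula.
    ri_elements: element subset summed into the composite RI.
    reference_element: conservative reference element for the EF.
    """

    iterations: int = 10_000
    seed: int = 2025
    confidence_level: float = 0.95
    ei_mode: str = "paper"
    ri_elements: tuple[str, ...] = DEFAULT_RI_ELEMENTS
    reference_element: str = "Al"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError("confidence_level must lie in (0, 1)")
        if self.ei_mode not in EI_MODES:
            raise ValueError(f"ei_mode must be one of {EI_MODES}")
        object.__setattr__(self, "ri_elements", tuple(self.ri_elements))
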