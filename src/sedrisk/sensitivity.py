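"""Contribution-to-variance sensitivity of Monte Carlo outputs.

The contribution of input j to an output is the signed, normalized squared
rank correlation

    contribution_j = sign(rho_j) * 100 * rho_j**2 / sum_k rho_k**2

with rho the Spearman coefficient between the input and output draw
vectors. The absolute contributions sum to 100%; rank correlation makes
the measure invariant to strictly monotone transforms of any input. A
Pearson (raw-value) variant is available via ``method``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SensitivityReport", "rank_correlation", "contribution_to_variance"]

log = logging.getLogger(__name__)


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("rank_correlation needs equal-length vectors of size >= 3")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class SensitivityReport:
    """Signed percentage contributions of inputs to one output."""

    output: str
    contributions: dict[str, float]
    iterations: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tornado-style table sorted by |contribution| descending."""
        df = pd.DataFrame(
            {"output": self.output, "input": list(self.contributions), "contribution_percent": list(self.contributions.values())}
        )
        return df.reindex(df.contribution_percent.abs().sort_values(ascending=False).index).reset_index(drop=True)


def contribution_to_variance(
    inputs: Mapping[str, np.ndarray],
    output,
    output_name: str = "output",
    method: str = "spearman",
    seed: int | None = None,
) -> SensitivityReport:
    """Signed, normalized squared correlation of each input with the output.

    Inputs with no variation (point specs) are excluded from the
    normalization. If every correlation is zero the contributions are
    reported as zeros with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    y = np.asarray(output, dtype=float)
    rhos: dict[str, float] = {}
    for name, x in inputs.items():
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"input {name!r} is not aligned with the output draws")
        if np.ptp(x) == 0.0:
            log.info("sensitivity input %s has no variation; excluded", name)
            continue
        if method == "spearman":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant output yields nan, handled below
                rho = float(stats.spearmanr(x, y).statistic)
        else:
            rho = float(np.corrcoef(x, y)[0, 1])
        rhos[name] = rho if np.isfinite(rho) else 0.0
    denom = sum(r * r for r in rhos.values())
    if denom == 0.0:
        warnings.warn("all input-output correlations are zero; contributions undefined, reporting zeros")
        contributions = {name: 0.0 for name in rhos}
    else:
        contributions = {name: float(np.sign(r)) * 100.0 * r * r / denom for name, r in rhos.items()}
    return SensitivityReport(output_name, contributions, iterations=int(y.size), seed=seed)
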