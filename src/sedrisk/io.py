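"""Sample-table CSV I/O with validation.

The exchange format is plain UTF-8 CSV with a mandatory header row: a
``site_id`` column followed by one column per element, concentrations in
mg/kg dry weight. Unknown element columns are kept with a warning so that
the toolkit generalizes beyond the default registry; non-positive or
non-numeric concentrations are rejected with the offending row and column
named.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ELEMENTS, REFERENCE_ELEMENT, ValidationError

__all__ = ["read_sample_table", "write_sample_table", "validate_sample_table"]

log = logging.getLogger(__name__)

_KNOWN = set(ELEMENTS) | {REFERENCE_ELEMENT}


def validate_sample_table(df: pd.DataFrame, source: str = "sample table") -> pd.DataFrame:
    """Validate a site × element concentration frame in place and return it."""
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValidationError(f"{source}: needs at least one site row and one element column")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate site_id values: {dup}")
    unknown = [c for c in df.columns if c not in _KNOWN]
    if unknown:
        log.warning("%s: columns outside the default element registry kept as-is: %s", source, unknown)
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values <= 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{source}: column {col!r}, row {row!r}: concentration must be a positive number, "
                f"got {df.loc[row, col]!r}"
            )
        df[col] = values.astype(float)
    return df


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a per-site concentration CSV.

    Returns a DataFrame indexed by ``site_id`` with float element columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "site_id":
        raise ValidationError(f"{path}: first column must be 'site_id', got {df.columns[0]!r}")
    df = df.set_index("site_id")
    return validate_sample_table(df, source=str(path))


def write_sample_table(df: pd.DataFrame, path) -> None:
    """Write a sample table; floats use shortest round-trip representation,
    so a read/write cycle is byte-stable."""
    out = df.copy()
    out.index.name = "site_id"
    out.to_csv(path)
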