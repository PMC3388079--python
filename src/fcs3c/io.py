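"""Delimited-text I/O for curves and band tables.

Curves are two- or three-column CSV with header ``lag_ms,G[,sd]``; band
tables carry the header
``condition,primer_pair,template_mass_ng,replicate,intensity``.
Numeric values are written at 17 significant digits, so a write/read
round trip is bit-exact for doubles. Header order is free; extra columns
are ignored on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .models import CorrelationCurve
from .threec import BAND_COLUMNS, validate_band_table

__all__ = ["read_curve", "write_curve", "read_bands", "write_bands"]


def write_curve(curve: CorrelationCurve, path: str | Path) -> None:
    """Write a curve as CSV (``lag_ms,G[,sd]``), 17 significant digits."""
    cols = {"lag_ms": curve.lags, "G": curve.values}
    if curve.sd is not None:
        cols["sd"] = curve.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_curve(path: str | Path) -> CorrelationCurve:
    """Read a curve written by :func:`write_curve` (any column order)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed file
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    for col in ("lag_ms", "G"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    try:
        return CorrelationCurve(
            df["lag_ms"].to_numpy(dtype=float),
            df["G"].to_numpy(dtype=float),
            sd=sd,
            meta={"source": str(path)},
        )
    except Exception as exc:
        raise SchemaError(f"{path}: invalid curve: {exc}") from exc


def write_bands(bands: pd.DataFrame, path: str | Path) -> None:
    """Write a validated band table as CSV, 17 significant digits."""
    validate_band_table(bands)
    bands.loc[:, list(BAND_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


def read_bands(path: str | Path) -> pd.DataFrame:
    """Read a band table, validating schema and invariants."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in BAND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df["template_mass_ng"] = df["template_mass_ng"].astype(float)
    df["intensity"] = df["intensity"].astype(float)
    try:
        return validate_band_table(df)
    except Exception as exc:
        raise SchemaError(f"{path}: invalid band table: {exc}") from exc
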