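"""Reading, validating, filtering and writing SMLM localization tables.

Tables are delimited text with a header; coordinates are standardized to
nm internally (the linking and precision thresholds are stated in nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "precision_nm")
OPTIONAL_COLUMNS = ("z_nm", "intensity", "molecule_id")

__all__ = [
    "LocalizationTable",
    "read_localizations",
    "write_localizations",
    "filter_precision",
    "PrecisionFilter",
]


@dataclass
class LocalizationTable:
    """Ordered collection of localizations with provenance.

    ``df`` columns: frame (0-based int), x_nm, y_nm, optional z_nm,
    precision_nm, optional intensity and ground-truth molecule_id.
    Rows are kept sorted by (frame, x_nm); the provenance log is
    append-only.
    """

    df: pd.DataFrame
    provenance: List[str] = field(default_factory=list)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "LocalizationTable":
        df = self.df.sort_values(["frame", "x_nm"], kind="mergesort").reset_index(drop=True)
        return LocalizationTable(df=df, provenance=list(self.provenance), n_dropped=self.n_dropped)

    def write(self, path) -> None:
        write_localizations(self, path)


def read_localizations(
    path,
    dialect: str = "simulator",
    column_map: Optional[Dict[str, str]] = None,
    sep: Optional[str] = None,
) -> LocalizationTable:
    """Read a localization table from delimited text.

    ``dialect`` is ``"simulator"`` for tables written by this package and
    ``"generic"`` for third-party localizer output, in which case
    ``column_map`` maps input column names onto the canonical ones
    (frame, x_nm, y_nm, z_nm, precision_nm, intensity).  The delimiter is
    sniffed unless ``sep`` is given.  Rows with non-finite coordinates are
    dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("simulator", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty localization file")
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {', '.join(missing)}")
    if len(df) == 0:
        warnings.warn(f"{path}: no localizations")

    coord_cols = ["x_nm", "y_nm"] + (["z_nm"] if "z_nm" in df.columns else [])
    finite = np.ones(len(df), dtype=bool)
    for c in coord_cols:
        finite &= np.isfinite(df[c].to_numpy(dtype=float))
    n_dropped = int((~finite).sum())
    df = df[finite]
    df = df.astype({"frame": int})
    df = df.sort_values(["frame", "x_nm"], kind="mergesort").reset_index(drop=True)
    prov = [f"read: {path} (dialect={dialect}, dropped {n_dropped} non-finite rows)"]
    return LocalizationTable(df=df, provenance=prov, n_dropped=n_dropped)


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table as comma-delimited text with header."""
    table.df.to_csv(path, index=False)


def filter_precision(table: LocalizationTable, max_precision_nm: float) -> LocalizationTable:
    """Keep localizations with precision strictly better than the threshold.

    "Better than 25 nm" is read literally: a row survives iff
    ``precision_nm < max_precision_nm``.  The threshold is recorded in the
    table's provenance.
    """
    if max_precision_nm <= 0:
        raise ValueError("max_precision_nm must be positive")
    keep = table.df["precision_nm"].to_numpy(dtype=float) < max_precision_nm
    df = table.df[keep].reset_index(drop=True)
    prov = list(table.provenance) + [f"filter_precision: < {max_precision_nm} nm, kept {len(df)}/{len(table)}"]
    return LocalizationTable(df=df, provenance=prov, n_dropped=table.n_dropped)


class PrecisionFilter(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`filter_precision` (stateless)."""

    def __init__(self, max_precision_nm: float = 25.0):
        self.max_precision_nm = max_precision_nm

    def fit(self, X: LocalizationTable, y=None):
        self.n_input_ = len(X)
        return self

    def transform(self, X: LocalizationTable) -> LocalizationTable:
        return filter_precision(X, self.max_precision_nm)
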