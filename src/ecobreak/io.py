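"""CSV ingestion for bivariate stress-response tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InvalidInputError, XYData

__all__ = ["read_xy_csv"]

logger = logging.getLogger(__name__)


def read_xy_csv(path, x_col: str, y_col: str, *,
                log10_x: bool = False, log10_y: bool = False) -> XYData:
    """Read an (x, y) table from CSV.

    Rows with missing values in either column are dropped (with a
    logged count).  Optional base-10 log transforms are applied to
    either column; nonpositive values under a log transform raise an
    error naming the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in (x_col, y_col):
        if col not in df.columns:
            raise InvalidInputError(
                f"column {col!r} not found in {path.name}; "
                f"available: {list(df.columns)}")
    sub = df[[x_col, y_col]].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d row(s) with missing values from %s",
                       dropped, path.name)
    sub = sub[keep]
    for col, flag in ((x_col, log10_x), (y_col, log10_y)):
        if flag:
            bad = sub.index[sub[col] <= 0].tolist()
            if bad:
                raise InvalidInputError(
                    f"log10 transform of {col!r} undefined for "
                    f"nonpositive values at rows {bad}")
            sub[col] = np.log10(sub[col])
    return XYData(sub[x_col].to_numpy(), sub[y_col].to_numpy())
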