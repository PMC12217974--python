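"""CSV reading/writing for timecourse datasets.

Dialect: comma-separated, UTF-8, header ``condition,time_min,product_nM,
sigma_nM``.  One dataset per condition label; the ``sigma_nM`` column may
be absent (the dataset is then unweighted and fitting warns).  Values are
written with 9 significant digits, which makes write-then-read lossless
at the stored precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TimecourseDataset

__all__ = ["ParseError", "read_timecourse_csv", "write_timecourse_csv"]

REQUIRED_COLUMNS = ("condition", "time_min", "product_nM")
SIGMA_COLUMN = "sigma_nM"


class ParseError(ValueError):
    """Malformed timecourse CSV; the message names the offending row."""


def write_timecourse_csv(datasets, path) -> None:
    """Write one or more datasets to a single CSV file."""
    if isinstance(datasets, TimecourseDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        frame = pd.DataFrame(
            {
                "condition": ds.condition,
                "time_min": ds.times,
                "product_nM": ds.product,
                SIGMA_COLUMN: ds.sigma if ds.sigma is not None else np.nan,
            }
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if out[SIGMA_COLUMN].isna().all():
        out = out.drop(columns=[SIGMA_COLUMN])
    out.to_csv(path, index=False, float_format="%.9g", encoding="utf-8")


def read_timecourse_csv(path) -> list[TimecourseDataset]:
    """Read a timecourse CSV into one dataset per condition label.

    Raises :class:`ParseError` for an empty file, missing required
    columns, non-numeric cells, or times that decrease within a
    condition (repeated times are allowed: replicate points).  A missing
    sigma column loads the data unweighted, with a warning.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, encoding="utf-8",
                          skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if raw.empty:
        raise ParseError(f"{path}: no data rows")

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    has_sigma = SIGMA_COLUMN in raw.columns
    if not has_sigma:
        warnings.warn(
            f"{path}: no {SIGMA_COLUMN} column; datasets will be unweighted",
            stacklevel=2,
        )

    numeric_cols = ["time_min", "product_nM"] + ([SIGMA_COLUMN] if has_sigma else [])
    numeric = {}
    for col in numeric_cols:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, after the header line
            raise ParseError(
                f"{path}: non-numeric value {raw[col][bad.idxmax()]!r} in "
                f"column {col!r} at line {row}"
            )
        numeric[col] = values.to_numpy(dtype=float)

    datasets = []
    conditions = raw["condition"].fillna("")
    for condition in conditions.unique():
        mask = (conditions == condition).to_numpy()
        idx = np.flatnonzero(mask)
        t = numeric["time_min"][mask]
        if np.any(np.isnan(t)) or np.any(np.isnan(numeric["product_nM"][mask])):
            row = int(idx[np.isnan(t).argmax()]) + 2
            raise ParseError(f"{path}: missing time/product value near line {row}")
        dec = np.flatnonzero(np.diff(t) < 0)
        if dec.size:
            row = int(idx[dec[0] + 1]) + 2
            raise ParseError(
                f"{path}: time decreases within condition {condition!r} at "
                f"line {row}"
            )
        sigma = None
        if has_sigma:
            s = numeric[SIGMA_COLUMN][mask]
            if not np.any(np.isnan(s)):
                sigma = s
        datasets.append(
            TimecourseDataset(
                condition=str(condition),
                times=t,
                product=numeric["product_nM"][mask],
                sigma=sigma,
            )
        )
    return datasets
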