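"""Cohort table I/O and validation.

The interchange format is CSV (UTF-8, '.' decimal): columns ``subject_id``,
``age`` and the 22 retained peak percentages ``GP1, GP2, GP4..GP19,
GP21..GP24``.  Columns for the excluded peaks GP3 (contaminated) and GP20
(unidentified structures) are tolerated on input but dropped with a warning;
peak sums outside the observed 96.5-99.9% range are warned about, never
rejected.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Union

import pandas as pd

from .network import PEAK_IDS
from .synth import COVERAGE_RANGE

__all__ = ["read_cohort", "write_cohort", "peak_columns"]

EXCLUDED_PEAKS = ("GP3", "GP20")


def peak_columns(df: pd.DataFrame) -> List[str]:
    """The 22 retained peak columns, in canonical order."""
    missing = [p for p in PEAK_IDS if p not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing peak columns: {missing}")
    return list(PEAK_IDS)


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Checks column presence, numeric and positive peak values, unique subject
    ids; drops GP3/GP20 with a warning and warns on peak sums outside the
    expected coverage range.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "age"):
        if col not in df.columns:
            raise ValueError(f"cohort file {path.name}: missing column {col!r}")
    dropped = [p for p in EXCLUDED_PEAKS if p in df.columns]
    if dropped:
        warnings.warn(f"{path.name}: excluded peaks present and dropped: "
                      f"{', '.join(dropped)}")
        df = df.drop(columns=dropped)
    cols = peak_columns(df)

    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r}")
    peaks = df[cols].apply(pd.to_numeric, errors="coerce")
    if peaks.isna().any().any():
        bad = peaks.columns[peaks.isna().any()][0]
        raise ValueError(f"non-numeric values in peak column {bad}")
    if (peaks <= 0).any().any():
        bad = peaks.columns[(peaks <= 0).any()][0]
        raise ValueError(f"non-positive values in peak column {bad}")
    df[cols] = peaks

    sums = peaks.sum(axis=1)
    lo, hi = COVERAGE_RANGE
    outside = (sums < lo - 1e-9) | (sums > hi + 1e-9)
    if outside.any():
        warnings.warn(
            f"{path.name}: {int(outside.sum())} subject(s) have peak sums "
            f"outside [{lo}, {hi}]% (range {sums.min():.1f}-{sums.max():.1f}%)")
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    path = Path(path)
    ordered = ["subject_id", "age"] + [c for c in PEAK_IDS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df[ordered + extra].to_csv(path, index=False)
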