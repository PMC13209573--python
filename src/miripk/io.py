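"""CSV interchange, validation and unit conversion.

Two table dialects cover the whole pipeline:

concentration table: ``subject_id, group, state, dose_mg_per_kg, time_min,
conc_mg_per_L, blq`` (state in {normal, miri}; blq 0/1)

effect table: ``group, time_min, ckmb_ng_per_mL``

Validation is strict and reports every offending row with its CSV line
number rather than stopping at the first problem.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reference import MOLECULAR_WEIGHT
from .synthetic_data import CONC_COLUMNS, EFFECT_COLUMNS

__all__ = [
    "TableValidationError",
    "read_concentration_table",
    "write_concentration_table",
    "read_effect_table",
    "write_effect_table",
    "conc_convert",
]


class TableValidationError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid table:\n" + "\n".join(problems))


def _validate_concentration(df: pd.DataFrame) -> None:
    problems: list[str] = []
    missing = [c for c in CONC_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError([f"missing columns: {', '.join(missing)}"])
    if df.empty:
        raise TableValidationError(["table has no data rows"])
    # +2: one for the header line, one for 0-based indexing
    for idx in df.index[df.conc_mg_per_L < 0]:
        problems.append(f"line {idx + 2}: negative concentration")
    for idx in df.index[df.time_min < 0]:
        problems.append(f"line {idx + 2}: negative time")
    for idx in df.index[~df.state.isin(["normal", "miri"])]:
        problems.append(f"line {idx + 2}: state must be 'normal' or 'miri'")
    for subject, sub in df.groupby("subject_id", sort=False):
        t = sub.time_min.to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        for b in bad:
            problems.append(
                f"line {sub.index[b + 1] + 2}: subject {subject} times "
                "not strictly ascending"
            )
        if sub.dose_mg_per_kg.nunique() > 1:
            problems.append(
                f"line {sub.index[0] + 2}: subject {subject} has varying dose"
            )
    if problems:
        raise TableValidationError(problems)


def read_concentration_table(path) -> pd.DataFrame:
    """Read and validate a long-format concentration table."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableValidationError(["file is empty"]) from None
    _validate_concentration(df)
    df = df.astype({"dose_mg_per_kg": float, "time_min": float,
                    "conc_mg_per_L": float, "blq": int})
    return df[CONC_COLUMNS]


def write_concentration_table(df: pd.DataFrame, path) -> None:
    df[CONC_COLUMNS].to_csv(path, index=False)


def read_effect_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableValidationError(["file is empty"]) from None
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError([f"missing columns: {', '.join(missing)}"])
    problems = [f"line {i + 2}: negative CK-MB"
                for i in df.index[df.ckmb_ng_per_mL < 0]]
    if problems:
        raise TableValidationError(problems)
    return df[EFFECT_COLUMNS].astype({"time_min": float, "ckmb_ng_per_mL": float})


def write_effect_table(df: pd.DataFrame, path) -> None:
    df[EFFECT_COLUMNS].to_csv(path, index=False)


def conc_convert(value: float, direction: str, mw: float = MOLECULAR_WEIGHT) -> float:
    """Convert between nM and mg/L: mg/L = nM * MW * 1e-6 (MW in g/mol)."""
    if value < 0:
        raise ValueError("concentration must be >= 0")
    if direction == "nM_to_mgL":
        return value * mw * 1e-6
    if direction == "mgL_to_nM":
        return value / (mw * 1e-6)
    raise ValueError(f"unknown direction {direction!r}")
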