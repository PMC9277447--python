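"""Reading, writing and validation of multiplet signal-ratio tables.

Canonical dialect: UTF-8 TSV with a mandatory header row and columns
``sample_id condition pool position multiplet ratio sem`` (comma-separated
files are accepted on read). Pool is GLU or LAC ("AKG_GLU" is accepted as an
alias of GLU); multiplet labels are C2S, C2D12, C2D23, C2Q, C3S, C3D, C3T,
C4S, C4D34, C4D45, C4Q, C5S, C5D45 for glutamate and LC2S, LC2D12, LC2D23,
LC2Q for lactate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .multiplets import CANONICAL_ROWS, TABLE_COLUMNS

__all__ = [
    "TableValidationError",
    "read_ratio_table",
    "write_ratio_table",
    "validate_ratio_table",
]

_KNOWN_ROWS = set(CANONICAL_ROWS)
_POOL_ALIASES = {"AKG_GLU": "GLU", "GLUTAMATE": "GLU", "LACTATE": "LAC"}

#: per-resonance fractions must sum to 1 within this measurement tolerance
SUM_TOL = 0.02


class TableValidationError(ValueError):
    """Malformed ratio table; ``rows`` lists offending row numbers (1-based,
    counting data rows as in the file)."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


def read_ratio_table(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a ratio table (TSV canonical; comma accepted)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "sem"]
    if missing:
        raise TableValidationError(f"missing columns: {missing}")
    if "sem" not in df.columns:
        df["sem"] = np.nan
    df = df[TABLE_COLUMNS].copy()
    df["pool"] = df["pool"].astype(str).str.upper().replace(_POOL_ALIASES)
    df["position"] = df["position"].astype(int)
    if validate:
        validate_ratio_table(df)
    return df


def write_ratio_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a ratio table as canonical TSV (fixed float precision)."""
    out = df[TABLE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def validate_ratio_table(df: pd.DataFrame, sum_tol: float = SUM_TOL) -> None:
    """Check a ratio table against the dialect contract.

    Raises :class:`TableValidationError` naming the offending data rows when
    a multiplet label is unknown, a ratio falls outside [0, 1], a sem is
    negative, or the fractions of one (sample, pool, position) resonance sum
    to something off 1 by more than ``sum_tol``.
    """
    problems: list[str] = []
    bad_rows: list[int] = []

    keys = list(zip(df["pool"], df["position"], df["multiplet"]))
    unknown = [i for i, k in enumerate(keys) if k not in _KNOWN_ROWS]
    if unknown:
        bad_rows += [i + 1 for i in unknown]
        examples = ", ".join(repr(keys[i][2]) for i in unknown[:5])
        problems.append(f"unknown multiplet labels (rows {[i + 1 for i in unknown]}): {examples}")

    ratio = pd.to_numeric(df["ratio"], errors="coerce")
    out_of_range = df.index[(ratio < 0) | (ratio > 1) | ratio.isna()].tolist()
    if out_of_range:
        rows = [df.index.get_loc(i) + 1 for i in out_of_range]
        bad_rows += rows
        problems.append(f"ratios outside [0, 1] at rows {rows}")

    sem = pd.to_numeric(df["sem"], errors="coerce")
    neg_sem = df.index[sem < 0].tolist()
    if neg_sem:
        rows = [df.index.get_loc(i) + 1 for i in neg_sem]
        bad_rows += rows
        problems.append(f"negative sem at rows {rows}")

    if not out_of_range and not unknown:
        grouped = df.groupby(["sample_id", "pool", "position"], sort=False)
        for key, sub in grouped:
            s = float(sub["ratio"].sum())
            if abs(s - 1.0) > sum_tol:
                rows = [df.index.get_loc(i) + 1 for i in sub.index]
                bad_rows += rows
                problems.append(
                    f"resonance {key} fractions sum to {s:.4f} (rows {rows})"
                )

    if problems:
        raise TableValidationError("; ".join(problems), rows=sorted(set(bad_rows)))
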