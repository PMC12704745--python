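"""Reading and writing the package's delimited-text formats.

The single data-interchange format is a comma-delimited trial table with a
fixed header (see :data:`bodymeta.simulate.TRIAL_COLUMNS`); result tables
are tidy delimited text, and run configurations are human-readable YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ValidationError
from .simulate import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "write_table", "read_config",
           "write_config"]

_SIDE_LEVELS = {"left", "right"}


def write_trials(trials: pd.DataFrame, path) -> Path:
    """Write a trial table (comma-delimited, fixed header)."""
    path = Path(path)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table.

    Raises :class:`ValidationError` naming the offending row and column on
    unknown columns, bad factor levels or malformed numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(TRIAL_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown column(s): {sorted(unknown)}")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s): {sorted(missing)}")

    out = pd.DataFrame(index=df.index)

    def numeric(col, kind, check=None):
        conv = pd.to_numeric(df[col], errors="coerce")
        bad = conv.isna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"malformed number in column {col!r}, row {row}")
        if check is not None:
            bad = ~check(conv)
            if bad.any():
                row = int(df.index[bad][0])
                raise ValidationError(f"invalid value in column {col!r}, row {row}")
        return conv.astype(kind)

    out["subject"] = numeric("subject", int, lambda v: v >= 1)
    out["experiment"] = df["experiment"]
    out["asynchrony_ms"] = numeric("asynchrony_ms", int, lambda v: v > 0)
    out["n_touches"] = numeric("n_touches", int, lambda v: v > 0)
    for col in ("sync_side", "response_side"):
        bad = ~df[col].isin(_SIDE_LEVELS)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"invalid level in column {col!r}, row {row}")
        out[col] = df[col]
    out["pas"] = numeric("pas", int, lambda v: v.isin([1, 2, 3]))
    out["rt_decision_s"] = numeric("rt_decision_s", float, lambda v: v >= 0)
    out["rt_postdecision_s"] = numeric("rt_postdecision_s", float, lambda v: v >= 0)
    cen = df["censored"].str.lower()
    bad = ~cen.isin({"true", "false", "0", "1"})
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"invalid level in column 'censored', row {row}")
    out["censored"] = cen.isin({"true", "1"})
    return out[TRIAL_COLUMNS]


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a tidy result table as comma-delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
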