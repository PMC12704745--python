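"""Type-1 signal detection for the 2AFC body-ownership task.

Hits are "right hand chosen when the right hand was synchronously tapped"
and false alarms are "right hand chosen when the left hand was synchronously
tapped".  Sensitivity uses the 2AFC convention

    d' = (1/sqrt(2)) [Z(P_hit) - Z(P_fa)]

and the bias index is C = -(1/2) [Z(P_hit) + Z(P_fa)].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ValidationError

__all__ = ["CountTable", "SDTResult", "tabulate_counts", "dprime_2afc",
           "sdt_by_subject", "validate_trials", "EstimationError"]

_SIDES = {"left", "right"}
_RESP_INDEX = {"left": 0, "right": 1}


class EstimationError(RuntimeError):
    """Raised when an estimate cannot be formed from the data provided."""


@dataclass
class CountTable:
    """Type-1 outcome counts plus the type-2 (rating) table.

    ``type2`` has shape (response: left/right, correctness: wrong/right,
    rating: 1..n_ratings) and marginalises to the type-1 counts:
    hits + misses come from synchronous-right trials, etc.
    """

    n_hit: int
    n_miss: int
    n_fa: int
    n_cr: int
    type2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2, 3), dtype=float))
    n_ratings: int = 3

    @property
    def n_trials(self) -> int:
        return int(self.n_hit + self.n_miss + self.n_fa + self.n_cr)

    def validate(self) -> None:
        t2 = np.asarray(self.type2)
        if t2.shape != (2, 2, self.n_ratings):
            raise ValidationError("type2 table has wrong shape")
        # type-2 counts must marginalise to the type-1 counts
        marg = {
            ("right", 1): self.n_hit,   # correct right response
            ("left", 0): self.n_miss,   # wrong left response (sync right)
            ("right", 0): self.n_fa,    # wrong right response (sync left)
            ("left", 1): self.n_cr,     # correct left response
        }
        for (resp, corr), n in marg.items():
            if not np.isclose(t2[_RESP_INDEX[resp], corr].sum(), n):
                raise ValidationError("type-2 counts do not marginalise to type-1 counts")


@dataclass
class SDTResult:
    dprime: float
    criterion_c: float
    n_trials: int
    correction_applied: bool
    p_hit: float
    p_fa: float

    def summary(self) -> str:
        return (f"d' = {self.dprime:.4f}, C = {self.criterion_c:.4f} "
                f"(n = {self.n_trials}, corrected = {self.correction_applied})")


def validate_trials(trials: pd.DataFrame) -> None:
    """Schema check for a trial table; raises :class:`ValidationError` naming
    the offending column."""
    required = {"subject", "sync_side", "response_side", "pas"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if not set(trials["sync_side"].unique()) <= _SIDES:
        raise ValidationError("sync_side contains values outside {left, right}")
    if not set(trials["response_side"].unique()) <= _SIDES:
        raise ValidationError("response_side contains values outside {left, right}")
    pas = pd.to_numeric(trials["pas"], errors="coerce")
    bad = ~pas.isin([1, 2, 3])
    if bad.any():
        row = int(trials.index[bad][0])
        raise ValidationError(f"pas outside {{1,2,3}} at row {row}")
    for col in ("rt_decision_s", "rt_postdecision_s"):
        if col in trials.columns:
            v = pd.to_numeric(trials[col], errors="coerce")
            if (v.dropna() < 0).any():
                raise ValidationError(f"negative values in {col}")


def tabulate_counts(trials: pd.DataFrame, condition=None, n_ratings: int = 3,
                    drop_censored: bool = True) -> CountTable:
    """Tabulate type-1 and type-2 counts for the selected trials.

    ``condition`` may be None (all trials), a boolean mask, or a dict of
    column -> value equality filters (e.g. ``{"asynchrony_ms": 31}``).
    """
    validate_trials(trials)
    sel = trials
    if isinstance(condition, dict):
        for col, val in condition.items():
            sel = sel[sel[col] == val]
    elif condition is not None:
        sel = trials[condition]
    if drop_censored and "censored" in sel.columns:
        sel = sel[~sel["censored"].astype(bool)]
    if len(sel) == 0:
        raise ValidationError("condition selector matched no trials")

    sync_right = (sel["sync_side"] == "right").to_numpy()
    resp_right = (sel["response_side"] == "right").to_numpy()
    correct = (sync_right == resp_right)
    pas = sel["pas"].to_numpy().astype(int)

    n_hit = int(np.sum(sync_right & resp_right))
    n_miss = int(np.sum(sync_right & ~resp_right))
    n_fa = int(np.sum(~sync_right & resp_right))
    n_cr = int(np.sum(~sync_right & ~resp_right))

    type2 = np.zeros((2, 2, n_ratings), dtype=float)
    for r_idx, r_val in ((0, False), (1, True)):
        for c_idx, c_val in ((0, False), (1, True)):
            mask = (resp_right == r_val) & (correct == c_val)
            if mask.any():
                type2[r_idx, c_idx] = np.bincount(
                    pas[mask] - 1, minlength=n_ratings)[:n_ratings]
    ct = CountTable(n_hit, n_miss, n_fa, n_cr, type2, n_ratings)
    ct.validate()
    return ct


def dprime_2afc(counts: CountTable, scaled: bool = True) -> SDTResult:
    """Sensitivity and bias from a 2AFC count table.

    Extreme rates (0 or 1) are handled by the log-linear rule: 0.5 is added
    to every type-1 cell before the rates are formed, keeping the quantile
    transform finite.  ``scaled=False`` drops the 1/sqrt(2) 2AFC factor
    (yes/no convention); the scaled form is the default and the convention
    used throughout the package.
    """
    n_sync_right = counts.n_hit + counts.n_miss
    n_sync_left = counts.n_fa + counts.n_cr
    if n_sync_right == 0 or n_sync_left == 0:
        raise EstimationError("need trials for both synchronous sides")
    p_hit = counts.n_hit / n_sync_right
    p_fa = counts.n_fa / n_sync_left
    correction = p_hit in (0.0, 1.0) or p_fa in (0.0, 1.0)
    if correction:
        p_hit = (counts.n_hit + 0.5) / (n_sync_right + 1.0)
        p_fa = (counts.n_fa + 0.5) / (n_sync_left + 1.0)
    zh, zf = norm.ppf(p_hit), norm.ppf(p_fa)
    scale = 1.0 / np.sqrt(2.0) if scaled else 1.0
    return SDTResult(
        dprime=float(scale * (zh - zf)),
        criterion_c=float(-0.5 * (zh + zf)),
        n_trials=counts.n_trials,
        correction_applied=bool(correction),
        p_hit=float(p_hit),
        p_fa=float(p_fa),
    )


def sdt_by_subject(trials: pd.DataFrame, by=("asynchrony_ms", "n_touches")) -> pd.DataFrame:
    """Tidy per-subject x condition SDT table (one row per cell)."""
    rows = []
    group_cols = ["subject"] + [c for c in by if c in trials.columns]
    for keys, sub in trials.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ct = tabulate_counts(sub)
        res = dprime_2afc(ct)
        row = dict(zip(group_cols, keys))
        row.update(dprime=res.dprime, criterion_c=res.criterion_c,
                   n_trials=res.n_trials, correction_applied=res.correction_applied)
        rows.append(row)
    return pd.DataFrame(rows)
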