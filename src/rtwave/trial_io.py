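"""Reading, validating and filtering trial-level behavioral tables.

A trial table is a pandas DataFrame with one row per trial and the
canonical columns ``participant``, ``actual_n``, ``estimate_or_target``,
``rt_ms`` and (optionally) ``correct``.  The filters implement the
preprocessing variants used across numerosity-estimation datasets:
exclusion of error responses, and trimming of RT outliers beyond ``k``
standard deviations from the global or the per-participant mean.

Pipeline order is fixed: error exclusion first, then outlier trimming, so
wrong-key lapses cannot inflate the trimming threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, InvalidParameterError, SchemaError

__all__ = [
    "FilterSpec",
    "read_trials",
    "write_trials",
    "filter_errors",
    "filter_outliers",
    "assign_differential",
    "REQUIRED_COLUMNS",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["participant", "actual_n", "estimate_or_target", "rt_ms"]


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing variant for a dataset.

    ``outlier_k`` is the SD multiple beyond which an RT counts as an
    outlier (common values: 1.96 and 3), or ``None`` for no trimming.
    ``outlier_scope`` selects whether the reference mean/SD are computed
    over the whole table or per participant.  ``drop_errors`` removes
    incorrect responses (requires a ``correct`` column).
    """

    outlier_k: float | None = 1.96
    outlier_scope: Literal["global", "participant"] = "global"
    drop_errors: bool = False

    def __post_init__(self) -> None:
        if self.outlier_k is not None and self.outlier_k <= 0:
            raise InvalidParameterError(f"outlier_k must be > 0, got {self.outlier_k}")
        if self.outlier_scope not in ("global", "participant"):
            raise InvalidParameterError(f"unknown outlier_scope {self.outlier_scope!r}")


def read_trials(path, column_map: Mapping[str, str] | None = None,
                sep: str | None = None) -> pd.DataFrame:
    """Read a delimited trial table and validate it.

    Parameters
    ----------
    path:
        Delimited text file with a header row.  The delimiter is sniffed
        when ``sep`` is not given.
    column_map:
        Mapping of file column names to the canonical names, e.g.
        ``{"RT": "rt_ms"}``.

    Rows violating the row invariants (``rt_ms > 0``, ``actual_n >= 1``,
    non-null required fields) are rejected; the count is logged and stored
    in ``result.attrs["n_rejected"]``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["actual_n"] = pd.to_numeric(df["actual_n"], errors="coerce")
    df["estimate_or_target"] = pd.to_numeric(df["estimate_or_target"], errors="coerce")
    if "correct" in df.columns:
        df["correct"] = df["correct"].map(
            {True: True, False: False, 1: True, 0: False, "True": True,
             "False": False, "true": True, "false": False, "1": True, "0": False}
        ).astype("boolean")

    valid = (
        df["rt_ms"].notna() & (df["rt_ms"] > 0)
        & df["actual_n"].notna() & (df["actual_n"] >= 1)
        & df["estimate_or_target"].notna()
        & df["participant"].notna()
    )
    n_rejected = int((~valid).sum())
    if n_rejected:
        log.warning("%s: rejected %d row(s) violating trial invariants", path, n_rejected)
    out = df.loc[valid].reset_index(drop=True)
    if out.empty:
        raise InputError(f"{path}: no valid trials after validation")
    out.attrs["n_rejected"] = n_rejected
    return out


def write_trials(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a trial table as delimited text with a header."""
    table.to_csv(path, sep=sep, index=False)


def filter_errors(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Drop incorrect responses when ``spec.drop_errors`` is set.

    Raises :class:`ConfigError` if error exclusion is requested but the
    table carries no usable ``correct`` flags (free-entry paradigms).
    """
    if not spec.drop_errors:
        out = table.copy()
        out.attrs["n_errors_removed"] = 0
        return out
    if "correct" not in table.columns or table["correct"].isna().all():
        raise ConfigError(
            "drop_errors requested but the table has no 'correct' flags "
            "(free-entry paradigm?)"
        )
    keep = table["correct"].fillna(False).astype(bool)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs["n_errors_removed"] = int(len(table) - len(out))
    return out


def _trim(rt: pd.Series, k: float) -> pd.Series:
    m = rt.mean()
    s = rt.std(ddof=1)
    if not np.isfinite(s) or s == 0:
        return pd.Series(True, index=rt.index)
    # strictly-greater rule: a trial exactly at k*SD is retained
    return (rt - m).abs() <= k * s


def filter_outliers(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Trim RT outliers beyond ``outlier_k`` sample SDs from the mean.

    The reference mean and sample SD (n-1 denominator) are computed over
    the whole table (``scope="global"``) or per participant
    (``scope="participant"``).  With ``outlier_k=None`` the table passes
    through unchanged.  A participant with fewer than 2 trials cannot be
    trimmed within-participant and passes unfiltered with a warning.
    """
    if table.empty:
        raise InputError("filter_outliers: empty trial table")
    if spec.outlier_k is None:
        out = table.copy()
        out.attrs["n_outliers_removed"] = 0
        return out
    if spec.outlier_scope == "global":
        keep = _trim(table["rt_ms"], spec.outlier_k)
    else:
        sizes = table.groupby("participant")["rt_ms"].transform("size")
        tiny = sizes < 2
        if tiny.any():
            warnings.warn(
                f"{table.loc[tiny, 'participant'].nunique()} participant(s) with "
                "< 2 trials pass unfiltered", stacklevel=2,
            )
        keep = table.groupby("participant", group_keys=False)["rt_ms"].apply(
            lambda g: _trim(g, spec.outlier_k) if len(g) >= 2
            else pd.Series(True, index=g.index)
        )
        keep = keep.reindex(table.index)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs["n_outliers_removed"] = int(len(table) - len(out))
    return out


def assign_differential(table: pd.DataFrame,
                        mode: Literal["vs_estimate", "vs_target"] = "vs_estimate",
                        ) -> pd.DataFrame:
    """Add the ``differential`` column: actual numerosity minus the
    estimate (free entry) or the comparison target (two-choice).

    Both modes share the same arithmetic — ``estimate_or_target`` holds
    whichever quantity the paradigm produced; ``mode`` documents which one
    and is recorded for the report.
    """
    if mode not in ("vs_estimate", "vs_target"):
        raise ConfigError(f"unknown differential mode {mode!r}")
    out = table.copy()
    out["differential"] = (out["actual_n"] - out["estimate_or_target"]).astype(int)
    out.attrs["differential_mode"] = mode
    return out
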