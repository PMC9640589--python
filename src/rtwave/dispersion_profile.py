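"""Per-differential dispersion profiles of response times.

The dispersion profile is the core descriptive object of the analysis: for
each distinct differential (numerosity error) it records the trial count,
the mean RT and the sample standard deviation of the RTs.  The wave-like
shape of the SD column along the differential axis is what the symmetry
analysis quantifies.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError, InvalidParameterError

__all__ = ["build_profile", "normalize_values", "write_profile", "read_profile",
           "PROFILE_COLUMNS"]

log = logging.getLogger(__name__)

PROFILE_COLUMNS = ["differential", "count", "mean_rt", "sd_rt"]


def build_profile(table: pd.DataFrame, min_count: int = 5,
                  bin_width: int | None = None) -> pd.DataFrame:
    """Bin trials by differential and compute count / mean RT / SD RT.

    Parameters
    ----------
    table:
        Trial table with a ``differential`` column assigned.
    min_count:
        Bins with fewer trials are dropped (their differentials are listed
        in ``result.attrs["dropped_bins"]``); a sample SD over very few
        trials is too noisy to be a meaningful profile point.
    bin_width:
        Optional width for grouping sparse free-entry differentials;
        ``None`` (default) keeps the raw integer differentials as bins.

    Returns an ordered DataFrame with columns
    ``differential, count, mean_rt, sd_rt`` (differentials strictly
    increasing).  If fewer than 4 bins survive on either side of zero a
    downstream-insufficiency warning is emitted and recorded in
    ``result.attrs["warnings"]``.
    """
    if "differential" not in table.columns:
        raise InputError("build_profile: table has no 'differential' column")
    if table.empty:
        raise InputError("build_profile: empty trial table")
    if min_count < 2:
        raise InvalidParameterError("min_count must be >= 2 (sample SD needs 2 trials)")

    d = table["differential"]
    if bin_width is not None:
        if bin_width < 1:
            raise InvalidParameterError("bin_width must be >= 1")
        d = (np.round(d / bin_width) * bin_width).astype(int)

    grouped = table.assign(differential=d).groupby("differential")["rt_ms"]
    prof = grouped.agg(count="size", mean_rt="mean", sd_rt=lambda x: x.std(ddof=1))
    prof = prof.reset_index().sort_values("differential").reset_index(drop=True)

    small = prof["count"] < min_count
    dropped = prof.loc[small, "differential"].tolist()
    if dropped:
        log.info("build_profile: dropped %d bin(s) below min_count=%d: %s",
                 len(dropped), min_count, dropped)
    prof = prof.loc[~small].reset_index(drop=True)

    notes: list[str] = []
    n_neg = int((prof["differential"] < 0).sum())
    n_pos = int((prof["differential"] > 0).sum())
    if n_neg < 4 or n_pos < 4:
        msg = (f"only {n_neg} negative / {n_pos} positive bins survive; "
               "arm splitting needs >= 4 per side")
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    prof["count"] = prof["count"].astype(int)
    prof.attrs["dropped_bins"] = dropped
    prof.attrs["warnings"] = notes
    return prof[PROFILE_COLUMNS]


def normalize_values(values) -> np.ndarray:
    """Linear rescaling of ``values`` onto [0, 1].

    The minimum maps to 0 and the maximum to 1.  Raises
    :class:`DegenerateInputError` for constant input (no scale exists) or
    fewer than two values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateInputError("normalize_values needs at least 2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError("normalize_values: constant input has no scale")
    return (v - lo) / (hi - lo)


def write_profile(profile: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a profile as delimited text for inspection and re-import."""
    profile.to_csv(path, sep=sep, index=False)


def read_profile(path, sep: str = "\t") -> pd.DataFrame:
    """Read a profile previously written by :func:`write_profile`."""
    prof = pd.read_csv(path, sep=sep)
    missing = [c for c in PROFILE_COLUMNS if c not in prof.columns]
    if missing:
        raise InputError(f"{path}: not a profile table, missing {missing}")
    return prof[PROFILE_COLUMNS]
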