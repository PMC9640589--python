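"""Mirror-symmetry statistic of a dispersion profile.

The profile is split at an axis (default: differential 0) into a negative
and a positive arm, each re-indexed by *eccentricity* — distance from the
axis — so the comparison is a mirror comparison.  Each arm is resampled
with a cubic smoothing spline onto a common K-point grid spanning its own
eccentricity range, and the two resampled curves are correlated with the
Pearson product-moment coefficient.  A high r means the dispersion wave on
one side of the axis is mirrored on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .dispersion_profile import normalize_values
from .errors import DegenerateInputError, InsufficientArmError

__all__ = [
    "ArmPair",
    "SymmetryResult",
    "split_arms",
    "resample_arm",
    "pearson_r",
    "arm_symmetry",
    "search_axis",
    "export_arm_curves",
]

MIN_ARM_POINTS = 4  # a cubic spline needs at least k+1 = 4 support points


@dataclass
class ArmPair:
    """Raw and resampled arms of a profile about an axis of symmetry.

    Eccentricities are ``|differential - axis|``, strictly increasing
    outward from the axis in both arms.  A profile point exactly at the
    axis belongs to neither arm.
    """

    negative_ecc: np.ndarray
    negative_val: np.ndarray
    positive_ecc: np.ndarray
    positive_val: np.ndarray
    resampled_negative: np.ndarray | None = None
    resampled_positive: np.ndarray | None = None


@dataclass(frozen=True)
class SymmetryResult:
    """Arm-symmetry correlation of a dispersion profile."""

    r: float
    axis: float
    K: int
    smoothing: float
    arms: ArmPair = field(repr=False)


def split_arms(profile: pd.DataFrame, axis: float = 0.0) -> ArmPair:
    """Split a profile's SD values into two arms about ``axis``.

    Points with differential < axis form the negative arm, > axis the
    positive arm; both are re-indexed by eccentricity.  Raises
    :class:`InsufficientArmError` if either side has fewer than 4 points.
    """
    d = np.asarray(profile["differential"], dtype=float)
    v = np.asarray(profile["sd_rt"], dtype=float)
    neg = d < axis
    pos = d > axis
    if neg.sum() < MIN_ARM_POINTS or pos.sum() < MIN_ARM_POINTS:
        raise InsufficientArmError(
            f"need >= {MIN_ARM_POINTS} points per side of axis {axis}; "
            f"got {int(neg.sum())} negative / {int(pos.sum())} positive"
        )
    neg_ecc = axis - d[neg]
    pos_ecc = d[pos] - axis
    neg_order = np.argsort(neg_ecc)
    pos_order = np.argsort(pos_ecc)
    return ArmPair(
        negative_ecc=neg_ecc[neg_order],
        negative_val=v[neg][neg_order],
        positive_ecc=pos_ecc[pos_order],
        positive_val=v[pos][pos_order],
    )


def resample_arm(ecc: np.ndarray, values: np.ndarray, K: int = 100,
                 smoothing: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Resample one arm onto ``K`` equally spaced eccentricities.

    Fits a univariate cubic smoothing spline to ``(ecc, values)`` — the
    least-squares cubic spline whose summed squared residuals stay within
    the smoothing budget — and evaluates it at ``K`` points spanning
    ``[ecc.min(), ecc.max()]``.  ``smoothing=None`` uses the conventional
    default of one unit of residual budget per data point (``len(ecc)``
    under unit weights); ``smoothing=0`` reproduces an exact interpolant.

    Returns ``(grid, curve)``.
    """
    ecc = np.asarray(ecc, dtype=float)
    values = np.asarray(values, dtype=float)
    if ecc.size < MIN_ARM_POINTS:
        raise InsufficientArmError(
            f"resample_arm needs >= {MIN_ARM_POINTS} points, got {ecc.size}")
    if np.any(np.diff(ecc) <= 0):
        raise InsufficientArmError("arm eccentricities must be strictly increasing")
    if K < MIN_ARM_POINTS:
        raise DegenerateInputError(f"K must be >= {MIN_ARM_POINTS}, got {K}")
    s = float(len(ecc)) if smoothing is None else float(smoothing)
    spline = UnivariateSpline(ecc, values, k=3, s=s)
    grid = np.linspace(ecc[0], ecc[-1], K)
    return grid, spline(grid)


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Invariant to positive-slope affine maps of either argument.  Raises
    :class:`DegenerateInputError` for constant input or mismatched length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise DegenerateInputError(
            f"pearson_r needs two equal-length vectors of >= 2 values "
            f"(got {a.size} and {b.size})")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("pearson_r: constant input has undefined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def arm_symmetry(profile: pd.DataFrame, axis: float = 0.0, K: int = 100,
                 smoothing: float | None = None, normalize: bool = True,
                 ) -> SymmetryResult:
    """Full arm-symmetry statistic of a dispersion profile.

    Composes normalization (optional — Pearson r is invariant to it),
    :func:`split_arms`, per-arm spline resampling to ``K`` points, and
    :func:`pearson_r`.  Arms of unequal eccentricity span are compared
    index-by-index on their own normalized grids.
    """
    prof = profile
    if normalize:
        prof = profile.copy()
        prof["sd_rt"] = normalize_values(profile["sd_rt"])
    arms = split_arms(prof, axis=axis)
    s_neg = float(len(arms.negative_ecc)) if smoothing is None else float(smoothing)
    _, curve_neg = resample_arm(arms.negative_ecc, arms.negative_val, K, smoothing)
    _, curve_pos = resample_arm(arms.positive_ecc, arms.positive_val, K, smoothing)
    arms.resampled_negative = curve_neg
    arms.resampled_positive = curve_pos
    r = pearson_r(curve_neg, curve_pos)
    return SymmetryResult(r=r, axis=float(axis), K=int(K), smoothing=s_neg, arms=arms)


def search_axis(profile: pd.DataFrame, offsets=(-2, -1, 0, 1, 2), K: int = 100,
                smoothing: float | None = None) -> SymmetryResult:
    """Exploratory: maximize r over a small grid of axis offsets.

    Picking the axis that maximizes r biases the statistic upward; use
    only for descriptive alignment checks, never for inference.  Offsets
    whose arms are too short are skipped.
    """
    best: SymmetryResult | None = None
    for off in offsets:
        try:
            res = arm_symmetry(profile, axis=float(off), K=K, smoothing=smoothing)
        except InsufficientArmError:
            continue
        if best is None or res.r > best.r:
            best = res
    if best is None:
        raise InsufficientArmError("no axis offset leaves >= 4 points per side")
    return best


def export_arm_curves(result: SymmetryResult) -> pd.DataFrame:
    """Tabulate the two resampled arm curves for plotting or export.

    Columns: ``grid_index``, ``eccentricity_fraction`` (position on the
    normalized [0, 1] grid), ``negative_value``, ``positive_value``.
    """
    arms = result.arms
    if arms.resampled_negative is None or arms.resampled_positive is None:
        raise DegenerateInputError("result carries no resampled curves")
    K = result.K
    return pd.DataFrame({
        "grid_index": np.arange(K),
        "eccentricity_fraction": np.linspace(0.0, 1.0, K),
        "negative_value": arms.resampled_negative,
        "positive_value": arms.resampled_positive,
    })
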