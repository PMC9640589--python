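"""Synthetic trial-level data with wave-modulated response-time dispersion.

The generator produces behavioral trial tables with the statistical
structure the downstream analysis looks for: the standard deviation of
response times (RTs), taken per value of the *differential* (actual
numerosity minus estimate/target), follows a sinusoidal envelope along the
differential axis.  The envelope can be perfectly mirrored about zero, be
deliberately phase-shifted on the negative arm (a negative control for the
symmetry statistic), or be flat (amplitude 0, the null condition).

Trial counts per differential emulate the three count distributions seen in
real numerosity experiments: flat (counterbalanced two-choice designs),
bipartite exponential (free-entry designs, responses pile up near the
correct answer), and bell-shaped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

__all__ = [
    "WaveParams",
    "DesignConfig",
    "dispersion_curve",
    "trial_counts",
    "generate_trials",
    "TRIAL_COLUMNS",
]

#: Canonical column order of a generated trial table.
TRIAL_COLUMNS = [
    "participant",
    "actual_n",
    "estimate_or_target",
    "rt_ms",
    "correct",
    "differential",
]

CountsShape = Literal["flat", "bipartite_exponential", "bell"]
ResponseType = Literal["free_entry", "two_choice"]


@dataclass(frozen=True)
class WaveParams:
    """Sinusoidal envelope of the per-differential RT standard deviation.

    Parameters
    ----------
    sigma0:
        Baseline RT standard deviation in ms.  Must be positive.
    amplitude:
        Wave amplitude of the SD envelope in ms.  ``amplitude = 0`` yields a
        flat (null) dispersion profile.  ``sigma0 - amplitude`` must stay
        positive so the dispersion never becomes non-positive.
    wavelength:
        Period of the wave in differential units.
    phase:
        Phase offset in radians, applied to both arms.
    asymmetry_phase_shift:
        Extra phase (radians) added on the negative arm only.  Zero gives a
        perfectly mirrored envelope; ``pi`` gives anti-phase arms.
    """

    sigma0: float
    amplitude: float = 0.0
    wavelength: float = 5.0
    phase: float = 0.0
    asymmetry_phase_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise InvalidParameterError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.amplitude < 0:
            raise InvalidParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.sigma0 - self.amplitude <= 0:
            raise InvalidParameterError(
                "sigma0 - amplitude must be > 0 so the dispersion stays positive "
                f"(sigma0={self.sigma0}, amplitude={self.amplitude})"
            )
        if self.wavelength <= 0:
            raise InvalidParameterError(f"wavelength must be > 0, got {self.wavelength}")


@dataclass(frozen=True)
class DesignConfig:
    """Design of a synthetic numerosity-estimation dataset.

    The defaults describe a counterbalanced design with 30 informative
    differential bins (-15..15), 200 trials per bin and a ~1 s mean RT,
    the regime in which the arm-symmetry analysis is typically run.

    ``error_rate_intercept``/``error_rate_slope`` parameterize the logistic
    accuracy model ``P(correct) = expit(intercept + slope * |d|)`` used for
    two-choice designs (accuracy improves as the stimulus moves away from
    the comparison target).
    """

    differential_min: int = -15
    differential_max: int = 15
    counts_shape: CountsShape = "flat"
    trials_per_bin: int = 200
    mean_rt_ms: float = 1000.0
    response_type: ResponseType = "free_entry"
    n_participants: int = 20
    error_rate_intercept: float = 0.5
    error_rate_slope: float = 0.3
    #: decay rate of the bipartite-exponential counts curve (per |d| unit)
    decay_rate: float = 0.3
    #: SD of the bell-shaped counts curve; ``None`` -> (range width) / 4
    bell_sd: float | None = None
    numerosity_min: int = 40
    numerosity_max: int = 69
    #: include the d = 0 bin; ``None`` -> yes for free_entry, no for two_choice
    #: (a two-choice response at the exact target has no higher/lower answer)
    include_zero: bool | None = None
    #: extra mean RT (ms) at d = 0, decaying linearly to 0 at the range edges;
    #: off by default so dispersion structure is isolated from mean structure
    difficulty_gradient_ms: float = 0.0
    rt_distribution: Literal["truncated_normal", "lognormal"] = "truncated_normal"

    def __post_init__(self) -> None:
        if not (self.differential_min < 0 < self.differential_max):
            raise InvalidParameterError(
                "differential range must bracket 0: "
                f"[{self.differential_min}, {self.differential_max}]"
            )
        if self.trials_per_bin < 2:
            raise InvalidParameterError("trials_per_bin must be >= 2")
        if self.mean_rt_ms <= 0:
            raise InvalidParameterError("mean_rt_ms must be > 0")
        if self.counts_shape not in ("flat", "bipartite_exponential", "bell"):
            raise InvalidParameterError(f"unknown counts_shape {self.counts_shape!r}")
        if self.response_type not in ("free_entry", "two_choice"):
            raise InvalidParameterError(f"unknown response_type {self.response_type!r}")
        if self.n_participants < 1:
            raise InvalidParameterError("n_participants must be >= 1")
        if self.decay_rate <= 0:
            raise InvalidParameterError("decay_rate must be > 0")
        if self.rt_distribution not in ("truncated_normal", "lognormal"):
            raise InvalidParameterError(f"unknown rt_distribution {self.rt_distribution!r}")

    def differentials(self) -> list[int]:
        """Ordered differential bins of the design."""
        include_zero = self.include_zero
        if include_zero is None:
            include_zero = self.response_type == "free_entry"
        ds = range(self.differential_min, self.differential_max + 1)
        return [d for d in ds if d != 0 or include_zero]


def dispersion_curve(d, w: WaveParams, arm_sign=None):
    """Target RT standard deviation at differential ``d``.

    ``sigma(d) = sigma0 + amplitude * sin(2*pi*|d|/wavelength + phase
    [+ asymmetry_phase_shift on the negative arm])``.

    Parameters
    ----------
    d:
        Differential value(s); scalar or array.
    arm_sign:
        Which arm ``d`` belongs to; defaults to ``sign(d)``.  The shift is
        applied where ``arm_sign < 0``.

    Returns
    -------
    float or ndarray of the same shape as ``d``, strictly positive.
    """
    d = np.asarray(d, dtype=float)
    if arm_sign is None:
        arm_sign = np.sign(d)
    arm_sign = np.asarray(arm_sign, dtype=float)
    phase = w.phase + np.where(arm_sign < 0, w.asymmetry_phase_shift, 0.0)
    sigma = w.sigma0 + w.amplitude * np.sin(
        2.0 * math.pi * np.abs(d) / w.wavelength + phase
    )
    if np.any(sigma <= 0):
        raise InvalidParameterError("dispersion_curve produced a non-positive SD")
    if sigma.ndim == 0:
        return float(sigma)
    return sigma


def trial_counts(cfg: DesignConfig) -> dict[int, int]:
    """Number of trials per differential bin under the configured shape.

    flat
        every bin gets ``trials_per_bin`` trials.
    bipartite_exponential
        ``round(trials_per_bin * exp(-decay_rate * |d|))`` — counts peak at
        d = 0 and decay exponentially with the error magnitude.
    bell
        counts proportional to a discretized normal over the range, scaled
        so the peak bin equals ``trials_per_bin``.

    Every bin is floored at 2 trials so a sample SD always exists.
    """
    counts: dict[int, int] = {}
    for d in cfg.differentials():
        if cfg.counts_shape == "flat":
            n = cfg.trials_per_bin
        elif cfg.counts_shape == "bipartite_exponential":
            n = round(cfg.trials_per_bin * math.exp(-cfg.decay_rate * abs(d)))
        else:  # bell
            sd = cfg.bell_sd
            if sd is None:
                sd = (cfg.differential_max - cfg.differential_min) / 4.0
            n = round(cfg.trials_per_bin * math.exp(-(d * d) / (2.0 * sd * sd)))
        counts[d] = max(int(n), 2)
    return counts


def _draw_rts(rng: np.random.Generator, n: int, mean: float, sd: float,
              distribution: str) -> np.ndarray:
    if distribution == "lognormal":
        # moment-match a lognormal to the requested mean and SD
        s2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - s2 / 2.0
        return rng.lognormal(mu, math.sqrt(s2), n)
    # normal truncated at 0; at the RT scales used (mean >> sd) the
    # truncation correction to mean/SD is negligible
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_trials(cfg: DesignConfig, w: WaveParams, seed: int) -> pd.DataFrame:
    """Generate a full synthetic trial table.

    For each differential bin ``d`` the generator draws
    ``trial_counts(cfg)[d]`` response times from a positively supported
    distribution with mean ``mean_rt_ms`` (plus the optional difficulty
    bump near d = 0) and SD ``dispersion_curve(d, w)``, assigns participant
    ids round-robin, and for two-choice designs draws correctness from the
    logistic accuracy model.  The same seed always yields an identical
    table.

    Returns a DataFrame with columns
    ``participant, actual_n, estimate_or_target, rt_ms, correct, differential``
    (``correct`` is NA for free-entry designs).
    """
    rng = np.random.default_rng(seed)
    counts = trial_counts(cfg)
    max_ecc = max(abs(cfg.differential_min), abs(cfg.differential_max))

    frames = []
    row_offset = 0
    for d in cfg.differentials():
        n = counts[d]
        mean = cfg.mean_rt_ms + cfg.difficulty_gradient_ms * (1.0 - abs(d) / max_ecc)
        sd = dispersion_curve(d, w)
        rts = _draw_rts(rng, n, mean, sd, cfg.rt_distribution)
        # keep the estimate/target at least 1 for any d in the design
        lo = max(cfg.numerosity_min, 1 + d)
        actual = rng.integers(lo, cfg.numerosity_max + 1, size=n)
        participants = [
            f"p{(row_offset + i) % cfg.n_participants + 1:02d}" for i in range(n)
        ]
        if cfg.response_type == "two_choice":
            p_correct = 1.0 / (1.0 + math.exp(-(cfg.error_rate_intercept
                                                + cfg.error_rate_slope * abs(d))))
            correct = rng.random(n) < p_correct
        else:
            correct = pd.array([pd.NA] * n, dtype="boolean")
        frames.append(pd.DataFrame({
            "participant": participants,
            "actual_n": actual,
            "estimate_or_target": actual - d,
            "rt_ms": rts,
            "correct": pd.array(correct, dtype="boolean"),
            "differential": d,
        }))
        row_offset += n

    table = pd.concat(frames, ignore_index=True)
    return table[TRIAL_COLUMNS]
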