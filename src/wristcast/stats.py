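"""Significance of forecasting performance against chance predictors.

Two complementary nulls:

* **Poisson chance predictor** — warning episodes are assumed to start as a
  Poisson process with rate λ_w and last d seconds on average.  A seizure is
  predicted by chance when some episode overlaps its preictal detection
  horizon τ, i.e. when an episode starts within a window of length τ + d, so
  c = 1 − exp(−λ_w·(τ + d)).  λ_w is calibrated from the observed warning
  behaviour (warning fraction w and mean episode duration d) via
  w = 1 − exp(−λ_w·d).  With n of N lead seizures predicted, the two-sided
  p-value is the binomial tail probability of a result at least as extreme
  as n under Binomial(N, c), doubling the smaller tail and capping at 1.
* **Surrogate seizure times** — randomized onset sequences that preserve the
  seizure count and the multiset of inter-seizure intervals (a random
  permutation of the intervals, anchored uniformly inside the test span).
  Re-scoring the fixed forecast against surrogates yields an empirical null
  for the AUC and sensitivity.

The sensitivity improvement over chance is the observed sensitivity minus the
chance sensitivity at identical time in warning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .e4_io import SeizureAnnotations

__all__ = [
    "ChanceModel",
    "SurrogateSet",
    "chance_model_from_warning",
    "snyder_pvalue",
    "surrogate_seizure_times",
    "improvement_over_chance",
]


@dataclass(frozen=True)
class ChanceModel:
    """Poisson chance-warning process.

    lambda_w : warning-episode arrival rate (per second).
    horizon : preictal detection horizon in seconds (default 60 min).
    mean_duration : mean warning-episode duration in seconds; an episode
        starting up to this long before the horizon still overlaps it.
    warning_fraction : observed fraction of time in warning used for
        calibration (kept for reporting).
    """

    lambda_w: float
    horizon: float = 3600.0
    mean_duration: float = 0.0
    warning_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.lambda_w < 0:
            raise ValueError("lambda_w must be >= 0")

    @property
    def hit_probability(self) -> float:
        """Per-seizure chance that a warning episode overlaps the horizon."""
        return float(1.0 - np.exp(-self.lambda_w * (self.horizon + self.mean_duration)))


def chance_model_from_warning(warning_fraction: float,
                              mean_warning_duration: float,
                              horizon: float = 3600.0) -> ChanceModel:
    """Calibrate λ_w so the Poisson predictor matches the observed warning load.

    Solves w = 1 − exp(−λ_w·d) for λ_w, with w the warning fraction and d the
    mean warning-episode duration (seconds).  Degenerate fractions (0 or 1)
    give λ_w = 0 or ∞-like behaviour handled in closed form (c = 0 or 1).
    """
    w = float(warning_fraction)
    if not 0.0 <= w <= 1.0:
        raise ValueError("warning_fraction must be in [0, 1]")
    if w == 0.0:
        return ChanceModel(0.0, horizon, 0.0, w)
    if w >= 1.0:
        # always in warning: certain chance hit
        return ChanceModel(np.inf, horizon, mean_warning_duration, 1.0)
    if mean_warning_duration <= 0:
        raise ValueError("mean_warning_duration must be positive when 0 < w < 1")
    lam = -np.log1p(-w) / mean_warning_duration
    return ChanceModel(float(lam), horizon, float(mean_warning_duration), w)


def snyder_pvalue(n_hit: int, n_seizures: int, chance: ChanceModel) -> float:
    """Two-sided binomial p-value of n_hit predicted seizures versus chance.

    Under the null the hit count is Binomial(N, c) with c the chance
    per-seizure hit probability; the smaller tail (including the observed
    count) is doubled and capped at 1.
    """
    if not 0 <= n_hit <= n_seizures or n_seizures < 1:
        raise ValueError("need 0 <= n_hit <= n_seizures >= 1")
    c = chance.hit_probability
    if c <= 0.0:
        return 1.0 if n_hit == 0 else 0.0
    if c >= 1.0:
        return 1.0 if n_hit == n_seizures else 0.0
    lower = float(sps.binom.cdf(n_hit, n_seizures, c))
    upper = float(sps.binom.sf(n_hit - 1, n_seizures, c))
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class SurrogateSet:
    """Interval-preserving randomized seizure-onset replicates."""

    replicates: list[np.ndarray]
    seed: int

    @property
    def n_reps(self) -> int:
        return len(self.replicates)


def surrogate_seizure_times(annotations: SeizureAnnotations,
                            span: tuple[float, float],
                            n_reps: int = 100,
                            seed: int = 0) -> SurrogateSet:
    """Randomized onset sequences preserving count and inter-onset intervals.

    Each replicate permutes the inter-onset intervals and anchors the sequence
    at a uniform random start such that all onsets fall inside ``span``.  With
    a single onset only the anchor is randomized.
    """
    onsets = annotations.onsets
    if onsets.size == 0:
        raise ValueError("cannot build surrogates without onsets")
    rng = np.random.default_rng(seed)
    intervals = np.diff(onsets)
    total = float(intervals.sum())
    lo, hi = span
    slack = (hi - lo) - total
    if slack < 0:
        raise ValueError("span shorter than the seizure sequence it must contain")
    reps = []
    for _ in range(n_reps):
        perm = rng.permutation(intervals) if intervals.size else intervals
        start = lo + rng.uniform(0.0, slack)
        reps.append(start + np.concatenate([[0.0], np.cumsum(perm)]))
    return SurrogateSet(reps, seed)


def improvement_over_chance(sensitivity: float, chance: ChanceModel) -> float:
    """Observed minus chance sensitivity at equal time in warning."""
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must be in [0, 1]")
    return float(sensitivity - chance.hit_probability)
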