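"""Posterior density linking the utility model to observed avoidance indices.

The sampler needs p(theta | y) up to a constant.  With a uniform prior on
the box [lower, upper] and a Gaussian error model whose variance is
marginalised analytically, the log posterior for theta = (alpha, beta) is

    log p(theta | y) = -(N/2) * log(SSE(theta))      (in-bounds)
                     = -inf                          (out of bounds)

where SSE is the sum of squared residuals between the observed AI series
and the capped model prediction, and N the number of observations.  A
floor on SSE guards the noiseless-data singularity SSE -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import AISeries
from .model import UtilityParams, avoidance_curve

__all__ = ["Dataset", "ParamBounds", "residuals", "sse", "log_posterior", "SSE_FLOOR"]

SSE_FLOOR = 1e-12


@dataclass(frozen=True)
class Dataset:
    """An observed AI time series at one light intensity."""

    observations: AISeries
    intensity: float

    def __post_init__(self) -> None:
        if len(self.observations) == 0:
            raise ValueError("dataset must be nonempty")
        if np.any(self.observations.times <= 0):
            raise ValueError("observation times must be > 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class ParamBounds:
    """Interval vectors (lower, upper) bounding the parameter box."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.shape != upper.shape:
            raise ValueError("lower and upper must have the same shape")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        if np.any(lower >= upper):
            raise ValueError("lower must be < upper componentwise")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def n_params(self) -> int:
        return len(self.lower)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


def residuals(u: UtilityParams, d: Dataset) -> np.ndarray:
    """Observed AI minus capped model prediction, elementwise."""
    predicted = avoidance_curve(u.alpha, u.beta, d.intensity, d.observations.times)
    return d.observations.ai - predicted


def sse(theta, d: Dataset) -> float:
    """Sum of squared residuals at theta = (alpha, beta); capped prediction."""
    alpha, beta = np.asarray(theta, dtype=float)
    predicted = avoidance_curve(alpha, beta, d.intensity, d.observations.times)
    r = d.observations.ai - predicted
    return float(r @ r)


def log_posterior(theta, d: Dataset, b: ParamBounds, sse_floor: float = SSE_FLOOR) -> float:
    """Log posterior density; -inf outside [lower, upper], else -(N/2) log(SSE)."""
    theta = np.asarray(theta, dtype=float)
    if not b.contains(theta):
        return -np.inf
    n = len(d.observations)
    return -(n / 2.0) * np.log(max(sse(theta, d), sse_floor))
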