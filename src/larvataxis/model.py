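"""Diffusion solution and the light-intensity utility model.

The model treats the build-up of a *Drosophila* larva's drive to leave the
lit half of a test plate as the concentration profile of a substance
diffusing from a constant source.  Fick's second law on a semi-infinite
domain with a constant-concentration boundary has the closed-form solution

    V(x, t) = Vs * [1 - erf(x / (2 * sqrt(D * t)))]

and the behavioural model inherits that shape: photophobia after ``t``
minutes of exposure to light of intensity ``l`` lux is

    f(t) = alpha * l * [1 - erf(beta / sqrt(t))]

with the avoidance index capped at 1 once every larva has reached the dark
half (the animals then receive no further stimulus).  ``alpha`` (AI per
lux) and ``beta`` (min^1/2) are free phenomenological constants estimated
from data; no mapping onto the physical Vs, D, x is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "DiffusionParams",
    "UtilityParams",
    "LightExposure",
    "PredictionCurve",
    "concentration_profile",
    "utility_raw",
    "cap_avoidance",
    "avoidance_curve",
    "predict_series",
    "predict_intensity_response",
    "write_predictions_csv",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the semi-infinite diffusion solution.

    source_concentration
        Boundary concentration Vs (arbitrary units, > 0).
    diffusion_coefficient
        D, area per unit time (> 0).
    distance
        x, distance from the source (>= 0).
    """

    source_concentration: float
    diffusion_coefficient: float
    distance: float

    def __post_init__(self) -> None:
        if not self.source_concentration > 0:
            raise ValueError("source_concentration must be > 0")
        if not self.diffusion_coefficient > 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class UtilityParams:
    """The fitted constants of the utility model: alpha (AI/lux), beta (min^1/2)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")


@dataclass(frozen=True)
class LightExposure:
    """A light stimulus: intensity in lux (>= 0) and exposure time in minutes (> 0)."""

    intensity: float
    time: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not self.time > 0:
            raise ValueError("time must be > 0")


@dataclass(frozen=True)
class PredictionCurve:
    """Model output on a time grid: raw f(t) and the capped avoidance index."""

    times: np.ndarray
    raw_values: np.ndarray
    capped_values: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.raw_values) == len(self.capped_values)):
            raise ValueError("times, raw_values and capped_values must have equal length")


def concentration_profile(p: DiffusionParams, t) -> np.ndarray | float:
    """Concentration V(x, t) = Vs * [1 - erf(x / (2 sqrt(D t)))] at time(s) ``t`` > 0.

    The boundary conditions are built in: V -> Vs at x = 0 and V -> 0 as
    t -> 0+ for x > 0.  The value always lies in [0, Vs].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    arg = p.distance / (2.0 * np.sqrt(p.diffusion_coefficient * t))
    out = p.source_concentration * (1.0 - erf(arg))
    return float(out) if out.ndim == 0 else out


def utility_raw(u: UtilityParams, e: LightExposure) -> float:
    """Uncapped photophobia f(t) = alpha * l * [1 - erf(beta / sqrt(t))].

    Nonnegative, strictly increasing in t for l > 0, proportional to l,
    and saturating at alpha * l as t -> infinity.
    """
    if not e.time > 0:
        raise ValueError("exposure time must be > 0")
    return float(u.alpha * e.intensity * (1.0 - erf(u.beta / np.sqrt(e.time))))


def cap_avoidance(f) -> np.ndarray | float:
    """Apply the saturation rule: an avoidance index cannot exceed 1.

    Values of f above 1 mean every larva has already crossed into the dark
    half, so the observable AI is pinned at 1.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("f must be >= 0")
    out = np.minimum(f, 1.0)
    return float(out) if out.ndim == 0 else out


def avoidance_curve(alpha: float, beta: float, intensity: float, times) -> np.ndarray:
    """Vectorised capped model curve, permissive at the alpha = 0 / beta = 0 edges.

    The strict ``UtilityParams`` type excludes zero, but samplers exploring a
    prior box [0, hi] may evaluate the boundary; the model is well defined
    there (f = alpha * l at beta = 0, f = 0 at alpha = 0).
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    raw = alpha * intensity * (1.0 - erf(beta / np.sqrt(times)))
    return np.minimum(raw, 1.0)


def _validate_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid is empty")
    if np.any(times <= 0):
        raise ValueError("all grid times must be > 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return times


def predict_series(u: UtilityParams, intensity: float, times) -> PredictionCurve:
    """Evaluate the model on a strictly increasing time grid at one intensity."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    times = _validate_grid(times)
    raw = u.alpha * intensity * (1.0 - erf(u.beta / np.sqrt(times)))
    return PredictionCurve(times=times, raw_values=raw, capped_values=cap_avoidance(raw))


def predict_intensity_response(
    u: UtilityParams, intensities, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and capped model AI across light intensities at a fixed exposure time.

    Below the cap the response is exactly linear in intensity.
    Returns ``(raw, capped)`` arrays, one entry per intensity.
    """
    if not t > 0:
        raise ValueError("t must be > 0")
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities < 0):
        raise ValueError("intensities must be >= 0")
    raw = u.alpha * intensities * (1.0 - erf(u.beta / np.sqrt(t)))
    return raw, cap_avoidance(raw)


def write_predictions_csv(path, times, intensity, raw, capped) -> None:
    """Write predictions with header ``time_min,intensity_lux,f_raw,ai_capped``."""
    t, l, r, c = np.broadcast_arrays(
        np.asarray(times, dtype=float),
        np.asarray(intensity, dtype=float),
        np.asarray(raw, dtype=float),
        np.asarray(capped, dtype=float),
    )
    frame = pd.DataFrame(
        {"time_min": t, "intensity_lux": l, "f_raw": r, "ai_capped": c}
    )
    frame.to_csv(path, index=False)
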