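"""Avoidance-index arithmetic, reference data, and a synthetic plate assay.

The light/dark choice assay: 20 early third-instar larvae on an 8 cm agar
plate, one half shaded, counted after (or during) an 11-minute test.  The
avoidance index is

    AI = (N_dark - N_light) / (N_dark + N_light)

ranging from -1 (all larvae in the light half) to +1 (all in the dark).
For dynamics experiments the light-half count is taken every 0.5 min.

The synthetic generator emulates that dynamics assay: at each grid time t
the number of larvae in the dark half is drawn Binomial(n, p(t)) with
p(t) = (AI_model(t) + 1) / 2, i.e. counts fluctuate binomially around the
capped model curve.  Counts are drawn independently across time points; a
real larva's position is autocorrelated, so this is a deliberately minimal
noise model (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import UtilityParams, avoidance_curve

__all__ = [
    "CountRecord",
    "AISeries",
    "IntensityTable",
    "AssayConfig",
    "ai_from_counts",
    "simulate_dynamics",
    "reference_data",
    "REFERENCE_INTENSITIES_LUX",
    "REFERENCE_AI",
    "FITTED_ALPHA",
    "FITTED_BETA",
    "write_counts_csv",
    "read_counts_csv",
    "write_ai_csv",
    "read_ai_csv",
]

# Experimental w1118 avoidance indices at five light intensities, and the
# (alpha, beta) fitted to the 550-lux dynamics data in the study that
# introduced this model.  These constants drive all reference predictions.
REFERENCE_INTENSITIES_LUX = (150.0, 350.0, 550.0, 750.0, 950.0)
REFERENCE_AI = (0.2, 0.4, 0.7, 0.8, 0.9)
FITTED_ALPHA = 0.001459
FITTED_BETA = 0.56532


@dataclass(frozen=True)
class CountRecord:
    """Larva counts on the two plate halves at one observation time."""

    time: float
    n_dark: int
    n_light: int

    def __post_init__(self) -> None:
        for name in ("n_dark", "n_light"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")


@dataclass(frozen=True)
class AISeries:
    """Time-indexed avoidance indices; times strictly increasing, AI in [-1, 1]."""

    times: np.ndarray
    ai: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ai = np.asarray(self.ai, dtype=float)
        if len(times) != len(ai):
            raise ValueError("times and ai must have equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(ai) > 1 + 1e-12):
            raise ValueError("avoidance indices must lie in [-1, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ai", ai)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class IntensityTable:
    """Avoidance index per light intensity; intensities strictly increasing."""

    intensities: np.ndarray
    ai: np.ndarray

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        ai = np.asarray(self.ai, dtype=float)
        if len(intensities) != len(ai):
            raise ValueError("intensities and ai must have equal length")
        if np.any(np.diff(intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")
        if np.any(np.abs(ai) > 1 + 1e-12):
            raise ValueError("avoidance indices must lie in [-1, 1]")
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "ai", ai)


@dataclass(frozen=True)
class AssayConfig:
    """Plate-assay parameters.

    Defaults reproduce the standard protocol: 20 larvae, 11-minute test,
    counts every half minute (a 22-point grid starting at t = 0.5 min; the
    model is undefined at t = 0, and the assay starts with all larvae in
    the light half anyway, which the model does not describe).
    """

    intensity: float
    seed: int
    n_larvae: int = 20
    duration: float = 11.0
    interval: float = 0.5

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if not self.interval > 0:
            raise ValueError("interval must be > 0")
        if self.duration < self.interval:
            raise ValueError("duration must be >= interval")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.interval + 1e-9))
        return self.interval * np.arange(1, n + 1)


def ai_from_counts(r: CountRecord) -> float:
    """AI = (N_dark - N_light) / (N_dark + N_light); requires at least one larva."""
    total = r.n_dark + r.n_light
    if total <= 0:
        raise ValueError("cannot score a record with zero larvae")
    return (r.n_dark - r.n_light) / total


def simulate_dynamics(
    u: UtilityParams, c: AssayConfig, noise: bool = True
) -> tuple[list[CountRecord] | None, AISeries]:
    """Synthetic dynamics assay: binomial half-plate counts around the model curve.

    With ``noise=True`` (default), at each grid time t the dark-half count is
    Binomial(n_larvae, p(t)) with p(t) = (AI_model(t) + 1)/2, and the AI is
    recomputed from the counts; identical seeds give identical series.  With
    ``noise=False`` the returned series is exactly the capped model curve and
    no counts are produced (the expectation is generally not an integer).
    """
    times = c.time_grid()
    curve = avoidance_curve(u.alpha, u.beta, c.intensity, times)
    if not noise:
        return None, AISeries(times=times, ai=curve)
    p = (curve + 1.0) / 2.0
    rng = np.random.default_rng(c.seed)
    n_dark = rng.binomial(c.n_larvae, p)
    records = [
        CountRecord(time=float(t), n_dark=int(d), n_light=int(c.n_larvae - d))
        for t, d in zip(times, n_dark)
    ]
    ai = np.array([ai_from_counts(r) for r in records])
    return records, AISeries(times=times, ai=ai)


def reference_data() -> tuple[IntensityTable, UtilityParams]:
    """The embedded experimental intensity/AI table and the published fit (alpha, beta)."""
    table = IntensityTable(
        intensities=np.array(REFERENCE_INTENSITIES_LUX),
        ai=np.array(REFERENCE_AI),
    )
    return table, UtilityParams(alpha=FITTED_ALPHA, beta=FITTED_BETA)


# -- CSV dialects: comma-separated, UTF-8, no index column ------------------


def write_counts_csv(path, records: list[CountRecord]) -> None:
    """Header ``time_min,n_dark,n_light``."""
    pd.DataFrame(
        {
            "time_min": [r.time for r in records],
            "n_dark": [r.n_dark for r in records],
            "n_light": [r.n_light for r in records],
        }
    ).to_csv(path, index=False)


def read_counts_csv(path) -> list[CountRecord]:
    frame = pd.read_csv(path)
    _require_columns(frame, ("time_min", "n_dark", "n_light"), path)
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                CountRecord(
                    time=float(row["time_min"]),
                    n_dark=int(row["n_dark"]),
                    n_light=int(row["n_light"]),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return records


def write_ai_csv(path, series: AISeries) -> None:
    """Header ``time_min,ai``."""
    pd.DataFrame({"time_min": series.times, "ai": series.ai}).to_csv(path, index=False)


def read_ai_csv(path) -> AISeries:
    frame = pd.read_csv(path)
    _require_columns(frame, ("time_min", "ai"), path)
    values = np.column_stack(
        [pd.to_numeric(frame[c], errors="coerce").to_numpy() for c in ("time_min", "ai")]
    )
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}, line {bad[0] + 2}: non-numeric or missing value")
    return AISeries(times=values[:, 0], ai=values[:, 1])


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}, line 1: missing column(s) {', '.join(missing)}")
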