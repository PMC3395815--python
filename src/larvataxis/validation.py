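"""Model-adequacy statistics: error moments, R-squared, and the F-test.

Errors follow the convention ``observed - predicted`` and standard
deviations use the sample (n-1) denominator.  The F statistic is the
simple-regression form F = R^2 (n-2) / (1 - R^2) on (1, n-2) degrees of
freedom, compared against the upper quantile of the F distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "ErrorStats",
    "FitQuality",
    "error_stats",
    "r_squared",
    "f_statistic",
    "f_critical",
    "validate_fit",
    "round_half_up",
    "write_validation_report",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, used only when reporting against printed values."""
    if math.isinf(x) or math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ErrorStats:
    """The four error moments, in AI units."""

    mean_error: float
    std_error: float
    mean_abs_error: float
    std_abs_error: float


@dataclass(frozen=True)
class FitQuality:
    """Determination coefficient and F-test outcome."""

    r_squared: float
    f_value: float
    f_critical: float
    passes_f_test: bool
    n_points: int


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 2:
        raise ValueError("need at least 2 points")
    return observed, predicted


def error_stats(observed, predicted) -> ErrorStats:
    """Mean/std of error and absolute error, error = observed - predicted."""
    observed, predicted = _check_pair(observed, predicted)
    err = observed - predicted
    return ErrorStats(
        mean_error=float(err.mean()),
        std_error=float(err.std(ddof=1)),
        mean_abs_error=float(np.abs(err).mean()),
        std_abs_error=float(np.abs(err).std(ddof=1)),
    )


def r_squared(observed, predicted) -> float:
    """Determination coefficient 1 - SSE/SST, SST about the observed mean."""
    observed, predicted = _check_pair(observed, predicted)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst

def f_statistic(r2: float, n: int) -> float:
    """F = R^2 (n-2) / (1 - R^2) on (1, n-2) degrees of freedom.

    A perfect fit (R^2 = 1) returns the +inf sentinel.
    """
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    if r2 == 1:
        return math.inf
    return r2 * (n - 2) / (1.0 - r2)


def f_critical(alpha_level: float, df1: int, df2: int) -> float:
    """Upper alpha_level quantile of the F(df1, df2) distribution."""
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(1.0 - alpha_level, df1, df2))


def validate_fit(observed, predicted, alpha_level: float = 0.01) -> tuple[FitQuality, ErrorStats]:
    """Full adequacy report: R^2, F-test at ``alpha_level``, and error moments."""
    observed, predicted = _check_pair(observed, predicted)
    if observed.size < 3:
        raise ValueError("F-test needs at least 3 points")
    r2 = r_squared(observed, predicted)
    n = observed.size
    f_value = f_statistic(max(r2, 0.0), n)
    f_crit = f_critical(alpha_level, 1, n - 2)
    quality = FitQuality(
        r_squared=r2,
        f_value=f_value,
        f_critical=f_crit,
        passes_f_test=f_value > f_crit,
        n_points=int(n),
    )
    return quality, error_stats(observed, predicted)


def write_validation_report(path, quality: FitQuality, errors: ErrorStats,
                            alpha_level: float = 0.01) -> None:
    """JSON report mirroring the standard adequacy-statistics block."""
    report = {
        "alpha_level": alpha_level,
        "error_stats": asdict(errors),
        "fit_quality": asdict(quality),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
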