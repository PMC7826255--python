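"""Per-pattern repair kinetics: T50 estimation from 4-48 h time courses.

T50 is the time at which an editing pattern reaches half of its maximal
frequency.  The primary estimator is a bounded least-squares fit of the
saturation model

    f(t) = F_max * (1 - 2 ** (-t / T50))

for which T50 is a direct parameter (f(T50) = F_max / 2).  When the fit
fails to converge or leaves too much residual, the estimator falls back
to monotone linear interpolation of the 0.5 crossing on the normalized
curve (with an implicit (0, 0) anchor); the method used is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.optimize import curve_fit

from .core import DataError

__all__ = [
    "TimeCourse",
    "KineticFit",
    "CategoryT50Summary",
    "normalize_to_final",
    "check_eligibility",
    "fit_t50",
    "summarize_t50",
]

T50_BOUNDS = (1e-6, 96.0)
FMAX_BOUNDS = (1e-9, 1.0)
# Mean squared residual above this fraction of F_max^2 triggers the
# interpolation fallback.
DEFAULT_RSS_FRAC = 0.01
# The fitted half-crossing must be observed, not extrapolated: accept the
# least-squares T50 only if it lies within this fraction of the last
# sampled timepoint (slow, delayed patterns otherwise run to the bound
# with deceptively small residuals).
T50_ACCEPT_FRAC = 0.75
MAX_ABS_THRESHOLD = 0.01  # eligibility: peak absolute frequency must exceed 1%
INDEL_SHARE_THRESHOLD = 0.02  # and final share of total indels must exceed 2%


@dataclass(frozen=True)
class TimeCourse:
    """Frequency trajectory of one editing pattern.

    ``total_indels_final`` is the total edited fraction of the sample at
    the final timepoint; it anchors the share-of-indels eligibility rule.
    """

    pattern_id: str
    points: tuple[tuple[float, float], ...]  # (hours, frequency)
    total_indels_final: float = 1.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataError("timepoints must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for _, f in self.points):
            raise DataError("frequencies must lie in [0, 1]")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.points)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(f for _, f in self.points)

    @property
    def final_frequency(self) -> float:
        return self.points[-1][1]


@dataclass(frozen=True)
class KineticFit:
    pattern_id: str
    t50: float | None
    f_max: float | None
    rss: float | None
    method: str  # least_squares | interpolation | failed | ineligible
    eligible: bool


@dataclass(frozen=True)
class CategoryT50Summary:
    category: str
    mean_t50: float
    sd_t50: float
    n: int


def normalize_to_final(tc: TimeCourse) -> TimeCourse:
    """Divide every frequency by the final-timepoint frequency."""
    final = tc.final_frequency
    if final <= 0:
        raise DataError(f"pattern {tc.pattern_id!r}: final frequency is zero")
    points = tuple((t, min(f / final, 1.0)) for t, f in tc.points)
    return replace(tc, points=points)


def check_eligibility(tc: TimeCourse) -> bool:
    """Peak absolute frequency > 1% and final share of total indels > 2%."""
    peak = max(tc.frequencies, default=0.0)
    if peak <= MAX_ABS_THRESHOLD:
        return False
    if tc.total_indels_final <= 0:
        return False
    share = tc.final_frequency / tc.total_indels_final
    return share > INDEL_SHARE_THRESHOLD


def _model(t, f_max, t50):
    return f_max * (1.0 - np.exp2(-t / t50))


def _interpolate_half_crossing(tc: TimeCourse) -> float | None:
    """T50 by linear interpolation of the normalized curve crossing 0.5.

    The curve is anchored at (0, 0); a monotone envelope is applied so a
    noisy dip after the crossing cannot create a second crossing.
    """
    norm = normalize_to_final(tc)
    times = (0.0,) + norm.times
    freqs = (0.0,) + tuple(np.maximum.accumulate(norm.frequencies))
    for (t0, f0), (t1, f1) in zip(zip(times, freqs), zip(times[1:], freqs[1:])):
        if f0 < 0.5 <= f1:
            if f1 == f0:
                return t1
            return t0 + (t1 - t0) * (0.5 - f0) / (f1 - f0)
    return None


def fit_t50(
    tc: TimeCourse,
    rss_frac: float = DEFAULT_RSS_FRAC,
    require_eligible: bool = True,
) -> KineticFit:
    """Estimate T50 for one pattern trajectory.

    Requires >= 4 timepoints.  Ineligible patterns (see
    :func:`check_eligibility`) are returned unfitted unless
    ``require_eligible`` is False.
    """
    eligible = check_eligibility(tc)
    if require_eligible and not eligible:
        return KineticFit(tc.pattern_id, None, None, None, "ineligible", False)
    if len(tc.points) < 4:
        raise DataError("need at least 4 timepoints to fit T50")

    t = np.asarray(tc.times, dtype=float)
    f = np.asarray(tc.frequencies, dtype=float)
    f_max0 = float(f.max())
    t50_0 = _interpolate_half_crossing(tc) if tc.final_frequency > 0 else None

    params = None
    rss = math.inf
    if f_max0 > 0:
        p0 = (f_max0, t50_0 if t50_0 is not None else float(np.median(t)))
        try:
            popt, _ = curve_fit(
                _model,
                t,
                f,
                p0=p0,
                bounds=((FMAX_BOUNDS[0], T50_BOUNDS[0]), (FMAX_BOUNDS[1], T50_BOUNDS[1])),
                maxfev=10000,
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            params = (float(popt[0]), float(popt[1]))
            rss = float(np.sum((f - _model(t, *popt)) ** 2))
        except (RuntimeError, ValueError):
            params = None

    if params is not None:
        exact = rss <= 1e-10 * len(t) * max(params[0] ** 2, 1e-12)
        plausible = (
            rss <= rss_frac * len(t) * params[0] ** 2
            and params[1] <= T50_ACCEPT_FRAC * t[-1]
        )
        if exact or plausible:
            return KineticFit(
                tc.pattern_id, params[1], params[0], rss, "least_squares", eligible
            )

    # Fallback: interpolation on the normalized curve.
    if tc.final_frequency > 0 and t50_0 is not None:
        return KineticFit(
            tc.pattern_id,
            t50_0,
            f_max0,
            rss if params is not None else None,
            "interpolation",
            eligible,
        )
    return KineticFit(tc.pattern_id, None, None, None, "failed", eligible)


def summarize_t50(
    fits: Iterable[tuple[str, KineticFit]],
) -> list[CategoryT50Summary]:
    """Per-category mean +/- sample sd of eligible, successful T50 fits.

    ``fits`` is an iterable of (category label, fit).  Categories with no
    eligible fit are omitted.  A single fit reports sd = 0.
    """
    by_cat: dict[str, list[float]] = {}
    for category, fit in fits:
        if category is None or not fit.eligible or fit.t50 is None:
            continue
        by_cat.setdefault(category, []).append(fit.t50)
    out = []
    for category in sorted(by_cat):
        values = by_cat[category]
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        out.append(CategoryT50Summary(category, mean, sd, len(values)))
    return out
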