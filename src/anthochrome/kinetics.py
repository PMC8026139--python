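"""First-order color-loss kinetics for pigment stability time courses.

A stability series tracks the absorbance at λmax over days; fading is
modeled mono-exponentially, A(t) = A0·e^(−kt), and summarized as a rate
constant k (per day), a half-life ln2/k, and the percent loss
100·(1 − A(t)/A(0)) at a time of interest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DecaySeries", "DecayFit", "fit_first_order", "percent_loss"]


@dataclass(frozen=True)
class DecaySeries:
    """Absorbance at λmax over non-negative, strictly increasing days."""

    time_days: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_days, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time_days", t)
        object.__setattr__(self, "absorbance", a)
        if t.size != a.size:
            raise ValueError("time and absorbance must have equal length")
        if t.size and t[0] < 0:
            raise ValueError("time must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class DecayFit:
    """Mono-exponential fit A(t) = A0·e^(−kt); k ≥ 0 by construction."""

    k_per_day: float
    A0: float
    n: int

    @property
    def half_life_days(self) -> float:
        return math.inf if self.k_per_day == 0 else math.log(2.0) / self.k_per_day

    def absorbance_at(self, t_days: float) -> float:
        return self.A0 * math.exp(-self.k_per_day * t_days)

    def to_dict(self) -> dict:
        return {
            "k_per_day": self.k_per_day,
            "half_life_days": self.half_life_days,
            "A0": self.A0,
            "n": self.n,
        }


def fit_first_order(d: DecaySeries) -> DecayFit:
    """Least-squares mono-exponential fit with the rate bounded at k ≥ 0.

    Starting values come from a log-linear regression (exact for noiseless
    data).  An all-equal series short-circuits to k = 0 with an infinite
    half-life.
    """
    t, a = d.time_days, d.absorbance
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(a <= 0):
        raise ValueError("absorbances must be positive for a first-order fit")
    if np.allclose(a, a[0], rtol=0, atol=0):
        return DecayFit(k_per_day=0.0, A0=float(a[0]), n=int(t.size))
    # log-linear initialization: ln A = ln A0 − k t
    slope, intercept = np.polyfit(t, np.log(a), 1)
    k0 = max(-float(slope), 0.0)
    a0 = float(np.exp(intercept))
    popt, _ = curve_fit(
        lambda tt, A0, k: A0 * np.exp(-k * tt),
        t,
        a,
        p0=[a0, k0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    return DecayFit(k_per_day=float(popt[1]), A0=float(popt[0]), n=int(t.size))


def percent_loss(d: DecaySeries | DecayFit, t_days: float) -> float:
    """Percent of initial absorbance lost by day ``t_days``.

    Uses the fitted model: 100·(1 − e^(−kt)).  A ``DecaySeries`` is fitted
    first.  Extrapolation beyond the observed span is allowed but warned
    about.
    """
    if isinstance(d, DecaySeries):
        if t_days > d.time_days[-1]:
            warnings.warn(
                f"t = {t_days} d extrapolates beyond the observed span "
                f"({d.time_days[-1]} d)",
                stacklevel=2,
            )
        fit = fit_first_order(d)
    else:
        fit = d
    if fit.A0 <= 0:
        raise ValueError("A(0) must be positive")
    return 100.0 * (1.0 - math.exp(-fit.k_per_day * t_days))
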