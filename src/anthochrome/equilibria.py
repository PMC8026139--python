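"""Flavylium multistate speciation vs pH and apparent-pK′h fitting.

Anthocyanins interconvert among a red flavylium cation (AH⁺), colored
quinoidal bases (A), and colorless hydration products (hemiketal B and
chalcones C).  Lumping the colorless species through an apparent hydration
constant pK′h and the deprotonation through pKa gives the colored fraction

    f(pH) = (1 + 10^(pH − pKa)) / (1 + 10^(pH − pKa) + 10^(pH − pK′h))

A higher pK′h means the pigment resists water addition at C2 and keeps its
color to higher pH.  In the acidic regime (quinoidal base negligible) the
absorbance at fixed wavelength follows the two-parameter sigmoid
A(pH) = A0 / (1 + 10^(pH − pK′h)), which is the model ``fit_pkh`` fits —
the conventional way an apparent hydration constant is measured from
equilibrium-endpoint absorbances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from lmfit import Model

__all__ = [
    "MultistateParams",
    "TitrationSeries",
    "PkhFit",
    "colored_fraction",
    "simulate_titration",
    "fit_pkh",
]


@dataclass(frozen=True)
class MultistateParams:
    """Lumped equilibrium constants of the flavylium multistate.

    ``pKa`` — flavylium → quinoidal base acidity constant (log units).
    ``pKh_prime`` — apparent hydration constant lumping hemiketal and
    chalcones (log units).  ``math.inf`` for ``pKa`` disables deprotonation
    (pure hydration sigmoid).
    """

    pKa: float
    pKh_prime: float

    def __post_init__(self) -> None:
        for name, v in (("pKa", self.pKa), ("pKh_prime", self.pKh_prime)):
            if math.isnan(v):
                raise ValueError(f"{name} must not be NaN")
            if v != math.inf and not (0.0 <= v <= 10.0):
                warnings.warn(
                    f"{name} = {v} is outside the typical 0-10 range",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class TitrationSeries:
    """Absorbance at a fixed wavelength across a strictly increasing pH grid."""

    pH: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    sample_id: str = ""
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ph = np.asarray(self.pH, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "pH", ph)
        object.__setattr__(self, "absorbance", ab)
        if ph.size != ab.size:
            raise ValueError("pH and absorbance must have equal length")
        if np.any(np.diff(ph) <= 0):
            raise ValueError("pH must be strictly increasing")


def colored_fraction(pH, p: MultistateParams):
    """Fraction of colored forms (flavylium + quinoidal base) at ``pH``.

    Accepts a scalar or array pH; always in [0, 1] and monotone
    non-increasing in pH.
    """
    ph = np.asarray(pH, dtype=float)
    acid = np.zeros_like(ph) if math.isinf(p.pKa) else 10.0 ** (ph - p.pKa)
    hyd = 10.0 ** (ph - p.pKh_prime)
    out = (1.0 + acid) / (1.0 + acid + hyd)
    return float(out) if np.isscalar(pH) else out


def simulate_titration(
    p: MultistateParams,
    pH_grid,
    A0: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    wavelength_nm: float = 640.0,
    sample_id: str = "",
) -> TitrationSeries:
    """Simulate equilibrium-endpoint absorbances A(pH) = A0·f(pH) + noise.

    Gaussian noise of standard deviation ``noise_sd`` is drawn from a
    generator seeded with ``seed``; the same seed reproduces the series
    bit for bit.
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ph = np.asarray(pH_grid, dtype=float)
    a = A0 * colored_fraction(ph, p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=ph.size)
    return TitrationSeries(
        pH=ph,
        absorbance=a,
        wavelength_nm=wavelength_nm,
        sample_id=sample_id,
        metadata={"pKa": p.pKa, "pKh_prime": p.pKh_prime, "A0": A0,
                  "noise_sd": noise_sd, "seed": seed},
    )


@dataclass(frozen=True)
class PkhFit:
    """Result of a hydration-sigmoid fit."""

    pKh_prime: float
    pKh_stderr: float | None
    A0: float
    A0_stderr: float | None
    n: int
    converged: bool
    transition_spanned: bool

    @property
    def ci95(self) -> tuple[float, float] | None:
        if self.pKh_stderr is None:
            return None
        return (
            self.pKh_prime - 1.96 * self.pKh_stderr,
            self.pKh_prime + 1.96 * self.pKh_stderr,
        )

    def to_dict(self) -> dict:
        return {
            "estimate": self.pKh_prime,
            "stderr": self.pKh_stderr,
            "CI95": list(self.ci95) if self.ci95 else None,
            "A0": self.A0,
            "A0_stderr": self.A0_stderr,
            "n": self.n,
            "converged": self.converged,
            "transition_spanned": self.transition_spanned,
        }


def _sigmoid(pH, A0, pKh):
    return A0 / (1.0 + 10.0 ** (pH - pKh))


def fit_pkh(data: TitrationSeries) -> PkhFit:
    """Nonlinear least-squares fit of A(pH) = A0 / (1 + 10^(pH − pK′h)).

    Starting values are data-driven and deterministic: A0 at the maximum
    absorbance, pK′h at the pH where the absorbance first crosses half of
    that maximum (linear interpolation).  A fit whose data do not span the
    transition is flagged (``transition_spanned=False``) rather than
    rejected; non-convergence raises.
    """
    if data.pH.size < 5:
        raise ValueError("need at least 5 titration points")
    a = data.absorbance
    a0_init = float(np.max(a))
    if a0_init <= 0:
        raise ValueError("absorbances must contain positive values")
    half = a0_init / 2.0
    below = np.nonzero(a <= half)[0]
    if below.size and below[0] > 0:
        i = below[0]
        frac = (a[i - 1] - half) / (a[i - 1] - a[i])
        pkh_init = float(data.pH[i - 1] + frac * (data.pH[i] - data.pH[i - 1]))
    else:
        pkh_init = float(np.median(data.pH))
    spanned = bool(np.min(a) < 0.25 * a0_init and np.max(a) > 0.75 * a0_init)

    model = Model(_sigmoid)
    params = model.make_params(A0=a0_init, pKh=pkh_init)
    result = model.fit(a, params, pH=data.pH)
    if not result.success:
        raise RuntimeError(
            f"hydration fit did not converge (last iterate pKh="
            f"{result.params['pKh'].value:.4f})"
        )
    pkh = result.params["pKh"]
    a0 = result.params["A0"]
    return PkhFit(
        pKh_prime=float(pkh.value),
        pKh_stderr=None if pkh.stderr is None else float(pkh.stderr),
        A0=float(a0.value),
        A0_stderr=None if a0.stderr is None else float(a0.stderr),
        n=int(data.pH.size),
        converged=True,
        transition_spanned=spanned,
    )
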