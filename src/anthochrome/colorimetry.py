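"""Transmission colorimetry: absorbance → XYZ → CIELAB, hue angle, ΔE*ab.

The chain mirrors how a solution colorant is judged against a reference
shade: Beer–Lambert converts absorbance to transmittance, the CIE 1931 2°
standard observer weighted by an illuminant (D65 by default) integrates
transmittance to tristimulus XYZ, and CIELAB provides the perceptual axes
(L* lightness, a* green–red, b* blue–yellow).  Hue angle
h = atan2(b*, a*) is the quantity used for colorant matching; ΔE*ab (CIE76)
gives the overall color difference.

The 5-nm CIE 1931 2° color-matching functions and the D65 spectral power
distribution ship with the package (``data/``) and are interpolated to the
configured wavelength step; no tables are downloaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import Spectrum, resample

__all__ = [
    "LabColor",
    "ColorimetrySettings",
    "absorbance_to_transmittance",
    "spectrum_to_xyz",
    "whitepoint",
    "xyz_to_lab",
    "hue_chroma",
    "delta_e76",
    "color_report",
]

_CMF_FILE = "cie_1931_2deg_cmf_5nm.csv"
_ILLUMINANTS = {"D65": "illuminant_d65_5nm.csv", "E": None}


@dataclass(frozen=True)
class LabColor:
    """A CIE 1976 L*a*b* color."""

    L_star: float
    a_star: float
    b_star: float


@dataclass(frozen=True)
class ColorimetrySettings:
    """Observer/illuminant configuration for the XYZ integration.

    The defaults (CIE 1931 2° observer, illuminant D65, 1-nm step) are
    explicit configuration, not measurement metadata: transmission
    colorimetry of a solution depends on the chosen viewing model.
    ``path_scale`` rescales absorbance before the Beer–Lambert transform
    (e.g. 0.1 to predict the color of a 1-mm path from a 10-mm spectrum).
    """

    observer: str = "cie_1931_2deg"
    illuminant: str = "D65"
    wavelength_step_nm: float = 1.0
    path_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.observer != "cie_1931_2deg":
            raise ValueError(f"unknown observer {self.observer!r}")
        if self.illuminant not in _ILLUMINANTS:
            raise ValueError(
                f"unknown illuminant {self.illuminant!r}; "
                f"available: {sorted(_ILLUMINANTS)}"
            )
        if self.wavelength_step_nm <= 0 or self.path_scale <= 0:
            raise ValueError("wavelength_step_nm and path_scale must be positive")


@lru_cache(maxsize=None)
def _load_table(name: str) -> pd.DataFrame:
    with resources.files("anthochrome.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=8)
def _tables(illuminant: str, step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(wavelength grid, CMF (n,3), illuminant power (n,)) at ``step`` nm."""
    grid = np.arange(380.0, 780.0 + step / 2, step)
    cmf = _load_table(_CMF_FILE)
    bars = np.column_stack(
        [
            np.interp(grid, cmf["wavelength_nm"], cmf[c])
            for c in ("xbar", "ybar", "zbar")
        ]
    )
    if illuminant == "E":
        power = np.ones_like(grid)
    else:
        ill = _load_table(_ILLUMINANTS[illuminant])
        power = np.interp(grid, ill["wavelength_nm"], ill["relative_power"])
    return grid, bars, power


def absorbance_to_transmittance(s: Spectrum, path_scale: float = 1.0) -> Spectrum:
    """Beer–Lambert: T(λ) = 10^(−A(λ)·path_scale), clipped to [0, 1]."""
    if path_scale <= 0:
        raise ValueError("path_scale must be positive")
    t = np.clip(10.0 ** (-s.absorbance * path_scale), 0.0, 1.0)
    meta = dict(s.metadata)
    meta["quantity"] = "transmittance"
    meta["path_scale"] = path_scale
    return Spectrum(s.wavelengths_nm, t, meta)


def spectrum_to_xyz(
    t: Spectrum, cfg: ColorimetrySettings = ColorimetrySettings()
) -> tuple[float, float, float]:
    """Integrate a transmittance spectrum to tristimulus XYZ.

    X,Y,Z = k·Σ T(λ)·S(λ)·(x̄,ȳ,z̄)(λ)·Δλ with k chosen so that a perfect
    transmitter (T ≡ 1) has Y = 100.  The spectrum must cover 380–780 nm.
    """
    grid, bars, power = _tables(cfg.illuminant, cfg.wavelength_step_nm)
    if t.wavelengths_nm[0] > grid[0] or t.wavelengths_nm[-1] < grid[-1]:
        raise ValueError(
            f"transmittance must cover {grid[0]:.0f}-{grid[-1]:.0f} nm; got "
            f"[{t.wavelengths_nm[0]}, {t.wavelengths_nm[-1]}] nm"
        )
    tt = resample(t, grid).absorbance  # transmittance values on the CIE grid
    k = 100.0 / float(power @ bars[:, 1])
    weighted = (tt * power)[:, None] * bars
    x, y, z = (k * weighted.sum(axis=0)).tolist()
    return float(x), float(y), float(z)


def whitepoint(
    cfg: ColorimetrySettings = ColorimetrySettings(),
) -> tuple[float, float, float]:
    """XYZ of the configured illuminant (T ≡ 1), with Y = 100."""
    grid, bars, power = _tables(cfg.illuminant, cfg.wavelength_step_nm)
    k = 100.0 / float(power @ bars[:, 1])
    x, y, z = (k * (power[:, None] * bars).sum(axis=0)).tolist()
    return float(x), float(y), float(z)


def _f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def xyz_to_lab(
    xyz: tuple[float, float, float], wp: tuple[float, float, float]
) -> LabColor:
    """CIE 1976 L*a*b*, including the linear segment below (6/29)³."""
    xyz_arr = np.asarray(xyz, dtype=float)
    wp_arr = np.asarray(wp, dtype=float)
    if np.any(wp_arr <= 0):
        raise ValueError("whitepoint components must be positive")
    if np.any(xyz_arr < 0):
        raise ValueError("negative XYZ is not physically realizable")
    fx, fy, fz = _f(xyz_arr / wp_arr)
    return LabColor(
        L_star=float(116.0 * fy - 16.0),
        a_star=float(500.0 * (fx - fy)),
        b_star=float(200.0 * (fy - fz)),
    )


def hue_chroma(lab: LabColor) -> tuple[float | None, float]:
    """Hue angle in degrees in [0, 360) and chroma C* = √(a*²+b*²).

    On the neutral axis (a* = b* = 0) the hue is undefined and ``None`` is
    returned in its place.
    """
    chroma = math.hypot(lab.a_star, lab.b_star)
    if lab.a_star == 0.0 and lab.b_star == 0.0:
        return None, 0.0
    hue = math.degrees(math.atan2(lab.b_star, lab.a_star)) % 360.0
    return hue, chroma


def delta_e76(x: LabColor, y: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in L*a*b*."""
    return math.sqrt(
        (x.L_star - y.L_star) ** 2
        + (x.a_star - y.a_star) ** 2
        + (x.b_star - y.b_star) ** 2
    )


def color_report(
    s: Spectrum,
    cfg: ColorimetrySettings = ColorimetrySettings(),
    sample: str | None = None,
) -> dict:
    """Full absorbance→color summary for one spectrum, JSON-serialisable."""
    t = absorbance_to_transmittance(s, cfg.path_scale)
    xyz = spectrum_to_xyz(t, cfg)
    lab = xyz_to_lab(xyz, whitepoint(cfg))
    hue, chroma = hue_chroma(lab)
    return {
        "sample": sample or s.metadata.get("name", "unnamed"),
        "XYZ": list(xyz),
        "Lab": [lab.L_star, lab.a_star, lab.b_star],
        "hue_deg": hue,
        "chroma": chroma,
        "settings": {
            "observer": cfg.observer,
            "illuminant": cfg.illuminant,
            "wavelength_step_nm": cfg.wavelength_step_nm,
            "path_scale": cfg.path_scale,
        },
    }
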