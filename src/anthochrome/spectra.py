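"""Absorbance spectra: data model, CSV I/O, and spectral metrics.

The metrics implemented here are the ones used to characterise blue
colorants in solution:

* ``find_lambda_max`` — wavelength of the global absorbance maximum within
  an analysis window (default 400–700 nm, the visible band).
* ``violet_contribution`` — area under the absorbance curve between 500 and
  600 nm, computed as a left Riemann sum (height = absorbance, width =
  spectral resolution).  A low violet contribution means a purer cyan.
* ``bathochromic_shift`` — displacement of λmax between two spectra;
  positive values are red-shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralMetrics",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "find_lambda_max",
    "violet_contribution",
    "bathochromic_shift",
    "VISIBLE_WINDOW",
    "VC_WINDOW",
]

#: Default analysis window for λmax (nm): the visible band.
VISIBLE_WINDOW: tuple[float, float] = (400.0, 700.0)

#: Window over which the violet contribution is integrated (nm).
VC_WINDOW: tuple[float, float] = (500.0, 600.0)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed absorbance series.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres (at least 2 points).
    absorbance
        Absorbance in AU, same length.  Values may be negative (baseline
        noise is not clipped).
    metadata
        Free-form record (sample name, pH, Al equivalents, path length...).
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1:
            raise ValueError("wavelengths and absorbance must be 1-D")
        if wl.size != ab.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {ab.size} absorbances"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def resolution_nm(self) -> float:
        """Median grid spacing in nm."""
        return float(np.median(np.diff(self.wavelengths_nm)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.wavelengths_nm)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass(frozen=True)
class SpectralMetrics:
    """λmax, the absorbance at λmax, and (optionally) the violet contribution."""

    lambda_max_nm: float
    a_max: float
    violet_contribution: float | None = None

    def __post_init__(self) -> None:
        if self.violet_contribution is not None and not math.isfinite(
            self.violet_contribution
        ):
            raise ValueError("violet_contribution must be finite")


def read_spectrum(
    path: str | Path, metadata: Mapping[str, Any] | None = None
) -> Spectrum:
    """Read a two-column CSV (wavelength_nm, absorbance).

    A single optional header line is auto-detected.  Rows are sorted by
    wavelength; duplicate wavelengths raise, and non-numeric data rows
    raise with the offending line number.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    df = pd.DataFrame(rows, columns=["wavelength_nm", "absorbance"])
    if df["wavelength_nm"].duplicated().any():
        dups = df.loc[df["wavelength_nm"].duplicated(), "wavelength_nm"].tolist()
        raise ValueError(f"{path}: duplicate wavelengths {dups}")
    df = df.sort_values("wavelength_nm")
    meta = dict(metadata or {})
    meta.setdefault("path", str(path))
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(), meta)


def write_spectrum(s: Spectrum, path: str | Path, header: bool = True) -> None:
    """Write a spectrum as a two-column CSV at 6 significant digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write("wavelength_nm,absorbance\n")
        for wl, ab in zip(s.wavelengths_nm, s.absorbance):
            fh.write(f"{wl:.6g},{ab:.6g}\n")


def resample(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    Points of the original grid are reproduced exactly when they appear in
    the target grid.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavelengths_nm[0], s.wavelengths_nm[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"resample grid [{grid[0]}, {grid[-1]}] extends beyond spectrum "
            f"support [{lo}, {hi}]; extrapolation is not performed"
        )
    values = np.interp(grid, s.wavelengths_nm, s.absorbance)
    return Spectrum(grid, values, dict(s.metadata))


def _window_slice(s: Spectrum, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (s.wavelengths_nm >= lo) & (s.wavelengths_nm <= hi)
    if not mask.any():
        raise ValueError(
            f"analysis window [{lo}, {hi}] nm does not overlap spectrum support "
            f"[{s.wavelengths_nm[0]}, {s.wavelengths_nm[-1]}] nm"
        )
    return mask


def find_lambda_max(
    s: Spectrum, window: tuple[float, float] = VISIBLE_WINDOW
) -> SpectralMetrics:
    """Wavelength of the global absorbance maximum within ``window``.

    Ties on the sampled grid are broken toward the *longer* wavelength so
    plateaus give a deterministic answer.
    """
    mask = _window_slice(s, window)
    wl = s.wavelengths_nm[mask]
    ab = s.absorbance[mask]
    # argmax of the reversed array → last (longest-wavelength) maximum
    idx = ab.size - 1 - int(np.argmax(ab[::-1]))
    return SpectralMetrics(lambda_max_nm=float(wl[idx]), a_max=float(ab[idx]))


def violet_contribution(
    s: Spectrum,
    vc_window: tuple[float, float] = VC_WINDOW,
    resample_step_nm: float = 1.0,
) -> float:
    """Left-Riemann area (nm·AU) of absorbance over ``vc_window``.

    The sum runs over left endpoints in [low, high): the upper edge itself
    contributes no rectangle.  Non-uniform grids are first resampled to a
    uniform ``resample_step_nm`` grid, since the rectangle width is the
    spectral resolution and presumes uniform sampling.  Absorbance is
    summed signed (negative baseline noise is not clipped).
    """
    lo, hi = vc_window
    if s.wavelengths_nm[0] > lo or s.wavelengths_nm[-1] < hi:
        missing = []
        if s.wavelengths_nm[0] > lo:
            missing.append(f"[{lo}, {min(s.wavelengths_nm[0], hi)}) nm")
        if s.wavelengths_nm[-1] < hi:
            missing.append(f"({max(s.wavelengths_nm[-1], lo)}, {hi}] nm")
        raise ValueError(
            "spectrum does not cover the violet-contribution window; "
            "missing " + " and ".join(missing)
        )
    if not s.is_uniform:
        n = int(round((s.wavelengths_nm[-1] - s.wavelengths_nm[0]) / resample_step_nm))
        grid = s.wavelengths_nm[0] + resample_step_nm * np.arange(n + 1)
        grid = grid[grid <= s.wavelengths_nm[-1] + 1e-12]
        s = resample(s, grid)
    step = float(s.wavelengths_nm[1] - s.wavelengths_nm[0])
    mask = (s.wavelengths_nm >= lo) & (s.wavelengths_nm < hi)
    return float(np.sum(s.absorbance[mask]) * step)


def bathochromic_shift(
    reference: Spectrum,
    shifted: Spectrum,
    window: tuple[float, float] = VISIBLE_WINDOW,
) -> float:
    """λmax(shifted) − λmax(reference) in nm; positive = red-shift."""
    return (
        find_lambda_max(shifted, window).lambda_max_nm
        - find_lambda_max(reference, window).lambda_max_nm
    )
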