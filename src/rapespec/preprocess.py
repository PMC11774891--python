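"""Spectral resampling and first-derivative computation.

All edge-based features downstream are defined on the first derivative of the
reflectance spectrum dR/dλ (units: reflectance · nm⁻¹), computed on the
canonical 1 nm grid. Instruments deliver spectra on their native grid
(e.g. ~4.95 nm spacing over 380–1091 nm); :func:`resample` moves them onto the
canonical 400–1000 nm grid by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

#: Canonical analysis grid: 400–1000 nm at 1 nm → 601 bands.
CANONICAL_GRID = np.arange(400.0, 1001.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: wavelengths (nm) and values (reflectance or dR/dλ)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D of equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Exact at shared nodes. Raises if ``grid`` extends beyond the spectrum's
    wavelength span — extrapolation is never silent.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("target grid is empty")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("target grid must be strictly increasing")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond spectrum span [{lo}, {hi}]; "
            "extrapolation is not supported"
        )
    if grid.size == spectrum.wavelengths.size and np.array_equal(grid, spectrum.wavelengths):
        return spectrum
    values = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, values)


def resample_matrix(wavelengths: np.ndarray, reflectance: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Row-wise :func:`resample` for an (n_seeds × n_bands) reflectance matrix."""
    grid = np.asarray(grid, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if grid[0] < wavelengths[0] or grid[-1] > wavelengths[-1]:
        raise ValueError("grid extends beyond spectrum span; extrapolation is not supported")
    out = np.empty((reflectance.shape[0], grid.size))
    for i, row in enumerate(reflectance):
        out[i] = np.interp(grid, wavelengths, row)
    return out


def first_derivative(spectrum: Spectrum, smooth: bool = False,
                     window_length: int = 11, polyorder: int = 2) -> Spectrum:
    """First derivative dR/dλ on a uniform grid.

    Central differences at interior points, one-sided at the endpoints
    (``np.gradient``), which is exact for quadratics at interior points.
    An optional Savitzky–Golay pre-smoothing is off by default.
    """
    wl, vals = spectrum.wavelengths, spectrum.values
    if wl.size < 3:
        raise ValueError("first derivative needs at least 3 points")
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0]):
        raise ValueError("first derivative requires a uniform wavelength grid")
    if smooth:
        vals = savgol_filter(vals, window_length=window_length, polyorder=polyorder)
    deriv = np.gradient(vals, wl)
    return Spectrum(wl, deriv)


def derivative_matrix(wavelengths: np.ndarray, reflectance: np.ndarray) -> np.ndarray:
    """Row-wise first derivative for an (n_seeds × n_bands) matrix."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size < 3:
        raise ValueError("first derivative needs at least 3 points")
    steps = np.diff(wavelengths)
    if not np.allclose(steps, steps[0]):
        raise ValueError("first derivative requires a uniform wavelength grid")
    return np.gradient(reflectance, wavelengths, axis=1)
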