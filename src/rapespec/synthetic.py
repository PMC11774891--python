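"""Synthetic seed-lot generator: coupled reflectance spectra and RGB triples.

No seed accession is publicly deposited for the yellow- vs dark-seeded
*Brassica napus* problem, so the pipeline is exercised on a statistical
emulator of a 300-seed lot. Each seed is a smooth sigmoidal reflectance
curve — low in the blue, rising through the red edge to a near-infrared
plateau — whose plateau height, edge position/steepness, and a visible-band
hump differ between the yellow-coated and dark-coated classes. Per-seed
jitter of those curve parameters provides within-class spectral variability;
i.i.d. measurement noise of ``spectrum_noise_sd`` is added on the emulated
native instrument grid before resampling onto the canonical 1 nm grid.

RGB is coupled to the spectrum through window means: each channel is an
affine function of the mean reflectance in a channel-relevant window
(blue 450–490, green 520–560, red 620–680 nm) plus Gaussian noise, scaled so
the class-conditional RGB means and SDs match the configured values. The
coupling strength per channel is chosen so that band combinations correlate
strongly with R and G but only weakly with B, mirroring the behaviour of real
seed lots where the two classes differ in red/green brightness but share
nearly identical blue values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import CANONICAL_GRID, resample_matrix

CHANNELS = ("R", "G", "B")

#: Class-conditional RGB statistics of the reference 300-seed lot
#: (103 yellow / 197 non-yellow).
REFERENCE_RGB_MEANS = {
    "yellow": (202.786, 135.796, 63.747),
    "nonyellow": (118.426, 79.061, 63.035),
}
REFERENCE_RGB_SDS = {
    "yellow": (16.737, 17.443, 6.065),
    "nonyellow": (31.735, 9.63, 6.673),
}

#: Spectrum→RGB coupling: channel-relevant window (nm) and within-class
#: correlation between the window mean and the channel value.
DEFAULT_COUPLING = {
    "R": {"window": (620.0, 680.0), "rho": 0.9},
    "G": {"window": (520.0, 560.0), "rho": 0.9},
    "B": {"window": (450.0, 490.0), "rho": 0.4},
}

#: Class-level curve parameters: NIR plateau, visible base, red-edge inflection
#: (nm), edge width (nm), and amplitude of the visible hump centred at 600 nm.
_CLASS_CURVES = {
    "yellow": {"base": 0.10, "plateau": 0.55, "edge": 650.0, "width": 40.0, "hump": 0.10},
    "nonyellow": {"base": 0.04, "plateau": 0.46, "edge": 705.0, "width": 28.0, "hump": 0.0},
}

#: Relative (or absolute, for edge position) SD of per-seed curve-parameter jitter.
_DEFAULT_JITTER = {"base": 0.10, "plateau": 0.06, "edge": 6.0, "width": 0.05, "hump": 0.15}

#: Native instrument grid emulated before resampling: 380–1091 nm at 4.9458 nm.
NATIVE_RESOLUTION = 4.9458


def native_grid(lo: float = 380.0, hi: float = 1091.0,
                step: float = NATIVE_RESOLUTION) -> np.ndarray:
    return np.arange(lo, hi + 1e-9, step)


@dataclass
class GeneratorConfig:
    n_samples: int = 300
    yellow_fraction: float = 103.0 / 300.0
    wavelength_grid: np.ndarray = field(default_factory=lambda: CANONICAL_GRID.copy())
    class_rgb_means: dict = field(default_factory=lambda: {k: tuple(v) for k, v in REFERENCE_RGB_MEANS.items()})
    class_rgb_sds: dict = field(default_factory=lambda: {k: tuple(v) for k, v in REFERENCE_RGB_SDS.items()})
    spectrum_noise_sd: float = 0.005
    param_jitter: dict = field(default_factory=lambda: dict(_DEFAULT_JITTER))
    coupling: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COUPLING.items()})
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if not np.isfinite(self.yellow_fraction) or not 0.0 <= self.yellow_fraction <= 1.0:
            raise ValueError("yellow_fraction must lie in [0, 1]")
        grid = np.asarray(self.wavelength_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("wavelength_grid is empty")
        if not np.all(np.isfinite(grid)) or (grid.size >= 2 and not np.all(np.diff(grid) > 0)):
            raise ValueError("wavelength_grid must be finite and strictly increasing")
        if not np.isfinite(self.spectrum_noise_sd) or self.spectrum_noise_sd < 0:
            raise ValueError("spectrum_noise_sd must be a finite non-negative number")
        for cls in ("yellow", "nonyellow"):
            means = np.asarray(self.class_rgb_means[cls], dtype=float)
            sds = np.asarray(self.class_rgb_sds[cls], dtype=float)
            if means.shape != (3,) or sds.shape != (3,):
                raise ValueError(f"class '{cls}' RGB means/sds must be triples")
            if not np.all(np.isfinite(means)) or not np.all(np.isfinite(sds)):
                raise ValueError(f"class '{cls}' RGB statistics must be finite")
            if np.any(sds < 0):
                raise ValueError(f"class '{cls}' RGB SDs must be non-negative")
        for ch in CHANNELS:
            spec = self.coupling[ch]
            lo, hi = spec["window"]
            if not lo < hi:
                raise ValueError(f"coupling window for {ch} must satisfy lo < hi")
            if not -1.0 <= spec["rho"] <= 1.0:
                raise ValueError(f"coupling rho for {ch} must lie in [-1, 1]")


@dataclass
class SampleSet:
    """n seeds × (shared wavelength grid, reflectance, RGB, optional label).

    ``label`` is a float vector with values in {0, 1} or NaN (unlabeled);
    1 marks the yellow-seeded (positive) class.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    rgb: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.label = np.asarray(self.label, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.reflectance.shape[0]
        if self.wavelengths.ndim != 1 or (self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0)):
            raise ValueError("wavelengths must be a strictly increasing 1-D vector")
        if self.reflectance.ndim != 2 or self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError("reflectance must be n × n_bands matching the grid")
        if not np.all(np.isfinite(self.reflectance)) or np.any(self.reflectance < 0):
            raise ValueError("reflectance must be finite and non-negative")
        if self.rgb.shape != (n, 3):
            raise ValueError("rgb must be n × 3")
        bad = np.argwhere((self.rgb < 0) | (self.rgb > 255) | ~np.isfinite(self.rgb))
        if bad.size:
            r, c = bad[0]
            raise ValueError(f"RGB value out of [0, 255] at row {r}, channel {CHANNELS[c]}")
        if self.label.shape != (n,):
            raise ValueError("label must be an n-vector")
        lab = self.label[~np.isnan(self.label)]
        if lab.size and not np.all(np.isin(lab, (0.0, 1.0))):
            raise ValueError("labels must be 0, 1 or missing")

    @property
    def n(self) -> int:
        return self.reflectance.shape[0]

    def band_index(self, wavelength: float) -> int:
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= self.wavelengths.size or not np.isclose(self.wavelengths[idx], wavelength):
            raise ValueError(f"wavelength {wavelength} nm is not on the grid")
        return int(idx)

    def subset(self, indices: np.ndarray) -> "SampleSet":
        indices = np.asarray(indices)
        return SampleSet(self.wavelengths, self.reflectance[indices],
                         self.rgb[indices], self.label[indices])

    def with_labels(self, labels: np.ndarray) -> "SampleSet":
        return SampleSet(self.wavelengths, self.reflectance, self.rgb,
                         np.asarray(labels, dtype=float))

    def channel(self, name: str) -> np.ndarray:
        return self.rgb[:, CHANNELS.index(name)]


def _stream(master_seed: int, name: str) -> np.random.Generator:
    """Named sub-stream of the master seed; adding a stage never perturbs others."""
    tags = {"class": 0, "curve": 1, "noise": 2, "rgb": 3}
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(tags[name],)))


def _sigmoid_curves(grid: np.ndarray, params: dict) -> np.ndarray:
    """Vectorized curve family: base + (plateau−base)·σ((λ−edge)/width) + hump·gauss(600, 40)."""
    lam = grid[None, :]
    base = params["base"][:, None]
    plateau = params["plateau"][:, None]
    edge = params["edge"][:, None]
    width = params["width"][:, None]
    hump = params["hump"][:, None]
    sig = 1.0 / (1.0 + np.exp(-(lam - edge) / width))
    bump = np.exp(-0.5 * ((lam - 600.0) / 40.0) ** 2)
    return base + (plateau - base) * sig + hump * bump


def generate_samples(config: GeneratorConfig) -> SampleSet:
    """Draw a labeled synthetic seed lot per the configured class structure."""
    config.validate()
    grid = np.asarray(config.wavelength_grid, dtype=float)
    n = config.n_samples
    if n == 0:
        return SampleSet(grid, np.empty((0, grid.size)), np.empty((0, 3)), np.empty(0))

    n_yellow = int(round(n * config.yellow_fraction))
    labels = np.zeros(n)
    labels[:n_yellow] = 1.0
    _stream(config.seed, "class").shuffle(labels)

    curve_rng = _stream(config.seed, "curve")
    params = {k: np.empty(n) for k in ("base", "plateau", "edge", "width", "hump")}
    jit = config.param_jitter
    for cls, mask in (("yellow", labels == 1.0), ("nonyellow", labels == 0.0)):
        m = int(mask.sum())
        ref = _CLASS_CURVES[cls]
        z = curve_rng.standard_normal((m, 5))
        params["base"][mask] = ref["base"] * (1.0 + jit["base"] * z[:, 0])
        params["plateau"][mask] = ref["plateau"] * (1.0 + jit["plateau"] * z[:, 1])
        params["edge"][mask] = ref["edge"] + jit["edge"] * z[:, 2]
        params["width"][mask] = ref["width"] * (1.0 + jit["width"] * z[:, 3])
        params["hump"][mask] = ref["hump"] * (1.0 + jit["hump"] * z[:, 4])
    params["base"] = np.clip(params["base"], 1e-3, None)
    params["width"] = np.clip(params["width"], 5.0, None)

    # Emulate the native instrument grid (covering the canonical span), add
    # measurement noise there, then resample onto the requested grid.
    nat = native_grid()
    if grid[0] < nat[0] or grid[-1] > nat[-1]:
        nat = np.linspace(grid[0], grid[-1], max(int((grid[-1] - grid[0]) / NATIVE_RESOLUTION) + 2, 2))
    refl_native = _sigmoid_curves(nat, params)
    if config.spectrum_noise_sd > 0:
        refl_native = refl_native + _stream(config.seed, "noise").normal(
            0.0, config.spectrum_noise_sd, refl_native.shape)
    refl_native = np.clip(refl_native, 1e-4, 1.0)
    reflectance = resample_matrix(nat, refl_native, grid)

    rgb_rng = _stream(config.seed, "rgb")
    eps = rgb_rng.standard_normal((n, 3))
    rgb = np.empty((n, 3))
    for c, ch in enumerate(CHANNELS):
        lo, hi = config.coupling[ch]["window"]
        rho = float(config.coupling[ch]["rho"])
        in_win = (grid >= lo) & (grid <= hi)
        if not in_win.any():
            raise ValueError(f"coupling window for {ch} contains no grid points")
        w = reflectance[:, in_win].mean(axis=1)
        for cls, mask in (("yellow", labels == 1.0), ("nonyellow", labels == 0.0)):
            if not mask.any():
                continue
            mu = float(config.class_rgb_means[cls][c])
            sd = float(config.class_rgb_sds[cls][c])
            wsd = w[mask].std()
            z = (w[mask] - w[mask].mean()) / wsd if mask.sum() > 1 and wsd > 0 else 0.0
            rgb[mask, c] = mu + sd * (rho * z + np.sqrt(1.0 - rho**2) * eps[mask, c])
    rgb = np.clip(rgb, 0.0, 255.0)
    return SampleSet(grid, reflectance, rgb, labels)


# ---------------------------------------------------------------------------
# CSV I/O: header `label,R,G,B,wl_0400,...`; one row per seed.

_WL_RE = re.compile(r"^wl_([0-9]+(?:\.[0-9]+)?)$")


def _wl_columns(wavelengths: np.ndarray) -> list[str]:
    cols = []
    for w in wavelengths:
        cols.append(f"wl_{int(round(w)):04d}" if np.isclose(w, round(w)) else f"wl_{w:g}")
    return cols


def to_frame(samples: SampleSet) -> pd.DataFrame:
    label = pd.array(samples.label, dtype="Int64") if not np.isnan(samples.label).any() \
        else samples.label
    data = {"label": label}
    for c, ch in enumerate(CHANNELS):
        data[ch] = samples.rgb[:, c]
    frame = pd.DataFrame(data)
    spec = pd.DataFrame(samples.reflectance, columns=_wl_columns(samples.wavelengths))
    return pd.concat([frame, spec], axis=1)


def write_samples(samples: SampleSet, path: Path | str) -> Path:
    path = Path(path)
    to_frame(samples).to_csv(path, index=False, float_format="%.6g")
    return path


def read_samples(path: Path | str) -> SampleSet:
    frame = pd.read_csv(path)
    for col in ("label", "R", "G", "B"):
        if col not in frame.columns:
            raise ValueError(f"missing required column '{col}'")
    wl_cols, wavelengths = [], []
    for col in frame.columns[4:]:
        m = _WL_RE.match(col)
        if m is None:
            raise ValueError(f"unrecognized spectral column '{col}' (expected wl_<nm>)")
        wl_cols.append(col)
        wavelengths.append(float(m.group(1)))
    if not wl_cols:
        raise ValueError("no wavelength columns found (expected header wl_0400, ...)")
    wavelengths = np.asarray(wavelengths)
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelength columns are not in strictly increasing order")
    label = frame["label"].to_numpy(dtype=float)
    rgb = frame[list(CHANNELS)].to_numpy(dtype=float)
    reflectance = frame[wl_cols].to_numpy(dtype=float)
    return SampleSet(wavelengths, reflectance, rgb, label)


def config_from_dict(data: dict) -> GeneratorConfig:
    cfg = GeneratorConfig()
    known = {f for f in cfg.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown generator config fields: {sorted(unknown)}")
    if "wavelength_grid" in data:
        data = {**data, "wavelength_grid": np.asarray(data["wavelength_grid"], dtype=float)}
    return replace(cfg, **data)
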