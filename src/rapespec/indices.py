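"""Two-band spectral indices and exhaustive band-pair optimization.

Three index families over reflectances R(λ1), R(λ2):

    RSI  = R(λ1) / R(λ2)                 (ratio)
    DSI  = R(λ1) − R(λ2)                 (difference)
    NDSI = (R(λ1) − R(λ2)) / (R(λ1) + R(λ2))   (normalized difference)

The band-pair search evaluates one family over every ordered wavelength pair
on the grid and scores each pair by the Pearson correlation between the index
and a target RGB channel, averaged over repeated random half-splits (the
correlation is computed on each repetition's training half). The pair with
the largest mean |cc| defines the selected index; the signed mean correlation
is reported, so anti-correlated optima keep their sign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SampleSet

FAMILIES = ("RSI", "DSI", "NDSI")


@dataclass(frozen=True)
class SpectralIndexSpec:
    """A selected index: family, ordered band pair, fitted mean correlation."""

    family: str
    lambda1: float
    lambda2: float
    mean_cc: float
    channel: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown index family '{self.family}'")
        if not -1.0 <= self.mean_cc <= 1.0:
            raise ValueError("mean_cc must lie in [-1, 1]")

    @property
    def name(self) -> str:
        return f"{self.family}_{int(round(self.lambda1))}_{int(round(self.lambda2))}"

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: Path | str) -> "SpectralIndexSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CorrelationSurface:
    """Mean correlation over all ordered band pairs for one family/channel.

    ``cc[i, j]`` is the repetition-averaged Pearson correlation between
    index(grid[i], grid[j]) and the channel; degenerate pairs are NaN.
    """

    family: str
    channel: str
    grid: np.ndarray
    cc: np.ndarray

    def to_csv(self, path: Path | str) -> Path:
        path = Path(path)
        labels = [f"{w:g}" for w in self.grid]
        pd.DataFrame(self.cc, index=labels, columns=labels).to_csv(path, float_format="%.6g")
        return path


def _index_values(family: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if family == "RSI":
        return a / b
    if family == "DSI":
        return a - b
    if family == "NDSI":
        return (a - b) / (a + b)
    raise ValueError(f"unknown index family '{family}'")


def compute_index(family: str, samples: SampleSet, lambda1: float, lambda2: float) -> np.ndarray:
    """Per-seed index values at an ordered band pair; order preserved."""
    i, j = samples.band_index(lambda1), samples.band_index(lambda2)
    a, b = samples.reflectance[:, i], samples.reflectance[:, j]
    if family == "RSI":
        zero = np.nonzero(b == 0)[0]
        if zero.size:
            raise ZeroDivisionError(f"RSI denominator R({lambda2}) is zero for seed {zero[0]}")
    if family == "NDSI":
        zero = np.nonzero(a + b == 0)[0]
        if zero.size:
            raise ZeroDivisionError(f"NDSI denominator R({lambda1})+R({lambda2}) is zero for seed {zero[0]}")
    return _index_values(family, a, b)


def compute_index_matrix(samples: SampleSet, specs: list[SpectralIndexSpec]) -> pd.DataFrame:
    """Index values for a list of specs as a named-column table."""
    return pd.DataFrame(
        {s.name: compute_index(s.family, samples, s.lambda1, s.lambda2) for s in specs}
    )


def _pairwise_correlation(family: str, refl: np.ndarray, y: np.ndarray,
                          block: int = 48) -> np.ndarray:
    """Pearson cc between index(λi, λj) and y for every ordered pair.

    DSI decomposes through the band covariance matrix; RSI/NDSI are evaluated
    blockwise over λ1 to bound memory at n·block·n_bands floats.
    """
    n, n_bands = refl.shape
    yc = y - y.mean()
    y_ss = float(np.sqrt((yc**2).sum()))
    if y_ss == 0.0:
        raise ValueError("zero-variance target: channel is constant across seeds")
    cc = np.full((n_bands, n_bands), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "DSI":
            rc = refl - refl.mean(axis=0)
            cov_y = rc.T @ yc                     # n·cov(band, y)
            gram = rc.T @ rc                      # n·cov(band, band)
            diag = np.diag(gram)
            num = cov_y[:, None] - cov_y[None, :]
            ss = diag[:, None] + diag[None, :] - 2.0 * gram
            ss = np.where(ss > 0, ss, np.nan)
            cc = num / (np.sqrt(ss) * y_ss)
        else:
            for i0 in range(0, n_bands, block):
                i1 = min(i0 + block, n_bands)
                a = refl[:, i0:i1, None]
                b = refl[:, None, :]
                vals = _index_values(family, a, b)
                vals = np.where(np.isfinite(vals), vals, np.nan)
                vc = vals - vals.mean(axis=0)
                num = np.einsum("nij,n->ij", vc, yc)
                ss = (vc**2).sum(axis=0)
                ss = np.where(ss > 0, ss, np.nan)
                cc[i0:i1] = num / (np.sqrt(ss) * y_ss)
    return np.clip(cc, -1.0, 1.0)


def correlation_surface(family: str, samples: SampleSet, channel: str,
                        n_reps: int = 100, split_fraction: float = 0.5,
                        seed: int | None = None, use_full: bool = False) -> CorrelationSurface:
    """Repetition-averaged correlation surface for one family and channel.

    Each repetition draws a random training half (``split_fraction`` of the
    seeds); correlations are computed on that half only and averaged across
    repetitions. ``use_full=True`` computes a single surface on all seeds.
    A pair degenerate (zero-variance or non-finite) in any repetition is NaN.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown index family '{family}'")
    y_all = samples.channel(channel)
    if np.ptp(y_all) == 0:
        raise ValueError("zero-variance target: channel is constant across seeds")
    refl = samples.reflectance
    if use_full:
        cc = _pairwise_correlation(family, refl, y_all)
        return CorrelationSurface(family, channel, samples.wavelengths.copy(), cc)
    n_train = int(round(samples.n * split_fraction))
    if n_train < 3 or samples.n - n_train < 0:
        raise ValueError("need at least 3 seeds in each training half")
    rng = np.random.default_rng(seed)
    acc = np.zeros((refl.shape[1], refl.shape[1]))
    for _ in range(n_reps):
        idx = rng.permutation(samples.n)[:n_train]
        acc += _pairwise_correlation(family, refl[idx], y_all[idx])
    return CorrelationSurface(family, channel, samples.wavelengths.copy(), acc / n_reps)


def select_best_pair(surface: CorrelationSurface) -> SpectralIndexSpec:
    """Pair maximizing |mean cc|; signed value reported; ties → smallest λ1 then λ2."""
    cc = surface.cc
    finite = np.isfinite(cc)
    if not finite.any():
        raise ValueError("correlation surface has no non-missing entries")
    best = np.nanmax(np.abs(np.where(finite, cc, np.nan)))
    ii, jj = np.nonzero(finite & np.isclose(np.abs(cc), best, rtol=0, atol=1e-12))
    order = np.lexsort((surface.grid[jj], surface.grid[ii]))
    i, j = ii[order[0]], jj[order[0]]
    return SpectralIndexSpec(surface.family, float(surface.grid[i]), float(surface.grid[j]),
                             float(cc[i, j]), surface.channel)
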