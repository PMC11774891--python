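"""The 23 trilateral (three-edge) parameters of the first-derivative spectrum.

Three edge windows of the visible/NIR derivative spectrum carry most of the
coat-color signal: the blue edge (490–530 nm), yellow edge (560–640 nm) and
red edge (680–760 nm). Per edge the derivative's maximum (D*), its wavelength
(BD*), minimum (D*min), trapezoidal integral over the window (SD*, the edge
"area") and normalized amplitude ND* = (D*−D*min)/(D*+D*min) are computed;
across edges the area ratios Srb, Sry, Syb, the normalized area differences
NBDb, Nry, Nby, and the kurtosis/skewness of the red-edge derivative complete
the set. ``Nrb``, an alternative name for the red/blue normalized difference,
resolves to NBDb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Spectrum, derivative_matrix, first_derivative
from .synthetic import SampleSet

EDGES = {"blue": (490.0, 530.0), "yellow": (560.0, 640.0), "red": (680.0, 760.0)}

PARAM_NAMES = (
    "Db", "BDb", "SDb", "Dbmin", "NDb",
    "Dy", "BDy", "SDy", "Dymin", "NDy",
    "Dr", "BDr", "SDr", "Drmin", "NDr",
    "Srb", "Sry", "Syb", "NBDb", "Nry", "Nby", "Kur", "Ske",
)

#: Alternative spellings used in the field → canonical column names.
ALIASES = {"Nrb": "NBDb", "ske": "Ske", "kur": "Kur"}


@dataclass(frozen=True)
class EdgeDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.name not in EDGES:
            raise ValueError(f"unknown edge '{self.name}'")
        if not self.lo < self.hi:
            raise ValueError("edge window must satisfy lo < hi")


def canonical_name(name: str) -> str:
    name = ALIASES.get(name, name)
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown trilateral parameter '{name}'")
    return name


def _edge_mask(wavelengths: np.ndarray, edge: str) -> np.ndarray:
    lo, hi = EDGES[edge]
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError(f"{edge} edge window [{lo}, {hi}] not covered by the grid")
    return mask


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    bad = np.nonzero(den == 0)[0]
    if bad.size:
        raise ZeroDivisionError(f"zero denominator computing {name} (seed {bad[0]})")
    return num / den


def _moments(deriv_red: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Excess kurtosis and Fisher–Pearson skewness of the red-edge derivative.

    A constant derivative has undefined moments; defined as 0 with a warning
    so degenerate (e.g. exactly linear) spectra stay representable.
    """
    scale = np.maximum(np.max(np.abs(deriv_red), axis=1), 1e-300)
    const = np.ptp(deriv_red, axis=1) <= 1e-9 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        kur = stats.kurtosis(deriv_red, axis=1, fisher=True, bias=True)
        ske = stats.skew(deriv_red, axis=1, bias=True)
    if const.any():
        warnings.warn("constant red-edge derivative: Kur/Ske defined as 0", RuntimeWarning)
    kur = np.where(const | ~np.isfinite(kur), 0.0, kur)
    ske = np.where(const | ~np.isfinite(ske), 0.0, ske)
    return kur, ske


def trilateral_table(samples: SampleSet) -> pd.DataFrame:
    """All 23 parameters for every seed (vectorized); columns per PARAM_NAMES."""
    wl = samples.wavelengths
    deriv = derivative_matrix(wl, samples.reflectance)
    out: dict[str, np.ndarray] = {}
    for edge, tag in (("blue", "b"), ("yellow", "y"), ("red", "r")):
        mask = _edge_mask(wl, edge)
        d, w = deriv[:, mask], wl[mask]
        out[f"D{tag}"] = d.max(axis=1)
        out[f"BD{tag}"] = w[d.argmax(axis=1)]           # argmax ties → lowest λ
        out[f"D{tag}min"] = d.min(axis=1)
        out[f"SD{tag}"] = np.trapezoid(d, w, axis=1)
        out[f"ND{tag}"] = _safe_ratio(out[f"D{tag}"] - out[f"D{tag}min"],
                                      out[f"D{tag}"] + out[f"D{tag}min"], f"ND{tag}")
    out["Srb"] = _safe_ratio(out["SDr"], out["SDb"], "Srb")
    out["Sry"] = _safe_ratio(out["SDr"], out["SDy"], "Sry")
    out["Syb"] = _safe_ratio(out["SDy"], out["SDb"], "Syb")
    out["NBDb"] = _safe_ratio(out["SDr"] - out["SDb"], out["SDr"] + out["SDb"], "NBDb")
    out["Nry"] = _safe_ratio(out["SDr"] - out["SDy"], out["SDr"] + out["SDy"], "Nry")
    out["Nby"] = _safe_ratio(out["SDb"] - out["SDy"], out["SDb"] + out["SDy"], "Nby")
    out["Kur"], out["Ske"] = _moments(deriv[:, _edge_mask(wl, "red")])
    return pd.DataFrame({name: out[name] for name in PARAM_NAMES})


def trilateral_parameters(spectrum: Spectrum) -> dict[str, float]:
    """The 23 parameters for a single spectrum covering the canonical grid."""
    samples = SampleSet(spectrum.wavelengths, spectrum.values[None, :],
                        np.zeros((1, 3)), np.array([np.nan]))
    return trilateral_table(samples).iloc[0].to_dict()


def rank_trilateral(samples: SampleSet, channel: str, n_reps: int = 100,
                    subset_size: int = 150, seed: int | None = None) -> pd.DataFrame:
    """Rank the 23 parameters by mean |Pearson cc| with a channel over random subsets.

    Each repetition correlates every parameter with the channel on a random
    subset of ``subset_size`` seeds; absolute values are averaged. A parameter
    with zero variance on a subset skips that repetition (with a warning)
    rather than propagating NaN. Ties break alphabetically by name.
    """
    if samples.n < subset_size:
        raise ValueError(f"need at least subset_size={subset_size} seeds, have {samples.n}")
    table = trilateral_table(samples).to_numpy()
    y_all = samples.channel(channel)
    rng = np.random.default_rng(seed)
    abs_cc = np.zeros((n_reps, table.shape[1]))
    counts = np.zeros(table.shape[1], dtype=int)
    for r in range(n_reps):
        idx = rng.permutation(samples.n)[:subset_size]
        x, y = table[idx], y_all[idx]
        yc = y - y.mean()
        y_ss = np.sqrt((yc**2).sum())
        if y_ss == 0:
            raise ValueError("zero-variance target: channel is constant across the subset")
        xc = x - x.mean(axis=0)
        ss = np.sqrt((xc**2).sum(axis=0))
        degenerate = ss == 0
        if degenerate.any():
            names = [PARAM_NAMES[k] for k in np.nonzero(degenerate)[0]]
            warnings.warn(f"zero-variance parameter(s) {names} on subset; repetition skipped "
                          "for those parameters", RuntimeWarning)
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = (xc.T @ yc) / (ss * y_ss)
        abs_cc[r] = np.where(degenerate, np.nan, np.abs(cc))
        counts += ~degenerate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(abs_cc, axis=0)
        sd = np.nanstd(abs_cc, axis=0)
    frame = pd.DataFrame({
        "parameter": PARAM_NAMES,
        "mean_abs_cc": np.where(counts > 0, mean, np.nan),
        "sd": np.where(counts > 0, sd, np.nan),
    })
    # ties (to 12 decimals, absorbing float noise) break alphabetically
    frame["_key"] = np.round(frame["mean_abs_cc"], 12)
    frame = frame.sort_values(["_key", "parameter"],
                              ascending=[False, True], kind="mergesort",
                              na_position="last").drop(columns="_key").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def top_parameters(ranking: pd.DataFrame, k: int = 3) -> list[str]:
    return ranking["parameter"].head(k).tolist()
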