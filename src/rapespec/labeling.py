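"""Yellow/non-yellow labeling from RGB triples by box thresholds.

A seed is yellow-coated iff its R, G and B values each lie strictly inside a
channel interval: R ∈ (164.1, 245.3), G ∈ (101.1, 226.2), B ∈ (9.1, 92.2).
The intervals follow internationally used yellow-seed color conventions; the
inequalities are strict, so boundary triples label 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SampleSet


@dataclass(frozen=True)
class RGBThresholds:
    SR: tuple[float, float] = (164.1, 245.3)
    SG: tuple[float, float] = (101.1, 226.2)
    SB: tuple[float, float] = (9.1, 92.2)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("SR", self.SR), ("SG", self.SG), ("SB", self.SB)):
            if not lo < hi:
                raise ValueError(f"threshold interval {name} must satisfy lo < hi")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.SR, self.SG, self.SB])


DEFAULT_THRESHOLDS = RGBThresholds()


def label_rgb(rgb, thresholds: RGBThresholds = DEFAULT_THRESHOLDS) -> np.ndarray | int:
    """1 iff every channel lies strictly inside its interval; vectorized.

    Accepts a single (R, G, B) triple (returns an int) or an n × 3 matrix
    (returns an int vector).
    """
    arr = np.asarray(rgb, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("rgb must be a triple or an n × 3 matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError("rgb values must be finite")
    b = DEFAULT_THRESHOLDS.bounds if thresholds is None else thresholds.bounds
    inside = (arr > b[:, 0]) & (arr < b[:, 1])
    labels = inside.all(axis=1).astype(int)
    return int(labels[0]) if single else labels


def label_samples(samples: SampleSet,
                  thresholds: RGBThresholds = DEFAULT_THRESHOLDS) -> tuple[SampleSet, dict]:
    """Label every seed from its RGB; returns the labeled set and class counts."""
    labels = label_rgb(samples.rgb, thresholds)
    counts = {"yellow": int(labels.sum()), "nonyellow": int(len(labels) - labels.sum())}
    return samples.with_labels(labels.astype(float)), counts
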