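"""Feature assembly: selected index/trilateral fusions and the 633-feature pool.

The full pool for penalized selection concatenates the 601 canonical 1 nm
reflectance bands, the 9 channel-optimized spectral indices (three families ×
three channels) and the 23 trilateral parameters: 601 + 9 + 23 = 633 named
features per seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indices import SpectralIndexSpec, compute_index_matrix
from .synthetic import SampleSet, _wl_columns
from .trilateral import canonical_name, trilateral_table

#: Channel-optimized band pairs and mean correlations from the reference
#: 300-seed study (ratio/difference/normalized-difference × R/G/B).
REFERENCE_INDEX_SPECS = (
    SpectralIndexSpec("RSI", 705, 910, 0.9673, "R"),
    SpectralIndexSpec("RSI", 582, 983, 0.9278, "G"),
    SpectralIndexSpec("RSI", 534, 571, 0.4449, "B"),
    SpectralIndexSpec("DSI", 418, 610, 0.9165, "R"),
    SpectralIndexSpec("DSI", 421, 536, -0.9440, "G"),
    SpectralIndexSpec("DSI", 419, 994, -0.4068, "B"),
    SpectralIndexSpec("NDSI", 646, 995, 0.9660, "R"),
    SpectralIndexSpec("NDSI", 568, 988, 0.9380, "G"),
    SpectralIndexSpec("NDSI", 531, 571, 0.4563, "B"),
)

#: Top-3 trilateral parameters for the red (and green) channel in the
#: reference study: Nrb (= NBDb), Srb, SDb.
REFERENCE_TOP3_TRILATERAL = ("NBDb", "Srb", "SDb")


def assemble_pool(samples: SampleSet,
                  index_specs: tuple[SpectralIndexSpec, ...] = REFERENCE_INDEX_SPECS,
                  trilateral: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reflectance bands + index values + trilateral parameters, named columns."""
    bands = pd.DataFrame(samples.reflectance, columns=_wl_columns(samples.wavelengths))
    idx = compute_index_matrix(samples, list(index_specs))
    tri = trilateral_table(samples) if trilateral is None else trilateral.reset_index(drop=True)
    pool = pd.concat([bands, idx, tri], axis=1)
    if pool.columns.duplicated().any():
        raise ValueError("duplicate feature names in pool")
    return pool


def fused_features(samples: SampleSet, channel: str,
                   index_specs: tuple[SpectralIndexSpec, ...] = REFERENCE_INDEX_SPECS,
                   top3: tuple[str, ...] = REFERENCE_TOP3_TRILATERAL,
                   trilateral: pd.DataFrame | None = None) -> pd.DataFrame:
    """The six-feature fusion for one channel: top-3 trilateral + that
    channel's three family-optimized indices."""
    tri = trilateral_table(samples) if trilateral is None else trilateral.reset_index(drop=True)
    names = [canonical_name(p) for p in top3]
    chan_specs = [s for s in index_specs if s.channel == channel]
    if len(chan_specs) != 3:
        raise ValueError(f"expected 3 index specs for channel {channel}, got {len(chan_specs)}")
    idx = compute_index_matrix(samples, chan_specs)
    return pd.concat([tri[names].reset_index(drop=True), idx], axis=1)
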