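"""db4 discrete wavelet decomposition and per-subband summary features.

A level-4 decomposition of a 2048 Hz epoch yields five subbands with
dyadic edges: A4 (0-64 Hz), D4 (64-128), D3 (128-256), D2 (256-512),
D1 (512-1024).  With the periodized boundary the transform is orthogonal,
so coefficient energy equals signal energy and reconstruction is exact.

Which scalar is taken per subband is configurable; the default is RMS and
MAV of the coefficients of each subband, giving 10 columns named
``WT_<band>_<stat>`` in the fixed order (A4, D4, D3, D2, D1) x (RMS, MAV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from ..preprocess import EpochSet
from .classic import mav, rms

__all__ = ["WaveletDecomposition", "dwt_db4", "reconstruct", "wavelet_features",
           "wavelet_feature_table", "WAVELET_BANDS"]

WAVELET_BANDS = ("A4", "D4", "D3", "D2", "D1")

_STATS = {"RMS": rms, "MAV": mav}


@dataclass
class WaveletDecomposition:
    """Coefficients of a level-4 db4 decomposition."""

    A4: np.ndarray
    D4: np.ndarray
    D3: np.ndarray
    D2: np.ndarray
    D1: np.ndarray
    boundary_mode: str = "periodization"

    def subbands(self):
        return {b: getattr(self, b) for b in WAVELET_BANDS}

    def coeff_list(self):
        # pywt ordering: [cA4, cD4, cD3, cD2, cD1]
        return [self.A4, self.D4, self.D3, self.D2, self.D1]

    def energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.coeff_list()))


def dwt_db4(x, level: int = 4, boundary: str = "periodization") -> WaveletDecomposition:
    """Orthogonal db4 decomposition to the given level."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if x.size < 2**level:
        raise ValueError(f"need at least 2**{level} samples, got {x.size}")
    coeffs = pywt.wavedec(x, "db4", mode=boundary, level=level)
    if level != 4:
        raise ValueError("subband naming assumes level 4")
    cA4, cD4, cD3, cD2, cD1 = coeffs
    return WaveletDecomposition(cA4, cD4, cD3, cD2, cD1, boundary)


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse transform."""
    return pywt.waverec(dec.coeff_list(), "db4", mode=dec.boundary_mode)


def wavelet_features(dec: WaveletDecomposition, stats=("RMS", "MAV")) -> dict:
    """Summary statistics of each subband's coefficients, band-major order."""
    for s in stats:
        if s not in _STATS:
            raise ValueError(f"unknown statistic {s!r}; choose from {sorted(_STATS)}")
    return {f"WT_{band}_{stat}": _STATS[stat](coeffs)
            for band, coeffs in dec.subbands().items() for stat in stats}


def wavelet_feature_table(epochs: EpochSet, stats=("RMS", "MAV"),
                          boundary: str = "periodization") -> pd.DataFrame:
    """Feature table of subband statistics for every epoch row."""
    rows = [wavelet_features(dwt_db4(epochs.X[i], boundary=boundary), stats)
            for i in range(len(epochs))]
    return pd.concat([epochs.meta.reset_index(drop=True),
                      pd.DataFrame(rows)], axis=1)
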