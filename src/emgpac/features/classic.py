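"""Classic time- and frequency-domain surface-EMG features.

Sixteen scalar features per epoch: RMS, v-order, log detector, MAV,
myopulse percentage rate (MYOP), zero crossings (ZC), slope sign changes
(SSC), Willison amplitude (WAMP), absolute third/fourth/fifth temporal
moments, waveform length (WL), difference absolute standard deviation
(DASDV), square integral (SI), and the periodogram mean and median
frequencies (MNF, MDF).

Conventions (documented, since the usual formulae leave them open):

* v-order and the log detector operate on ``|x|`` — fractional powers and
  logarithms of negative samples are undefined; zeros are floored at
  machine epsilon inside the log.
* The log detector defaults to the classical geometric-mean form
  ``exp(mean(ln |x|))``; ``mode="paper-literal"`` evaluates
  ``e**mean(log10 |x|)`` instead.
* TM3 and TM5 are reported as absolute values (TM4 is non-negative
  already).
* ZC counts sign changes whose adjacent-sample difference also clears the
  threshold; MYOP/ZC/SSC/WAMP share one amplitude threshold (default 0.01,
  raw amplitude units, no pre-normalisation).
* MNF/MDF use the full-epoch one-sided periodogram with the DC bin
  excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ..preprocess import EpochSet

__all__ = [
    "ThresholdConfig", "rms", "v_order", "log_detector", "mav",
    "threshold_counts", "temporal_moments", "waveform_measures",
    "spectral_features", "classic_feature_vector", "classic_features",
    "CLASSIC_FEATURE_NAMES",
]

CLASSIC_FEATURE_NAMES = (
    "RMS", "V", "LOG", "MAV", "MYOP", "ZC", "SSC", "WAMP",
    "TM3", "TM4", "TM5", "WL", "DASDV", "SI", "MNF", "MDF",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Shared amplitude threshold for MYOP, ZC, SSC and WAMP."""

    threshold: float = 0.01

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


def _as_signal(x, min_len=1, name="x"):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_len:
        raise ValueError(f"{name} must be 1-D with at least {min_len} samples")
    return x


def rms(x) -> float:
    """Root mean square, sqrt(mean(x**2))."""
    x = _as_signal(x)
    return float(np.sqrt(np.mean(x**2)))


def v_order(x, v: float = 2.0) -> float:
    """(mean |x|**v)**(1/v); reduces to RMS at v=2."""
    if v <= 0:
        raise ValueError("v must be positive")
    x = _as_signal(x)
    return float(np.mean(np.abs(x) ** v) ** (1.0 / v))


def log_detector(x, mode: str = "classical") -> float:
    """Log detector of contraction strength.

    mode="classical": exp(mean(ln |x|)) — the geometric mean of |x|.
    mode="paper-literal": e**mean(log10 |x|).
    """
    x = np.abs(_as_signal(x))
    x = np.maximum(x, np.finfo(float).eps)  # guard zeros
    if mode == "classical":
        return float(np.exp(np.mean(np.log(x))))
    if mode == "paper-literal":
        return float(np.exp(np.mean(np.log10(x))))
    raise ValueError(f"unknown log detector mode {mode!r}")


def mav(x) -> float:
    """Mean absolute value."""
    return float(np.mean(np.abs(_as_signal(x))))


def threshold_counts(x, cfg: ThresholdConfig = ThresholdConfig()) -> dict:
    """MYOP, ZC, SSC and WAMP under a shared amplitude threshold.

    MYOP = mean(|x_n| >= thr)
    ZC   = #{n : x_n * x_{n+1} < 0 and |x_n - x_{n+1}| >= thr}
    SSC  = #{n : (x_n - x_{n-1}) * (x_n - x_{n+1}) >= thr}
    WAMP = #{n : |x_n - x_{n+1}| >= thr}
    """
    x = _as_signal(x, min_len=3)
    thr = cfg.threshold
    diff = x[:-1] - x[1:]
    myop = float(np.mean(np.abs(x) >= thr))
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(diff) >= thr)))
    ssc = int(np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) >= thr))
    wamp = int(np.sum(np.abs(diff) >= thr))
    return {"MYOP": myop, "ZC": zc, "SSC": ssc, "WAMP": wamp}


def temporal_moments(x) -> dict:
    """Absolute third, plain fourth, absolute fifth temporal moments."""
    x = _as_signal(x)
    return {
        "TM3": float(abs(np.mean(x**3))),
        "TM4": float(np.mean(x**4)),
        "TM5": float(abs(np.mean(x**5))),
    }


def waveform_measures(x) -> dict:
    """Waveform length, DASDV and square integral."""
    x = _as_signal(x, min_len=2)
    d = np.diff(x)
    return {
        "WL": float(np.sum(np.abs(d))),
        "DASDV": float(np.sqrt(np.mean(d**2))),
        "SI": float(np.sum(x**2)),
    }


def spectral_features(x, fs: float) -> dict:
    """Mean and median frequency of the one-sided periodogram (DC excluded)."""
    x = _as_signal(x, min_len=8)
    freqs, power = sps.periodogram(x, fs=fs)
    freqs, power = freqs[1:], power[1:]
    total = power.sum()
    if total <= 0:
        raise ValueError("all-zero signal: spectral ratio undefined")
    mnf = float(np.sum(freqs * power) / total)
    cumulative = np.cumsum(power)
    mdf = float(freqs[np.searchsorted(cumulative, total / 2.0)])
    return {"MNF": mnf, "MDF": mdf}


def classic_feature_vector(x, fs: float, v: float = 2.0,
                           cfg: ThresholdConfig = ThresholdConfig(),
                           log_mode: str = "classical") -> dict:
    """All sixteen classic features of one epoch, keyed by name."""
    out = {
        "RMS": rms(x),
        "V": v_order(x, v),
        "LOG": log_detector(x, log_mode),
        "MAV": mav(x),
    }
    out.update(threshold_counts(x, cfg))
    out.update(temporal_moments(x))
    out.update(waveform_measures(x))
    out.update(spectral_features(x, fs))
    return {k: out[k] for k in CLASSIC_FEATURE_NAMES}


def classic_features(epochs: EpochSet, v: float = 2.0,
                     cfg: ThresholdConfig = ThresholdConfig(),
                     log_mode: str = "classical") -> pd.DataFrame:
    """Feature table: metadata columns + one column per classic feature."""
    rows = [classic_feature_vector(epochs.X[i], epochs.fs, v, cfg, log_mode)
            for i in range(len(epochs))]
    return pd.concat([epochs.meta.reset_index(drop=True),
                      pd.DataFrame(rows)], axis=1)
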