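"""Preprocessing chain: band-pass filtering, bad-channel removal, epoching.

The analysis unit downstream of this module is the *epoch row*: one
(channel, 500 ms segment) pair.  ``segment`` returns an :class:`EpochSet`
holding the stacked epoch signals plus an aligned metadata frame
(subject, group, muscle, channel, segment index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import Recording

__all__ = ["FilterSpec", "EpochSet", "bandpass", "drop_bad_channels", "segment",
           "preprocess", "concat_epochsets"]

META_COLUMNS = ["subject_id", "group", "muscle", "channel_index", "segment_index"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``zero_phase=True`` applies the filter forward and backward
    (zero group delay, effective order doubled); the single-pass causal
    mode is available for streaming-like use.
    """

    order: int = 2
    band: tuple = (20.0, 450.0)
    zero_phase: bool = True


@dataclass
class EpochSet:
    """Stacked fixed-length epochs with aligned per-row metadata.

    ``X`` has shape (n_rows, epoch_len); row i is described by row i of
    ``meta`` (columns: subject_id, group, muscle, channel_index,
    segment_index).
    """

    X: np.ndarray
    meta: pd.DataFrame
    fs: float

    def __post_init__(self):
        if self.X.shape[0] != len(self.meta):
            raise ValueError("X and meta must have the same number of rows")

    def __len__(self):
        return self.X.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.X.shape[1]


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-pass filter every channel of a recording."""
    lo, hi = spec.band
    if hi >= rec.fs / 2 or lo <= 0:
        raise ValueError(f"band {spec.band} outside (0, Nyquist={rec.fs / 2})")
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs, output="sos")
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    else:
        filtered = sps.sosfilt(sos, rec.samples, axis=1)
    meta = dict(rec.meta)
    meta["filter"] = {"order": spec.order, "band": list(spec.band),
                      "family": "butterworth", "zero_phase": spec.zero_phase}
    return Recording(filtered, rec.fs, list(rec.channel_labels), rec.subject_id,
                     rec.group, rec.bad_channel_mask.copy(), meta)


def drop_bad_channels(rec: Recording) -> Recording:
    """Remove channels flagged in ``bad_channel_mask``.

    Raises if nothing is left; warns (and keeps the subject) when a whole
    muscle disappears.
    """
    keep = ~rec.bad_channel_mask
    if not keep.any():
        raise ValueError(f"subject {rec.subject_id}: all channels flagged bad")
    kept_labels = [lab for lab, k in zip(rec.channel_labels, keep) if k]
    lost = {m for m, _ in rec.channel_labels} - {m for m, _ in kept_labels}
    if lost:
        warnings.warn(
            f"subject {rec.subject_id}: all channels removed for muscle(s) "
            f"{sorted(lost)}; subject retained with remaining muscles"
        )
    return Recording(rec.samples[keep], rec.fs, kept_labels, rec.subject_id,
                     rec.group, np.zeros(int(keep.sum()), dtype=bool), dict(rec.meta))


def segment(rec: Recording, epoch_s: float = 0.5) -> EpochSet:
    """Cut each channel into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.  Channels
    still flagged bad are excluded (equivalent to ``drop_bad_channels``
    first).
    """
    epoch_len = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // epoch_len
    if n_epochs < 1:
        raise ValueError(
            f"subject {rec.subject_id}: recording of {rec.n_samples} samples "
            f"shorter than one {epoch_len}-sample epoch"
        )
    rows, meta_rows = [], []
    for ch in range(rec.n_channels):
        if rec.bad_channel_mask[ch]:
            continue
        muscle, ch_idx = rec.channel_labels[ch]
        sig = rec.samples[ch, : n_epochs * epoch_len].reshape(n_epochs, epoch_len)
        rows.append(sig)
        for seg_idx in range(n_epochs):
            meta_rows.append((rec.subject_id, rec.group, muscle, ch_idx, seg_idx))
    X = np.concatenate(rows, axis=0)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return EpochSet(X, meta, rec.fs)


def preprocess(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Filter then drop bad channels (the standard chain before epoching)."""
    return drop_bad_channels(bandpass(rec, spec))


def concat_epochsets(sets) -> EpochSet:
    """Stack EpochSets from several subjects into one."""
    sets = list(sets)
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    fs = sets[0].fs
    ln = sets[0].epoch_len
    for s in sets:
        if s.fs != fs or s.epoch_len != ln:
            raise ValueError("epoch sets differ in fs or epoch length")
    X = np.concatenate([s.X for s in sets], axis=0)
    meta = pd.concat([s.meta for s in sets], ignore_index=True)
    return EpochSet(X, meta, fs)
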