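"""Phase-amplitude coupling via complex Morlet transform and coherence.

The estimator: for a candidate pair (f_phase, f_amp) the signal is
convolved with unit-energy complex Morlet wavelets at both frequencies;
``ph(t) = cos(angle W(f_phase, t))`` is the unit-amplitude phase carrier
of the slow rhythm and ``amp(t) = |W(f_amp, t)|`` the fast rhythm's
amplitude envelope.  Coupling strength is the magnitude-squared coherence
between ``ph`` and ``amp``, Welch-estimated (Hann segments, 50% overlap)
and read off at the Welch frequency bin nearest ``f_phase`` (never the DC
bin, which carries no phase information after detrending).  Scanning a
grid of (phase, amplitude) frequencies yields a comodulogram whose cells
lie in [0, 1].

The wavelet width parameter is interpreted in *cycles*: sigma_t =
cycles / (2 pi f), so every frequency is analysed with the same relative
bandwidth (an absolute-seconds mode is available).  Wavelet support is
truncated at +-4 sigma_t.

Epochs of 500 ms are too short for stable coherence at low phase
frequencies, so per-channel PAC features are computed on longer analysis
windows (default 4 s = 8 consecutive epochs) and shared by the epochs
inside each window; trailing epochs that do not fill a window fall back
to per-epoch estimation with 128-sample Welch segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ..preprocess import META_COLUMNS
from ..simulate import Recording

__all__ = [
    "MorletParams", "WelchConfig", "Comodulogram",
    "morlet_wavelet", "morlet_transform", "pac_coherence", "comodulogram",
    "vectorize_comodulogram", "comodulogram_from_vector",
    "default_phase_grid", "default_amp_grid", "pac_feature_table",
]


@dataclass(frozen=True)
class MorletParams:
    """Complex Morlet parameters.

    ``cycles`` sets the Gaussian width: in the default ``mode="cycles"``
    sigma_t = cycles / (2 pi f); ``mode="seconds"`` reads it as an
    absolute width in seconds.  Sampled wavelets are L2-normalised to
    unit energy.
    """

    cycles: float = 7.0
    mode: str = "cycles"
    support_sigmas: float = 4.0

    def sigma_t(self, freq: float) -> float:
        if self.mode == "cycles":
            return self.cycles / (2 * np.pi * freq)
        if self.mode == "seconds":
            return float(self.cycles)
        raise ValueError(f"unknown Morlet mode {self.mode!r}")


@dataclass(frozen=True)
class WelchConfig:
    """Welch cross-spectral settings for the coherence estimate."""

    nperseg: int = 256
    overlap: float = 0.5
    window: str = "hann"

    @property
    def noverlap(self) -> int:
        return int(self.nperseg * self.overlap)


@dataclass
class Comodulogram:
    """Coupling strength over a (phase frequency x amplitude frequency) grid.

    Cells with amplitude frequency <= phase frequency are masked (NaN).
    """

    values: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray

    def argmax_cell(self):
        """(f_phase, f_amp) of the strongest unmasked cell."""
        flat = np.nanargmax(self.values)
        i, j = np.unravel_index(flat, self.values.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])

    def cells_away(self, f_phase: float, f_amp: float) -> int:
        """Chebyshev grid distance between the argmax cell and the cell
        nearest the given (f_phase, f_amp) pair."""
        fp, fa = self.argmax_cell()
        i0 = int(np.argmin(np.abs(self.phase_freqs - f_phase)))
        j0 = int(np.argmin(np.abs(self.amp_freqs - f_amp)))
        i1 = int(np.argmin(np.abs(self.phase_freqs - fp)))
        j1 = int(np.argmin(np.abs(self.amp_freqs - fa)))
        return max(abs(i1 - i0), abs(j1 - j0))

    def value_at(self, f_phase: float, f_amp: float) -> float:
        i = int(np.argmin(np.abs(self.phase_freqs - f_phase)))
        j = int(np.argmin(np.abs(self.amp_freqs - f_amp)))
        return float(self.values[i, j])


def default_phase_grid() -> np.ndarray:
    """Phase frequencies 2-30 Hz in 2 Hz steps."""
    return np.arange(2.0, 31.0, 2.0)


def default_amp_grid() -> np.ndarray:
    """Amplitude frequencies 30-350 Hz in 10 Hz steps."""
    return np.arange(30.0, 351.0, 10.0)


def paper_mode_grids(fs: float, step_phase: float = 1.0, step_amp: float = 1.0):
    """Full 1-350 Hz grids on both axes (amp > phase cells retained)."""
    hi = min(350.0, fs / 2 - 1)
    return np.arange(1.0, hi + 1e-9, step_phase), np.arange(1.0, hi + 1e-9, step_amp)


def morlet_wavelet(freq: float, fs: float, params: MorletParams = MorletParams()):
    """Sampled unit-energy complex Morlet wavelet at one frequency."""
    if not 0 < freq < fs / 2:
        raise ValueError(f"frequency {freq} outside (0, Nyquist)")
    st = params.sigma_t(freq)
    half = int(np.ceil(params.support_sigmas * st * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * st**2))
    return w / np.linalg.norm(w)


def morlet_transform(x, fs: float, freqs, params: MorletParams = MorletParams()):
    """Convolve x with unit-energy Morlets at each frequency.

    Returns (kept_freqs, W) where W is complex with shape
    (len(kept_freqs), len(x)); frequencies whose truncated support
    exceeds the signal length are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    kept, rows = [], []
    for f in freqs:
        w = morlet_wavelet(f, fs, params)
        if w.size > x.size:
            warnings.warn(
                f"dropping {f:g} Hz: wavelet support {w.size} exceeds "
                f"signal length {x.size}")
            continue
        kept.append(f)
        rows.append(sps.fftconvolve(x, w, mode="same"))
    if not kept:
        raise ValueError("no analysable frequencies: signal too short")
    return np.asarray(kept), np.asarray(rows)


def _segment_ffts(sig: np.ndarray, cfg: WelchConfig):
    """Windowed, detrended segment rFFTs (Welch building block)."""
    n = sig.size
    step = cfg.nperseg - cfg.noverlap
    n_seg = (n - cfg.noverlap) // step
    if n_seg < 2:
        raise ValueError(
            f"only {n_seg} Welch segment(s) of {cfg.nperseg} samples in a "
            f"{n}-sample signal; coherence needs at least 2")
    win = sps.get_window(cfg.window, cfg.nperseg)
    idx = np.arange(cfg.nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = sig[idx]
    segs = segs - segs.mean(axis=1, keepdims=True)  # constant detrend
    return np.fft.rfft(segs * win, axis=1)


def _coherence_bin(f_phase: float, fs: float, cfg: WelchConfig) -> int:
    df = fs / cfg.nperseg
    return max(1, int(round(f_phase / df)))  # never the DC bin


def _coherence_from_ffts(Fp, Fa, bin_idx: int) -> float:
    pxx = np.mean(np.abs(Fp[:, bin_idx]) ** 2)
    pyy = np.mean(np.abs(Fa[:, bin_idx]) ** 2)
    pxy = np.mean(Fp[:, bin_idx] * np.conj(Fa[:, bin_idx]))
    denom = pxx * pyy
    if denom <= 0:
        return 0.0
    return float(min(1.0, np.abs(pxy) ** 2 / denom))


def pac_coherence(x, fs: float, f_phase: float, f_amp: float,
                  params: MorletParams = MorletParams(),
                  welch: WelchConfig = WelchConfig()) -> float:
    """Coupling strength in [0, 1] for a single (f_phase, f_amp) pair."""
    if f_amp <= f_phase:
        raise ValueError("f_amp must exceed f_phase")
    _, W = morlet_transform(x, fs, [f_phase, f_amp], params)
    if W.shape[0] < 2:
        raise ValueError("signal too short for both analysis frequencies")
    ph = np.cos(np.angle(W[0]))
    amp = np.abs(W[1])
    Fp = _segment_ffts(ph, welch)
    Fa = _segment_ffts(amp, welch)
    return _coherence_from_ffts(Fp, Fa, _coherence_bin(f_phase, fs, welch))


def comodulogram(x, fs: float, phase_freqs=None, amp_freqs=None,
                 params: MorletParams = MorletParams(),
                 welch: WelchConfig = WelchConfig()) -> Comodulogram:
    """Scan the full (phase, amplitude) grid on one signal.

    Morlet transforms and Welch segment FFTs are computed once per unique
    frequency and shared across cells.
    """
    phase_freqs = default_phase_grid() if phase_freqs is None else np.asarray(phase_freqs, float)
    amp_freqs = default_amp_grid() if amp_freqs is None else np.asarray(amp_freqs, float)
    if phase_freqs.size == 0 or amp_freqs.size == 0:
        raise ValueError("empty frequency grid")
    if not np.any(amp_freqs[None, :] > phase_freqs[:, None]):
        raise ValueError("no grid cell satisfies f_amp > f_phase")

    kept_p, Wp = morlet_transform(x, fs, phase_freqs, params)
    kept_a, Wa = morlet_transform(x, fs, amp_freqs, params)
    ph_ffts = [_segment_ffts(np.cos(np.angle(w)), welch) for w in Wp]
    amp_ffts = [_segment_ffts(np.abs(w), welch) for w in Wa]

    values = np.full((kept_p.size, kept_a.size), np.nan)
    for i, fp in enumerate(kept_p):
        b = _coherence_bin(fp, fs, welch)
        for j, fa in enumerate(kept_a):
            if fa <= fp:
                continue
            values[i, j] = _coherence_from_ffts(ph_ffts[i], amp_ffts[j], b)
    return Comodulogram(values, kept_p, kept_a)


def _fmt(f: float) -> str:
    return f"{f:g}"


def vectorize_comodulogram(c: Comodulogram):
    """Row-major flattening of unmasked cells.

    Returns (names, values); names are ``PAC_<fphase>_<famp>``.
    """
    names, vals = [], []
    for i, fp in enumerate(c.phase_freqs):
        for j, fa in enumerate(c.amp_freqs):
            if np.isnan(c.values[i, j]):
                continue
            names.append(f"PAC_{_fmt(fp)}_{_fmt(fa)}")
            vals.append(c.values[i, j])
    return names, np.asarray(vals)


def comodulogram_from_vector(names, values, phase_freqs, amp_freqs) -> Comodulogram:
    """Inverse of :func:`vectorize_comodulogram` on a known grid."""
    phase_freqs = np.asarray(phase_freqs, float)
    amp_freqs = np.asarray(amp_freqs, float)
    grid = np.full((phase_freqs.size, amp_freqs.size), np.nan)
    lookup = {n: v for n, v in zip(names, values)}
    for i, fp in enumerate(phase_freqs):
        for j, fa in enumerate(amp_freqs):
            key = f"PAC_{_fmt(fp)}_{_fmt(fa)}"
            if key in lookup:
                grid[i, j] = lookup[key]
    return Comodulogram(grid, phase_freqs, amp_freqs)


def pac_feature_table(rec: Recording, epoch_s: float = 0.5, window_s: float = 4.0,
                      phase_freqs=None, amp_freqs=None,
                      params: MorletParams = MorletParams(),
                      welch: WelchConfig = WelchConfig(),
                      fallback_nperseg: int = 128) -> pd.DataFrame:
    """Per-epoch PAC feature table for one (preprocessed) recording.

    Rows align exactly with ``segment(rec, epoch_s)``: each 500 ms epoch
    row carries the comodulogram vector of the 4 s analysis window it
    belongs to; trailing epochs outside the last full window are analysed
    individually with shorter Welch segments.
    """
    phase_freqs = default_phase_grid() if phase_freqs is None else np.asarray(phase_freqs, float)
    amp_freqs = default_amp_grid() if amp_freqs is None else np.asarray(amp_freqs, float)
    epoch_len = int(round(epoch_s * rec.fs))
    epochs_per_window = max(1, int(round(window_s / epoch_s)))
    window_len = epochs_per_window * epoch_len
    n_epochs = rec.n_samples // epoch_len
    if n_epochs < 1:
        raise ValueError(f"subject {rec.subject_id}: recording too short")
    short_welch = WelchConfig(fallback_nperseg, welch.overlap, welch.window)

    # Fixed column set from the requested grid (structural mask excluded),
    # so windowed and fallback rows always align.
    names = [f"PAC_{_fmt(fp)}_{_fmt(fa)}"
             for fp in phase_freqs for fa in amp_freqs if fa > fp]

    def _full_vector(c: Comodulogram) -> np.ndarray:
        got, vals = vectorize_comodulogram(c)
        lookup = dict(zip(got, vals))
        # Cells unanalysable in a short fallback epoch (wavelet support
        # longer than the epoch) carry 0 = no coupling evidence.
        return np.asarray([lookup.get(n, 0.0) for n in names])

    meta_rows, feat_rows = [], []
    for ch in range(rec.n_channels):
        if rec.bad_channel_mask[ch]:
            continue
        muscle, ch_idx = rec.channel_labels[ch]
        sig = rec.samples[ch]
        n_windows = n_epochs // epochs_per_window
        vectors = []
        for w in range(n_windows):
            c = comodulogram(sig[w * window_len:(w + 1) * window_len], rec.fs,
                             phase_freqs, amp_freqs, params, welch)
            vectors.extend([_full_vector(c)] * epochs_per_window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for e in range(n_windows * epochs_per_window, n_epochs):
                try:
                    c = comodulogram(sig[e * epoch_len:(e + 1) * epoch_len],
                                     rec.fs, phase_freqs, amp_freqs, params,
                                     short_welch)
                    vectors.append(_full_vector(c))
                except ValueError:
                    # epoch too short for any requested phase wavelet
                    vectors.append(np.zeros(len(names)))
        for e in range(n_epochs):
            meta_rows.append((rec.subject_id, rec.group, muscle, ch_idx, e))
            feat_rows.append(vectors[e])
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return pd.concat([meta, pd.DataFrame(feat_rows, columns=names)], axis=1)
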