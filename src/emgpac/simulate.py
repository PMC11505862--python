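"""Synthetic two-group HD-sEMG cohort generator.

Produces multi-channel surface-EMG-like recordings for a case/control
cohort in which the case group carries injected phase-amplitude coupling
(PAC): a low-frequency rhythm (default 10 Hz) modulating the amplitude of
a high-frequency carrier (default 150 Hz) on a configurable subset of
muscles.  Channels are band-limited (20-450 Hz) Gaussian noise scaled to
a target RMS; after coupling injection every channel is rescaled back to
the target RMS so that whole-epoch amplitude features are matched across
groups and the class signal lives in the cross-frequency structure, not
in raw amplitude.

The generator is fully deterministic: per-subject random streams are
derived from ``SimConfig.seed`` and the subject index via
``numpy.random.SeedSequence``, so any subject can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = ["SimConfig", "Recording", "generate_subject", "generate_cohort"]

DEFAULT_MUSCLES = ("ECR", "EDC", "ECU", "FCR")

#: Range of per-subject exercise durations (seconds) emulated by default.
DURATION_RANGE_S = (9.1, 95.9)


@dataclass
class Recording:
    """One subject's multi-channel recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitude matrix, channels in rows.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of (muscle, index)
        One ``(muscle_name, within-muscle channel index)`` pair per row.
    subject_id : str
    group : {"case", "control"}
    bad_channel_mask : ndarray of bool, shape (n_channels,)
        True marks a channel to be dropped before analysis.
    meta : dict
        Provenance (true coupling parameters, duration, filter history...).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list
    subject_id: str
    group: str
    bad_channel_mask: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal channel count")
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros(self.n_channels, dtype=bool)
        self.bad_channel_mask = np.asarray(self.bad_channel_mask, dtype=bool)
        if self.bad_channel_mask.shape != (self.n_channels,):
            raise ValueError("bad_channel_mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def label_strings(self):
        """Channel labels as 'MUSCLE_i' strings."""
        return [f"{m}_{i}" for m, i in self.channel_labels]


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    ``duration_s=None`` draws each subject's exercise duration uniformly
    from 9.1-95.9 s; a float fixes it for every subject.  ``coupling_strength``
    (``m``) is the modulation depth of the injected PAC component, in [0, 1].
    ``subject_jitter`` is the relative s.d. applied to the per-subject
    phase frequency, amplitude frequency and coupling strength.
    """

    n_cases: int = 14
    n_controls: int = 14
    fs: float = 2048.0
    duration_s: float | None = None
    muscles: tuple = DEFAULT_MUSCLES
    channels_per_muscle: int = 7
    band: tuple = (20.0, 450.0)
    pac_phase_freq: float = 10.0
    pac_amp_freq: float = 150.0
    coupling_strength: float = 0.8
    coupled_muscles: tuple = ("ECR", "EDC")
    subject_jitter: float = 0.05
    rhythm_gain: float = 0.3
    rms_target: float = 1.0
    bad_channel_rate: float = 0.12
    carrier: str = "sinusoid"  # or "noise" (band-limited noise carrier)
    control_mode: str = "matched"  # or "noise" (controls = background only)
    control_mod_freq: float = 50.0  # controls' (unlocked) AM rate, Hz
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.band[0] < self.band[1] < self.fs / 2):
            raise ValueError("band must lie inside (0, fs/2)")
        if self.pac_amp_freq <= self.pac_phase_freq:
            raise ValueError("pac_amp_freq must exceed pac_phase_freq")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.channels_per_muscle < 1 or not self.muscles:
            raise ValueError("need at least one channel and one muscle")
        if self.duration_s is not None and self.duration_s * self.fs < 0.5 * self.fs:
            raise ValueError("duration too short to hold one 500 ms epoch")
        if self.carrier not in ("sinusoid", "noise"):
            raise ValueError("carrier must be 'sinusoid' or 'noise'")
        if self.control_mode not in ("matched", "noise"):
            raise ValueError("control_mode must be 'matched' or 'noise'")
        unknown = set(self.coupled_muscles) - set(self.muscles)
        if unknown:
            raise ValueError(f"coupled_muscles not in muscles: {sorted(unknown)}")


def _bandlimited_noise(rng, n, fs, band, order=4):
    """Gaussian noise band-passed with a zero-phase Butterworth filter."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


def _subject_rng(cfg: SimConfig, subject_index: int):
    # SeedSequence(seed, index): deterministic per-subject stream,
    # regenerable in isolation.
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index)))


def generate_subject(cfg: SimConfig, subject_index: int, group: str) -> Recording:
    """Generate one subject's recording.

    Case subjects receive, on the coupled muscles, an additive component

        a(t) = m * rms_target * [ (1 + cos(2 pi f_p t + phi)) / 2 * carrier(t)
                                  + rhythm_gain * cos(2 pi f_p t + phi) ]

    i.e. the amplitude-modulated fast carrier *plus* the slow rhythm that
    drives the modulation, phase-locked to the envelope.  The rhythm term
    is what makes the coupling physically detectable: a phase-amplitude
    coupled signal whose slow rhythm is absent carries no phase
    information at f_p, so no phase-referenced estimator could recover
    the coupling.  Per-subject jitter applies to ``f_p``, ``f_a`` and
    ``m``; ``phi``, ``psi`` are random per channel.  Every channel is
    rescaled to ``rms_target`` after injection so whole-epoch RMS is
    group-matched.
    """
    cfg.validate()
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    rng = _subject_rng(cfg, subject_index)

    if cfg.duration_s is None:
        duration = rng.uniform(*DURATION_RANGE_S)
    else:
        duration = float(cfg.duration_s)
    n = int(round(duration * cfg.fs))
    epoch_len = int(round(0.5 * cfg.fs))
    if n < epoch_len:
        raise ValueError(
            f"subject {subject_index}: duration {duration:.3f}s too short "
            "to hold one 500 ms epoch"
        )

    jit = cfg.subject_jitter
    f_p = cfg.pac_phase_freq * (1.0 + jit * rng.standard_normal())
    f_a = cfg.pac_amp_freq * (1.0 + jit * rng.standard_normal())
    m = float(np.clip(cfg.coupling_strength * (1.0 + jit * rng.standard_normal()), 0.0, 1.0))
    if cfg.coupling_strength == 0.0:
        m = 0.0

    t = np.arange(n) / cfg.fs
    labels = [(mus, i) for mus in cfg.muscles for i in range(cfg.channels_per_muscle)]
    samples = np.empty((len(labels), n))
    for ch, (mus, _idx) in enumerate(labels):
        x = _bandlimited_noise(rng, n, cfg.fs, cfg.band)
        x *= cfg.rms_target / np.sqrt(np.mean(x**2))
        # Same generator path for both groups: phases are always drawn so
        # that m=0 cases are distributionally identical to controls.
        phi = rng.uniform(0, 2 * np.pi)
        psi = rng.uniform(0, 2 * np.pi)
        if cfg.carrier == "noise":
            carrier = _bandlimited_noise(rng, n, cfg.fs, (f_a - 15.0, f_a + 15.0))
            carrier /= np.sqrt(np.mean(carrier**2)) * np.sqrt(2)
        else:
            carrier = None
        inject = mus in cfg.coupled_muscles and m > 0 and (
            group == "case" or cfg.control_mode == "matched")
        if inject:
            if carrier is None:
                carrier = np.cos(2 * np.pi * f_a * t + psi)
            if group == "case":
                # fast carrier amplitude-locked to the slow rhythm's phase
                envelope = (1.0 + np.cos(2 * np.pi * f_p * t + phi)) / 2.0
                comp = envelope * carrier \
                    + cfg.rhythm_gain * np.cos(2 * np.pi * f_p * t + phi)
            else:
                # matched controls: same-depth AM but at a fast rate with
                # phases independent of the slow rhythm -- identical
                # amplitude statistics and spectral summaries, no
                # phase-amplitude locking
                phi_c = rng.uniform(0, 2 * np.pi)
                phi_r = rng.uniform(0, 2 * np.pi)
                envelope = (1.0 + np.cos(
                    2 * np.pi * cfg.control_mod_freq * t + phi_c)) / 2.0
                comp = envelope * carrier \
                    + cfg.rhythm_gain * np.cos(2 * np.pi * f_p * t + phi_r)
            x = x + m * cfg.rms_target * comp
            x *= cfg.rms_target / np.sqrt(np.mean(x**2))
        samples[ch] = x

    bad = rng.random(len(labels)) < cfg.bad_channel_rate
    if bad.all():  # keep the subject usable
        bad[rng.integers(len(labels))] = False

    sid = f"{'p' if group == 'case' else 's'}{subject_index:02d}"
    meta = {
        "subject_index": subject_index,
        "duration_s": duration,
        "true_f_phase": f_p,
        "true_f_amp": f_a,
        "true_m": m,
        "coupled_muscles": list(cfg.coupled_muscles) if group == "case" else [],
        "seed": cfg.seed,
    }
    return Recording(samples, cfg.fs, labels, sid, group, bad, meta)


def generate_cohort(cfg: SimConfig):
    """Generate the full cohort.

    Returns
    -------
    recordings : list of Recording
        Cases first, then controls.
    manifest : dict
        subject_id -> {group, duration_s, true coupling parameters}.
    """
    cfg.validate()
    if cfg.n_cases < 1 or cfg.n_controls < 1:
        raise ValueError("need at least one case and one control")
    recordings = []
    manifest = {}
    groups = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    for idx, group in enumerate(groups):
        rec = generate_subject(cfg, idx, group)
        recordings.append(rec)
        manifest[rec.subject_id] = {
            "group": group,
            "duration_s": rec.meta["duration_s"],
            "true_f_phase": rec.meta["true_f_phase"],
            "true_f_amp": rec.meta["true_f_amp"],
            "true_m": rec.meta["true_m"],
            "coupled_muscles": rec.meta["coupled_muscles"],
            "n_bad_channels": int(rec.bad_channel_mask.sum()),
        }
    return recordings, manifest


def scaled_down_config(**overrides) -> SimConfig:
    """A reduced-size cohort configuration for quick end-to-end runs.

    Keeps the cohort composition (14 cases + 14 controls) and coupling
    parameters of the default conditions but shortens recordings to 20 s
    and uses 3 channels per muscle so a full leave-one-subject-out sweep
    runs in minutes on one CPU.
    """
    base = SimConfig(duration_s=20.0, channels_per_muscle=3, bad_channel_rate=0.0)
    return replace(base, **overrides)
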