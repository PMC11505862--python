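"""Recording readers and writers: CSV (+JSON sidecar), EDF, cohort manifests.

CSV is the reference interchange format: one column per channel (header
``MUSCLE_i``), one row per sample, written at full float precision so the
write -> read round trip is bit-exact.  Subject metadata (fs, group,
bad-channel mask) travels in a JSON sidecar next to the CSV.

EDF support: a compact EDF writer (16-bit samples, one file per subject)
is implemented here; reading EDF goes through :mod:`mne` (optional
dependency, imported lazily).  EDF round trips are exact only to 16-bit
quantisation of each channel's amplitude range.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Recording

__all__ = [
    "write_csv_recording", "read_csv_recording",
    "write_edf_recording", "read_edf_recording",
    "write_manifest", "read_manifest",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_csv_recording(rec: Recording, path) -> Path:
    """Write a recording as time x channels CSV plus a JSON sidecar."""
    path = Path(path)
    header = ",".join(rec.label_strings())
    np.savetxt(path, rec.samples.T, delimiter=",", header=header,
               comments="", fmt="%.17g")
    sidecar = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "channel_labels": [[m, i] for m, i in rec.channel_labels],
        "bad_channel_mask": rec.bad_channel_mask.astype(int).tolist(),
        "meta": _jsonable(rec.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_csv_recording(path, fs: float | None = None) -> Recording:
    """Read a CSV recording; uses the JSON sidecar when present."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    samples = frame.to_numpy(dtype=float).T
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sc = json.loads(sidecar_file.read_text())
        labels = [tuple(lab) for lab in sc["channel_labels"]]
        return Recording(samples, sc["fs"], labels, sc["subject_id"], sc["group"],
                         np.asarray(sc["bad_channel_mask"], dtype=bool),
                         sc.get("meta", {}))
    if fs is None:
        raise ValueError(f"{path}: no JSON sidecar found; pass fs explicitly")
    labels = [_parse_label(c) for c in frame.columns]
    return Recording(samples, fs, labels, path.stem, "unknown")


def _parse_label(column: str):
    muscle, _, idx = column.rpartition("_")
    try:
        return (muscle, int(idx))
    except ValueError:
        return (column, 0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_number(value: float, width: int) -> bytes:
    # Fit a float into EDF's fixed-width ASCII numeric fields.
    for fmt in (f"%.{width - 2}g", "%.6g", "%.4g", "%.2g"):
        s = ("%s" % (fmt % value)).replace("e+0", "e+").replace("e-0", "e-")
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf_recording(rec: Recording, path, record_s: float = 0.5) -> Path:
    """Write a recording as a standard continuous EDF file.

    Samples are quantised to 16 bits over each channel's own amplitude
    range; the final data record is zero-padded when the recording length
    is not a whole number of records.
    """
    path = Path(path)
    n_sig = rec.n_channels
    spr = int(round(record_s * rec.fs))
    if abs(spr - record_s * rec.fs) > 1e-9 or spr < 1:
        raise ValueError("record_s must give an integer number of samples")
    n_rec = -(-rec.n_samples // spr)  # ceil
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : rec.n_samples] = rec.samples

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    digital = np.round((padded - phys_min[:, None]) / span[:, None] * 65535 - 32768)
    digital = digital.astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"{rec.subject_id} {rec.group}", 80),
        _edf_field("emgpac synthetic HD-sEMG", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_sig)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_number(record_s, 8),
        _edf_field(str(n_sig), 4),
    ])
    labels = rec.label_strings()
    header += b"".join(_edf_field(lab, 16) for lab in labels)
    header += b"".join(_edf_field("sEMG electrode", 80) for _ in labels)
    header += b"".join(_edf_field("uV", 8) for _ in labels)
    header += b"".join(_edf_number(v, 8) for v in phys_min)
    header += b"".join(_edf_number(v, 8) for v in phys_max)
    header += b"".join(_edf_field("-32768", 8) for _ in labels)
    header += b"".join(_edf_field("32767", 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)
    header += b"".join(_edf_field(str(spr), 8) for _ in labels)
    header += b"".join(_edf_field("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        # EDF interleaves: per record, all samples of signal 0, then 1, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf_recording(path, subject_id=None, group="unknown") -> Recording:
    """Read an EDF file into a Recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package "
                          "(install emgpac[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data()
    labels = [_parse_label(c) for c in raw.ch_names]
    return Recording(samples, float(raw.info["sfreq"]), labels,
                     subject_id or Path(path).stem, group)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(manifest), indent=1, sort_keys=True))
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
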