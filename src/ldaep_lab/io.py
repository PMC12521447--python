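"""Dataset I/O: EDF recordings, BIDS-style TSV sidecars, cohort CSVs, epochs.

Raw recordings are written as 16-bit EDF with per-channel physical scaling
(quantization step = physical range / 65535) plus BIDS-style
``*_events.tsv`` (onset, duration, trial_type = intensity in dB) and
``*_channels.tsv`` (name, type, units, sampling_frequency) sidecars.
Recordings are read back through MNE's native EDF reader.  Cleaned epochs
are stored as a ``.npy`` array with a JSON sidecar carrying the sampling
rate, window, channel labels/types, intensity labels and keep flags.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from ldaep_lab.paradigm import EventList
from ldaep_lab.preprocessing import EpochSet
from ldaep_lab.simulate import RawRecording

__all__ = [
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
    "write_channels_tsv",
    "read_channels_tsv",
    "write_bids_subject",
    "read_bids_subject",
    "save_epochs",
    "load_epochs",
]


def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def _num8(v: float) -> str:
    """Shortest float representation fitting the 8-char EDF numeric field."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot represent {v} in 8 characters")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (one 1-second data record per second).

    The sampling rate must be an integer.  Physical units are μV; digital
    range is the full int16 span, physical range the per-channel data range
    (symmetric fallback ±1 μV for flat channels).
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    dig_min, dig_max = -32768, 32767

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        b"".join(_pad(lab, 16) for lab in rec.channel_labels),
        b"".join(_pad("EEG" if t == "EEG" else "EOG", 80) for t in rec.channel_types),
        b"".join(_pad("uV", 8) for _ in range(n_ch)),
        b"".join(_pad(_num8(phys_min[i]), 8) for i in range(n_ch)),
        b"".join(_pad(_num8(phys_max[i]), 8) for i in range(n_ch)),
        b"".join(_pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(fs), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ]
    # physical min/max written with limited precision: reuse the parsed values
    pmin = np.array([float(_num8(phys_min[i])) for i in range(n_ch)])
    pmax = np.array([float(_num8(phys_max[i])) for i in range(n_ch)])
    pmax = np.where(pmax <= pmin, pmin + 1.0, pmax)

    scale = (dig_max - dig_min) / (pmax - pmin)
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :rec.n_samples] = rec.data
    dig = np.clip(
        np.rint((padded - pmin[:, None]) * scale[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for blk in fields:
            fh.write(blk)
        for r in range(n_rec):
            fh.write(dig[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path, events: EventList | None = None) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (μV) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    types = ["EOG" if lab.upper().startswith(("EOG", "VEOG", "HEOG", "EXG")) else "EEG"
             for lab in labels]
    data = raw.get_data() * 1e6  # volts -> μV
    return RawRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_types=types,
        events=events,
        reference_state="raw",
    )


def write_events_tsv(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "onset": events.onsets_s,
        "duration": np.full(len(events), events.tone_duration_ms / 1000.0),
        "trial_type": events.intensity_db.astype(int).astype(str),
    }).to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    dur = float(df["duration"].iloc[0]) * 1000.0 if len(df) else 30.0
    return EventList(
        onsets_s=df["onset"].to_numpy(dtype=float),
        intensity_db=df["trial_type"].to_numpy(dtype=float),
        tone_duration_ms=dur,
    )


def write_channels_tsv(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "name": rec.channel_labels,
        "type": rec.channel_types,
        "units": ["uV"] * rec.n_channels,
        "sampling_frequency": [rec.fs] * rec.n_channels,
    }).to_csv(path, sep="\t", index=False)
    return path


def read_channels_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bids_subject(rec: RawRecording, root: str | Path, subject_id: str,
                       task: str = "ldaep") -> dict[str, Path]:
    """Write one subject's EDF + events/channels TSVs in a BIDS-style layout."""
    root = Path(root)
    eeg_dir = root / subject_id / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{subject_id}_task-{task}"
    paths = {
        "eeg": write_edf(rec, eeg_dir / f"{stem}_eeg.edf"),
        "channels": write_channels_tsv(rec, eeg_dir / f"{stem}_channels.tsv"),
    }
    if rec.events is not None:
        paths["events"] = write_events_tsv(rec.events, eeg_dir / f"{stem}_events.tsv")
    return paths


def read_bids_subject(root: str | Path, subject_id: str, task: str = "ldaep"
                      ) -> RawRecording:
    root = Path(root)
    eeg_dir = root / subject_id / "eeg"
    stem = f"{subject_id}_task-{task}"
    events_path = eeg_dir / f"{stem}_events.tsv"
    events = read_events_tsv(events_path) if events_path.exists() else None
    rec = read_edf(eeg_dir / f"{stem}_eeg.edf", events=events)
    ch_path = eeg_dir / f"{stem}_channels.tsv"
    if ch_path.exists():
        ch = read_channels_tsv(ch_path)
        lut = dict(zip(ch["name"], ch["type"]))
        rec.channel_types = [lut.get(lab, t) for lab, t in
                             zip(rec.channel_labels, rec.channel_types)]
    return rec


def save_epochs(es: EpochSet, path_stem: str | Path) -> tuple[Path, Path]:
    """Save an epoch set as ``<stem>.npy`` + ``<stem>.json`` sidecar."""
    stem = Path(path_stem)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, es.data)
    with open(meta, "w") as fh:
        json.dump({
            "fs": es.fs,
            "times": es.times.tolist(),
            "intensity_db": es.intensity_db.tolist(),
            "keep": es.keep.astype(bool).tolist(),
            "channel_labels": es.channel_labels,
            "channel_types": es.channel_types,
            "subject_id": es.subject_id,
            "drop_reasons": {str(k): v for k, v in es.drop_reasons.items()},
        }, fh)
    return npy, meta


def load_epochs(path_stem: str | Path) -> EpochSet:
    stem = Path(path_stem)
    data = np.load(stem.with_suffix(".npy"))
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return EpochSet(
        data=data,
        fs=float(meta["fs"]),
        times=np.asarray(meta["times"]),
        intensity_db=np.asarray(meta["intensity_db"]),
        keep=np.asarray(meta["keep"], dtype=bool),
        channel_labels=list(meta["channel_labels"]),
        channel_types=list(meta["channel_types"]),
        subject_id=meta.get("subject_id", ""),
        drop_reasons={int(k): v for k, v in meta.get("drop_reasons", {}).items()},
    )
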