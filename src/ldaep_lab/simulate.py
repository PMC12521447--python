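"""Raw multichannel EEG simulation for auditory-evoked-potential studies.

Each stimulus adds a stereotyped N1 + P2 response to every EEG channel,
scaled by a fixed spatial topography that is maximal at Cz and has zero mean
across EEG channels (so the average reference leaves the Cz response
unchanged).  Component amplitudes vary linearly with stimulus intensity:

    A_N1(dB) = n1_intercept + n1_slope * (dB - 75)     (negative)
    A_P2(dB) = p2_intercept + p2_slope * (dB - 75)     (positive)

The default component kernel is a unit-peak DPSS (Slepian) window of
half-width 70 ms: strictly zero outside its support and spectrally
concentrated below ~26 Hz, so the downstream 30 Hz low-pass and the
2048→512 Hz resampling transmit the component peaks essentially unchanged.
Peak latencies sit exactly on the 512 Hz analysis grid (99.6 ms and
179.7 ms), mid-window for the 60–140 ms (N1) and 150–250 ms (P2) detection
windows.  A Gaussian kernel (σ = 15/25 ms) is available as an option.

Background activity: pink (1/f) noise per channel, a 50 Hz line-noise
sinusoid, and Poisson-scheduled biphasic blink transients (~400 ms,
≥100 μV on the EOG channels, frontally weighted on EEG).  Bad channels
(flat or high-variance) and bad segments (broadband bursts) can be injected
for testing the artifact screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from ldaep_lab.paradigm import ConfigurationError, EventList
from ldaep_lab.cohort import SubjectProfile

__all__ = [
    "RawRecording",
    "make_montage",
    "simulate_recording",
    "erp_kernel",
    "erp_topography",
    "N1_PEAK_S",
    "P2_PEAK_S",
]

# Component peak latencies on the 512 Hz analysis grid (mid-window).
N1_PEAK_S = 51.0 / 512.0  # ≈ 99.6 ms
P2_PEAK_S = 92.0 / 512.0  # ≈ 179.7 ms
KERNEL_HALF_WIDTH_S = 0.070
KERNEL_NW = 3.5

DEFAULT_EEG = ("Fz", "F3", "F4", "Cz", "C3", "C4", "Pz", "Oz")
DEFAULT_EOG = ("VEOG", "HEOG")


@dataclass
class RawRecording:
    """Channels × samples EEG signal in μV with event metadata."""

    data: np.ndarray  # (n_channels, n_samples), μV
    fs: float
    channel_labels: list[str]
    channel_types: list[str]  # "EEG" | "EOG"
    events: EventList | None = None
    reference_state: str = "raw"  # "raw" | "average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length mismatch")
        if len(self.channel_types) != len(self.channel_labels):
            raise ValueError("channel_types length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero([t == "EEG" for t in self.channel_types])

    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero([t == "EOG" for t in self.channel_types])

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy())


def make_montage(name: str = "default8") -> tuple[list[str], list[str]]:
    """Return (labels, types) for a named montage.

    ``default8``: 8 EEG + 2 EOG channels (fast simulations).
    ``biosemi64``: the 64-channel 10-10 layout plus 4 periocular EOG
    channels (EXG1–EXG4), matching a BioSemi ActiveTwo setup.
    """
    if name == "default8":
        labels = list(DEFAULT_EEG) + list(DEFAULT_EOG)
        types = ["EEG"] * len(DEFAULT_EEG) + ["EOG"] * len(DEFAULT_EOG)
    elif name == "biosemi64":
        import mne

        eeg = list(mne.channels.make_standard_montage("biosemi64").ch_names)
        labels = eeg + ["EXG1", "EXG2", "EXG3", "EXG4"]
        types = ["EEG"] * len(eeg) + ["EOG"] * 4
    else:
        raise ConfigurationError(f"unknown montage {name!r}")
    return labels, types


def erp_kernel(fs: float, kind: str = "dpss", component: str = "n1") -> np.ndarray:
    """Unit-peak component kernel sampled at ``fs`` (odd length, peak centred)."""
    if kind == "dpss":
        m = 2 * int(round(KERNEL_HALF_WIDTH_S * fs)) + 1
        w = signal.windows.dpss(m, KERNEL_NW)
        return w / w.max()
    if kind == "gaussian":
        sigma = 0.015 if component == "n1" else 0.025
        half = int(round(4 * sigma * fs))
        t = np.arange(-half, half + 1) / fs
        return np.exp(-0.5 * (t / sigma) ** 2)
    raise ConfigurationError(f"unknown kernel kind {kind!r}")


def _prefix_weight(label: str, table: dict[str, float], default: float) -> float:
    best = default
    best_len = 0
    for prefix, w in table.items():
        if label.upper().startswith(prefix.upper()) and len(prefix) > best_len:
            best = w
            best_len = len(prefix)
    return best


_ERP_W = {
    "Cz": 1.0, "C": 0.55, "FC": 0.6, "CP": 0.5, "Fz": 0.55, "F": 0.4,
    "AF": 0.25, "Fp": 0.2, "Pz": 0.45, "P": 0.3, "PO": 0.15, "O": 0.1,
    "T": 0.2, "Iz": 0.05,
}

_BLINK_W = {
    "Fp": 1.0, "AF": 0.8, "F": 0.45, "FC": 0.25, "C": 0.12, "T": 0.1,
    "CP": 0.06, "P": 0.04, "PO": 0.02, "O": 0.01,
}


def erp_topography(labels: list[str], types: list[str]) -> np.ndarray:
    """Fixed spatial profile of the auditory response: zero-mean over EEG
    channels with weight exactly 1 at Cz; zero on EOG channels."""
    labels = list(labels)
    if "Cz" not in labels or types[labels.index("Cz")] != "EEG":
        raise ConfigurationError("montage must contain an EEG channel named Cz")
    w = np.zeros(len(labels))
    eeg = [i for i, t in enumerate(types) if t == "EEG"]
    for i in eeg:
        w[i] = _prefix_weight(labels[i], _ERP_W, 0.3)
    w[eeg] -= np.mean(w[eeg])
    cz = labels.index("Cz")
    if w[cz] <= 0:
        raise ConfigurationError("degenerate montage: Cz weight non-positive")
    w /= w[cz]
    return w


def _blink_topography(labels: list[str], types: list[str]) -> np.ndarray:
    w = np.zeros(len(labels))
    for i, (lab, typ) in enumerate(zip(labels, types)):
        w[i] = 1.0 if typ == "EOG" else _prefix_weight(lab, _BLINK_W, 0.02)
    return w


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, rms_uv: float, spatial_scale: float = 1.5) -> np.ndarray:
    """Spatially correlated 1/f background activity.

    Independent pink (1/f, flat below 1 Hz) sources are mixed across
    channels with a Gaussian index-distance kernel (``spatial_scale`` in
    channel-index units), emulating the smooth inter-channel correlation
    that volume conduction produces in real EEG.  Each output channel is
    scaled to ``rms_uv``.  ``spatial_scale = 0`` yields independent noise.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shape[0] = 0.0  # no DC offset
    src = np.empty((n_channels, n_samples))
    for c in range(n_channels):
        spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        src[c] = np.fft.irfft(spec * shape, n_samples)
    if n_channels > 1 and spatial_scale > 0:
        idx = np.arange(n_channels)
        mix = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / spatial_scale) ** 2)
        out = mix @ src
    else:
        out = src
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out * (rms_uv / sd)


def _blink_waveform(fs: float) -> np.ndarray:
    """Biphasic transient, ~400 ms total, unit positive peak."""
    n1 = int(round(0.28 * fs))
    n2 = int(round(0.12 * fs))
    lobe1 = np.hanning(n1)
    lobe2 = -0.25 * np.hanning(n2)
    return np.concatenate([lobe1, lobe2])


def simulate_recording(
    profile: SubjectProfile,
    events: EventList,
    fs: float = 2048.0,
    montage: str | tuple[list[str], list[str]] = "default8",
    seed: int = 0,
    kernel: str = "dpss",
    blink_amp_uv: float = 150.0,
    eog_noise_uv: float = 4.0,
    lead_out_s: float = 2.0,
    bad_channels: dict[str, str] | None = None,
    bad_segments: list[tuple[float, float]] | None = None,
) -> RawRecording:
    """Simulate a raw recording for one subject.

    Parameters
    ----------
    profile
        Ground-truth generative parameters.
    events
        Stimulus schedule (onsets must fit in the recording).
    montage
        Montage name or explicit ``(labels, types)``.
    kernel
        ``"dpss"`` (default) or ``"gaussian"`` component kernel.
    bad_channels
        Mapping label → ``"flat"`` or ``"noisy"``; injected after signal
        construction for testing the bad-channel screen.
    bad_segments
        List of (start_s, end_s) spans receiving a broadband high-amplitude
        burst, for testing the bad-segment screen.
    """
    labels, types = make_montage(montage) if isinstance(montage, str) else montage
    labels, types = list(labels), list(types)
    rng = np.random.default_rng(seed)
    n_ch = len(labels)

    duration = float(events.onsets_s[-1]) + max(lead_out_s, 0.5)
    n = int(round(duration * fs))
    data = np.zeros((n_ch, n))

    topo = erp_topography(labels, types)
    k1 = erp_kernel(fs, kernel, "n1")
    k2 = erp_kernel(fs, kernel, "p2")
    h1, h2 = (len(k1) - 1) // 2, (len(k2) - 1) // 2

    cz_trace = np.zeros(n)
    for onset, db in zip(events.onsets_s, events.intensity_db):
        a_n1 = profile.true_n1_intercept_uv + profile.true_n1_slope_uv_per_db * (db - 75.0)
        a_p2 = profile.true_p2_intercept_uv + profile.true_p2_slope_uv_per_db * (db - 75.0)
        c1 = int(round((onset + N1_PEAK_S) * fs))
        c2 = int(round((onset + P2_PEAK_S) * fs))
        if c1 - h1 < 0 or c2 + h2 >= n:
            raise ConfigurationError("event does not fit within the recording")
        cz_trace[c1 - h1:c1 + h1 + 1] += a_n1 * k1
        cz_trace[c2 - h2:c2 + h2 + 1] += a_p2 * k2
    data += topo[:, None] * cz_trace[None, :]

    # pink background noise on EEG; independent noise on EOG
    eeg = np.flatnonzero([t == "EEG" for t in types])
    eog = np.flatnonzero([t == "EOG" for t in types])
    if profile.noise_sigma_uv > 0:
        data[eeg] += _pink_noise(rng, eeg.size, n, fs, profile.noise_sigma_uv)
    if eog_noise_uv > 0 and profile.noise_sigma_uv > 0:
        data[eog] += _pink_noise(rng, eog.size, n, fs, eog_noise_uv)

    # 50 Hz line noise, common phase across EEG channels
    if profile.line_amp_uv > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data[eeg] += profile.line_amp_uv * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]

    # Poisson-scheduled blink transients
    if profile.blink_rate_hz > 0:
        blink = _blink_waveform(fs)
        blink_topo = _blink_topography(labels, types)
        n_blinks = rng.poisson(profile.blink_rate_hz * duration)
        starts = rng.uniform(0, max(duration - len(blink) / fs, 0.0), size=n_blinks)
        trace = np.zeros(n)
        for s in np.sort(starts):
            i0 = int(round(s * fs))
            trace[i0:i0 + len(blink)] += blink_amp_uv * rng.uniform(0.8, 1.2) * blink
        data += blink_topo[:, None] * trace[None, :]

    for start_s, end_s in bad_segments or []:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        data[:, i0:i1] += rng.standard_normal((n_ch, max(i1 - i0, 0))) * 100.0

    # bad channels injected last so they stay flat/noisy end to end
    for lab, kind in (bad_channels or {}).items():
        i = labels.index(lab)
        if kind == "flat":
            data[i] = 0.0
        elif kind == "noisy":
            data[i] = rng.standard_normal(n) * 100.0
        else:
            raise ConfigurationError(f"unknown bad-channel kind {kind!r}")

    return RawRecording(
        data=data,
        fs=fs,
        channel_labels=labels,
        channel_types=types,
        events=events,
        reference_state="raw",
    )
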