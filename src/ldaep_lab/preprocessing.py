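"""Four-stage EEG cleaning chain: from raw recording to artifact-screened epochs.

Stage order (recorded in the run manifest):

1. FFT resampling to 512 Hz;
2. bad-channel detection on a *detection copy* (1 Hz high-pass + 50 Hz
   spectral interpolation, unreferenced): robust-z of log-variance,
   windowed inter-channel correlation floor, and robust-z of >40 Hz
   relative power;
3. exclusion of bad channels, re-reference to the average of the remaining
   channels (for a fixed channel subset this equals re-referencing twice,
   first to all channels and then to the subset, so the analysis path is
   the conventional one), bad-segment detection on a second detection copy
   (1–100 Hz
   band-pass + line suppression; 5-s blocks dropped when more than 25% of
   channels exceed a 25 μV sample SD), and ocular-artifact removal by
   whole-recording least-squares regression on the EOG channels;
4. 30 Hz low-pass, segmentation into 600 ms epochs (−100 to +500 ms,
   baseline-corrected on the pre-stimulus mean), and FASTER-style epoch
   rejection (|z| > 3 on amplitude range, variance, and channel-mean
   deviation, each averaged over channels).

Filters are zero-phase spectral (FFT) filters with raised-cosine
transitions; the low-pass passband is unity up to the nominal cutoff, which
keeps band-limited signal content numerically intact.  Epochs overlapping a
dropped segment are excluded rather than excising samples from the
continuous recording, which keeps event bookkeeping exact
(kept + dropped = scheduled, per intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ldaep_lab.paradigm import ConfigurationError, EventList
from ldaep_lab.simulate import RawRecording

__all__ = [
    "PreprocConfig",
    "ChannelReport",
    "SegmentMask",
    "EpochSet",
    "rereference_average",
    "resample",
    "suppress_line_noise",
    "detect_bad_channels",
    "detect_bad_segments",
    "remove_ocular_artifacts",
    "epoch_data",
    "reject_epochs",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocConfig:
    resample_fs: float = 512.0
    line_freq: float = 50.0
    hp_detect: float = 1.0  # detection-copy high-pass only
    bandpass: tuple[float, float] = (1.0, 100.0)  # segment-detection copy
    final_lowpass: float = 30.0
    lowpass_transition: float = 4.0
    segment_block_s: float = 5.0
    segment_channel_fraction: float = 0.25
    segment_sd_uv: float = 25.0
    epoch_window_s: tuple[float, float] = (-0.100, 0.500)
    epoch_reject_z: float = 3.0
    baseline: bool = True
    bad_var_z: float = 5.0
    bad_corr_floor: float = 0.4
    bad_spec_z: float = 5.0

    def __post_init__(self) -> None:
        nyq = self.resample_fs / 2.0
        for f in (self.line_freq, self.hp_detect, *self.bandpass, self.final_lowpass):
            if f >= nyq:
                raise ConfigurationError(f"frequency {f} Hz >= Nyquist {nyq} Hz")
        if not self.epoch_window_s[0] < 0.0 < self.epoch_window_s[1]:
            raise ConfigurationError("epoch window must straddle stimulus onset")


@dataclass
class ChannelReport:
    """Per-channel quality flags (one primary flag per channel) and metrics."""

    flags: dict[str, str]  # label -> good | bad_variance | bad_correlation | bad_spectrum
    metrics: dict[str, dict[str, float]]

    def bad_channels(self) -> list[str]:
        return [c for c, f in self.flags.items() if f != "good"]


@dataclass
class SegmentMask:
    """Keep/drop decision per consecutive block of the recording."""

    keep: np.ndarray  # (n_blocks,) bool
    bounds: np.ndarray  # (n_blocks + 1,) sample indices
    fs: float

    def n_dropped(self) -> int:
        return int(np.sum(~self.keep))

    def dropped_spans_s(self) -> list[tuple[float, float]]:
        return [
            (self.bounds[i] / self.fs, self.bounds[i + 1] / self.fs)
            for i in np.flatnonzero(~self.keep)
        ]


@dataclass
class EpochSet:
    """Trials × channels × samples array aligned to stimulus onset."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples), μV
    fs: float
    times: np.ndarray  # (n_samples,), seconds, 0 = onset
    intensity_db: np.ndarray  # (n_epochs,)
    keep: np.ndarray  # (n_epochs,) bool
    channel_labels: list[str]
    channel_types: list[str]
    subject_id: str = ""
    drop_reasons: dict[int, str] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def kept_counts(self) -> dict[float, int]:
        vals = np.unique(self.intensity_db)
        return {float(v): int(np.sum(self.keep & (self.intensity_db == v))) for v in vals}

    def scheduled_counts(self) -> dict[float, int]:
        vals, cnts = np.unique(self.intensity_db, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))


# ---------------------------------------------------------------------------
# spectral filtering helpers

def _fft_filter(data: np.ndarray, fs: float, lo: float | None, hi: float | None,
                lo_tw: float = 1.0, hi_tw: float = 4.0) -> np.ndarray:
    """Zero-phase spectral filter with raised-cosine transitions.

    Passband gain is exactly 1 between ``lo`` and ``hi``; the high-pass
    transition spans [lo − lo_tw, lo], the low-pass transition [hi, hi + hi_tw].
    """
    n = data.shape[-1]
    f = np.fft.rfftfreq(n, 1.0 / fs)
    h = np.ones_like(f)
    if lo is not None and lo > 0:
        f0 = max(lo - lo_tw, 0.0)
        ramp = (f > f0) & (f < lo)
        h[f <= f0] = 0.0
        if lo > f0:
            h[ramp] = 0.5 * (1 - np.cos(np.pi * (f[ramp] - f0) / (lo - f0)))
    if hi is not None:
        f1 = hi + hi_tw
        ramp = (f > hi) & (f < f1)
        h[ramp] = 0.5 * (1 + np.cos(np.pi * (f[ramp] - hi) / hi_tw))
        h[f >= f1] = 0.0
    return np.fft.irfft(np.fft.rfft(data, axis=-1) * h, n, axis=-1)


# ---------------------------------------------------------------------------
# operations

def rereference_average(rec: RawRecording, channel_subset: list[str] | None = None
                        ) -> RawRecording:
    """Re-reference the EEG channels in ``channel_subset`` to their average.

    Channels outside the subset (and all EOG channels) are left untouched.
    After the call the mean across the referenced channels is zero at every
    sample.
    """
    out = rec.copy()
    eeg = set(np.asarray(rec.channel_labels)[rec.eeg_indices()])
    if channel_subset is None:
        subset = sorted(eeg)
    else:
        subset = [c for c in channel_subset if c in eeg]
    if len(subset) < 2:
        raise ConfigurationError("need at least 2 EEG channels to re-reference")
    idx = [rec.channel_labels.index(c) for c in subset]
    ref = out.data[idx].mean(axis=0)
    out.data[idx] -= ref[None, :]
    out.reference_state = "average"
    return out


def resample(rec: RawRecording, target_fs: float) -> RawRecording:
    """FFT-resample to ``target_fs`` (downsampling only); onsets stay in seconds."""
    if target_fs > rec.fs:
        raise ConfigurationError("upsampling not supported")
    if target_fs == rec.fs:
        return rec.copy()
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    from scipy.signal import resample as _scipy_resample

    out = rec.copy()
    out.data = _scipy_resample(rec.data, n_out, axis=-1)
    out.fs = float(target_fs)
    return out


def suppress_line_noise(rec: RawRecording, line_freq: float = 50.0,
                        half_bw: float = 1.0, flank_bw: float = 2.0) -> RawRecording:
    """Suppress line noise by spectral interpolation.

    The amplitude spectrum within ``line_freq ± half_bw`` is replaced, per
    channel, by log-magnitude linear interpolation between the mean flanking
    magnitudes; phase is preserved.
    """
    if line_freq + half_bw + flank_bw >= rec.fs / 2.0:
        raise ConfigurationError("interpolation band exceeds Nyquist")
    out = rec.copy()
    n = rec.n_samples
    f = np.fft.rfftfreq(n, 1.0 / rec.fs)
    band = np.flatnonzero(np.abs(f - line_freq) <= half_bw)
    lo_flank = np.flatnonzero((f >= line_freq - half_bw - flank_bw) & (f < line_freq - half_bw))
    hi_flank = np.flatnonzero((f > line_freq + half_bw) & (f <= line_freq + half_bw + flank_bw))
    if band.size == 0 or lo_flank.size == 0 or hi_flank.size == 0:
        return out
    spec = np.fft.rfft(out.data, axis=-1)
    tiny = 1e-30
    mag = np.abs(spec)
    log_lo = np.log(np.maximum(mag[:, lo_flank].mean(axis=1), tiny))
    log_hi = np.log(np.maximum(mag[:, hi_flank].mean(axis=1), tiny))
    f_lo, f_hi = f[lo_flank].mean(), f[hi_flank].mean()
    w = (f[band] - f_lo) / (f_hi - f_lo)
    target = np.exp(log_lo[:, None] * (1 - w)[None, :] + log_hi[:, None] * w[None, :])
    phase = np.where(mag[:, band] > 0, spec[:, band] / np.maximum(mag[:, band], tiny), 1.0)
    # channels that are exactly zero stay zero
    zero_ch = mag.max(axis=1) == 0
    target[zero_ch] = 0.0
    spec[:, band] = target * phase
    out.data = np.fft.irfft(spec, n, axis=-1)
    return out


def _robust_z(x: np.ndarray, min_scale: float = 0.0) -> np.ndarray:
    """Median/MAD z-score.  ``min_scale`` floors the scale estimate so that
    spreads below measurement meaningfulness (e.g. float rounding on
    degenerate noiseless inputs) do not produce spurious outliers."""
    med = np.median(x)
    scale = max(1.4826 * np.median(np.abs(x - med)), min_scale)
    if scale == 0:
        return np.where(x == med, 0.0, np.inf * np.sign(x - med))
    return (x - med) / scale


def detect_bad_channels(rec: RawRecording, config: PreprocConfig = PreprocConfig()
                        ) -> ChannelReport:
    """Flag bad EEG channels by variance, inter-correlation, and spectrum.

    Expects a detection copy (high-passed at ``hp_detect`` and
    line-suppressed).  A channel is flagged when (a) the robust z-score of
    its log-variance exceeds ``bad_var_z`` in magnitude, (b) its maximum
    absolute correlation with any other channel falls below
    ``bad_corr_floor``, or (c) the robust z-score of its >40 Hz relative
    power exceeds ``bad_spec_z``.
    """
    eeg = rec.eeg_indices()
    labels = [rec.channel_labels[i] for i in eeg]
    x = rec.data[eeg]
    n_ch = len(labels)
    flags = {lab: "good" for lab in labels}
    metrics: dict[str, dict[str, float]] = {lab: {} for lab in labels}

    var = x.var(axis=1)
    logvar = np.log(np.maximum(var, 1e-30))
    vz = _robust_z(logvar, min_scale=1e-3)

    # inter-channel correlation: per-window max |corr|, median across windows
    # (a single broadband burst then cannot decorrelate every channel)
    if n_ch >= 4:
        win = max(int(round(config.segment_block_s * rec.fs)), 2)
        starts = range(0, max(rec.n_samples - win + 1, 1), win)
        per_win = []
        for s in starts:
            seg = x[:, s:s + win]
            sd = seg.std(axis=1)
            corr = np.zeros((n_ch, n_ch))
            ok = np.flatnonzero(sd > 0)
            if ok.size >= 2:
                corr[np.ix_(ok, ok)] = np.corrcoef(seg[ok])
            np.fill_diagonal(corr, 0.0)
            per_win.append(np.abs(corr).max(axis=1))
        max_corr = np.median(per_win, axis=0)
    else:
        warnings.warn("fewer than 4 EEG channels: correlation criterion skipped")
        max_corr = np.ones(n_ch)

    # high-frequency relative power
    f = np.fft.rfftfreq(rec.n_samples, 1.0 / rec.fs)
    psd = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    total = psd.sum(axis=1)
    hf = psd[:, f > 40.0].sum(axis=1)
    rel_hf = np.where(total > 0, hf / np.maximum(total, 1e-30), 0.0)
    sz = _robust_z(rel_hf, min_scale=1e-4)

    for i, lab in enumerate(labels):
        metrics[lab] = dict(
            variance=float(var[i]), log_variance_z=float(vz[i]),
            max_abs_correlation=float(max_corr[i]), hf_relative_power_z=float(sz[i]),
        )
        if np.abs(vz[i]) > config.bad_var_z:
            flags[lab] = "bad_variance"
        elif max_corr[i] < config.bad_corr_floor:
            flags[lab] = "bad_correlation"
        elif sz[i] > config.bad_spec_z:
            flags[lab] = "bad_spectrum"
    return ChannelReport(flags=flags, metrics=metrics)


def detect_bad_segments(rec: RawRecording, config: PreprocConfig = PreprocConfig()
                        ) -> SegmentMask:
    """Mark consecutive blocks where too many channels are too noisy.

    A block is dropped iff strictly more than ``segment_channel_fraction`` of
    the EEG channels have a sample SD strictly exceeding ``segment_sd_uv``.
    The trailing partial block is evaluated the same way.
    """
    eeg = rec.eeg_indices()
    block = int(round(config.segment_block_s * rec.fs))
    n = rec.n_samples
    bounds = list(range(0, n, block)) + [n]
    if len(bounds) >= 2 and bounds[-1] == bounds[-2]:
        bounds.pop()
    bounds = np.asarray(bounds)
    keep = np.ones(len(bounds) - 1, dtype=bool)
    for b in range(len(bounds) - 1):
        seg = rec.data[eeg, bounds[b]:bounds[b + 1]]
        frac = np.mean(seg.std(axis=1) > config.segment_sd_uv)
        if frac > config.segment_channel_fraction:
            keep[b] = False
    return SegmentMask(keep=keep, bounds=bounds, fs=rec.fs)


def remove_ocular_artifacts(rec: RawRecording) -> RawRecording:
    """Subtract the least-squares projection of each EEG channel onto the EOG
    channels (whole-recording regression, no intercept).

    EOG channels are preserved.  With all-zero EOG the output equals the
    input; with no EOG channels at all, the recording passes through with a
    warning.
    """
    eog = rec.eog_indices()
    if eog.size == 0:
        warnings.warn("no EOG channels: ocular-artifact removal skipped")
        return rec.copy()
    out = rec.copy()
    eeg = rec.eeg_indices()
    x = rec.data[eog].T  # (n_samples, n_eog)
    y = rec.data[eeg].T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    out.data[eeg] = (y - x @ beta).T
    return out


def epoch_data(rec: RawRecording, events: EventList | None = None,
               window: tuple[float, float] = (-0.100, 0.500),
               baseline: bool = True, subject_id: str = "") -> EpochSet:
    """Cut stimulus-locked epochs with pre-stimulus baseline correction.

    Sample indices run over ``[round(w0·fs), round(w1·fs))`` relative to the
    onset sample; events too close to a recording edge are dropped (recorded
    in ``drop_reasons``).
    """
    if events is None:
        events = rec.events
    if events is None:
        raise ConfigurationError("no events available for epoching")
    fs = rec.fs
    i0 = int(round(window[0] * fs))  # negative
    n_samp = int(round((window[1] - window[0]) * fs))
    times = (np.arange(n_samp) + i0) / fs
    pre = times < 0

    data = []
    labels = []
    keep = []
    reasons: dict[int, str] = {}
    for e, (onset, db) in enumerate(zip(events.onsets_s, events.intensity_db)):
        c = int(round(onset * fs))
        a, b = c + i0, c + i0 + n_samp
        labels.append(db)
        if a < 0 or b > rec.n_samples:
            data.append(np.zeros((rec.n_channels, n_samp)))
            keep.append(False)
            reasons[e] = "edge"
            continue
        ep = rec.data[:, a:b].copy()
        if baseline and pre.any():
            ep -= ep[:, pre].mean(axis=1, keepdims=True)
        data.append(ep)
        keep.append(True)
    return EpochSet(
        data=np.asarray(data),
        fs=fs,
        times=times,
        intensity_db=np.asarray(labels, dtype=float),
        keep=np.asarray(keep, dtype=bool),
        channel_labels=list(rec.channel_labels),
        channel_types=list(rec.channel_types),
        subject_id=subject_id,
        drop_reasons=reasons,
    )


def reject_epochs(es: EpochSet, z_threshold: float = 3.0) -> EpochSet:
    """FASTER-style epoch screen on currently kept epochs.

    Three per-epoch metrics, each averaged over channels: amplitude range,
    variance, and the deviation of the epoch's channel means from the
    channel grand means.  An epoch is dropped iff any metric's |z| across
    kept epochs exceeds ``z_threshold``.
    """
    out = replace(es, keep=es.keep.copy(), drop_reasons=dict(es.drop_reasons))
    kept = np.flatnonzero(out.keep)
    if kept.size < 3:
        warnings.warn("fewer than 3 kept epochs: rejection skipped")
        return out
    x = out.data[kept]
    rng_metric = (x.max(axis=2) - x.min(axis=2)).mean(axis=1)
    var_metric = x.var(axis=2).mean(axis=1)
    ch_means = x.mean(axis=2)  # (n_kept, n_ch)
    dev_metric = np.abs(ch_means - ch_means.mean(axis=0, keepdims=True)).mean(axis=1)

    bad = np.zeros(kept.size, dtype=bool)
    for m in (rng_metric, var_metric, dev_metric):
        sd = m.std()
        if sd == 0 or not np.isfinite(sd):
            continue
        z = (m - m.mean()) / sd
        bad |= np.abs(z) > z_threshold
    for i in kept[bad]:
        out.keep[i] = False
        out.drop_reasons[int(i)] = "faster_z"
    return out


# ---------------------------------------------------------------------------
# full chain

def preprocess_recording(rec: RawRecording, config: PreprocConfig = PreprocConfig(),
                         events: EventList | None = None, subject_id: str = ""
                         ) -> tuple[EpochSet, dict]:
    """Run the full four-stage chain; returns epochs and a stage report."""
    events = events if events is not None else rec.events
    report: dict = {"stage_order": [], "subject_id": subject_id}

    # stage 1: resample
    rec1 = resample(rec, config.resample_fs)
    report["stage_order"].append(f"resample_{int(config.resample_fs)}")

    # stage 2: bad channels on an *unreferenced* detection copy.  (After an
    # average reference a flat channel carries minus-the-average and can no
    # longer be told apart from a live one, especially on small montages.)
    det = rec1.copy()
    det.data[det.eeg_indices()] = _fft_filter(
        det.data[det.eeg_indices()], det.fs, config.hp_detect, None)
    det = suppress_line_noise(det, config.line_freq)
    chan_report = detect_bad_channels(det, config)
    bad = chan_report.bad_channels()
    report["stage_order"].append("detect_bad_channels")
    report["bad_channels"] = bad

    # stage 3: exclude bad channels, re-reference remaining, segments + ocular
    good_eeg = [c for i, c in enumerate(rec1.channel_labels)
                if rec1.channel_types[i] == "EEG" and c not in bad]
    if len(good_eeg) < 2:
        raise ConfigurationError("fewer than 2 good EEG channels remain")
    keep_idx = [i for i, c in enumerate(rec1.channel_labels)
                if c not in bad]
    rec2 = RawRecording(
        data=rec1.data[keep_idx],
        fs=rec1.fs,
        channel_labels=[rec1.channel_labels[i] for i in keep_idx],
        channel_types=[rec1.channel_types[i] for i in keep_idx],
        events=events,
        reference_state=rec1.reference_state,
    )
    rec2 = rereference_average(rec2)
    report["stage_order"].append("rereference_remaining")

    det2 = rec2.copy()
    det2.data[det2.eeg_indices()] = _fft_filter(
        det2.data[det2.eeg_indices()], det2.fs, config.bandpass[0], config.bandpass[1])
    det2 = suppress_line_noise(det2, config.line_freq)
    seg_mask = detect_bad_segments(det2, config)
    report["stage_order"].append("detect_bad_segments")
    report["n_bad_segments"] = seg_mask.n_dropped()

    rec3 = remove_ocular_artifacts(rec2)
    report["stage_order"].append("remove_ocular_artifacts")

    # stage 4: 30 Hz low-pass, epoch, reject
    rec3.data[rec3.eeg_indices()] = _fft_filter(
        rec3.data[rec3.eeg_indices()], rec3.fs, None, config.final_lowpass,
        hi_tw=config.lowpass_transition)
    report["stage_order"].append("lowpass_30")

    es = epoch_data(rec3, events, config.epoch_window_s, config.baseline,
                    subject_id=subject_id)
    report["stage_order"].append("epoch")
    n_edge = sum(1 for r in es.drop_reasons.values() if r == "edge")

    # drop epochs overlapping bad segments
    n_seg_drop = 0
    if seg_mask.n_dropped() > 0:
        fs = rec3.fs
        i0 = int(round(config.epoch_window_s[0] * fs))
        n_samp = es.data.shape[2]
        starts = np.round(np.asarray(events.onsets_s) * fs).astype(int) + i0
        ends = starts + n_samp
        for b in np.flatnonzero(~seg_mask.keep):
            b0, b1 = seg_mask.bounds[b], seg_mask.bounds[b + 1]
            overlap = (starts < b1) & (ends > b0) & es.keep
            for i in np.flatnonzero(overlap):
                es.keep[i] = False
                es.drop_reasons[int(i)] = "bad_segment"
                n_seg_drop += 1
    report["n_epochs_dropped_segments"] = n_seg_drop
    report["n_epochs_dropped_edge"] = n_edge

    n_before = int(es.keep.sum())
    es = reject_epochs(es, config.epoch_reject_z)
    report["stage_order"].append("reject_epochs")
    report["n_epochs_rejected"] = n_before - int(es.keep.sum())
    report["kept_per_intensity"] = {str(k): v for k, v in es.kept_counts().items()}
    report["scheduled_per_intensity"] = {str(k): v for k, v in es.scheduled_counts().items()}
    return es, report
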