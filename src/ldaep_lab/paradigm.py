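"""Auditory stimulation paradigm: intensity schedule and event timing.

Five tone intensities (55–95 dB SPL) are each presented ``trials_per_intensity``
times in a pseudo-randomized order.  Pseudo-randomization is operationalized as
an independent uniform shuffle within consecutive blocks that contain one trial
of every intensity, which keeps the sequence balanced over time.  Onset-to-onset
gaps are drawn uniformly from the ISI range and quantized to the analysis-grid
sampling rate (default 512 Hz) so that stimulus onsets coincide exactly with
samples of the resampled recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParadigmSpec", "EventList", "generate_paradigm"]


class ConfigurationError(ValueError):
    """Invalid paradigm/cohort/preprocessing configuration."""


@dataclass(frozen=True)
class ParadigmSpec:
    """Stimulation-paradigm parameters.

    Parameters
    ----------
    intensities_db
        Tone intensities in dB SPL.  Must be distinct.
    trials_per_intensity
        Number of presentations of each intensity.
    isi_range_ms
        (min, max) onset-to-onset interstimulus interval in milliseconds.
        The tone duration is not added to the gap (scheduling convention).
    tone_duration_ms
        Tone duration; carried as event metadata only.
    lead_in_s
        Silence before the first stimulus onset.
    schedule_grid_hz
        Sampling grid the onsets are quantized to.
    seed
        Seed for the per-block shuffles and ISI draws.
    """

    intensities_db: tuple[float, ...] = (55.0, 65.0, 75.0, 85.0, 95.0)
    trials_per_intensity: int = 80
    isi_range_ms: tuple[float, float] = (1200.0, 1800.0)
    tone_duration_ms: float = 30.0
    lead_in_s: float = 2.0
    schedule_grid_hz: float = 512.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intensities_db) == 0:
            raise ConfigurationError("intensity list is empty")
        if len(set(self.intensities_db)) != len(self.intensities_db):
            raise ConfigurationError("intensities must be distinct")
        if not self.isi_range_ms[0] < self.isi_range_ms[1]:
            raise ConfigurationError(
                f"invalid ISI range {self.isi_range_ms}: min must be < max"
            )
        if self.trials_per_intensity < 1:
            raise ConfigurationError("trials_per_intensity must be >= 1")


@dataclass
class EventList:
    """Stimulus events: monotonically increasing onsets with intensity labels."""

    onsets_s: np.ndarray
    intensity_db: np.ndarray
    tone_duration_ms: float = 30.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.intensity_db = np.asarray(self.intensity_db, dtype=float)
        if self.onsets_s.shape != self.intensity_db.shape:
            raise ValueError("onsets and labels must have equal length")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets_s.size

    def counts(self) -> dict[float, int]:
        """Number of events per intensity."""
        vals, cnts = np.unique(self.intensity_db, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))


def generate_paradigm(spec: ParadigmSpec) -> EventList:
    """Generate the pseudo-randomized event schedule.

    Returns one event per (intensity, trial), ``trials_per_intensity`` blocks
    each holding a fresh permutation of the intensity set.  Deterministic for
    a given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    intens = np.asarray(spec.intensities_db, dtype=float)
    labels = np.concatenate(
        [rng.permutation(intens) for _ in range(spec.trials_per_intensity)]
    )
    n = labels.size
    grid = spec.schedule_grid_hz
    lo = int(np.ceil(spec.isi_range_ms[0] / 1000.0 * grid))
    hi = int(np.floor(spec.isi_range_ms[1] / 1000.0 * grid))
    if hi < lo:
        raise ConfigurationError("ISI range too narrow for the scheduling grid")
    gaps = rng.integers(lo, hi + 1, size=n - 1) if n > 1 else np.array([], dtype=int)
    start = round(spec.lead_in_s * grid)
    onset_samples = start + np.concatenate([[0], np.cumsum(gaps)])
    return EventList(
        onsets_s=onset_samples / grid,
        intensity_db=labels,
        tone_duration_ms=spec.tone_duration_ms,
    )
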