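"""Averaged AEP waveforms, N1/P2 peak detection, and LDAEP slope regression.

The loudness dependence of the auditory evoked potential (LDAEP) is the
slope of a linear regression of component amplitude (μV) on stimulus
intensity (dB SPL) across the five intensities.  N1 is the most negative
peak 60–140 ms after stimulus onset; P2 the most positive peak 150–250 ms;
the N1P2 amplitude is the peak-to-peak difference P2 − N1 per intensity.
Because ordinary least squares is linear in the response, the N1P2 slope
equals the P2 slope minus the N1 slope exactly.

Sign convention: a steeper LDAEP (more negative N1 slope, more positive
P2/N1P2 slope) is conventionally read as lower central serotonergic
activity; this module asserts only the numeric convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ldaep_lab.preprocessing import EpochSet

__all__ = [
    "AEPWaveform",
    "PeakMeasurement",
    "LDAEPResult",
    "PEAK_WINDOWS",
    "average_by_intensity",
    "detect_peak",
    "compute_ldaep",
    "ldaep_from_epochs",
    "ldaep_table",
]

PEAK_WINDOWS = {"N1": (0.060, 0.140), "P2": (0.150, 0.250)}


class MissingIntensityError(ValueError):
    """An intensity has no kept epochs; the subject's slope is undefined."""


@dataclass
class AEPWaveform:
    channel: str
    intensity_db: float
    times: np.ndarray
    amplitude: np.ndarray  # μV
    n_epochs: int


@dataclass
class PeakMeasurement:
    component: str  # "N1" | "P2"
    latency_s: float
    amplitude_uv: float
    window_s: tuple[float, float]


@dataclass
class LDAEPResult:
    subject_id: str
    channel: str
    intensities_db: np.ndarray
    n1_uv: np.ndarray
    p2_uv: np.ndarray
    n1p2_uv: np.ndarray
    n1_slope: float
    p2_slope: float
    n1p2_slope: float
    n1_intercept: float
    p2_intercept: float
    n1p2_intercept: float
    n1_r2: float
    p2_r2: float
    n1p2_r2: float
    n_epochs: dict[float, int] = field(default_factory=dict)


def average_by_intensity(es: EpochSet, channel: str = "Cz") -> list[AEPWaveform]:
    """Arithmetic mean over kept epochs at one channel, per intensity."""
    if channel not in es.channel_labels:
        raise ValueError(f"channel {channel!r} not in epoch set")
    ci = es.channel_labels.index(channel)
    waves = []
    for db in np.unique(es.intensity_db):
        sel = es.keep & (es.intensity_db == db)
        n = int(sel.sum())
        if n == 0:
            raise MissingIntensityError(
                f"no kept epochs at {db} dB for subject {es.subject_id!r}")
        waves.append(AEPWaveform(
            channel=channel,
            intensity_db=float(db),
            times=es.times,
            amplitude=es.data[sel, ci, :].mean(axis=0),
            n_epochs=n,
        ))
    return waves


def detect_peak(w: AEPWaveform, component: str,
                window: tuple[float, float] | None = None) -> PeakMeasurement:
    """Signed extremum over the (inclusive) component window.

    Minimum for N1, maximum for P2; ties resolve to the earliest latency
    (at sample resolution).
    """
    component = component.upper()
    if component not in PEAK_WINDOWS:
        raise ValueError(f"unknown component {component!r}")
    win = window if window is not None else PEAK_WINDOWS[component]
    mask = (w.times >= win[0]) & (w.times <= win[1])
    if not mask.any():
        raise ValueError(f"window {win} outside epoch time axis")
    seg = w.amplitude[mask]
    t_seg = w.times[mask]
    i = int(np.argmin(seg)) if component == "N1" else int(np.argmax(seg))
    return PeakMeasurement(
        component=component,
        latency_s=float(t_seg[i]),
        amplitude_uv=float(seg[i]),
        window_s=(float(win[0]), float(win[1])),
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of ordinary least squares of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    sxx = float(np.dot(xd, xd))
    if sxx == 0:
        raise ValueError("need at least 2 distinct design points")
    slope = float(np.dot(xd, y) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sst = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - float(np.dot(resid, resid)) / sst if sst > 0 else 1.0
    return slope, intercept, r2


def compute_ldaep(n1_uv: np.ndarray, p2_uv: np.ndarray, intensities_db: np.ndarray,
                  subject_id: str = "", channel: str = "Cz",
                  n_epochs: dict[float, int] | None = None) -> LDAEPResult:
    """OLS slopes of N1, P2 and N1P2 amplitude on intensity (μV/dB).

    The abscissa is the physical intensity in dB SPL (55…95 by default),
    so slopes are in μV/dB over the 40 dB span.
    """
    x = np.asarray(intensities_db, dtype=float)
    n1 = np.asarray(n1_uv, dtype=float)
    p2 = np.asarray(p2_uv, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need measurements at >= 2 distinct intensities")
    n1p2 = p2 - n1
    s1, b1, r1 = _ols_line(x, n1)
    s2, b2, r2 = _ols_line(x, p2)
    s12, b12, r12 = _ols_line(x, n1p2)
    return LDAEPResult(
        subject_id=subject_id, channel=channel, intensities_db=x,
        n1_uv=n1, p2_uv=p2, n1p2_uv=n1p2,
        n1_slope=s1, p2_slope=s2, n1p2_slope=s12,
        n1_intercept=b1, p2_intercept=b2, n1p2_intercept=b12,
        n1_r2=r1, p2_r2=r2, n1p2_r2=r12,
        n_epochs=n_epochs or {},
    )


def ldaep_from_epochs(es: EpochSet, channel: str = "Cz") -> LDAEPResult:
    """Full per-subject LDAEP extraction from an epoch set."""
    waves = average_by_intensity(es, channel)
    n1 = [detect_peak(w, "N1").amplitude_uv for w in waves]
    p2 = [detect_peak(w, "P2").amplitude_uv for w in waves]
    return compute_ldaep(
        np.asarray(n1), np.asarray(p2),
        np.asarray([w.intensity_db for w in waves]),
        subject_id=es.subject_id, channel=channel,
        n_epochs={w.intensity_db: w.n_epochs for w in waves},
    )


def ldaep_table(results: list[LDAEPResult], cohort: pd.DataFrame | None = None
                ) -> pd.DataFrame:
    """Tidy per-subject LDAEP table, optionally joined with cohort covariates."""
    rows = []
    for r in results:
        row = dict(subject_id=r.subject_id, channel=r.channel,
                   n1_slope=r.n1_slope, p2_slope=r.p2_slope, n1p2_slope=r.n1p2_slope,
                   n1_r2=r.n1_r2, p2_r2=r.p2_r2, n1p2_r2=r.n1p2_r2)
        for db, a_n1, a_p2, a12 in zip(r.intensities_db, r.n1_uv, r.p2_uv, r.n1p2_uv):
            key = f"{int(db)}db"
            row[f"n1_{key}"] = a_n1
            row[f"p2_{key}"] = a_p2
            row[f"n1p2_{key}"] = a12
            row[f"n_epochs_{key}"] = r.n_epochs.get(db, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    if cohort is not None:
        df = df.merge(cohort, on="subject_id", how="left")
    return df


def plot_waveforms(waves: list[AEPWaveform], path=None):
    """Quick per-subject AEP plot (one trace per intensity)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for w in waves:
        ax.plot(w.times * 1e3, w.amplitude, label=f"{w.intensity_db:.0f} dB")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (μV)")
    ax.axvline(0, color="k", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
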