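"""Slow-wave negative half-wave detection and downslope measurement.

Slow waves are detected on a frontal derivation (Fz referenced to the
earlobe average) after 0.5–35 Hz zero-phase bandpass filtering and a 50-ms
moving average.  Candidate waves are delimited by zero-crossings of the
smoothed signal; the duration window decides the band — by default the period
between successive descending zero-crossings, 1.1–2 s for slow oscillations
(0.5–0.91 Hz) and 0.25–1.0 s for delta waves (1–4 Hz).  The trough is the
signal minimum between the bounding crossings and must reach −5 µV.  The
downslope is the amplitude from the descending zero-crossing to the trough
divided by the elapsed time (µV/s, stored as a positive magnitude).

A literal mode measuring the separation of the two crossings bounding the
negative half-wave alone is available (``criterion="halfwave"``); note that
1.1–2 s half-waves correspond to 0.25–0.45 Hz full waves, outside the SO
band, which is why the period criterion is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EPOCH_SECONDS, NREM_STAGES, Hypnogram

__all__ = [
    "AMPLITUDE_THRESHOLD_UV",
    "DURATION_WINDOWS",
    "HalfWave",
    "smooth",
    "detect_halfwaves",
    "summarize_slopes",
    "SlopeSummary",
]

#: Trough must be at or below this amplitude (µV).
AMPLITUDE_THRESHOLD_UV = -5.0

#: Closed duration windows (s) deciding the band of a detected wave.
DURATION_WINDOWS = {"so": (1.1, 2.0), "delta": (0.25, 1.0)}

SMOOTH_SECONDS = 0.05


@dataclass(frozen=True)
class HalfWave:
    """One detected slow-wave negative half-wave."""

    band: str  # "so" | "delta"
    t_zero_cross: float  # descending zero-crossing, s from segment start
    t_trough: float  # s
    trough_amp: float  # µV, negative
    separation: float  # bounding zero-crossing separation, s
    downslope: float  # µV/s, positive magnitude

    @property
    def epoch_index(self) -> int:
        """Epoch containing the trough (30-s grid anchored at recording start)."""
        return int(self.t_trough // EPOCH_SECONDS)


def smooth(x: np.ndarray, fs: float, duration: float = SMOOTH_SECONDS) -> np.ndarray:
    """Centered moving average of ``round(duration·fs)`` samples.

    Edges are handled by shrinking the window to the available samples, so a
    constant signal is returned unchanged everywhere.
    """
    k = int(round(duration * fs))
    if k <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(k)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones(len(x)), kernel, mode="same")
    return sums / counts


def _descending_crossings(x: np.ndarray, fs: float) -> np.ndarray:
    """Times (s) of positive-to-negative zero-crossings, linearly interpolated."""
    pos = x > 0
    idx = np.where(pos[:-1] & ~pos[1:])[0]
    # linear interpolation of the crossing instant between samples i and i+1
    x0 = x[idx]
    x1 = x[idx + 1]
    frac = np.where(x1 != x0, x0 / (x0 - x1), 0.0)
    return (idx + frac) / fs


def _ascending_crossings(x: np.ndarray, fs: float) -> np.ndarray:
    neg = x < 0
    idx = np.where(neg[:-1] & ~neg[1:])[0]
    x0 = x[idx]
    x1 = x[idx + 1]
    frac = np.where(x1 != x0, -x0 / (x1 - x0), 0.0)
    return (idx + frac) / fs


def detect_halfwaves(
    x: np.ndarray,
    fs: float,
    threshold: float = AMPLITUDE_THRESHOLD_UV,
    windows: dict[str, tuple[float, float]] | None = None,
    criterion: str = "period",
    t_offset: float = 0.0,
) -> list[HalfWave]:
    """Detect slow-wave negative half-waves on a smoothed, filtered signal.

    Parameters
    ----------
    x : array
        Conditioned (bandpassed and smoothed) signal, µV.
    fs : float
        Sampling rate, Hz.
    threshold : float
        Amplitude criterion: troughs above this (less negative) are discarded.
    windows : dict, optional
        Band duration windows in seconds; defaults to
        ``{"so": (1.1, 2.0), "delta": (0.25, 1.0)}``.
    criterion : str
        ``"period"`` (default): the separation is between successive
        *descending* zero-crossings, i.e. one full wave period.
        ``"halfwave"``: the separation is between the descending and the next
        ascending crossing (the negative half-wave alone).
    t_offset : float
        Added to all returned times (s); lets callers keep segment times on
        the recording clock.

    Returns an empty list for segments shorter than 2 s.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        return []
    if windows is None:
        windows = DURATION_WINDOWS
    desc = _descending_crossings(x, fs)
    out: list[HalfWave] = []
    if criterion == "period":
        bounds = zip(desc[:-1], desc[1:])
    elif criterion == "halfwave":
        asc = _ascending_crossings(x, fs)
        pairs = []
        j = 0
        for t0 in desc:
            while j < len(asc) and asc[j] <= t0:
                j += 1
            if j < len(asc):
                pairs.append((t0, asc[j]))
        bounds = iter(pairs)
    else:
        raise ValueError(f"unknown duration criterion {criterion!r}")

    for t0, t1 in bounds:
        sep = t1 - t0
        band = None
        for name, (lo, hi) in windows.items():
            if lo <= sep <= hi:
                band = name
                break
        if band is None:
            continue
        i0 = int(np.ceil(t0 * fs))
        i1 = int(np.floor(t1 * fs)) + 1
        seg = x[i0:i1]
        if not len(seg):
            continue
        # global minimum is the trough; argmin returns the earliest on ties
        k = int(np.argmin(seg))
        trough = float(seg[k])
        if trough > threshold:
            continue
        t_tr = (i0 + k) / fs
        dt = t_tr - t0
        if dt <= 0:
            continue
        out.append(
            HalfWave(
                band=band,
                t_zero_cross=t0 + t_offset,
                t_trough=t_tr + t_offset,
                trough_amp=trough,
                separation=sep,
                downslope=abs(trough) / dt,
            )
        )
    return out


@dataclass
class SlopeSummary:
    """Per-band NREM mean downslope (mean of per-epoch means) and counts."""

    mean_slope: dict[str, float]  # band -> µV/s (NaN when undefined)
    epoch_means: dict[str, dict[int, float]]  # band -> {epoch_index: mean slope}
    counts: dict[str, int]  # band -> total detections in NREM epochs
    portion: str
    missing: bool = False
    reason: str | None = None


def summarize_slopes(
    halfwaves: list[HalfWave],
    hyp: Hypnogram,
    portion: str = "diagnostic",
    stages: tuple[str, ...] = NREM_STAGES,
    pooling: str = "epoch-mean",
) -> SlopeSummary:
    """Summarize downslopes over NREM epochs of one study portion.

    Per-band slopes are first averaged within each 30-s epoch, then across
    the NREM epochs that contain at least one detection (``"epoch-mean"``,
    the default two-step summary).  ``pooling="detection"`` instead weights
    every detection equally.
    """
    eligible = {
        e.index for e in hyp if e.stage in stages and e.portion == portion and not e.artifact
    }
    per_epoch: dict[str, dict[int, list[float]]] = {b: {} for b in DURATION_WINDOWS}
    for hw in halfwaves:
        if hw.epoch_index in eligible:
            per_epoch[hw.band].setdefault(hw.epoch_index, []).append(hw.downslope)

    epoch_means = {
        b: {i: float(np.mean(v)) for i, v in d.items()} for b, d in per_epoch.items()
    }
    counts = {b: int(sum(len(v) for v in d.values())) for b, d in per_epoch.items()}
    mean_slope = {}
    for b, d in epoch_means.items():
        if not d:
            mean_slope[b] = float("nan")
        elif pooling == "epoch-mean":
            mean_slope[b] = float(np.mean(list(d.values())))
        elif pooling == "detection":
            allv = [s for ep in per_epoch[b].values() for s in ep]
            mean_slope[b] = float(np.mean(allv))
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
    if all(np.isnan(v) for v in mean_slope.values()):
        return SlopeSummary(mean_slope, epoch_means, counts, portion, missing=True, reason="no detections")
    return SlopeSummary(mean_slope, epoch_means, counts, portion)
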