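"""Relative power spectral density of sleep EEG in seven canonical bands.

The slow-wave activity spectrum is split into a slow-oscillation band
(SO, 0.5–0.9 Hz) and a delta band (1–3.9 Hz); theta, alpha, sigma, beta and
low-gamma complete the set used for the relative (%) normalization.  Band
limits are closed intervals exactly as defined; gap frequencies between
adjacent bands (e.g. 0.9–1.0 Hz) belong to no band.

The signal is conditioned by a 2000-tap Hamming-window FIR bandpass
(0.5–35 Hz) applied forward–backward for zero net phase shift, then cut into
30-s epochs; per-epoch band powers come from Welch's method (10-s Hamming
segments, 50% overlap, 0.1 Hz resolution so every printed band edge falls
exactly on a frequency bin) integrated over each band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EPOCH_SECONDS, NREM_STAGES, EpochWindow, Hypnogram

__all__ = [
    "BANDS",
    "BandDefinition",
    "design_bandpass",
    "filter_zero_phase",
    "filter_gain",
    "epoch_band_powers",
    "summarize_relative_psd",
    "EpochBandPower",
    "RelativePSDSummary",
]

FILTER_NUMTAPS = 2000
FILTER_BAND = (0.5, 35.0)

#: Minimum N3 representation (in 30-s epochs) for an N3-only summary: 15 min.
MIN_N3_EPOCHS = 30


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"invalid band limits {self.f_lo}-{self.f_hi}")

    def contains(self, f) -> np.ndarray:
        return (np.asarray(f) >= self.f_lo) & (np.asarray(f) <= self.f_hi)


#: The seven analysis bands (Hz, closed intervals).
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("so", 0.5, 0.9),
    BandDefinition("delta", 1.0, 3.9),
    BandDefinition("theta", 4.0, 7.9),
    BandDefinition("alpha", 8.0, 11.9),
    BandDefinition("sigma", 12.0, 14.9),
    BandDefinition("beta", 15.0, 29.9),
    BandDefinition("gamma", 30.0, 35.0),
)

BAND_NAMES = tuple(b.name for b in BANDS)


def design_bandpass(fs: float, numtaps: int = FILTER_NUMTAPS, band: tuple[float, float] = FILTER_BAND) -> np.ndarray:
    """Design the linear-phase FIR bandpass used for all EEG conditioning.

    2000 taps, Hamming window, passband 0.5–35 Hz.  Requires the upper band
    edge to sit below Nyquist.
    """
    if fs < 2 * band[1] * (1 + 1e-9):
        raise ValueError(f"sampling rate {fs} Hz too low for a {band[1]} Hz band edge")
    return sps.firwin(numtaps, band, pass_zero=False, window="hamming", fs=fs)


def filter_zero_phase(x: np.ndarray, fs: float, taps: np.ndarray | None = None, mode: str = "filtfilt") -> np.ndarray:
    """Apply the bandpass with zero net phase shift.

    ``mode="filtfilt"`` (default) runs the filter forward and backward, which
    squares the magnitude response; ``mode="shift"`` applies a single pass and
    compensates the constant group delay of the linear-phase filter.
    """
    if taps is None:
        taps = design_bandpass(fs)
    if mode == "filtfilt":
        return sps.filtfilt(taps, [1.0], x)
    if mode == "shift":
        delay = (len(taps) - 1) // 2
        y = sps.lfilter(taps, [1.0], np.concatenate([x, np.zeros(delay)]))
        return y[delay:]
    raise ValueError(f"unknown zero-phase mode {mode!r}")


def filter_gain(freqs, fs: float, mode: str = "filtfilt") -> np.ndarray:
    """Amplitude gain of the conditioning filter at given frequencies.

    Closed-form evaluation of the designed frequency response; the
    forward–backward application squares the single-pass magnitude.  Used by
    the synthetic ground truth to state filter-aware expected band powers.
    """
    taps = design_bandpass(fs)
    w, h = sps.freqz(taps, worN=2 ** 16, fs=fs)
    g = np.interp(np.asarray(freqs, dtype=float), w, np.abs(h))
    return g ** 2 if mode == "filtfilt" else g


@dataclass
class EpochBandPower:
    """Absolute (µV²) and relative (%) band powers of one 30-s epoch."""

    epoch_index: int
    stage: str
    portion: str
    artifact: bool
    absolute: dict[str, float] = field(default_factory=dict)
    relative: dict[str, float] = field(default_factory=dict)
    missing: bool = False

    @property
    def total_power(self) -> float:
        return float(sum(self.absolute.values()))


def epoch_band_powers(
    window: np.ndarray | EpochWindow,
    fs: float,
    bands: tuple[BandDefinition, ...] = BANDS,
    nperseg_seconds: float = 10.0,
    method: str = "welch",
) -> EpochBandPower:
    """Band powers of one 30-s window via Welch PSD integration.

    Power per band integrates the PSD over the closed interval
    [f_lo, f_hi]; relative power divides by the sum over the seven bands
    (× 100).  An all-zero window yields a missing (undefined) epoch.

    The default 10-s Hamming segments give 0.1 Hz resolution, on whose grid
    all band edges lie; the slow-oscillation band (0.5-0.9 Hz) then holds an
    in-band tone's full spectral mainlobe, which shorter segments cannot do
    (at 4 s the band is two bins wide and leaks ~13% of an on-bin tone's
    power into delta).  ``nperseg_seconds=4.0`` restores the shorter
    convention; ``method="periodogram"`` switches to a single-taper
    periodogram of the whole window.
    """
    if isinstance(window, EpochWindow):
        meta = window
        x = window.samples
    else:
        x = np.asarray(window, dtype=float)
        meta = EpochWindow(0, "N2", "diagnostic", False, x)
    expected = int(round(EPOCH_SECONDS * fs))
    if len(x) != expected:
        raise ValueError(f"window must hold exactly {expected} samples (30 s at {fs} Hz), got {len(x)}")

    out = EpochBandPower(meta.index, meta.stage, meta.portion, meta.artifact)
    if meta.artifact:
        out.missing = True
        return out
    if not np.any(x):
        out.missing = True
        return out

    if method == "welch":
        nper = int(round(nperseg_seconds * fs))
        f, p = sps.welch(x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2)
    elif method == "periodogram":
        f, p = sps.periodogram(x, fs=fs, window="hamming")
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    df = f[1] - f[0]
    for b in bands:
        out.absolute[b.name] = float(np.sum(p[b.contains(f)]) * df)
    total = out.total_power
    if total <= 0:
        out.missing = True
        return out
    out.relative = {k: 100.0 * v / total for k, v in out.absolute.items()}
    return out


@dataclass
class RelativePSDSummary:
    """Mean relative PSD per band over the selected epochs."""

    mean_relative: dict[str, float]
    n_epochs: int
    selection: str  # "nrem" or "n3"
    portion: str
    missing: bool = False
    reason: str | None = None


def summarize_relative_psd(
    epoch_powers: list[EpochBandPower],
    selection: str = "nrem",
    portion: str = "diagnostic",
    min_n3_epochs: int = MIN_N3_EPOCHS,
) -> RelativePSDSummary:
    """Unweighted mean relative PSD over eligible non-artifact epochs.

    ``selection="nrem"`` pools N1–N3 epochs; ``selection="n3"`` restricts to
    N3 and requires at least ``min_n3_epochs`` epochs (15 min by default),
    otherwise the summary is missing with reason ``"insufficient N3"``.
    """
    if selection not in ("nrem", "n3"):
        raise ValueError("selection must be 'nrem' or 'n3'")
    wanted = NREM_STAGES if selection == "nrem" else ("N3",)
    rows = [
        e
        for e in epoch_powers
        if e.stage in wanted and e.portion == portion and not e.artifact and not e.missing
    ]
    if selection == "n3" and len(rows) < min_n3_epochs:
        return RelativePSDSummary({}, len(rows), selection, portion, missing=True, reason="insufficient N3")
    if not rows:
        return RelativePSDSummary({}, 0, selection, portion, missing=True, reason="no eligible epochs")
    means = {
        name: float(np.mean([e.relative[name] for e in rows])) for name in BAND_NAMES
    }
    return RelativePSDSummary(means, len(rows), selection, portion)
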