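"""End-to-end slow-wave feature extraction from a recording and hypnogram.

Runs the full conditioning chain — derivation, optional resampling to 500 Hz,
zero-phase 0.5–35 Hz bandpass — then per-epoch relative band powers on Fz-Cz
and half-wave downslopes on Fz referenced to the earlobe average, and
summarizes both per study portion over NREM (and optionally N3-only) epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Derivation, Hypnogram, Recording, detect_artifacts, epoch_slices
from .slowwaves import detect_halfwaves, smooth, summarize_slopes
from .spectral import (
    BAND_NAMES,
    design_bandpass,
    epoch_band_powers,
    filter_zero_phase,
    summarize_relative_psd,
)

__all__ = ["ParticipantFeatures", "FeatureExtraction", "extract_features", "TARGET_FS"]

#: The conditioning chain (2000-tap filter, 25-sample smoother) is defined
#: at this rate; other rates are polyphase-resampled to it by default.
TARGET_FS = 500.0


@dataclass
class ParticipantFeatures:
    """NREM summary slow-wave features of one study portion."""

    portion: str
    selection: str  # "nrem" | "n3"
    so_pct: float
    delta_pct: float
    so_slope: float
    delta_slope: float
    n_epochs: int
    so_count: int
    delta_count: int
    missing: bool = False
    reason: str | None = None

    @property
    def band_ratio(self) -> float:
        return self.so_pct / self.delta_pct if self.delta_pct else float("nan")

    @property
    def slope_ratio(self) -> float:
        return self.so_slope / self.delta_slope if self.delta_slope else float("nan")

    def as_row(self) -> dict:
        return {
            "portion": self.portion,
            "selection": self.selection,
            "so_pct": self.so_pct,
            "delta_pct": self.delta_pct,
            "so_slope": self.so_slope,
            "delta_slope": self.delta_slope,
            "band_ratio": self.band_ratio,
            "slope_ratio": self.slope_ratio,
            "n_epochs": self.n_epochs,
            "so_count": self.so_count,
            "delta_count": self.delta_count,
            "missing": self.missing,
            "reason": self.reason,
        }


@dataclass
class FeatureExtraction:
    """Per-epoch table plus per-portion participant summaries."""

    epochs: pd.DataFrame
    summaries: list[ParticipantFeatures]
    halfwaves: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_row() for s in self.summaries])

    def get_summary(self, portion: str = "diagnostic", selection: str = "nrem") -> ParticipantFeatures:
        for s in self.summaries:
            if s.portion == portion and s.selection == selection:
                return s
        raise KeyError(f"no summary for portion={portion!r} selection={selection!r}")


def _maybe_resample(x: np.ndarray, fs: float, resample: bool) -> tuple[np.ndarray, float]:
    if not resample or fs == TARGET_FS:
        return x, fs
    from fractions import Fraction

    frac = Fraction(int(round(TARGET_FS * 1000)), int(round(fs * 1000)))
    return sps.resample_poly(x, frac.numerator, frac.denominator), TARGET_FS


def extract_features(
    rec: Recording,
    hyp: Hypnogram,
    spectral_derivation: Derivation | str = "Fz-Cz",
    slope_derivation: Derivation | str = "Fz:(A1,A2)",
    resample_to_500: bool = True,
    reject_artifacts: bool = True,
    n3_summary: bool = True,
    zero_phase_mode: str = "filtfilt",
    apply_bandpass: bool = True,
) -> FeatureExtraction:
    """Extract per-epoch and participant-level slow-wave features.

    Parameters
    ----------
    rec, hyp
        The recording (µV) and its 30-s hypnogram.
    spectral_derivation, slope_derivation
        Derivations for the band-power and half-wave paths; strings are
        parsed (``"Fz-Cz"``, ``"Fz:(A1,A2)"``).
    resample_to_500
        Polyphase-resample other sampling rates to 500 Hz, where the filter
        and smoother lengths are defined.
    reject_artifacts
        Run the per-epoch amplitude/flatline rejector in addition to any
        externally supplied artifact flags.
    apply_bandpass
        Apply the 0.5–35 Hz acquisition bandpass before feature extraction
        (the default).  Disable only for input already band-limited to the
        analysis range (e.g. ideal synthetic mixtures), where the real
        filter's transition-band loss near 0.5 Hz would otherwise bias
        slow-oscillation amplitudes; the 50-ms smoothing on the slope path
        is applied regardless.
    """
    if isinstance(spectral_derivation, str):
        spectral_derivation = Derivation.parse(spectral_derivation)
    if isinstance(slope_derivation, str):
        slope_derivation = Derivation.parse(slope_derivation)
    if reject_artifacts:
        hyp = detect_artifacts(rec, hyp, spectral_derivation)

    fs = rec.fs
    from .io import make_derivation

    x_spec = make_derivation(rec, spectral_derivation)
    x_slope = make_derivation(rec, slope_derivation)
    x_spec, fs2 = _maybe_resample(x_spec, fs, resample_to_500)
    x_slope, _ = _maybe_resample(x_slope, fs, resample_to_500)
    fs = fs2

    if apply_bandpass:
        taps = design_bandpass(fs)
        x_spec = filter_zero_phase(x_spec, fs, taps, mode=zero_phase_mode)
        x_slope = filter_zero_phase(x_slope, fs, taps, mode=zero_phase_mode)
    x_slope = smooth(x_slope, fs)

    # spectral path: filter the continuous signal first, window afterwards,
    # so epochs carry no per-epoch filter edge artifacts
    rec_f = Recording({"_spec": x_spec}, fs=fs)
    windows = epoch_slices(rec_f, hyp, x_spec)
    powers = [epoch_band_powers(w, fs) for w in windows]

    halfwaves = detect_halfwaves(x_slope, fs)

    rows = []
    hw_by_epoch: dict[int, dict[str, list[float]]] = {}
    for hw in halfwaves:
        hw_by_epoch.setdefault(hw.epoch_index, {}).setdefault(hw.band, []).append(hw.downslope)
    for ep, p in zip(hyp, powers):
        row = {
            "epoch_index": ep.index,
            "stage": ep.stage,
            "portion": ep.portion,
            "artifact": ep.artifact,
            "missing": p.missing,
        }
        for b in BAND_NAMES:
            row[f"abs_{b}"] = p.absolute.get(b, np.nan)
            row[f"rel_{b}"] = p.relative.get(b, np.nan)
        slopes = hw_by_epoch.get(ep.index, {})
        for b in ("so", "delta"):
            v = slopes.get(b)
            row[f"{b}_slope"] = float(np.mean(v)) if v else np.nan
            row[f"{b}_count"] = len(v) if v else 0
        rows.append(row)
    epoch_df = pd.DataFrame(rows)

    portions = sorted({ep.portion for ep in hyp})
    summaries: list[ParticipantFeatures] = []
    selections = ["nrem"] + (["n3"] if n3_summary else [])
    for portion in portions:
        for selection in selections:
            psd = summarize_relative_psd(powers, selection=selection, portion=portion)
            stages = ("N1", "N2", "N3") if selection == "nrem" else ("N3",)
            sl = summarize_slopes(halfwaves, hyp, portion=portion, stages=stages)
            missing = psd.missing or sl.missing
            summaries.append(
                ParticipantFeatures(
                    portion=portion,
                    selection=selection,
                    so_pct=psd.mean_relative.get("so", float("nan")),
                    delta_pct=psd.mean_relative.get("delta", float("nan")),
                    so_slope=sl.mean_slope.get("so", float("nan")),
                    delta_slope=sl.mean_slope.get("delta", float("nan")),
                    n_epochs=psd.n_epochs,
                    so_count=sl.counts.get("so", 0),
                    delta_count=sl.counts.get("delta", 0),
                    missing=missing,
                    reason=psd.reason or sl.reason,
                )
            )

    hw_df = pd.DataFrame(
        {
            "band": [h.band for h in halfwaves],
            "t_zero_cross": [h.t_zero_cross for h in halfwaves],
            "t_trough": [h.t_trough for h in halfwaves],
            "trough_amp": [h.trough_amp for h in halfwaves],
            "separation": [h.separation for h in halfwaves],
            "downslope": [h.downslope for h in halfwaves],
            "epoch_index": [h.epoch_index for h in halfwaves],
        }
    )
    return FeatureExtraction(epoch_df, summaries, hw_df)
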