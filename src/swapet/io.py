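"""Polysomnography I/O: EDF recordings, hypnograms, derivations and epoching.

EEG is handled in physical units (µV) throughout.  A :class:`Recording` is a
thin multichannel container; a :class:`Hypnogram` is the per-30-s-epoch stage
annotation aligned to the recording start; a :class:`Derivation` expresses a
referential montage such as Fz-Cz or Fz referenced to the earlobe average
(A1+A2)/2.

Reading goes through :mod:`mne`.  Writing uses a minimal 16-bit EDF encoder so
simulated recordings can round-trip through the same reader used for clinical
files.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 30.0

#: Sleep stages following AASM nomenclature.
STAGES = ("W", "N1", "N2", "N3", "R")
NREM_STAGES = ("N1", "N2", "N3")

#: Study portions of a split-night polysomnogram.
PORTIONS = ("diagnostic", "titration")


class ChannelNotFoundError(KeyError):
    """Requested channel label absent from a recording."""


class AlignmentError(ValueError):
    """Hypnogram does not fit onto the recording timeline."""


@dataclass
class Recording:
    """Multichannel EEG recording in µV.

    Parameters
    ----------
    channels : dict
        Mapping of channel label to 1-D sample array (µV).  All channels must
        have the same length.
    fs : float
        Sampling rate in Hz.
    start_time : datetime.datetime, optional
        Acquisition start; informational only.
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_time: datetime.datetime | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return list(self.channels)

    def get(self, label: str) -> np.ndarray:
        try:
            return self.channels[label]
        except KeyError:
            raise ChannelNotFoundError(
                f"channel {label!r} not found; available: {self.labels}"
            ) from None


@dataclass(frozen=True)
class HypnogramEpoch:
    """One 30-s epoch of the hypnogram."""

    index: int
    stage: str
    portion: str = "diagnostic"
    artifact: bool = False


@dataclass
class Hypnogram:
    """Sequence of contiguous 30-s epoch annotations starting at index 0."""

    epochs: list[HypnogramEpoch]

    def __post_init__(self) -> None:
        for i, ep in enumerate(self.epochs):
            if ep.index != i:
                raise ValueError(f"epoch indices must be contiguous from 0; got {ep.index} at position {i}")
            if ep.stage not in STAGES:
                raise ValueError(f"unknown stage {ep.stage!r}; expected one of {STAGES}")
            if ep.portion not in PORTIONS:
                raise ValueError(f"unknown portion {ep.portion!r}; expected one of {PORTIONS}")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def duration(self) -> float:
        """Covered duration in seconds."""
        return len(self.epochs) * EPOCH_SECONDS

    def stages(self) -> np.ndarray:
        return np.array([e.stage for e in self.epochs])


@dataclass(frozen=True)
class Derivation:
    """Referential derivation: ``positive`` minus the mean of ``references``.

    ``Derivation("Fz-A1A2", "Fz", ("A1", "A2"))`` realizes Fz referenced to
    the earlobe average (A1+A2)/2.
    """

    name: str
    positive: str
    references: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def parse(cls, text: str) -> "Derivation":
        """Parse ``"Fz-Cz"`` or ``"Fz:(A1,A2)"`` style derivation strings."""
        text = text.strip()
        if ":" in text:
            pos, refs = text.split(":", 1)
            refs = refs.strip().lstrip("(").rstrip(")")
            ref_tuple = tuple(r.strip() for r in refs.split(",") if r.strip())
            return cls(text, pos.strip(), ref_tuple)
        if "-" in text:
            pos, ref = text.split("-", 1)
            return cls(text, pos.strip(), (ref.strip(),))
        return cls(text, text, ())


def make_derivation(rec: Recording, d: Derivation) -> np.ndarray:
    """Return the derived single-channel signal ``positive − mean(references)`` in µV."""
    x = rec.get(d.positive).copy()
    if not d.references:
        raise ValueError(f"derivation {d.name!r} has an empty reference list")
    ref = np.mean([rec.get(r) for r in d.references], axis=0)
    return x - ref


@dataclass(frozen=True)
class EpochWindow:
    """A 30-s sample window tagged with its hypnogram annotation."""

    index: int
    stage: str
    portion: str
    artifact: bool
    samples: np.ndarray


def epoch_slices(rec: Recording, hyp: Hypnogram, derivation: Derivation | np.ndarray) -> list[EpochWindow]:
    """Slice a derivation into stage-labelled 30-s windows.

    The epoch grid is anchored at the recording start with half-open windows
    [i·30 s, (i+1)·30 s).  A trailing partial epoch in the recording is
    discarded with a warning; a hypnogram longer than the recording raises
    :class:`AlignmentError`.
    """
    if isinstance(derivation, Derivation):
        signal = make_derivation(rec, derivation)
    else:
        signal = np.asarray(derivation, dtype=float)
        if len(signal) != rec.n_samples:
            raise ValueError("derived signal length does not match recording")
    spe = int(round(EPOCH_SECONDS * rec.fs))  # samples per epoch
    n_full = len(signal) // spe
    if len(hyp) > n_full:
        raise AlignmentError(
            f"hypnogram covers {len(hyp)} epochs but recording holds only {n_full} full epochs"
        )
    if len(signal) % spe:
        logger.warning(
            "recording has a trailing partial epoch of %.1f s; discarded",
            (len(signal) % spe) / rec.fs,
        )
    out = []
    for ep in hyp:
        w = signal[ep.index * spe : (ep.index + 1) * spe]
        out.append(EpochWindow(ep.index, ep.stage, ep.portion, ep.artifact, w))
    return out


def detect_artifacts(
    rec: Recording,
    hyp: Hypnogram,
    derivation: Derivation,
    amplitude_limit: float = 250.0,
    flat_seconds: float = 5.0,
) -> Hypnogram:
    """Flag epochs with gross artifacts on the given derivation.

    An epoch is rejected when any sample exceeds ``amplitude_limit`` µV in
    magnitude or when the signal stays flat (zero first difference) for more
    than ``flat_seconds``.  Externally supplied flags are preserved (OR-ed).
    """
    windows = epoch_slices(rec, hyp, derivation)
    flat_run = int(round(flat_seconds * rec.fs))
    new = []
    for ep, w in zip(hyp, windows):
        bad = bool(np.any(np.abs(w.samples) > amplitude_limit))
        if not bad and flat_run < len(w.samples):
            d = np.diff(w.samples) == 0
            # longest run of identical consecutive samples
            if d.any():
                run = 0
                longest = 0
                for v in d:
                    run = run + 1 if v else 0
                    longest = max(longest, run)
                bad = longest >= flat_run
        new.append(HypnogramEpoch(ep.index, ep.stage, ep.portion, ep.artifact or bad))
    return Hypnogram(new)


# ---------------------------------------------------------------------------
# Hypnogram TSV dialect: columns epoch_index, stage, portion, artifact
# ---------------------------------------------------------------------------

def read_hypnogram(path) -> Hypnogram:
    """Read a hypnogram TSV (columns: epoch_index, stage, portion, artifact)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"epoch_index", "stage"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram TSV must have columns {sorted(required)}; got {list(df.columns)}")
    if "portion" not in df.columns:
        df["portion"] = "diagnostic"
    if "artifact" not in df.columns:
        df["artifact"] = False
    df = df.sort_values("epoch_index")
    eps = [
        HypnogramEpoch(int(r.epoch_index), str(r.stage), str(r.portion), bool(r.artifact))
        for r in df.itertuples()
    ]
    return Hypnogram(eps)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "epoch_index": [e.index for e in hyp],
            "stage": [e.stage for e in hyp],
            "portion": [e.portion for e in hyp],
            "artifact": [int(e.artifact) for e in hyp],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (samples in µV).

    Parameters
    ----------
    path : str or Path
        EDF file.
    channels : list of str, optional
        Subset of channel labels to load; all by default.  A missing label
        raises :class:`ChannelNotFoundError` listing the available ones.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = raw.ch_names
    wanted = channels if channels is not None else available
    missing = [c for c in wanted if c not in available]
    if missing:
        raise ChannelNotFoundError(f"channels {missing} not found; available: {available}")
    data = raw.get_data(picks=wanted) * 1e6  # volts -> µV
    start = None
    meas = raw.info.get("meas_date")
    if meas is not None:
        start = meas.replace(tzinfo=None)
    return Recording({c: data[i] for i, c in enumerate(wanted)}, fs=float(raw.info["sfreq"]), start_time=start)


def write_edf(rec: Recording, path) -> None:
    """Write a :class:`Recording` to a 16-bit EDF file (physical unit µV).

    Each channel's physical range is its own data range, so the quantization
    step is (max−min)/65535 µV; a read-back therefore matches to within one
    digital step.
    """
    channels = list(rec.channels.items())
    n_sig = len(channels)
    if n_sig == 0:
        raise ValueError("recording has no channels")
    n = rec.n_samples
    record_dur = 1.0
    spr = int(round(rec.fs * record_dur))
    if abs(spr - rec.fs * record_dur) > 1e-9:
        raise ValueError("sampling rate must yield an integer number of samples per 1-s record")
    n_rec = int(np.ceil(n / spr)) if n else 0
    start = rec.start_time or datetime.datetime(2000, 1, 1)

    def pad(s: str, w: int) -> bytes:
        b = s.encode("ascii")[:w]
        return b.ljust(w)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate %s X X X" % start.strftime("%d-%b-%Y").upper(), 80),
            pad(start.strftime("%d.%m.%y"), 8),
            pad(start.strftime("%H.%M.%S"), 8),
            pad(str(256 * (1 + n_sig)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("%g" % record_dur, 8),
            pad(str(n_sig), 4),
        ]
    )

    pmins, pmaxs, digital = [], [], []
    for _, x in channels:
        pmin = float(np.min(x)) if len(x) else -1.0
        pmax = float(np.max(x)) if len(x) else 1.0
        if pmax <= pmin:
            pmax = pmin + 1.0
        gain = (pmax - pmin) / 65535.0
        d = np.round((x - pmin) / gain - 32768.0).astype("<i2")
        full = np.zeros(n_rec * spr, dtype="<i2")
        full[:n] = d
        pmins.append(pmin)
        pmaxs.append(pmax)
        digital.append(full)

    sig_header = b"".join(
        [
            b"".join(pad(lab, 16) for lab, _ in channels),
            b"".join(pad("", 80) for _ in channels),
            b"".join(pad("uV", 8) for _ in channels),
            b"".join(pad(("%.8g" % v)[:8], 8) for v in pmins),
            b"".join(pad(("%.8g" % v)[:8], 8) for v in pmaxs),
            b"".join(pad("-32768", 8) for _ in channels),
            b"".join(pad("32767", 8) for _ in channels),
            b"".join(pad("", 80) for _ in channels),
            b"".join(pad(str(spr), 8) for _ in channels),
            b"".join(pad("", 32) for _ in channels),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())
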