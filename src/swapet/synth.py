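"""Synthetic polysomnography and cohort generation with analytic ground truth.

Every downstream stage of the pipeline gets an oracle from here:

* **Recordings** are mixtures of per-stage components — continuous
  band-limited sinusoids (for spectral oracles), isolated slow-wave *events*
  (for detection/slope oracles) and a 1/f noise floor.  An event is 1.5
  cycles of ``A·sin(2πft)``: a positive half-wave followed by one full wave
  bounded by two descending zero-crossings exactly one period apart, whose
  negative trough has amplitude A and analytic downslope ``4·A·f`` µV/s
  (amplitude A over a quarter period).  Events are countable, so detection
  counts and slopes can be checked one-for-one.

* **Cohort tables** draw slow-wave features and covariates from
  distributions matching a realistic elderly OSA sample and generate the
  annualized amyloid-accumulation outcome from a known linear model, so
  coefficient recovery and CI coverage can be verified.

All randomness flows through one seeded generator; the same seed reproduces
outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EPOCH_SECONDS, Hypnogram, HypnogramEpoch, Recording
from .spectral import BANDS, filter_gain

__all__ = [
    "StageComponent",
    "SyntheticPSGSpec",
    "InjectedEvent",
    "GroundTruth",
    "synthesize_recording",
    "default_stage_sequence",
    "default_components",
    "SyntheticCohortSpec",
    "synthesize_cohort",
]


def _band_of(freq: float) -> str | None:
    for b in BANDS:
        if b.f_lo <= freq <= b.f_hi:
            return b.name
    return None


@dataclass(frozen=True)
class StageComponent:
    """One signal component active during a given sleep stage.

    mode
        ``"sinusoid"`` — continuous sinusoid across the epoch (power A²/2);
        ``"events"`` — isolated 1.5-cycle slow-wave packets at ``density``
        events per minute.
    amplitude : µV (peak)
    frequency : Hz
    density : events/min (events mode only)
    """

    mode: str
    amplitude: float
    frequency: float
    density: float = 0.0

    def __post_init__(self):
        if self.mode not in ("sinusoid", "events"):
            raise ValueError(f"unknown component mode {self.mode!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")


@dataclass
class SyntheticPSGSpec:
    """Specification of a synthetic split-night polysomnogram.

    stage_sequence
        List of ``(stage, n_epochs)`` or ``(stage, n_epochs, portion)``
        blocks laid out consecutively on the 30-s epoch grid.
    components
        Mapping stage -> list of :class:`StageComponent`.
    noise_exponent, noise_scale
        1/f^exponent background with RMS ``noise_scale`` µV (0 disables).
    """

    stage_sequence: list
    components: dict[str, list[StageComponent]] = field(default_factory=dict)
    fs: float = 500.0
    noise_exponent: float = 1.0
    noise_scale: float = 0.0
    seed: int = 0

    def normalized_sequence(self) -> list[tuple[str, int, str]]:
        if not self.stage_sequence:
            raise ValueError("stage_sequence must not be empty")
        out = []
        for item in self.stage_sequence:
            if len(item) == 2:
                stage, n = item
                portion = "diagnostic"
            else:
                stage, n, portion = item
            out.append((str(stage), int(n), str(portion)))
        return out


@dataclass(frozen=True)
class InjectedEvent:
    """Ground-truth record of one injected slow-wave event."""

    onset: float  # s, start of the 1.5-cycle packet
    duration: float  # s (= 1.5/frequency)
    amplitude: float  # µV
    frequency: float  # Hz
    band: str  # "so" | "delta"
    downslope: float  # analytic, 4·A·f µV/s
    epoch_index: int


@dataclass
class GroundTruth:
    """Analytic expectations for a synthesized recording."""

    events: list[InjectedEvent]
    epoch_components: dict[int, list[StageComponent]]
    fs: float

    def expected_relative_psd(self, epoch_index: int, filter_aware: bool = False) -> dict[str, float]:
        """Analytic relative band powers (%) of one epoch's sinusoid mixture.

        Defined for *continuous sinusoid* components only (band power A²/2
        per tone); isolated event packets are broadband transients and carry
        no analytic narrowband split, so epochs with only event components
        return NaN.  With ``filter_aware=True`` the amplitudes are first
        scaled by the forward–backward conditioning-filter gain at the tone
        frequency — the closed-form frequency response, independent of the
        Welch estimation path.
        """
        comps = [c for c in self.epoch_components.get(epoch_index, []) if c.mode == "sinusoid"]
        power = {b.name: 0.0 for b in BANDS}
        for c in comps:
            band = _band_of(c.frequency)
            if band is None:
                continue
            amp = c.amplitude
            if filter_aware:
                amp = amp * float(filter_gain(c.frequency, self.fs))
            power[band] += amp ** 2 / 2.0
        total = sum(power.values())
        if total == 0:
            return {k: float("nan") for k in power}
        return {k: 100.0 * v / total for k, v in power.items()}

    def events_in_band(self, band: str) -> list[InjectedEvent]:
        return [e for e in self.events if e.band == band]


def _event_waveform(amplitude: float, frequency: float, fs: float) -> np.ndarray:
    """1.5 cycles of A·sin(2πft): positive half then one full negative-leading wave."""
    n = int(round(1.5 / frequency * fs))
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * frequency * t)


def _pink_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    x *= rms / np.std(x)
    return x


def synthesize_recording(spec: SyntheticPSGSpec) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Render a synthetic recording, its hypnogram and the analytic ground truth.

    The signal is placed on channel Fz; Cz, A1 and A2 are flat, so both the
    spectral (Fz-Cz) and the slope (Fz referenced to (A1+A2)/2) derivations
    reproduce the injected mixture exactly.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.normalized_sequence()
    epochs = []
    i = 0
    for stage, n, portion in seq:
        for _ in range(n):
            epochs.append(HypnogramEpoch(i, stage, portion, False))
            i += 1
    hyp = Hypnogram(epochs)
    n_epochs = len(epochs)
    spe = int(round(EPOCH_SECONDS * spec.fs))
    n_samples = n_epochs * spe
    x = np.zeros(n_samples)
    if spec.noise_scale > 0:
        x += _pink_noise(n_samples, spec.noise_exponent, spec.noise_scale, rng)

    events: list[InjectedEvent] = []
    epoch_components: dict[int, list[StageComponent]] = {}
    t_full = np.arange(n_samples) / spec.fs
    for ep in epochs:
        comps = spec.components.get(ep.stage, [])
        epoch_components[ep.index] = list(comps)
        lo = ep.index * spe
        hi = lo + spe
        planned: list[tuple[StageComponent, np.ndarray]] = []
        for c in comps:
            if c.mode == "sinusoid":
                # phase tied to the absolute clock so the tone is continuous
                # across epochs of the same stage
                x[lo:hi] += c.amplitude * np.sin(2 * np.pi * c.frequency * t_full[lo:hi])
            else:
                wave = _event_waveform(c.amplitude, c.frequency, spec.fs)
                n_events = int(c.density / 60.0 * EPOCH_SECONDS)
                if rng.random() < (c.density / 60.0 * EPOCH_SECONDS - n_events):
                    n_events += 1
                planned.extend((c, wave) for _ in range(n_events))
        if planned:
            # joint schedule across all event components: shuffled order,
            # greedy placement with random gaps, never overlapping and never
            # straddling the epoch boundary; events that do not fit are
            # dropped (and absent from the ground truth)
            order = rng.permutation(len(planned))
            total_len = sum(len(w) for _, w in planned)
            slack = max(0, spe - total_len)
            gaps = rng.dirichlet(np.ones(len(planned) + 1)) * slack
            cursor = int(gaps[0])
            for gi, j in enumerate(order):
                c, wave = planned[j]
                if cursor + len(wave) > spe:
                    break
                a = lo + cursor
                x[a : a + len(wave)] += wave
                events.append(
                    InjectedEvent(
                        onset=a / spec.fs,
                        duration=len(wave) / spec.fs,
                        amplitude=c.amplitude,
                        frequency=c.frequency,
                        band=_band_of(c.frequency) or "none",
                        downslope=4.0 * c.amplitude * c.frequency,
                        epoch_index=ep.index,
                    )
                )
                cursor += len(wave) + int(gaps[gi + 1])
    events.sort(key=lambda e: e.onset)
    flat = np.zeros(n_samples)
    rec = Recording(
        {"Fz": x, "Cz": flat, "A1": flat.copy(), "A2": flat.copy()},
        fs=spec.fs,
    )
    return rec, hyp, GroundTruth(events, epoch_components, spec.fs)


def default_stage_sequence(tst_min: float = 168.0, portion: str = "diagnostic") -> list[tuple[str, int, str]]:
    """Stage blocks approximating the diagnostic-portion architecture of an
    elderly OSA sample: N1 25%, N2 48%, N3 16%, REM 11% of total sleep time,
    arranged as two NREM cycles with a REM period and brief wake bouts."""
    total = int(round(tst_min * 2))  # 30-s epochs
    n1 = int(round(total * 0.25))
    n2 = int(round(total * 0.48))
    n3 = int(round(total * 0.16))
    rem = max(0, total - n1 - n2 - n3)
    seq = [
        ("W", 4, portion),
        ("N1", n1 // 2, portion),
        ("N2", n2 // 2, portion),
        ("N3", n3 // 2, portion),
        ("N2", n2 - n2 // 2, portion),
        ("R", rem, portion),
        ("W", 2, portion),
        ("N1", n1 - n1 // 2, portion),
        ("N3", n3 - n3 // 2, portion),
    ]
    return [(s, n, p) for s, n, p in seq if n > 0]


def default_components() -> dict[str, list[StageComponent]]:
    """Per-stage mixtures giving plausible relative-PSD and slope profiles."""
    return {
        "W": [StageComponent("sinusoid", 20.0, 10.0)],
        "N1": [
            StageComponent("sinusoid", 15.0, 5.0),
            StageComponent("events", 20.0, 2.0, density=10.0),
        ],
        "N2": [
            StageComponent("sinusoid", 10.0, 13.0),
            StageComponent("events", 40.0, 0.7, density=5.0),
            StageComponent("events", 30.0, 2.0, density=20.0),
        ],
        "N3": [
            StageComponent("events", 60.0, 0.7, density=8.0),
            StageComponent("events", 40.0, 2.0, density=25.0),
        ],
        "R": [StageComponent("sinusoid", 12.0, 6.0)],
    }


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

#: Slow-wave feature distributions of the emulated sample: mean, SD.
FEATURE_DISTRIBUTIONS = {
    "so_pct": (25.7, 6.6),
    "delta_pct": (46.3, 5.4),
    "so_slope": (95.1, 28.9),
    "delta_slope": (130.8, 34.8),
}

#: Within-family feature correlations (slopes strongly, bands inversely).
FEATURE_CORRELATIONS = {("so_slope", "delta_slope"): 0.88, ("so_pct", "delta_pct"): -0.45}

#: Generating coefficients per 1 SD of feature on ΔPiB(log)/year.
DEFAULT_BETAS = {"so_slope": 0.0069, "delta_slope": -0.0082}

#: Covariate effects on ΔPiB(log)/year (age per year; binaries per category).
DEFAULT_COVARIATE_EFFECTS = {"age_baseline": 0.0003, "apoe4": 0.003, "pib_positive": 0.0117}

#: Mean shifts (diagnostic − titration) and SDs of the paired differences.
PORTION_SHIFTS = {
    "so_pct": (1.63, 4.02),
    "delta_pct": (0.56, 3.44),
    "so_slope": (12.5, 20.55),
    "delta_slope": (16.2, 24.07),
}


@dataclass
class SyntheticCohortSpec:
    """Generating model for a synthetic cohort table.

    The outcome is ``dpib_log_yr = intercept + Σ β_k·z(feature_k)
    + Σ γ_c·covariate_c + ε`` with ``ε ~ N(0, residual_sd)``; betas are per
    sample-SD of the feature (applied to the population z-score).
    """

    n: int = 64
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    covariate_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    intercept: float = -0.022  # centres the outcome near the observed mean
    residual_sd: float = 0.010
    feature_distributions: dict = field(default_factory=lambda: dict(FEATURE_DISTRIBUTIONS))
    feature_correlations: dict = field(default_factory=lambda: dict(FEATURE_CORRELATIONS))
    paired_portions: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        n_terms = len(self.betas) + len(self.covariate_effects)
        if self.n < n_terms + 2:
            raise ValueError(f"n={self.n} too small for {n_terms} model terms")


def synthesize_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with the generating parameters.

    Columns: participant_id, the four slow-wave features (plus
    ``*_titration`` paired columns when requested), covariates
    (age_baseline, apoe4, pib_positive, interval_years, psg_pet_interval,
    tst_min, effective_pap, n3_pct), and the outcome ``dpib_log_yr`` with its
    centiloid-scale counterpart ``dpib_cl_yr``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    names = list(spec.feature_distributions)
    k = len(names)
    corr = np.eye(k)
    for (a, b), r in spec.feature_correlations.items():
        if a in names and b in names:
            ia, ib = names.index(a), names.index(b)
            corr[ia, ib] = corr[ib, ia] = r
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k)) @ chol.T
    df = pd.DataFrame({"participant_id": [f"S{i:03d}" for i in range(n)]})
    for j, name in enumerate(names):
        mu, sd = spec.feature_distributions[name]
        df[name] = mu + sd * z[:, j]

    df["age_baseline"] = rng.normal(72.9, 7.5, n)
    df["apoe4"] = rng.binomial(1, 0.27, n)
    df["pib_positive"] = rng.binomial(1, 0.39, n)
    df["interval_years"] = np.exp(rng.normal(np.log(2.7), 0.39, n))
    df["psg_pet_interval"] = rng.normal(0.7, 1.2, n)
    df["tst_min"] = np.clip(rng.normal(168.0, 45.0, n), 60, None)
    df["effective_pap"] = rng.binomial(1, 0.45, n)
    df["n3_pct"] = np.clip(rng.normal(16.0, 13.0, n), 0, None)

    lin = np.full(n, spec.intercept)
    for j, name in enumerate(names):
        beta = spec.betas.get(name, 0.0)
        lin += beta * z[:, j]  # beta is per population SD of the feature
    for cov, g in spec.covariate_effects.items():
        lin += g * df[cov].to_numpy(dtype=float)
    eps = rng.normal(0.0, spec.residual_sd, n)
    df["dpib_log_yr"] = lin + eps
    # affine centiloid companion: CL/yr scales with SUVR/yr; for a typical
    # baseline SUVR ~1.5 the log-scale rate maps to roughly 100·0.9467/1.067·1.5
    df["dpib_cl_yr"] = df["dpib_log_yr"] * (100.0 * 0.9467 / 1.067 * 1.5)

    if spec.paired_portions:
        for name in names:
            shift, sd_diff = PORTION_SHIFTS[name]
            df[f"{name}_titration"] = df[name] - rng.normal(shift, sd_diff, n)

    params = {
        "betas": dict(spec.betas),
        "covariate_effects": dict(spec.covariate_effects),
        "intercept": spec.intercept,
        "residual_sd": spec.residual_sd,
        "feature_sds": {k: v[1] for k, v in spec.feature_distributions.items()},
        "seed": spec.seed,
    }
    return df, params
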