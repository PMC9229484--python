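"""Seeded synthetic cohort generator.

Emulates a desk-scale acquisition session: a cohort of volunteers with
physiological covariates drawn from stated ranges, a 3-minute
dual-wavelength (red / infrared) PPG recording per volunteer, and one
bioimpedance frequency sweep per minute of recording.

The signals carry a *known* glucose dependence so that the downstream
feature extraction, dimensionality reduction, and regression stages can be
tested for recoverability:

* PPG pulse amplitude is attenuated exponentially with glucose
  (Beer–Lambert-inspired): ``A(g) = base * exp(-eps * g / 110)``, with a
  distinct absorption coefficient ``eps`` per wavelength.
* The Cole zero-frequency resistance shrinks linearly with glucose:
  ``R0(g) = R0_base * (1 - beta * (g - 110) / 110)`` — tissue conductivity
  rises with glucose concentration.

Both couplings are explicit surrogates, not first-principles optics or
electrochemistry; their magnitudes are configuration defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "AcquisitionConfig",
    "SweepConfig",
    "ParticipantRecord",
    "DualPPGRecording",
    "ImpedanceSweep",
    "Cohort",
    "SWEEP_FREQUENCIES_KHZ",
    "beat_times",
    "generate_participant",
    "generate_dual_ppg",
    "generate_impedance_sweep",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: The 11 swept excitation frequencies, 50–100 kHz in 5 kHz steps.
SWEEP_FREQUENCIES_KHZ: tuple[float, ...] = tuple(float(f) for f in range(50, 105, 5))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Cohort size plus (center, half-width) for every covariate.

    Each covariate is drawn uniformly from ``[center - half_width,
    center + half_width]`` — the published "center ± spread" table is read
    as a hard range, which guarantees in-range draws. Age is a uniform
    integer on ``age_range`` inclusive.
    """

    n_participants: int = 40
    seed: int = 0
    age_range: tuple[int, int] = (18, 25)
    height_cm: tuple[float, float] = (165.0, 20.0)
    weight_kg: tuple[float, float] = (65.0, 30.0)
    heart_rate_bpm: tuple[float, float] = (70.0, 28.0)
    blood_flow_mm_s: tuple[float, float] = (280.0, 100.0)
    hemoglobin_g_l: tuple[float, float] = (160.0, 20.0)
    spo2_pct: tuple[float, float] = (94.0, 5.0)
    glucose_mg_dl: tuple[float, float] = (110.0, 15.0)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigurationError(f"invalid age_range {self.age_range}")
        for name in ("height_cm", "weight_kg", "heart_rate_bpm", "blood_flow_mm_s",
                     "hemoglobin_g_l", "spo2_pct", "glucose_mg_dl"):
            center, half = getattr(self, name)
            if half < 0:
                raise ConfigurationError(f"{name}: half-width {half} < 0")
            if center <= 0:
                raise ConfigurationError(f"{name}: center {center} must be positive")
        if self.spo2_pct[0] + self.spo2_pct[1] > 100.0:
            raise ConfigurationError("spo2 range exceeds 100%")


@dataclass(frozen=True)
class AcquisitionConfig:
    """PPG acquisition model parameters.

    The waveform per channel is ``drift(t) + A(g) * sum_beats pulse(t - t_b)
    + noise``: a two-Gaussian pulse (systolic lobe plus a delayed, smaller
    dicrotic lobe) repeated at the participant's heart rate, riding on a
    sum of slow sinusoids standing in for motion/respiration baseline
    drift, plus i.i.d. Gaussian sensor noise.
    """

    duration_s: float = 180.0
    sampling_rate_hz: float = 100.0
    #: pulse amplitude base per wavelength (a.u.)
    red_amplitude: float = 1.0
    infrared_amplitude: float = 1.2
    #: dimensionless absorption coefficients; red is more glucose-sensitive here
    red_absorption: float = 0.35
    infrared_absorption: float = 0.25
    drift_amplitude: float = 0.3
    drift_bandwidth_hz: float = 0.15
    n_drift_components: int = 3
    noise_sigma: float = 0.01
    dicrotic_rel_amplitude: float = 0.35
    dicrotic_delay_s: float = 0.25
    systolic_width_s: float = 0.09
    dicrotic_width_s: float = 0.12

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigurationError("duration and sampling rate must be positive")
        if self.sampling_rate_hz < 20.0:
            raise ConfigurationError("sampling rate below 20 Hz cannot resolve PPG morphology")
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration_s * sampling_rate_hz must be an integer sample count")
        if self.noise_sigma < 0 or self.drift_amplitude < 0:
            raise ConfigurationError("noise sigma and drift amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sampling_rate_hz)


@dataclass(frozen=True)
class SweepConfig:
    """Cole-model bioimpedance sweep parameters.

    ``Z(f) = Rinf + (R0(g) - Rinf) / (1 + (i f / fc)^alpha)`` with
    ``R0(g) = R0_base * (1 - beta * (g - 110) / 110)``. Gaussian noise is
    added to the real and imaginary parts; phase and magnitude are then
    recomputed from the noisy parts so they stay mutually consistent.
    """

    frequencies_khz: tuple[float, ...] = SWEEP_FREQUENCIES_KHZ
    R0_base: float = 500.0
    Rinf: float = 100.0
    fc_khz: float = 70.0
    alpha: float = 0.85
    glucose_beta: float = 0.2
    noise_sigma: float = 0.5
    sweeps_per_participant: int = 3

    def __post_init__(self) -> None:
        if not (self.R0_base > self.Rinf > 0):
            raise ConfigurationError("need R0_base > Rinf > 0")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")
        freqs = np.asarray(self.frequencies_khz, dtype=float)
        if len(freqs) != 11 or not np.allclose(np.diff(freqs), 5.0):
            raise ConfigurationError("expected 11 frequencies in arithmetic 5 kHz steps")
        if self.fc_khz <= 0 or self.noise_sigma < 0 or self.sweeps_per_participant < 1:
            raise ConfigurationError("invalid sweep config")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantRecord:
    """One volunteer's covariates plus ground-truth glucose (mg/dL)."""

    id: str
    age: int
    height_cm: float
    weight_kg: float
    heart_rate_bpm: float
    blood_flow_mm_s: float
    hemoglobin_g_l: float
    spo2_pct: float
    glucose_mg_dl: float

    @property
    def physio_vector(self) -> np.ndarray:
        """The 7 physiological network inputs, in canonical order."""
        return np.array([self.age, self.height_cm, self.weight_kg,
                         self.heart_rate_bpm, self.blood_flow_mm_s,
                         self.hemoglobin_g_l, self.spo2_pct], dtype=float)


@dataclass(frozen=True)
class DualPPGRecording:
    """Time-aligned red (~660 nm) and infrared (~900 nm) PPG channels."""

    sampling_rate_hz: float
    red: np.ndarray
    infrared: np.ndarray

    def __post_init__(self) -> None:
        if len(self.red) != len(self.infrared):
            raise ConfigurationError("channels must have equal length")
        if not (np.all(np.isfinite(self.red)) and np.all(np.isfinite(self.infrared))):
            raise ConfigurationError("PPG samples must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.red)) / self.sampling_rate_hz


@dataclass(frozen=True)
class ImpedanceSweep:
    """Complex impedance at the 11 swept frequencies.

    Invariant: ``magnitude = hypot(real, imag)`` and
    ``phase = arctan2(imag, real)`` hold element-wise.
    """

    frequency_khz: np.ndarray
    real_ohm: np.ndarray
    imag_ohm: np.ndarray
    phase_rad: np.ndarray
    magnitude_ohm: np.ndarray

    @classmethod
    def from_complex(cls, frequency_khz: np.ndarray, z: np.ndarray) -> "ImpedanceSweep":
        real = np.asarray(z).real.copy()
        imag = np.asarray(z).imag.copy()
        return cls(
            frequency_khz=np.asarray(frequency_khz, dtype=float).copy(),
            real_ohm=real,
            imag_ohm=imag,
            phase_rad=np.arctan2(imag, real),
            magnitude_ohm=np.hypot(real, imag),
        )


@dataclass(frozen=True)
class Cohort:
    participants: tuple[ParticipantRecord, ...]
    recordings: tuple[DualPPGRecording, ...]
    sweeps: tuple[tuple[ImpedanceSweep, ...], ...]
    cohort_config: CohortConfig
    acquisition_config: AcquisitionConfig
    sweep_config: SweepConfig

    def __len__(self) -> int:
        return len(self.participants)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _uniform(rng: np.random.Generator, center_half: tuple[float, float]) -> float:
    center, half = center_half
    return float(rng.uniform(center - half, center + half))


def generate_participant(config: CohortConfig, rng: np.random.Generator,
                         pid: str = "p000") -> ParticipantRecord:
    """Draw one participant's covariates uniformly from their ranges."""
    age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
    return ParticipantRecord(
        id=pid,
        age=age,
        height_cm=_uniform(rng, config.height_cm),
        weight_kg=_uniform(rng, config.weight_kg),
        heart_rate_bpm=_uniform(rng, config.heart_rate_bpm),
        blood_flow_mm_s=_uniform(rng, config.blood_flow_mm_s),
        hemoglobin_g_l=_uniform(rng, config.hemoglobin_g_l),
        spo2_pct=_uniform(rng, config.spo2_pct),
        glucose_mg_dl=_uniform(rng, config.glucose_mg_dl),
    )


def beat_times(heart_rate_bpm: float, duration_s: float) -> np.ndarray:
    """Deterministic beat onsets: one every 60/HR seconds from t=0."""
    period = 60.0 / heart_rate_bpm
    return np.arange(0.0, duration_s, period)


def pulse_amplitude(base: float, absorption: float, glucose_mg_dl: float) -> float:
    """Glucose-attenuated pulse amplitude ``base * exp(-eps * g / 110)``."""
    return base * float(np.exp(-absorption * glucose_mg_dl / 110.0))


def _pulse_train(t: np.ndarray, beats: np.ndarray, acq: AcquisitionConfig,
                 rate_hz: float) -> np.ndarray:
    """Unit-amplitude pulse train: systolic Gaussian + delayed dicrotic lobe."""
    out = np.zeros_like(t)
    # each pulse only matters within a few widths of its center
    reach_s = acq.dicrotic_delay_s + 5.0 * max(acq.systolic_width_s, acq.dicrotic_width_s)
    half = int(np.ceil(reach_s * rate_hz))
    n = len(t)
    for tb in beats:
        c = int(round(tb * rate_hz))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        dt = t[lo:hi] - tb
        out[lo:hi] += np.exp(-0.5 * (dt / acq.systolic_width_s) ** 2)
        out[lo:hi] += acq.dicrotic_rel_amplitude * np.exp(
            -0.5 * ((dt - acq.dicrotic_delay_s) / acq.dicrotic_width_s) ** 2)
    return out


def generate_dual_ppg(p: ParticipantRecord, acq: AcquisitionConfig,
                      rng: np.random.Generator) -> DualPPGRecording:
    """Synthesize one dual-wavelength PPG recording for a participant.

    Both channels share beat times and drift realization (they observe the
    same finger) but have independent sensor noise and wavelength-specific
    glucose-attenuated amplitudes.
    """
    n = acq.n_samples
    t = np.arange(n) / acq.sampling_rate_hz
    beats = beat_times(p.heart_rate_bpm, acq.duration_s)
    train = _pulse_train(t, beats, acq, acq.sampling_rate_hz)

    # shared low-frequency drift: sum of slow sinusoids with random phase
    drift = np.zeros(n)
    for _ in range(acq.n_drift_components):
        f = rng.uniform(0.01, acq.drift_bandwidth_hz)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = acq.drift_amplitude * rng.uniform(0.5, 1.0) / max(acq.n_drift_components, 1)
        drift += amp * np.sin(2.0 * np.pi * f * t + phase)

    a_red = pulse_amplitude(acq.red_amplitude, acq.red_absorption, p.glucose_mg_dl)
    a_ir = pulse_amplitude(acq.infrared_amplitude, acq.infrared_absorption, p.glucose_mg_dl)
    red = drift + a_red * train + rng.normal(0.0, acq.noise_sigma, n)
    infrared = drift + a_ir * train + rng.normal(0.0, acq.noise_sigma, n)
    return DualPPGRecording(sampling_rate_hz=acq.sampling_rate_hz, red=red, infrared=infrared)


def cole_impedance(f_khz: np.ndarray, R0: float, Rinf: float, fc_khz: float,
                   alpha: float) -> np.ndarray:
    """Single-dispersion Cole impedance ``Rinf + (R0-Rinf)/(1+(i f/fc)^a)``."""
    jf = (1j * np.asarray(f_khz, dtype=float) / fc_khz) ** alpha
    return Rinf + (R0 - Rinf) / (1.0 + jf)


def generate_impedance_sweep(p: ParticipantRecord, sc: SweepConfig,
                             rng: np.random.Generator) -> ImpedanceSweep:
    """One noisy Cole-model sweep with glucose-dependent R0."""
    r0 = sc.R0_base * (1.0 - sc.glucose_beta * (p.glucose_mg_dl - 110.0) / 110.0)
    if r0 <= sc.Rinf:
        raise ConfigurationError(
            f"R0(g)={r0:.1f} <= Rinf={sc.Rinf}: glucose sensitivity too large")
    f = np.asarray(sc.frequencies_khz, dtype=float)
    z = cole_impedance(f, r0, sc.Rinf, sc.fc_khz, sc.alpha)
    real = z.real + rng.normal(0.0, sc.noise_sigma, len(f))
    imag = z.imag + rng.normal(0.0, sc.noise_sigma, len(f))
    return ImpedanceSweep(
        frequency_khz=f.copy(),
        real_ohm=real,
        imag_ohm=imag,
        phase_rad=np.arctan2(imag, real),
        magnitude_ohm=np.hypot(real, imag),
    )


def generate_cohort(config: CohortConfig,
                    acq: AcquisitionConfig | None = None,
                    sc: SweepConfig | None = None) -> Cohort:
    """Generate a full cohort from a single master seed.

    Each participant gets an independent child random stream spawned from
    the master seed, so adding participants never perturbs earlier ones
    and regeneration is bit-identical.
    """
    acq = acq or AcquisitionConfig()
    sc = sc or SweepConfig()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    participants, recordings, sweeps = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p = generate_participant(config, rng, pid=f"p{i:03d}")
        rec = generate_dual_ppg(p, acq, rng)
        swp = tuple(generate_impedance_sweep(p, sc, rng)
                    for _ in range(sc.sweeps_per_participant))
        participants.append(p)
        recordings.append(rec)
        sweeps.append(swp)
    return Cohort(tuple(participants), tuple(recordings), tuple(sweeps),
                  config, acq, sc)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["id", "age", "height_cm", "weight_kg", "heart_rate_bpm",
                  "blood_flow_mm_s", "hemoglobin_g_l", "spo2_pct", "glucose_mg_dl"]


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Participant covariates as a DataFrame (one row per volunteer)."""
    return pd.DataFrame([dataclasses.asdict(p) for p in cohort.participants],
                        columns=COHORT_COLUMNS)


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Write cohort.csv, ppg_<id>.csv and impedance_<id>.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    path = outdir / "cohort.csv"
    cohort_frame(cohort).to_csv(path, index=False)
    written.append(path)
    for p, rec, swps in zip(cohort.participants, cohort.recordings, cohort.sweeps):
        ppg_path = outdir / f"ppg_{p.id}.csv"
        pd.DataFrame({"t_s": rec.times_s, "red": rec.red,
                      "infrared": rec.infrared}).to_csv(ppg_path, index=False)
        written.append(ppg_path)
        rows = []
        for k, s in enumerate(swps):
            for j in range(len(s.frequency_khz)):
                rows.append((k, s.frequency_khz[j], s.real_ohm[j], s.imag_ohm[j],
                             s.phase_rad[j], s.magnitude_ohm[j]))
        imp_path = outdir / f"impedance_{p.id}.csv"
        pd.DataFrame(rows, columns=["sweep_index", "freq_khz", "real_ohm",
                                    "imag_ohm", "phase_rad", "magnitude_ohm"]
                     ).to_csv(imp_path, index=False)
        written.append(imp_path)
    return written


def read_cohort(indir: str | Path,
                sampling_rate_hz: float = 100.0) -> tuple[pd.DataFrame, dict, dict]:
    """Read back the CSV layout written by :func:`write_cohort`.

    Returns (cohort frame, {id: DualPPGRecording}, {id: list[ImpedanceSweep]}).
    """
    indir = Path(indir)
    frame = pd.read_csv(indir / "cohort.csv")
    recordings: dict[str, DualPPGRecording] = {}
    sweeps: dict[str, list[ImpedanceSweep]] = {}
    for pid in frame["id"]:
        ppg = pd.read_csv(indir / f"ppg_{pid}.csv")
        if len(ppg) > 1:
            rate = 1.0 / float(ppg["t_s"].iloc[1] - ppg["t_s"].iloc[0])
        else:
            rate = sampling_rate_hz
        recordings[pid] = DualPPGRecording(
            sampling_rate_hz=rate,
            red=ppg["red"].to_numpy(),
            infrared=ppg["infrared"].to_numpy())
        imp = pd.read_csv(indir / f"impedance_{pid}.csv")
        plist = []
        for _, grp in imp.groupby("sweep_index"):
            plist.append(ImpedanceSweep(
                frequency_khz=grp["freq_khz"].to_numpy(dtype=float),
                real_ohm=grp["real_ohm"].to_numpy(dtype=float),
                imag_ohm=grp["imag_ohm"].to_numpy(dtype=float),
                phase_rad=grp["phase_rad"].to_numpy(dtype=float),
                magnitude_ohm=grp["magnitude_ohm"].to_numpy(dtype=float)))
        sweeps[pid] = plist
    return frame, recordings, sweeps
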