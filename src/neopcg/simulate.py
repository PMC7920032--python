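"""Synthetic neonatal phonocardiogram / ECG generator with ground truth.

Emulates the recording setup the analysis pipeline targets: a neonate
instrumented with a contact-free piezoelectric vibration sensor (PS),
an electronic stethoscope, and a simultaneous ECG.  Each simulated
subject yields three synchronous channels plus a :class:`GroundTruth`
carrying the exact R-peak times, the four cardiac-phase intervals of
every beat (S1, systole, S2, diastole), and the noise-free component
tracks, so every downstream stage (filtering, envelope, segmentation,
SNR) can be validated against known truth.

Signal model, per beat anchored at an ECG R peak:

* **S1** — a Hann-windowed tone burst (default 60 Hz, 70 ms) starting
  30 ms after the R peak (electromechanical delay).
* **S2** — a shorter burst (default 80 Hz, 50 ms) at 40 % of the local
  RR interval (end of mechanical systole).
* **Systolic murmur** — band-limited Gaussian noise (default
  60-300 Hz) gated by a raised-cosine crescendo-decrescendo window
  spanning the S1-to-S2 gap.  Its amplitude is calibrated so that the
  mean Hilbert envelope of the murmur over systole equals
  ``murmur_ratio`` times the mean envelope of the diastolic broadband
  noise floor; the systole/diastole SNR statistic therefore has the
  known value ``20*log10(murmur_ratio)`` dB up to noise.
* **ECG** — stylized QRS complexes (Ricker wavelets) at jittered beat
  times; no P/T waves.

Channel composition: the stethoscope channel is clean PCG plus
broadband sensor noise; the PS channel is the clean PCG scaled by
``ps_attenuation`` (the sensor sits under a face towel and couples
less efficiently) plus low-frequency motion/respiration drift and its
own independent broadband noise, then low-pass filtered at 1 kHz.

All randomness derives from ``SimConfig.seed`` through fixed
per-component stream tags, so equal configs give bit-identical
recordings regardless of call order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
from scipy import signal as sps

from .filtering import lowpass

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Recording",
    "levine_to_ratio",
    "simulate_ecg",
    "simulate_heart_sounds",
    "simulate_recording",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

# Fixed stream tags: rng([seed, tag]) per independent noise component.
_TAG_ECG = 1
_TAG_MURMUR = 2
_TAG_MOTION = 3
_TAG_NOISE_STETH = 4
_TAG_NOISE_PS = 5

# Rayleigh envelope mean of unit-variance Gaussian noise.
_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))

# Beat geometry (seconds / fractions); manual segmentation in the field
# has no canonical values, these sit in the physiologic range.
S1_DELAY = 0.030     # R peak -> S1 onset
S1_DURATION = 0.070
S2_FRACTION = 0.40   # S2 onset as fraction of local RR
S2_DURATION = 0.050


def levine_to_ratio(grade: int) -> float:
    """Map a Levine murmur grade (0-6) to a murmur/noise envelope ratio.

    Grade 0 (no murmur) maps to 0; audible grades double per step with
    grade 2 -> 4 and grade 3 -> 8, placing the resulting SNR_sys in the
    5-25 dB span typical of graded systolic murmurs.
    """
    if not 0 <= grade <= 6:
        raise ValueError(f"Levine grade must be in 0..6, got {grade}")
    return 0.0 if grade == 0 else float(2.0 ** grade)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.  Units noted per field."""

    sampling_rate: float = 4000.0          # Hz
    duration: float = 10.0                 # s
    heart_rate: float = 140.0              # beats/min (neonatal)
    rr_jitter: float = 0.02                # fractional std of RR
    s1_amplitude: float = 1.0              # arbitrary sensor units
    s2_amplitude: float = 0.8
    s1_band: tuple[float, float] = (40.0, 80.0)    # Hz; tone at band center
    s2_band: tuple[float, float] = (60.0, 100.0)
    murmur_band: tuple[float, float] = (60.0, 300.0)
    murmur_ratio: float = 0.0              # envelope ratio vs diastolic floor
    motion_noise_amplitude: float = 0.05   # std of <30 Hz drift
    broadband_noise_amplitude: float = 0.01  # white-noise std, must be > 0
    ps_attenuation: float = 0.8            # PS gain relative to stethoscope
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        for name in ("s1_band", "s2_band", "murmur_band"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < low < high, got ({lo}, {hi})")
            if hi >= nyq:
                raise ValueError(f"{name} upper edge {hi} Hz exceeds Nyquist {nyq:g} Hz")
        if self.murmur_ratio < 0:
            raise ValueError("murmur_ratio must be >= 0")
        if not 0.0 < self.ps_attenuation <= 1.0:
            raise ValueError("ps_attenuation must lie in (0, 1]")
        if min(self.s1_amplitude, self.s2_amplitude, self.motion_noise_amplitude) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.broadband_noise_amplitude <= 0:
            raise ValueError(
                "broadband_noise_amplitude must be > 0 (a nonzero diastolic "
                "noise floor keeps the SNR denominators finite)"
            )
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")

    @classmethod
    def from_levine(cls, grade: int, **kwargs) -> "SimConfig":
        """Build a config with murmur_ratio set from a Levine grade."""
        return cls(murmur_ratio=levine_to_ratio(grade), **kwargs)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("s1_band", "s2_band", "murmur_band"):
            d[k] = list(d[k])
        return d


@dataclass
class PhaseIntervals:
    """Four half-open time intervals (seconds) of one beat."""

    s1: tuple[float, float]
    systole: tuple[float, float]
    s2: tuple[float, float]
    diastole: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"S1": self.s1, "SYS": self.systole, "S2": self.s2, "DIA": self.diastole}


@dataclass
class GroundTruth:
    """Exact generative annotations attached to a synthetic recording."""

    r_peak_times: np.ndarray              # seconds, strictly increasing
    phase_intervals: list[PhaseIntervals]  # one per complete beat
    true_murmur_ratio: float
    s1_track: np.ndarray
    s2_track: np.ndarray
    murmur_track: np.ndarray
    noise_track: np.ndarray               # stethoscope-channel broadband noise
    sampling_rate: float

    def phase_sample_intervals(self, label: str) -> list[tuple[int, int]]:
        """Half-open [start, end) sample intervals for one phase label."""
        key = {"S1": "s1", "SYS": "systole", "S2": "s2", "DIA": "diastole"}[label]
        fs = self.sampling_rate
        out = []
        for beat in self.phase_intervals:
            t0, t1 = getattr(beat, key)
            out.append((int(round(t0 * fs)), int(round(t1 * fs))))
        return out


@dataclass
class Recording:
    """A multi-channel synchronous recording of one subject."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    subject_id: str = ""
    group: str = ""          # "CHD" | "control" | ""
    position: str = "prone"  # "supine" | "prone"
    ground_truth: Optional[GroundTruth] = None
    config: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Recording needs at least one channel")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag)])


def _beat_times(config: SimConfig) -> np.ndarray:
    """Jittered R-peak times; first beat at 0.2 s, last fully inside."""
    rng = _rng(config.seed, _TAG_ECG)
    rr_nominal = 60.0 / config.heart_rate
    t = 0.2
    margin = 0.05  # keep the QRS pulse inside the record
    if config.duration < t + margin + rr_nominal:
        raise ValueError(
            f"duration {config.duration} s too short for a single beat at "
            f"{config.heart_rate} bpm"
        )
    times = []
    while t <= config.duration - margin:
        times.append(t)
        rr = rr_nominal * (1.0 + config.rr_jitter * rng.standard_normal())
        t += max(rr, 0.3 * rr_nominal)
    return np.asarray(times)


def simulate_ecg(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stylized single-lead ECG: Ricker-wavelet QRS at jittered beat times.

    Returns ``(signal, r_peak_times)`` with the peak of each wavelet at
    the corresponding R time (to within one sample).
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    r_times = _beat_times(config)
    ecg = np.zeros(n)
    width_s = 0.016  # QRS width parameter
    half = int(round(5 * width_s * fs))
    tt = (np.arange(-half, half + 1)) / fs
    a = width_s / 2.0
    # Ricker (Mexican hat): positive central lobe flanked by negative lobes,
    # a serviceable stand-in for a QRS complex.
    pulse = (1.0 - (tt / a) ** 2) * np.exp(-(tt**2) / (2 * a**2))
    for rt in r_times:
        c = int(round(rt * fs))
        lo, hi = c - half, c + half + 1
        plo, phi = max(0, -lo), len(pulse) - max(0, hi - n)
        ecg[max(lo, 0):min(hi, n)] += pulse[plo:phi]
    return ecg, r_times


def _tone_burst(fs: float, duration: float, freq: float, amplitude: float) -> np.ndarray:
    m = int(round(duration * fs))
    t = np.arange(m) / fs
    return amplitude * np.hanning(m) * np.sin(2 * np.pi * freq * t)


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    band: tuple[float, float]) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, white)


def simulate_heart_sounds(
    config: SimConfig, r_peaks: np.ndarray
) -> tuple[np.ndarray, GroundTruth]:
    """Clean phonocardiogram (S1 + S2 + murmur tracks) with ground truth.

    Only complete beats (R peak with a successor) get phase intervals;
    the final partial beat still receives an S1 burst so the signal has
    no abrupt silence at the end.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if len(r_peaks) == 0 or np.any(np.diff(r_peaks) <= 0):
        raise ValueError("r_peaks must be non-empty and strictly increasing")
    fs = config.sampling_rate
    nyq = fs / 2.0
    if config.murmur_band[1] >= nyq:
        raise ValueError(f"murmur_band exceeds Nyquist {nyq:g} Hz")
    n = int(round(config.duration * fs))

    s1_freq = 0.5 * (config.s1_band[0] + config.s1_band[1])
    s2_freq = 0.5 * (config.s2_band[0] + config.s2_band[1])
    s1_burst = _tone_burst(fs, S1_DURATION, s1_freq, config.s1_amplitude)
    s2_burst = _tone_burst(fs, S2_DURATION, s2_freq, config.s2_amplitude)

    s1_track = np.zeros(n)
    s2_track = np.zeros(n)
    murmur_track = np.zeros(n)
    beats: list[PhaseIntervals] = []

    def _add(track: np.ndarray, start_s: float, burst: np.ndarray) -> None:
        i0 = int(round(start_s * fs))
        i1 = min(i0 + len(burst), n)
        if i0 < n:
            track[i0:i1] += burst[: i1 - i0]

    for k, rt in enumerate(r_peaks):
        s1_on = rt + S1_DELAY
        _add(s1_track, s1_on, s1_burst)
        if k + 1 >= len(r_peaks):
            break  # no complete beat after the final R peak
        rr = r_peaks[k + 1] - rt
        s2_on = rt + S2_FRACTION * rr
        s2_off = s2_on + S2_DURATION
        _add(s2_track, s2_on, s2_burst)
        s1_off = s1_on + S1_DURATION
        next_s1_on = r_peaks[k + 1] + S1_DELAY
        if not (s1_off < s2_on < s2_off < next_s1_on):
            raise ValueError("beat geometry collapsed; RR interval too short")
        beats.append(
            PhaseIntervals(
                s1=(s1_on, s1_off),
                systole=(s1_off, s2_on),
                s2=(s2_on, s2_off),
                diastole=(s2_off, next_s1_on),
            )
        )

    if config.murmur_ratio > 0:
        rng = _rng(config.seed, _TAG_MURMUR)
        band_noise = _bandpass_noise(rng, n, fs, config.murmur_band)
        gate = np.zeros(n)
        for beat in beats:
            t0, t1 = beat.systole
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            u = np.arange(i1 - i0) / max(i1 - i0 - 1, 1)
            gate[i0:i1] = 0.5 - 0.5 * np.cos(2 * np.pi * u)  # crescendo-decrescendo
        raw = gate * band_noise
        # Calibrate: mean Hilbert envelope of the murmur over systole
        # equals murmur_ratio times the expected diastolic noise-floor
        # envelope (Rayleigh mean of the broadband noise std).
        env = np.abs(sps.hilbert(raw))
        sys_mask = gate > 0
        observed = float(env[sys_mask].mean()) if sys_mask.any() else 0.0
        if observed > 0:
            target = config.murmur_ratio * config.broadband_noise_amplitude * _RAYLEIGH_MEAN
            murmur_track = raw * (target / observed)

    clean = s1_track + s2_track + murmur_track
    truth = GroundTruth(
        r_peak_times=r_peaks,
        phase_intervals=beats,
        true_murmur_ratio=config.murmur_ratio,
        s1_track=s1_track,
        s2_track=s2_track,
        murmur_track=murmur_track,
        noise_track=np.zeros(n),
        sampling_rate=fs,
    )
    return clean, truth


def _motion_noise(config: SimConfig, n: int) -> np.ndarray:
    """Low-frequency (<30 Hz) baseline drift, std = motion_noise_amplitude."""
    if config.motion_noise_amplitude == 0:
        return np.zeros(n)
    rng = _rng(config.seed, _TAG_MOTION)
    white = rng.standard_normal(n)
    sos = sps.butter(4, 25.0, btype="lowpass", fs=config.sampling_rate, output="sos")
    drift = sps.sosfiltfilt(sos, white)
    sd = drift.std()
    return drift * (config.motion_noise_amplitude / sd) if sd > 0 else np.zeros(n)


def simulate_recording(
    config: SimConfig,
    subject_id: str = "sim",
    group: str = "",
    position: str = "prone",
) -> Recording:
    """Full three-channel recording (ps, stethoscope, ecg) plus truth.

    A ``group`` of ``"control"`` forces ``murmur_ratio`` to 0 (controls
    have no murmur by definition); a warning is logged if the config
    said otherwise.
    """
    if group == "control" and config.murmur_ratio != 0:
        logger.warning(
            "control subject %s: overriding murmur_ratio=%g to 0",
            subject_id, config.murmur_ratio,
        )
        config = config.with_(murmur_ratio=0.0)

    ecg, r_times = simulate_ecg(config)
    clean, truth = simulate_heart_sounds(config, r_times)
    n = len(clean)
    fs = config.sampling_rate

    noise_steth = config.broadband_noise_amplitude * _rng(config.seed, _TAG_NOISE_STETH).standard_normal(n)
    noise_ps = config.broadband_noise_amplitude * _rng(config.seed, _TAG_NOISE_PS).standard_normal(n)
    motion = _motion_noise(config, n)

    steth = clean + noise_steth
    ps_raw = config.ps_attenuation * clean + motion + noise_ps
    ps = lowpass(ps_raw, fs, cutoff=1000.0, provenance="ps").samples

    truth.noise_track = noise_steth
    return Recording(
        channels={"ps": ps, "stethoscope": steth, "ecg": ecg},
        sampling_rate=fs,
        subject_id=subject_id,
        group=group,
        position=position,
        ground_truth=truth,
        config=config,
    )


def simulate_cohort(
    n_chd: int,
    n_control: int,
    base_config: SimConfig | None = None,
    murmur_ratio_range: tuple[float, float] = (2.0, 18.0),
    seed: int = 0,
) -> list[Recording]:
    """A cohort of CHD and control subjects with deterministic sub-seeds.

    CHD subjects draw ``murmur_ratio`` uniformly from
    ``murmur_ratio_range`` (default 2-18, spanning SNR_sys of roughly
    6-25 dB); controls are murmur-free.  Per-subject seeds and ratio
    draws derive from the cohort ``seed`` alone.
    """
    if n_chd < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    lo, hi = murmur_ratio_range
    if not lo < hi:
        raise ValueError("murmur_ratio_range must be a non-empty interval")
    if base_config is None:
        base_config = SimConfig()
    rng = _rng(seed, 97)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_chd + n_control)
    ratios = rng.uniform(lo, hi, size=n_chd)
    recs = []
    for i in range(n_chd):
        cfg = base_config.with_(murmur_ratio=float(ratios[i]), seed=int(subject_seeds[i]))
        recs.append(simulate_recording(cfg, subject_id=f"chd{i + 1:02d}", group="CHD"))
    for j in range(n_control):
        cfg = base_config.with_(murmur_ratio=0.0, seed=int(subject_seeds[n_chd + j]))
        recs.append(simulate_recording(cfg, subject_id=f"ctl{j + 1:02d}", group="control"))
    return recs
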