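"""Phase-mean envelope amplitudes and the SNR statistics.

The murmur statistic treats the mean diastolic envelope amplitude as
the noise floor and expresses each phase's mean envelope amplitude
relative to it on a dB scale:

    SNR_s1  = 20 log10(S1_mean  / DIA_mean)
    SNR_s2  = 20 log10(S2_mean  / DIA_mean)
    SNR_sys = 20 log10(SYS_mean / DIA_mean)

A systolic murmur raises SYS_mean above the diastolic floor, so
SNR_sys quantifies murmur intensity; murmur-free recordings sit near
0 dB.  Phase means pool envelope samples across the selected beats
(beats weighted by duration); per-beat means are retained for the
standard errors of the cut-off-frequency sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .envelope import EnvelopeTrace, hilbert_envelope
from .filtering import highpass
from .segmentation import (
    PhaseSegmentation,
    RPeakSet,
    detect_r_peaks,
    segment_phases,
    segment_without_ecg,
    select_stable_beats,
)
from .simulate import Recording

__all__ = [
    "PhaseAmplitudes",
    "SnrResult",
    "SweepTable",
    "phase_amplitudes",
    "compute_snr",
    "analyze_recording",
    "cutoff_sweep",
    "DEFAULT_SWEEP_CUTOFFS",
]

DEFAULT_SWEEP_CUTOFFS = (20.0, 30.0, 50.0, 70.0, 100.0, 130.0, 160.0, 200.0)

_PHASE_FIELDS = {"S1": "s1_mean", "SYS": "sys_mean", "S2": "s2_mean", "DIA": "dia_mean"}


@dataclass(frozen=True)
class PhaseAmplitudes:
    """Mean envelope amplitude per cardiac phase, pooled over beats."""

    s1_mean: float
    sys_mean: float
    s2_mean: float
    dia_mean: float
    n_beats: int
    per_beat: Optional[pd.DataFrame] = None  # columns S1, SYS, S2, DIA

    def __post_init__(self) -> None:
        for name in ("s1_mean", "sys_mean", "s2_mean", "dia_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _db(num: float, den: float) -> float:
    if num == 0.0:
        return float("-inf")  # sentinel: phase with zero envelope
    return 20.0 * np.log10(num / den)


@dataclass(frozen=True)
class SnrResult:
    snr_s1: float
    snr_s2: float
    snr_sys: float
    amplitudes: PhaseAmplitudes
    hp_cutoff: Optional[float] = None
    sensor: str = ""

    def as_row(self) -> dict:
        a = self.amplitudes
        return {
            "sensor": self.sensor,
            "hp_cutoff_hz": self.hp_cutoff,
            "snr_s1_db": self.snr_s1,
            "snr_s2_db": self.snr_s2,
            "snr_sys_db": self.snr_sys,
            "s1_mean": a.s1_mean,
            "s2_mean": a.s2_mean,
            "sys_mean": a.sys_mean,
            "dia_mean": a.dia_mean,
            "n_beats": a.n_beats,
        }


def phase_amplitudes(envelope: EnvelopeTrace, seg: PhaseSegmentation) -> PhaseAmplitudes:
    """Pooled mean envelope amplitude per phase across all beats in ``seg``.

    Pooling concatenates every phase's samples before averaging, so
    longer beats carry proportionally more weight.  The per-beat means
    are stored alongside for dispersion statistics.
    """
    if len(seg) == 0:
        raise ValueError("empty segmentation")
    env = np.asarray(envelope.envelope, dtype=float)
    pooled: dict[str, float] = {}
    rows = []
    for phase in _PHASE_FIELDS:
        sums, counts = 0.0, 0
        for iv in seg.phase_intervals(phase):
            if iv.end > len(env):
                raise ValueError("segmentation extends past the envelope")
            sums += float(env[iv.as_slice()].sum())
            counts += len(iv)
        pooled[phase] = sums / counts
    for b in seg.beats:
        rows.append({p: float(env[b.interval(p).as_slice()].mean()) for p in _PHASE_FIELDS})
    return PhaseAmplitudes(
        s1_mean=pooled["S1"],
        sys_mean=pooled["SYS"],
        s2_mean=pooled["S2"],
        dia_mean=pooled["DIA"],
        n_beats=len(seg),
        per_beat=pd.DataFrame(rows),
    )


def compute_snr(
    amps: PhaseAmplitudes, hp_cutoff: float | None = None, sensor: str = ""
) -> SnrResult:
    """dB-scaled phase/diastole amplitude ratios."""
    if amps.dia_mean <= 0:
        raise ValueError("dia_mean must be > 0 (degenerate noise floor)")
    return SnrResult(
        snr_s1=_db(amps.s1_mean, amps.dia_mean),
        snr_s2=_db(amps.s2_mean, amps.dia_mean),
        snr_sys=_db(amps.sys_mean, amps.dia_mean),
        amplitudes=amps,
        hp_cutoff=hp_cutoff,
        sensor=sensor,
    )


def _segment(
    rec: Recording, env: EnvelopeTrace, r_peaks: RPeakSet | None
) -> PhaseSegmentation:
    if r_peaks is not None:
        return segment_phases(env, r_peaks)
    if "ecg" in rec.channels:
        r = detect_r_peaks(rec.channels["ecg"], rec.sampling_rate)
        return segment_phases(env, r)
    return segment_without_ecg(env)


def analyze_recording(
    rec: Recording,
    channel: str = "ps",
    hp_cutoff: float = 70.0,
    n_beats: int = 10,
    r_peaks: RPeakSet | None = None,
) -> SnrResult:
    """Full pipeline on one channel of a recording.

    high-pass -> Hilbert envelope -> (ECG-gated | audio-only) phase
    segmentation -> stable-beat selection -> phase means -> SNR.
    When the recording has an ECG channel it anchors the segmentation;
    otherwise the audio-only segmenter is used.  ``r_peaks`` can be
    supplied to reuse one detection across several calls.
    """
    if channel not in rec.channels:
        raise KeyError(f"channel {channel!r} not in recording "
                       f"(has {sorted(rec.channels)})")
    filt = highpass(rec.channels[channel], rec.sampling_rate,
                    cutoff=hp_cutoff, provenance=channel)
    env = hilbert_envelope(filt)
    seg = _segment(rec, env, r_peaks)
    sel = select_stable_beats(env, seg, n_beats=n_beats)
    amps = phase_amplitudes(env, sel)
    return compute_snr(amps, hp_cutoff=hp_cutoff, sensor=channel)


@dataclass
class SweepTable:
    """Mean and standard error of the per-beat SNRs per cut-off."""

    frame: pd.DataFrame  # columns: cutoff_hz, metric, mean_db, stderr_db, sensor
    sensor: str

    def metric(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["metric"] == name].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _per_beat_snrs(amps: PhaseAmplitudes) -> pd.DataFrame:
    pb = amps.per_beat
    out = pd.DataFrame()
    for phase, col in (("S1", "snr_s1"), ("S2", "snr_s2"), ("SYS", "snr_sys")):
        with np.errstate(divide="ignore"):
            out[col] = 20.0 * np.log10(pb[phase] / pb["DIA"])
    return out


def cutoff_sweep(
    rec: Recording,
    channel: str = "ps",
    cutoffs: Sequence[float] = DEFAULT_SWEEP_CUTOFFS,
    n_beats: int = 10,
    reference_cutoff: float = 70.0,
) -> SweepTable:
    """SNR statistics as a function of the high-pass cut-off frequency.

    Segmentation anchors are shared across the sweep: R peaks are
    detected once on the raw ECG and the phase intervals are delimited
    once at ``reference_cutoff`` (phases are anatomical and must not
    drift with the filter under study — at high cut-offs the heart
    sounds themselves can vanish from the pass-band, which is precisely
    the effect the sweep measures).  Only the envelope is recomputed
    per cut-off.  Standard errors are over the per-beat SNR values of
    the selected beats.
    """
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    nyq = rec.sampling_rate / 2.0
    if cutoffs[0] <= 0 or cutoffs[-1] >= nyq:
        raise ValueError(f"cutoffs must lie in (0, {nyq:g}) Hz")

    r_peaks = (detect_r_peaks(rec.channels["ecg"], rec.sampling_rate)
               if "ecg" in rec.channels else None)
    ref_filt = highpass(rec.channels[channel], rec.sampling_rate,
                        cutoff=reference_cutoff, provenance=channel)
    ref_env = hilbert_envelope(ref_filt)
    sel = select_stable_beats(ref_env, _segment(rec, ref_env, r_peaks),
                              n_beats=n_beats)

    rows = []
    for c in cutoffs:
        filt = highpass(rec.channels[channel], rec.sampling_rate, cutoff=c,
                        provenance=channel)
        env = hilbert_envelope(filt)
        amps = phase_amplitudes(env, sel)
        per_beat = _per_beat_snrs(amps)
        for col in ("snr_s1", "snr_s2", "snr_sys"):
            v = per_beat[col].to_numpy()
            rows.append({
                "cutoff_hz": c,
                "metric": col,
                "mean_db": float(np.mean(v)),
                "stderr_db": float(np.std(v, ddof=1) / np.sqrt(len(v))),
                "sensor": channel,
            })
    return SweepTable(pd.DataFrame(rows), sensor=channel)
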