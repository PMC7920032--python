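"""ECG R-peak detection and four-phase cardiac segmentation.

Each heartbeat is partitioned into four half-open sample intervals —
S1, systole, S2, diastole — using the heart-sound envelope gated by
the simultaneous ECG: S1 is the envelope lobe synchronized with the R
wave, S2 the lobe between consecutive R waves, systole the gap between
them, diastole the remainder up to the next beat's S1.  A fallback
segmenter handles stethoscope audio with no ECG by exploiting the fact
that at neonatal heart rates systole (S1->S2) is shorter than diastole
(S2->S1).

Conventions: sample indices are 0-based and intervals half-open
[start, end) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .envelope import EnvelopeTrace

__all__ = [
    "RPeakSet",
    "PhaseInterval",
    "Beat",
    "PhaseSegmentation",
    "detect_r_peaks",
    "segment_phases",
    "select_stable_beats",
    "segment_without_ecg",
    "UnsegmentableError",
]

logger = logging.getLogger(__name__)

PHASES = ("S1", "SYS", "S2", "DIA")

# Segmentation parameters (seconds / fractions), exposed for sensitivity
# analysis but stable defaults for neonatal recordings.
LOBE_THRESHOLD = 0.20       # lobe edge at this fraction of the lobe peak
LOBE_MAX_HALFWIDTH = 0.060  # bound each side of a lobe (total <= 120 ms)
S1_SEARCH = (-0.020, 0.100)   # S1 peak search window around the R peak
S2_SEARCH = (0.25, 0.60)      # S2 peak search band as fraction of RR
REFRACTORY = 0.250            # QRS refractory period
S2_MIN_PROMINENCE = 2.0       # S2 peak must exceed this x local median


class UnsegmentableError(ValueError):
    """Raised when a channel cannot be segmented into cardiac phases."""


@dataclass(frozen=True)
class RPeakSet:
    indices: np.ndarray  # sample positions, strictly increasing
    sampling_rate: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if len(idx) and np.any(np.diff(idx) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.sampling_rate

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class PhaseInterval:
    start: int  # inclusive sample
    end: int    # exclusive sample

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def as_slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class Beat:
    r_index: int
    s1: PhaseInterval
    systole: PhaseInterval
    s2: PhaseInterval
    diastole: PhaseInterval

    def interval(self, phase: str) -> PhaseInterval:
        return {"S1": self.s1, "SYS": self.systole,
                "S2": self.s2, "DIA": self.diastole}[phase]

    def __post_init__(self) -> None:
        if not (self.s1.end <= self.systole.start
                and self.systole.end <= self.s2.start
                and self.s2.end <= self.diastole.start):
            raise ValueError("beat phases out of order")


@dataclass
class PhaseSegmentation:
    beats: list[Beat]
    sampling_rate: float

    def __len__(self) -> int:
        return len(self.beats)

    def phase_intervals(self, phase: str) -> list[PhaseInterval]:
        return [b.interval(phase) for b in self.beats]


def detect_r_peaks(ecg: np.ndarray, sampling_rate: float) -> RPeakSet:
    """Locate QRS complexes in a single-lead ECG.

    Pan-Tompkins-style chain: 5-25 Hz zero-phase band-pass, squared
    derivative, 20 ms integration, adaptive threshold at half a 2 s
    rolling maximum, 250 ms refractory.  Peak positions are refined on
    the squared band-passed signal, which makes the detector invariant
    to lead polarity.
    """
    ecg = np.asarray(ecg, dtype=float)
    fs = float(sampling_rate)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG for R-peak detection")
    if not np.all(np.isfinite(ecg)):
        raise ValueError("non-finite ECG samples")

    sos = sps.butter(2, (5.0, 25.0), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    feat = np.gradient(bp) ** 2
    win = max(int(0.020 * fs), 1)
    feat = ndimage.uniform_filter1d(feat, size=win)

    roll = ndimage.maximum_filter1d(feat, size=int(2.0 * fs))
    global_scale = np.max(feat)
    if global_scale <= 0:
        raise UnsegmentableError("flat ECG: no QRS activity detected")
    # Floor the rolling max so silence between beats cannot drop the
    # threshold into the noise.
    thresh = 0.5 * np.maximum(roll, 0.05 * global_scale)

    above = feat > thresh
    # Suppress spurious activity in records that are pure noise.
    if not above.any():
        raise UnsegmentableError("no samples above QRS threshold")

    idx = np.flatnonzero(above)
    region_breaks = np.flatnonzero(np.diff(idx) > 1)
    region_starts = np.concatenate(([0], region_breaks + 1))
    region_ends = np.concatenate((region_breaks, [len(idx) - 1]))

    refractory = int(REFRACTORY * fs)
    half_refine = int(0.040 * fs)
    bp2 = bp**2
    peaks: list[int] = []
    strengths: list[float] = []
    for rs, re_ in zip(region_starts, region_ends):
        lo, hi = idx[rs], idx[re_] + 1
        c = lo + int(np.argmax(feat[lo:hi]))
        a, b = max(0, c - half_refine), min(len(ecg), c + half_refine + 1)
        p = a + int(np.argmax(bp2[a:b]))
        s = feat[c]
        if peaks and p - peaks[-1] < refractory:
            if s > strengths[-1]:
                peaks[-1], strengths[-1] = p, s
            continue
        peaks.append(p)
        strengths.append(s)

    if len(peaks) < 2:
        raise UnsegmentableError("fewer than two QRS complexes detected")
    return RPeakSet(np.asarray(peaks), fs)


def _lobe(env: np.ndarray, peak: int, fs: float,
          lo_bound: int, hi_bound: int) -> PhaseInterval:
    """Delimit the envelope lobe around ``peak`` at LOBE_THRESHOLD of
    its height, each side bounded by LOBE_MAX_HALFWIDTH and by
    [lo_bound, hi_bound)."""
    cut = LOBE_THRESHOLD * env[peak]
    max_half = int(LOBE_MAX_HALFWIDTH * fs)
    lo = peak
    floor = max(lo_bound, peak - max_half)
    while lo > floor and env[lo - 1] >= cut:
        lo -= 1
    hi = peak + 1
    ceil = min(hi_bound, peak + max_half)
    while hi < ceil and env[hi] >= cut:
        hi += 1
    return PhaseInterval(lo, hi)


def segment_phases(envelope: EnvelopeTrace, r_peaks: RPeakSet) -> PhaseSegmentation:
    """Partition each RR interval into S1 / systole / S2 / diastole.

    S1 is the envelope lobe around the largest peak in a window about
    the R wave; S2 the lobe around the largest peak in the 25-60 % RR
    band.  Beats whose S2 lobe is indistinguishable from the local
    noise floor (peak below ``S2_MIN_PROMINENCE`` x the RR-local median
    envelope), or whose phases collapse, are excluded with a log
    message.
    """
    if len(r_peaks) < 3:
        raise ValueError("need at least 3 R peaks to segment phases")
    env = np.asarray(envelope.envelope, dtype=float)
    fs = envelope.sampling_rate
    n = len(env)
    r = r_peaks.indices
    # Peak finding runs on a smoothed envelope so fast fluctuations of a
    # murmur's noise envelope cannot masquerade as a heart-sound lobe;
    # lobe delimitation still uses the raw envelope.
    smooth = ndimage.uniform_filter1d(env, size=max(int(0.025 * fs), 1))

    def _refine(p: int) -> int:
        half = int(0.012 * fs)
        a, b = max(0, p - half), min(n, p + half + 1)
        return a + int(np.argmax(env[a:b]))

    def peak_in(a: int, b: int) -> int | None:
        a, b = max(0, a), min(n, b)
        if b <= a:
            return None
        return _refine(a + int(np.argmax(smooth[a:b])))

    def last_prominent_peak_in(a: int, b: int) -> int | None:
        """Latest local max of the smoothed envelope in [a, b) that
        reaches 60% of the band maximum; S2 is the final coherent lobe
        before the quiet diastole, after any systolic murmur."""
        a, b = max(0, a), min(n, b)
        if b <= a:
            return None
        w = smooth[a:b]
        m = float(w.max())
        if m <= 0:
            return None
        cand, _ = sps.find_peaks(w, height=0.6 * m)
        p = (a + int(cand[-1])) if len(cand) else (a + int(np.argmax(w)))
        return _refine(p)

    # S1 lobes for every R peak (needed as next-beat anchors).
    s1_lobes: list[PhaseInterval | None] = []
    for rk in r:
        p = peak_in(rk + int(S1_SEARCH[0] * fs), rk + int(S1_SEARCH[1] * fs))
        if p is None or env[p] <= 0:
            s1_lobes.append(None)
            continue
        s1_lobes.append(_lobe(env, p, fs, 0, n))

    beats: list[Beat] = []
    for k in range(len(r) - 1):
        rr = r[k + 1] - r[k]
        s1 = s1_lobes[k]
        nxt = s1_lobes[k + 1]
        if s1 is None or nxt is None:
            logger.info("beat %d: missing S1 lobe, excluded", k)
            continue
        a = r[k] + int(S2_SEARCH[0] * rr)
        b = r[k] + int(S2_SEARCH[1] * rr)
        p2 = last_prominent_peak_in(a, b)
        local = env[r[k]:r[k + 1]]
        if p2 is None or env[p2] < S2_MIN_PROMINENCE * np.median(local):
            logger.info("beat %d: S2 lobe indistinguishable, excluded", k)
            continue
        s2 = _lobe(env, p2, fs, s1.end, nxt.start)
        try:
            beats.append(
                Beat(
                    r_index=int(r[k]),
                    s1=s1,
                    systole=PhaseInterval(s1.end, s2.start),
                    s2=s2,
                    diastole=PhaseInterval(s2.end, nxt.start),
                )
            )
        except ValueError:
            logger.info("beat %d: degenerate phase geometry, excluded", k)
    if not beats:
        raise UnsegmentableError("no segmentable beats")
    return PhaseSegmentation(beats, fs)


def _beat_rms(env: np.ndarray, beat: Beat) -> float:
    # root of the beat's total envelope energy: with fixed-energy heart
    # sounds this is insensitive to RR-jitter beat-length variation,
    # unlike a per-sample mean square, so only true artifacts stand out
    seg = env[beat.s1.start:beat.diastole.end]
    return float(np.sqrt(np.sum(seg**2)))


def select_stable_beats(
    envelope: EnvelopeTrace, seg: PhaseSegmentation, n_beats: int = 10
) -> PhaseSegmentation:
    """Pick ``n_beats`` consecutive artifact-free beats.

    Stability is judged on per-beat envelope RMS: a beat is stable if
    its RMS lies within median +- 3 MAD of all beats.  The first run of
    ``n_beats`` consecutive stable beats wins; if no such run exists,
    the run with minimal RMS dispersion is returned with a warning.
    Beats must also be contiguous in the underlying beat sequence (no
    excluded beat inside the run).
    """
    if len(seg) < n_beats:
        raise ValueError(f"need >= {n_beats} segmented beats, have {len(seg)}")
    env = np.asarray(envelope.envelope, dtype=float)
    rms = np.array([_beat_rms(env, b) for b in seg.beats])
    med = float(np.median(rms))
    # sigma-consistent MAD: robust to artifact beats, wide enough that
    # ordinary RR-jitter variation of beat RMS does not flag stable beats
    mad = 1.4826 * float(np.median(np.abs(rms - med)))
    tol = max(3.0 * mad, 1e-12 + 1e-6 * med)
    stable = np.abs(rms - med) <= tol

    # contiguity in time: consecutive beats must chain (diastole -> next S1)
    def contiguous(i: int, j: int) -> bool:
        return all(
            seg.beats[k].diastole.end == seg.beats[k + 1].s1.start
            for k in range(i, j - 1)
        )

    for i in range(len(seg) - n_beats + 1):
        j = i + n_beats
        if stable[i:j].all() and contiguous(i, j):
            return PhaseSegmentation(seg.beats[i:j], seg.sampling_rate)

    best_i, best_disp = 0, np.inf
    for i in range(len(seg) - n_beats + 1):
        j = i + n_beats
        if not contiguous(i, j):
            continue
        disp = float(np.std(rms[i:j]))
        if disp < best_disp:
            best_i, best_disp = i, disp
    logger.warning(
        "no fully stable run of %d beats; returning minimum-dispersion run "
        "starting at beat %d", n_beats, best_i,
    )
    return PhaseSegmentation(seg.beats[best_i:best_i + n_beats], seg.sampling_rate)


def segment_without_ecg(envelope: EnvelopeTrace, sampling_rate: float | None = None) -> PhaseSegmentation:
    """Segment heart-sound audio with no ECG channel.

    Detects alternating envelope lobes and assigns S1/S2 identity by
    the gap rule: at neonatal heart rates the S1->S2 gap (systole) is
    shorter than the S2->S1 gap (diastole).  Raises
    :class:`UnsegmentableError` when fewer than 6 lobes are found or
    the gap alternation is too ambiguous to trust.
    """
    env = np.asarray(envelope.envelope, dtype=float)
    fs = sampling_rate or envelope.sampling_rate
    if len(env) < 3 * fs:
        raise ValueError("need at least 3 s of signal")

    smooth = ndimage.uniform_filter1d(env, size=max(int(0.020 * fs), 1))
    floor = float(np.median(smooth))
    height = max(5.0 * floor, 0.25 * float(np.max(smooth)))
    peaks, _ = sps.find_peaks(smooth, height=height, distance=int(0.120 * fs))
    if len(peaks) < 6:
        raise UnsegmentableError(f"only {len(peaks)} envelope lobes found (need >= 6)")

    gaps = np.diff(peaks)
    even, odd = np.median(gaps[0::2]), np.median(gaps[1::2])
    ratio = max(even, odd) / min(even, odd)
    if ratio < 1.15:
        raise UnsegmentableError("lobe gap alternation ambiguous; cannot tell systole from diastole")
    # Lobes at the start of the SHORT gap are S1 (systole follows S1).
    first_s1 = 0 if even < odd else 1

    beats: list[Beat] = []
    for i in range(first_s1, len(peaks) - 2, 2):
        p1, p2, p_next = peaks[i], peaks[i + 1], peaks[i + 2]
        s1 = _lobe(env, p1, fs, 0, len(env))
        nxt = _lobe(env, p_next, fs, 0, len(env))
        s2 = _lobe(env, p2, fs, s1.end, nxt.start)
        try:
            beats.append(
                Beat(
                    r_index=int(p1),
                    s1=s1,
                    systole=PhaseInterval(s1.end, s2.start),
                    s2=s2,
                    diastole=PhaseInterval(s2.end, nxt.start),
                )
            )
        except ValueError:
            logger.info("audio-only beat at lobe %d excluded", i)
    if not beats:
        raise UnsegmentableError("no segmentable beats in audio-only mode")
    return PhaseSegmentation(beats, fs)
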