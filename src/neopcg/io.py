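"""File I/O: WAV channels, annotation tables, configuration.

External formats are deliberately plain: mono PCM WAV per channel,
tab-separated annotation files (onset_s, offset_s, label with labels
R / S1 / SYS / S2 / DIA, times in seconds to 6 decimals), flat YAML
configuration, CSV result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .segmentation import PhaseSegmentation
from .simulate import GroundTruth, Recording, SimConfig

__all__ = [
    "read_wav",
    "write_wav",
    "write_annotations",
    "read_annotations",
    "segmentation_to_frame",
    "PipelineConfig",
    "export_recording",
]

logger = logging.getLogger(__name__)

EXPECTED_RATE = 4000

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31,
              np.dtype("uint8"): 2**7}


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file, scaling integer PCM to [-1, 1].

    A warning is logged when the sampling rate differs from the 4 kHz
    the pipeline defaults assume; analysis proceeds at the file's rate.
    Multi-channel files are rejected: the workflow stores one channel
    per file.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: {data.shape[1]}-channel WAV; supply one mono file per channel"
        )
    if len(data) == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(float)
        if data.dtype == np.dtype("uint8"):
            samples = samples - 128.0
        samples /= _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(float)
    if rate != EXPECTED_RATE:
        logger.warning("%s: sampling rate %d Hz (pipeline default is %d Hz)",
                       path, rate, EXPECTED_RATE)
    return samples, float(rate)


def write_wav(path, samples: np.ndarray, sampling_rate: float,
              full_scale: float | None = None) -> None:
    """Write 16-bit PCM mono WAV.

    ``full_scale`` is the sample value mapped to digital full scale
    (default: 4x the max absolute sample, i.e. 12 dB headroom for the
    channel's own peaks); samples beyond it are clipped with a log
    message.
    """
    samples = np.asarray(samples, dtype=float)
    if full_scale is None:
        peak = float(np.max(np.abs(samples))) or 1.0
        full_scale = 4.0 * peak
    scaled = samples / full_scale
    n_clip = int(np.sum(np.abs(scaled) > 1.0))
    if n_clip:
        logger.warning("%s: clipping %d samples beyond full scale", path, n_clip)
        scaled = np.clip(scaled, -1.0, 1.0)
    pcm = np.clip(np.round(scaled * 2**15), -2**15, 2**15 - 1).astype(np.int16)
    wavfile.write(path, int(round(sampling_rate)), pcm)


def _truth_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [{"onset_s": t, "offset_s": t, "label": "R"} for t in truth.r_peak_times]
    for beat in truth.phase_intervals:
        for label, (t0, t1) in beat.as_dict().items():
            rows.append({"onset_s": t0, "offset_s": t1, "label": label})
    return pd.DataFrame(rows).sort_values(["onset_s", "label"]).reset_index(drop=True)


def segmentation_to_frame(seg: PhaseSegmentation) -> pd.DataFrame:
    """Segmentation as an annotation table (times in seconds)."""
    fs = seg.sampling_rate
    rows = [{"onset_s": b.r_index / fs, "offset_s": b.r_index / fs, "label": "R"}
            for b in seg.beats]
    for b in seg.beats:
        for label in ("S1", "SYS", "S2", "DIA"):
            iv = b.interval(label)
            rows.append({"onset_s": iv.start / fs, "offset_s": iv.end / fs,
                         "label": label})
    return pd.DataFrame(rows).sort_values(["onset_s", "label"]).reset_index(drop=True)


def write_annotations(path, obj: GroundTruth | PhaseSegmentation) -> None:
    """Write ground truth or a segmentation as a TSV annotation file."""
    frame = _truth_frame(obj) if isinstance(obj, GroundTruth) else segmentation_to_frame(obj)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_annotations(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    expected = {"onset_s", "offset_s", "label"}
    if set(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}, "
                         f"got {list(frame.columns)}")
    bad = set(frame["label"]) - {"R", "S1", "SYS", "S2", "DIA"}
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return frame


def export_recording(rec: Recording, out_dir, s1_amplitude: float | None = None) -> list[Path]:
    """Write one WAV per channel plus the ground-truth annotation TSV.

    Full scale is 4x the configured S1 amplitude so murmurs and noise
    never clip while S1 retains headroom.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if s1_amplitude is None:
        s1_amplitude = rec.config.s1_amplitude if rec.config else None
    written = []
    for name, samples in rec.channels.items():
        p = out_dir / f"{rec.subject_id}_{name}.wav"
        fs_scale = 4.0 * s1_amplitude if s1_amplitude else None
        write_wav(p, samples, rec.sampling_rate, full_scale=fs_scale)
        written.append(p)
    if rec.ground_truth is not None:
        p = out_dir / f"{rec.subject_id}_truth.tsv"
        write_annotations(p, rec.ground_truth)
        written.append(p)
    return written


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the pipeline in one flat, serializable record."""

    # simulation
    sampling_rate: float = 4000.0
    duration: float = 10.0
    heart_rate: float = 140.0
    rr_jitter: float = 0.02
    s1_amplitude: float = 1.0
    s2_amplitude: float = 0.8
    s1_band: tuple[float, float] = (40.0, 80.0)
    s2_band: tuple[float, float] = (60.0, 100.0)
    murmur_band: tuple[float, float] = (60.0, 300.0)
    murmur_ratio: float = 0.0
    motion_noise_amplitude: float = 0.05
    broadband_noise_amplitude: float = 0.01
    ps_attenuation: float = 0.8
    seed: int = 0
    # filtering
    hp_cutoff_hz: float = 70.0
    lp_cutoff_hz: float = 1000.0
    filter_order: int = 4
    # segmentation
    lobe_threshold: float = 0.20
    s2_search_lo: float = 0.25
    s2_search_hi: float = 0.60
    refractory_ms: float = 250.0
    n_beats: int = 10
    # sweep
    sweep_cutoffs: tuple[float, ...] = (20.0, 30.0, 50.0, 70.0, 100.0, 130.0, 160.0, 200.0)
    # bookkeeping
    output_dir: str = "."
    log_level: str = "INFO"

    _SIM_FIELDS = ("sampling_rate", "duration", "heart_rate", "rr_jitter",
                   "s1_amplitude", "s2_amplitude", "s1_band", "s2_band",
                   "murmur_band", "murmur_ratio", "motion_noise_amplitude",
                   "broadband_noise_amplitude", "ps_attenuation", "seed")

    def sim_config(self) -> SimConfig:
        kw = {}
        for f in self._SIM_FIELDS:
            v = getattr(self, f)
            kw[f] = tuple(v) if isinstance(v, (list, tuple)) else v
        return SimConfig(**kw)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kw = {}
        for k, v in raw.items():
            kw[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)
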