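"""Readers and writers for the WAV / label / tracking / session dialects.

* Mono WAV via ``scipy.io.wavfile``: float WAV round-trips bitwise,
  16-bit PCM within one LSB (scale 32767).  Multichannel files are
  rejected explicitly.
* Syllable labels as tab-separated ``onset_s<TAB>offset_s<TAB>label``
  lines (Audacity label-track dialect), written at microsecond
  precision, validated on read with file/line context.
* Tracking as CSV with a ``timestamp,x,y`` header in pixels; rows with
  blank coordinates are flagged invalid for gap interpolation, and
  non-monotone timestamps are rejected.
* Session metadata and provenance as JSON; run configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .errors import FormatError, ValidationError
from .preference import SessionLayout, Trajectory
from .syllables import AudioClip, DetectionConfig, SongSegmentation, Syllable

__all__ = [
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "read_tracking",
    "read_session",
    "write_session",
    "write_provenance",
    "RunConfig",
    "load_config",
    "resample",
    "PLAYBACK_RATE_HZ",
]

#: Playback export rate of the stimulus-delivery chain.
PLAYBACK_RATE_HZ = 260_420

_INT_SCALES = {np.dtype(np.int16): 32767.0, np.dtype(np.int32): 2147483647.0}


def read_wav(path) -> AudioClip:
    """Read a mono WAV file into an AudioClip (samples as float64).

    Integer PCM is scaled to [-1, 1]; float data is kept as-is, so a
    float WAV written by ``write_wav`` round-trips bitwise.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable WAV file ({exc})") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: multichannel WAV unsupported ({data.shape[1]} channels)")
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioClip(samples, int(rate))


def write_wav(clip: AudioClip, path, dtype: str = "float64") -> None:
    """Write an AudioClip as mono WAV (float64/float32/int16)."""
    if dtype == "float64":
        data = clip.samples
    elif dtype == "float32":
        data = clip.samples.astype(np.float32)
    elif dtype == "int16":
        data = np.round(np.clip(clip.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    else:
        raise FormatError(f"unsupported output dtype {dtype!r}")
    wavfile.write(path, clip.sample_rate, data)


def resample(clip: AudioClip, target_rate: int = PLAYBACK_RATE_HZ) -> AudioClip:
    """FFT-based resampling (used for playback export, not analysis)."""
    from scipy.signal import resample as _resample

    n_out = int(round(clip.n_samples * target_rate / clip.sample_rate))
    return AudioClip(_resample(clip.samples, n_out), target_rate)


def write_labels(seg: SongSegmentation, path) -> None:
    """Write syllable intervals as an Audacity-style label track."""
    with open(path, "w") as fh:
        for i, s in enumerate(seg.syllables):
            fh.write(f"{s.onset_s:.6f}\t{s.offset_s:.6f}\tsyl{i}\n")


def read_labels(path, duration_s: float | None = None) -> SongSegmentation:
    """Read a tab-separated label file into a SongSegmentation.

    Rejects reversed or overlapping intervals with the offending line
    number.  When ``duration_s`` is omitted, the song duration is taken
    as the last offset.
    """
    syllables = []
    prev_off = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError("expected onset<TAB>offset[<TAB>label]", path, lineno)
            try:
                onset, offset = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValidationError("non-numeric onset/offset", path, lineno) from None
            if offset <= onset:
                raise ValidationError(f"offset {offset} <= onset {onset}", path, lineno)
            if onset < prev_off - 1e-9:
                raise ValidationError(
                    f"interval overlaps previous (onset {onset} < offset {prev_off})",
                    path,
                    lineno,
                )
            syllables.append(Syllable(onset_s=onset, offset_s=offset))
            prev_off = offset
    if duration_s is None:
        duration_s = prev_off
    return SongSegmentation(tuple(syllables), duration_s=duration_s)


def read_tracking(path, mm_per_px: float = 1.0, nominal_rate_hz: float = 30.0) -> Trajectory:
    """Read a ``timestamp,x,y`` CSV (pixels) into a calibrated Trajectory.

    Blank x/y fields mark a frame invalid (body detection failed); the
    downstream ``interpolate_gaps`` fills them.  Non-monotone timestamps
    raise a validation error with the offending row.
    """
    if mm_per_px <= 0:
        raise ValidationError("mm_per_px calibration must be positive", path)
    df = pd.read_csv(path)
    required = {"timestamp", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(f"missing columns {sorted(required - set(df.columns))}", path)
    t = df["timestamp"].to_numpy(dtype=np.float64)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValidationError(
            f"non-monotone timestamp at row {int(bad[0]) + 2}", path, int(bad[0]) + 2
        )
    x = df["x"].to_numpy(dtype=np.float64)
    y = df["y"].to_numpy(dtype=np.float64)
    valid = ~(np.isnan(x) | np.isnan(y))
    x = np.where(valid, x, 0.0) * mm_per_px
    y = np.where(valid, y, 0.0) * mm_per_px
    return Trajectory(t_s=t, x_mm=x, y_mm=y, valid=valid, nominal_rate_hz=nominal_rate_hz)


def write_session(layout: SessionLayout, path, contrast: str | None = None) -> None:
    """Write session metadata (geometry, calibration, trial windows) as JSON."""
    payload = {
        "box_w_mm": layout.box_w_mm,
        "box_h_mm": layout.box_h_mm,
        "zone_depth_mm": layout.zone_depth_mm,
        "partition_halfwidth_mm": layout.partition_halfwidth_mm,
        "arm_length_mm": layout.arm_length_mm,
        "mm_per_px": layout.mm_per_px,
        "trial_windows": [list(w) for w in layout.trial_windows],
        "contrast": contrast,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_session(path) -> tuple[SessionLayout, str | None]:
    payload = json.loads(Path(path).read_text())
    windows = tuple((float(a), float(b), str(s)) for a, b, s in payload["trial_windows"])
    layout = SessionLayout(
        box_w_mm=payload.get("box_w_mm", 227.0),
        box_h_mm=payload.get("box_h_mm", 252.0),
        zone_depth_mm=payload.get("zone_depth_mm", 86.0),
        partition_halfwidth_mm=payload.get("partition_halfwidth_mm", 5.0),
        arm_length_mm=payload.get("arm_length_mm", 126.0),
        mm_per_px=payload.get("mm_per_px", 1.0),
        trial_windows=windows,
    )
    return layout, payload.get("contrast")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, *, inputs=(), seed=None, parameters=None) -> None:
    """Write a JSON provenance sidecar: input hashes, seed, parameters."""
    payload = {
        "inputs": {str(p): _sha256(p) for p in inputs},
        "seed": seed,
        "parameters": parameters or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration shared by the CLI commands."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    zone_depth_mm: float = 86.0
    mm_per_px: float = 1.0
    alpha: float = 0.05
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    det = DetectionConfig(**raw.get("detection", {}))
    kwargs = {k: v for k, v in raw.items() if k != "detection"}
    return RunConfig(detection=det, **kwargs)
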