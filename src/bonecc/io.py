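"""File I/O: WAV waveforms, CSV tap lists, JSON/YAML configurations."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .errors import ValidationError
from .signals import StereoSignal, TimeSignal

__all__ = [
    "read_wav",
    "write_wav",
    "read_taps_csv",
    "write_taps_csv",
    "load_config_file",
]


def write_wav(path: str | Path, signal: TimeSignal | StereoSignal, subtype: str = "float32") -> None:
    """Write a mono or stereo signal as a WAV file ('float32' or 'pcm16')."""
    if isinstance(signal, StereoSignal):
        data = np.stack([signal.left.samples, signal.right.samples], axis=1)
        rate = signal.rate_hz
    else:
        data = signal.samples
        rate = signal.rate_hz
    if subtype == "float32":
        wavfile.write(str(path), int(rate), data.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(data, -1.0, 1.0 - 2.0**-15)
        wavfile.write(str(path), int(rate), np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValidationError(f"unsupported WAV subtype {subtype!r}; use 'float32' or 'pcm16'")


def read_wav(path: str | Path) -> TimeSignal | StereoSignal:
    """Read a WAV file; stereo files map channel 0 to left."""
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, OSError) as exc:
        raise ValidationError(f"cannot read WAV file {path}: {exc}") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        return StereoSignal(
            left=TimeSignal(samples[:, 0], rate),
            right=TimeSignal(samples[:, 1], rate),
        )
    return TimeSignal(samples, rate)


def write_taps_csv(path: str | Path, taps: np.ndarray | TimeSignal) -> None:
    """Write filter/impulse-response taps as ``index,amplitude`` CSV."""
    samples = taps.samples if isinstance(taps, TimeSignal) else np.asarray(taps, dtype=float)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "amplitude"])
        for i, a in enumerate(samples):
            writer.writerow([i, repr(float(a))])


def read_taps_csv(path: str | Path) -> np.ndarray:
    """Read an ``index,amplitude`` CSV back into a tap array."""
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if [h.strip() for h in header[:2]] != ["index", "amplitude"]:
                raise ValidationError(
                    f"{path}: expected header 'index,amplitude', got {header!r}"
                )
            taps = [float(row[1]) for row in reader if row]
    except (OSError, IndexError, StopIteration) as exc:
        raise ValidationError(f"cannot read taps CSV {path}: {exc}") from exc
    except ValueError as exc:
        raise ValidationError(f"malformed amplitude in {path}: {exc}") from exc
    if not taps:
        raise ValidationError(f"{path}: no taps found")
    return np.asarray(taps)


def load_config_file(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file into a dict."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read config {path}: {exc}") from exc
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValidationError(f"malformed config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must contain a mapping at top level")
    return data
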