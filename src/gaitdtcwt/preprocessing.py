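"""Raw IMU stream conditioning: moving-average smoothing and recording I/O.

A recording is an 18-channel inertial time series from three body-worn
sensors (thigh, shank, foot), each contributing 3-axis acceleration (units
of g) and 3-axis angular velocity (deg/s), sampled at 96 Hz, together with
a binary foot-contact sequence (1 = instrumented foot on the ground).
Smoothing uses a centred 5-frame moving average; boundary frames average
over the truncated neighbourhood that exists, which keeps constant signals
exactly fixed and avoids zero-padding transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SENSORS",
    "AXES",
    "CHANNEL_NAMES",
    "PAPER_SAMPLE_RATE",
    "MultiChannelRecording",
    "moving_average",
    "smooth_recording",
    "read_recording",
    "write_recording",
]

SENSORS = ("thigh", "shank", "foot")
AXES = ("ax", "ay", "az", "gx", "gy", "gz")
CHANNEL_NAMES = tuple(f"{s}_{a}" for s in SENSORS for a in AXES)
PAPER_SAMPLE_RATE = 96.0


@dataclass
class MultiChannelRecording:
    """Time-aligned 18-channel IMU stream with contact sequence and metadata."""

    samples: np.ndarray          # frames x 18, sensor-major channel order
    contact: np.ndarray          # frames, binary
    sample_rate: float = PAPER_SAMPLE_RATE
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.contact = np.asarray(self.contact)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(CHANNEL_NAMES):
            raise ValueError(
                f"samples must be frames x {len(CHANNEL_NAMES)}; "
                f"got shape {self.samples.shape}")
        if self.contact.shape != (self.samples.shape[0],):
            raise ValueError("contact length must equal the sample frame count")
        if not np.isin(self.contact, (0, 1)).all():
            raise ValueError("contact sequence must be binary (0/1)")
        self.contact = self.contact.astype(np.int8)
        if self.sample_rate != PAPER_SAMPLE_RATE:
            warnings.warn(
                f"sample rate {self.sample_rate} Hz differs from the "
                f"{PAPER_SAMPLE_RATE:g} Hz the pipeline defaults assume",
                stacklevel=2)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


def moving_average(signal, width: int = 5) -> np.ndarray:
    """Centred moving average; boundary frames use the truncated neighbourhood.

    For even widths the window spans ``width // 2`` frames to the left and
    the remainder to the right of the centre frame.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > x.size:
        raise ValueError(f"width {width} exceeds signal length {x.size}")
    if width == 1:
        return x.copy()
    left = width // 2
    right = width - 1 - left
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    return (c[hi + 1] - c[lo]) / (hi + 1 - lo)


def smooth_recording(rec: MultiChannelRecording,
                     width: int = 5) -> MultiChannelRecording:
    """Apply the moving average independently to every channel.

    Contact sequence and metadata pass through unchanged.
    """
    smoothed = np.column_stack(
        [moving_average(rec.samples[:, k], width)
         for k in range(rec.samples.shape[1])])
    return replace(rec, samples=smoothed, contact=rec.contact.copy())


# ---------------------------------------------------------------------------
# Delimited-text recording format
# ---------------------------------------------------------------------------

_COLUMNS = ("time", "subject", "label", "contact") + CHANNEL_NAMES


def write_recording(rec: MultiChannelRecording, path: str | Path) -> None:
    frame = pd.DataFrame(rec.samples, columns=list(CHANNEL_NAMES))
    frame.insert(0, "time", np.arange(rec.n_frames) / rec.sample_rate)
    frame.insert(1, "subject", rec.subject_id)
    frame.insert(2, "label", rec.label if rec.label is not None else "")
    frame.insert(3, "contact", rec.contact)
    frame.to_csv(path, index=False)


def read_recording(path: str | Path,
                   sample_rate: float = PAPER_SAMPLE_RATE) -> MultiChannelRecording:
    frame = pd.read_csv(path, dtype={"subject": str, "label": str})
    if tuple(frame.columns) != _COLUMNS:
        raise ValueError(
            f"{path}: expected {len(_COLUMNS)} columns {_COLUMNS[:4]}..., "
            f"got {tuple(frame.columns)}")
    contact = frame["contact"].to_numpy()
    if not np.isin(contact, (0, 1)).all():
        raise ValueError(f"{path}: contact column must be binary (0/1)")
    subject = str(frame["subject"].iloc[0]) if len(frame) else ""
    label = frame["label"].iloc[0] if len(frame) else None
    if isinstance(label, float) and np.isnan(label):
        label = None
    return MultiChannelRecording(
        samples=frame[list(CHANNEL_NAMES)].to_numpy(),
        contact=contact, sample_rate=sample_rate,
        subject_id=subject, label=label if label else None)
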