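"""Gait-event segmentation: toe-off detection and fixed-length swing windows.

The locomotion vocabulary comprises 5 steady states — level walking (LW),
stair ascent (SA), stair descent (SD), ramp ascent (RA), ramp descent (RD)
— and the 8 transitional states between level walking and each other
terrain (LW-SA, LW-SD, LW-RA, LW-RD, SA-LW, SD-LW, RA-LW, RD-LW).  Each
analysis window starts at a toe-off event (a 1 -> 0 transition of the
foot-contact sequence, the start of swing phase) and spans a fixed even
number of frames, 46 by default at 96 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import CHANNEL_NAMES, MultiChannelRecording

__all__ = [
    "STEADY_LABELS",
    "TRANSITIONAL_LABELS",
    "ALL_LABELS",
    "MotionLabel",
    "GaitWindow",
    "detect_toe_offs",
    "extract_windows",
]

logger = logging.getLogger(__name__)

STEADY_LABELS = ("LW", "SA", "SD", "RA", "RD")
TRANSITIONAL_LABELS = ("LW-SA", "LW-SD", "LW-RA", "LW-RD",
                       "SA-LW", "SD-LW", "RA-LW", "RD-LW")
ALL_LABELS = STEADY_LABELS + TRANSITIONAL_LABELS


@dataclass(frozen=True)
class MotionLabel:
    """One of the 13 locomotion states, with its steady/transitional category."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in ALL_LABELS:
            raise ValueError(f"unknown motion label {self.code!r}; "
                             f"expected one of {ALL_LABELS}")

    @property
    def category(self) -> str:
        return "steady" if self.code in STEADY_LABELS else "transitional"


@dataclass
class GaitWindow:
    """Fixed-length 18-channel swing-phase segment starting at a toe-off."""

    samples: np.ndarray
    start_frame: int
    label: str | None
    subject_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(CHANNEL_NAMES):
            raise ValueError("window samples must be frames x 18")
        if self.samples.shape[0] % 2:
            raise ValueError(
                f"window length {self.samples.shape[0]} is odd; windows "
                "must contain an even number of frames")
        if self.label is not None:
            MotionLabel(self.label)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


def detect_toe_offs(contact) -> list[int]:
    """Indices i > 0 with contact[i-1] = 1 and contact[i] = 0, ascending."""
    c = np.asarray(contact)
    if c.ndim != 1:
        raise ValueError("contact must be a 1-D sequence")
    if c.size and not np.isin(c, (0, 1)).all():
        raise ValueError("contact sequence must be binary (0/1)")
    if c.size < 2:
        return []
    return list(np.flatnonzero((c[:-1] == 1) & (c[1:] == 0)) + 1)


def extract_windows(rec: MultiChannelRecording,
                    window_len: int = 46) -> list[GaitWindow]:
    """Cut one ``window_len``-frame window per toe-off event.

    Toe-offs too close to the end of the recording to supply a full window
    are skipped (never padded) and counted in the log.  Windows inherit the
    recording's label and subject.
    """
    if window_len < 2 or window_len % 2:
        raise ValueError(
            f"window_len {window_len} is invalid: the decomposition "
            "requires an even number of frames per window")
    events = detect_toe_offs(rec.contact)
    windows, skipped = [], 0
    for start in events:
        if start + window_len > rec.n_frames:
            skipped += 1
            continue
        windows.append(GaitWindow(
            samples=rec.samples[start:start + window_len],
            start_frame=start, label=rec.label, subject_id=rec.subject_id))
    if skipped:
        logger.info("extract_windows: skipped %d of %d toe-offs without "
                    "room for %d frames", skipped, len(events), window_len)
    return windows
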