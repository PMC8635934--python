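"""Level-5 low-frequency DTCWT features for gait windows.

Each channel of a gait window is decomposed to ``levels`` scales and the
final-level approximation (scaling) coefficients of both trees are kept as
the channel's features.  Under the transform's length policy a 46-frame
window at 5 levels yields 2 approximation coefficients per tree, i.e. 4 per
channel, so the default configuration maps an 18-channel window to a
72-dimensional vector (3 sensors x 6 channels x 4 coefficients).  The
layout is channel-major: for each channel, tree-a coefficients then tree-b
coefficients, each in coefficient order.

The deep approximation coefficients summarise the smooth, low-frequency
shape of the swing-phase waveform — the part of the signal that differs
most visibly between locomotion modes — while the half-sample-delayed dual
tree keeps them stable under small timing shifts of the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dtcwt import (approximation_reconstruction, dtcwt_forward,
                    level_coefficient_counts)
from .filters import FilterPairSet
from .preprocessing import CHANNEL_NAMES
from .segmentation import GaitWindow

__all__ = [
    "FeatureVector",
    "window_features",
    "fit_curve",
    "feature_dimension",
    "features_to_frame",
    "frame_to_features",
]


@dataclass
class FeatureVector:
    """Real-valued feature vector for one gait window."""

    values: np.ndarray
    label: str | None
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature values must be a 1-D vector")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


def feature_dimension(window_len: int, levels: int,
                      n_channels: int = len(CHANNEL_NAMES)) -> int:
    """Predicted feature count: channels x 2 trees x per-tree approximation count."""
    per_tree = level_coefficient_counts(window_len, levels)[-1]
    return n_channels * 2 * per_tree


def window_features(window: GaitWindow, levels: int = 5,
                    filters: FilterPairSet | None = None) -> FeatureVector:
    """Map a gait window to its low-frequency dual-tree coefficient vector."""
    n = window.n_frames
    try:
        level_coefficient_counts(n, levels)
    except ValueError as exc:
        raise ValueError(
            f"window of {n} frames cannot support {levels} decomposition "
            f"levels: {exc}") from exc
    parts = []
    for k in range(window.samples.shape[1]):
        coeffs = dtcwt_forward(window.samples[:, k], levels, filters)
        parts.append(np.real(coeffs.approximation))
        parts.append(np.imag(coeffs.approximation))
    return FeatureVector(values=np.concatenate(parts),
                         label=window.label, subject_id=window.subject_id)


def fit_curve(signal, levels: int = 5,
              filters: FilterPairSet | None = None) -> np.ndarray:
    """Smooth low-frequency fit: reconstruction from deep approximation only.

    Details at every level are zeroed and the two trees' approximation-only
    reconstructions averaged, turning the discrete window into the smooth
    continuous-curve fit used to visualise mode differences.  Not part of
    the classification path (the features are the coefficients themselves).
    """
    coeffs = dtcwt_forward(signal, levels, filters)
    ra = approximation_reconstruction(coeffs, filters, tree="a")
    rb = approximation_reconstruction(coeffs, filters, tree="b")
    return 0.5 * (ra + rb)


# ---------------------------------------------------------------------------
# Feature-table I/O (delimited text: subject,label,f000..f071)
# ---------------------------------------------------------------------------

def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    if not features:
        raise ValueError("no feature vectors to tabulate")
    dim = features[0].values.size
    cols = [f"f{i:03d}" for i in range(dim)]
    frame = pd.DataFrame([fv.values for fv in features], columns=cols)
    frame.insert(0, "subject", [fv.subject_id for fv in features])
    frame.insert(1, "label", [fv.label for fv in features])
    return frame


def frame_to_features(frame: pd.DataFrame) -> list[FeatureVector]:
    cols = [c for c in frame.columns if c.startswith("f")]
    return [FeatureVector(values=row[cols].to_numpy(dtype=float),
                          label=row["label"], subject_id=str(row["subject"]))
            for _, row in frame.iterrows()]


def write_features(features: list[FeatureVector], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FeatureVector]:
    return frame_to_features(pd.read_csv(path, dtype={"subject": str}))
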