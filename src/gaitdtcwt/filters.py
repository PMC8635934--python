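"""Analysis/synthesis filter banks for the 1-D dual-tree complex wavelet transform.

A dual-tree transform runs two parallel critically-sampled real wavelet
trees whose outputs form the real (tree a) and imaginary (tree b) parts of
complex coefficients.  Approximate analyticity — and with it approximate
shift invariance — comes from the group-delay relationship between the
trees:

* level 1: tree b uses the same biorthogonal pair as tree a, delayed by one
  sample (the delay is baked into the stored tree-b taps as a leading zero);
* levels >= 2: "Q-shift" orthonormal filters whose group delay sits a
  quarter sample off centre, with tree b the exact time reverse of tree a,
  so the two lowpass responses differ by half a sample of delay.

The default tap set ships as plain-text data files (one tap per line, one
file per filter, named ``<stage>_<tree>_<direction>_<band>.txt``).  It
consists of the LeGall 5/3 biorthogonal pair at level 1 (exact dyadic
rationals, scaled to a DC gain of sqrt(2)) and a length-14 Q-shift pair
designed by :func:`design_qshift_lowpass`.  Because the Q-shift filter is
produced by a paraunitary lattice, every analysis/synthesis stage is exactly
invertible regardless of the optimised lattice angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, minimize

__all__ = [
    "FilterPairSet",
    "default_filters",
    "load_filter_set",
    "save_filter_set",
    "design_qshift_lowpass",
    "qmf_highpass",
    "legall_level1_filters",
    "half_sample_delay",
]

STAGES = ("level1", "qshift")
TREES = ("a", "b")
DIRECTIONS = ("analysis", "synthesis")
BANDS = ("lowpass", "highpass")


# ---------------------------------------------------------------------------
# Q-shift design: paraunitary lattice parameterisation
# ---------------------------------------------------------------------------

def _lattice_filters(thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (paraunitary) two-channel pair from lattice angles.

    K angles produce filters of length 2K.  Any angle vector yields an
    exactly orthonormal filter bank, so perfect reconstruction never depends
    on the optimiser having converged.
    """
    c, s = np.cos(thetas[0]), np.sin(thetas[0])
    h0 = np.array([c, s])
    h1 = np.array([-s, c])
    for th in thetas[1:]:
        c, s = np.cos(th), np.sin(th)
        h0pad = np.concatenate([h0, [0.0, 0.0]])
        h1pad = np.concatenate([[0.0, 0.0], h1])
        h0, h1 = c * h0pad + s * h1pad, -s * h0pad + c * h1pad
    return h0, h1


def _group_delay(h: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = np.arange(len(h))
    E = np.exp(-1j * np.outer(w, n))
    H = E @ h
    dH = E @ (n * h)
    return np.real(dH / H)


def design_qshift_lowpass(length: int = 14, seed: int = 0,
                          n_restarts: int = 40) -> np.ndarray:
    """Design an orthonormal lowpass with quarter-sample-offset group delay.

    The filter is optimised so that its passband group delay approximates
    (length-1)/2 - 1/4; its time reverse then has delay (length-1)/2 + 1/4,
    and the two make a half-sample-delayed Q-shift pair for the dual tree.
    A zero at z = -1 (one vanishing moment) is enforced exactly by a final
    one-dimensional root find on the last lattice angle, so constant signals
    produce numerically zero detail coefficients.

    Deterministic for a fixed ``seed``.
    """
    if length < 10 or length % 2:
        raise ValueError("Q-shift filter length must be even and >= 10")
    K = length // 2
    target = (length - 1) / 2 - 0.25
    wp = np.linspace(0.0, 0.45 * np.pi, 60)
    ws = np.linspace(0.62 * np.pi, np.pi, 80)

    def objective(thetas: np.ndarray) -> float:
        h0, _ = _lattice_filters(thetas)
        n = np.arange(length)
        Hs = np.exp(-1j * np.outer(ws, n)) @ h0
        pen_delay = np.mean((_group_delay(h0, wp) - target) ** 2)
        pen_stop = np.mean(np.abs(Hs) ** 2)
        pen_pi = np.sum((-1.0) ** n * h0) ** 2
        pen_dc = (np.sum(h0) - np.sqrt(2.0)) ** 2
        return 30.0 * pen_delay + 8.0 * pen_stop + 50.0 * pen_pi + 5.0 * pen_dc

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        res = minimize(objective, rng.uniform(-np.pi, np.pi, K),
                       method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    thetas = best.x

    def zero_at_pi(t: float) -> float:
        v = thetas.copy()
        v[-1] = t
        h0, _ = _lattice_filters(v)
        n = np.arange(len(h0))
        return float(np.sum((-1.0) ** n * h0))

    lo, hi = thetas[-1] - 0.2, thetas[-1] + 0.2
    if zero_at_pi(lo) * zero_at_pi(hi) < 0:
        thetas[-1] = brentq(zero_at_pi, lo, hi, xtol=1e-15)
    h0, _ = _lattice_filters(thetas)
    if np.sum(h0) < 0:
        h0 = -h0
    return h0


def qmf_highpass(h0: np.ndarray) -> np.ndarray:
    """Orthonormal highpass companion h1[n] = (-1)^n h0[L-1-n]."""
    n = np.arange(len(h0))
    return ((-1.0) ** n) * np.asarray(h0)[::-1]


# ---------------------------------------------------------------------------
# Level-1 biorthogonal pair (LeGall 5/3)
# ---------------------------------------------------------------------------

def legall_level1_filters() -> dict[str, np.ndarray]:
    """LeGall 5/3 pair scaled to DC gain sqrt(2) on each lowpass.

    Returns the analysis lowpass/highpass and synthesis lowpass/highpass in
    the alignment convention used by the transform stages (correlation
    sampled at even shifts; see :mod:`gaitdtcwt.dtcwt`), for which the
    quadruple is exactly perfect-reconstructing on any even-length circular
    signal.
    """
    s2 = np.sqrt(2.0)
    h0 = np.array([-1.0, 2.0, 6.0, 2.0, -1.0]) / 8.0 * s2
    g0 = np.concatenate([[0.0], np.array([1.0, 2.0, 1.0]) / 2.0 / s2])
    h1 = np.concatenate([[0.0, 0.0],
                         np.array([1.0, -2.0, 1.0]) / 2.0 / s2])
    g1 = np.concatenate([[0.0],
                         np.array([1.0, 2.0, -6.0, 2.0, 1.0]) / 8.0 * s2])
    return {"analysis_lowpass": h0, "analysis_highpass": h1,
            "synthesis_lowpass": g0, "synthesis_highpass": g1}


# ---------------------------------------------------------------------------
# FilterPairSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterPairSet:
    """Complete tap set for both trees and both stages of the dual tree.

    ``taps[(stage, tree, direction, band)]`` holds one real tap sequence,
    with stage in {"level1", "qshift"}, tree in {"a", "b"}, direction in
    {"analysis", "synthesis"} and band in {"lowpass", "highpass"}.
    """

    taps: dict

    def __post_init__(self) -> None:
        for stage in STAGES:
            for tree in TREES:
                for direction in DIRECTIONS:
                    for band in BANDS:
                        key = (stage, tree, direction, band)
                        if key not in self.taps:
                            raise ValueError(f"missing filter {key}")
                        arr = np.asarray(self.taps[key], dtype=float)
                        if arr.ndim != 1 or arr.size < 2:
                            raise ValueError(f"filter {key} must be a 1-D tap sequence")
                        self.taps[key] = arr

    def get(self, stage: str, tree: str, direction: str, band: str) -> np.ndarray:
        return self.taps[(stage, tree, direction, band)]

    def stage_bank(self, stage: str, tree: str, direction: str):
        """(lowpass, highpass) pair for one stage of one tree."""
        return (self.get(stage, tree, direction, "lowpass"),
                self.get(stage, tree, direction, "highpass"))


def _make_default_taps() -> dict:
    lev1 = legall_level1_filters()
    taps = {}
    for band in BANDS:
        for direction in DIRECTIONS:
            a = lev1[f"{direction}_{band}"]
            taps[("level1", "a", direction, band)] = a
            # tree b = tree a delayed by one sample
            taps[("level1", "b", direction, band)] = np.concatenate([[0.0], a])
    h0a = design_qshift_lowpass()
    h1a = qmf_highpass(h0a)
    h0b, h1b = h0a[::-1], h1a[::-1]
    for tree, (lo, hi) in (("a", (h0a, h1a)), ("b", (h0b, h1b))):
        for direction in DIRECTIONS:
            # orthonormal stage: synthesis sum uses the analysis taps (adjoint)
            taps[("qshift", tree, direction, "lowpass")] = lo
            taps[("qshift", tree, direction, "highpass")] = hi
    return taps


def save_filter_set(filters: FilterPairSet, directory: str | Path) -> None:
    """Write one plain-text file per filter (one tap per line)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (stage, tree, direction, band), arr in filters.taps.items():
        name = f"{stage}_{tree}_{direction}_{band}.txt"
        np.savetxt(directory / name, arr, fmt="%.17g")


def load_filter_set(directory: str | Path) -> FilterPairSet:
    """Load a tap set from a directory of per-filter text files."""
    directory = Path(directory)
    taps = {}
    for stage in STAGES:
        for tree in TREES:
            for direction in DIRECTIONS:
                for band in BANDS:
                    path = directory / f"{stage}_{tree}_{direction}_{band}.txt"
                    if not path.exists():
                        raise FileNotFoundError(f"missing filter file {path}")
                    taps[(stage, tree, direction, band)] = np.loadtxt(path, ndmin=1)
    return FilterPairSet(taps)


_DEFAULT_CACHE: FilterPairSet | None = None


def default_filters() -> FilterPairSet:
    """The packaged default tap set (LeGall 5/3 + designed length-14 Q-shift)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        root = resources.files("gaitdtcwt") / "filter_data" / "default"
        with resources.as_file(root) as path:
            _DEFAULT_CACHE = load_filter_set(path)
    return _DEFAULT_CACHE


def half_sample_delay(h_a: np.ndarray, h_b: np.ndarray) -> float:
    """Estimated group-delay offset between two impulse responses.

    Cross-correlates the responses and refines the peak lag by parabolic
    interpolation.  For a Q-shift pair the magnitude of the returned lag is
    close to 0.5 samples.
    """
    h_a = np.asarray(h_a, float)
    h_b = np.asarray(h_b, float)
    c = np.correlate(h_b, h_a, mode="full")
    k = int(np.argmax(c))
    if k == 0 or k == len(c) - 1:
        return float(k - (len(h_a) - 1))
    y0, y1, y2 = c[k - 1], c[k], c[k + 1]
    frac = 0.5 * (y0 - y2) / (y0 - 2.0 * y1 + y2)
    return float(k + frac - (len(h_a) - 1))
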