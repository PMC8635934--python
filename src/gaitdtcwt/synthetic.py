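"""Synthetic labelled IMU gait recordings for all 13 locomotion states.

The study data behind this pipeline are not public, so this module
generates a stand-in corpus with the structural properties every pipeline
stage needs: per-state periodic 18-channel waveforms, a stance/swing
contact sequence with known toe-off frames, additive sensor noise and
between-subject variability.  All data produced here are synthetic.

Signal model
------------
Each channel of each state is a sum of harmonics of the gait cycle,

    w_c(u) = o_c + Re sum_k C_{c,k} exp(2 pi i k u),   u in [0, 1),

with complex harmonic coefficients ``C`` and offsets ``o`` drawn once per
state from a seeded generator.  Transitional states interpolate the
coefficients of their two steady endpoint states linearly across the cycle
(the transitional step), so e.g. LW-SA starts shaped like level walking
and ends shaped like stair ascent.  Confusable state pairs reported for
real data (SD vs RD, and consequently LW-SD vs LW-RD, SD-LW vs SD) are
built to be the closest templates: the ramp-descent template is a small
perturbation of stair descent.

Subjects scale amplitude and cycle length, perturb the per-state harmonic
coefficients (the subject effect that separates user-dependent from
user-independent difficulty) and add Gaussian sensor noise.  Acceleration
channels are in units of g (noise floor 0.03 g), angular-velocity channels
in deg/s (noise floor 2 deg/s).  The nominal cycle is 104 frames at 96 Hz
(~1.08 s) with a 0.5 swing fraction, so a full 46-frame swing window fits
in every cycle.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import AXES, CHANNEL_NAMES, MultiChannelRecording, SENSORS
from .segmentation import ALL_LABELS, STEADY_LABELS, MotionLabel

__all__ = [
    "GaitTemplate",
    "SubjectProfile",
    "make_default_templates",
    "generate_recording",
    "generate_dataset",
    "DEFAULT_CYCLE_FRAMES",
    "DEFAULT_SWING_FRACTION",
]

N_CHANNELS = len(CHANNEL_NAMES)
N_HARMONICS = 4
DEFAULT_CYCLE_FRAMES = 104
DEFAULT_SWING_FRACTION = 0.5
WINDOW_FRAMES = 46

# per-channel scales: accelerations O(0.4 g), angular velocities O(80 deg/s)
_IS_ACCEL = np.array([a.startswith("a") for s in SENSORS for a in AXES])
CHANNEL_AMPLITUDE = np.where(_IS_ACCEL, 0.4, 80.0)
CHANNEL_NOISE_FLOOR = np.where(_IS_ACCEL, 0.03, 2.0)
# gravity shows up as a ~1 g offset on the vertical accelerometer axes
_GRAVITY_OFFSET = np.array([1.0 if a == "az" else 0.0
                            for s in SENSORS for a in AXES])


@dataclass
class GaitTemplate:
    """Harmonic waveform parameters of one state over one gait cycle.

    ``coeffs_start``/``coeffs_end`` are (18, H) complex harmonic
    coefficients; steady states have identical start and end, transitional
    states interpolate between their two steady endpoints across the cycle.
    """

    label: str
    coeffs_start: np.ndarray
    coeffs_end: np.ndarray
    offset_start: np.ndarray
    offset_end: np.ndarray
    cycle_frames: int = DEFAULT_CYCLE_FRAMES
    swing_fraction: float = DEFAULT_SWING_FRACTION

    def __post_init__(self) -> None:
        MotionLabel(self.label)
        if not 0.0 < self.swing_fraction < 1.0:
            raise ValueError("swing_fraction must lie strictly in (0, 1)")
        for arr in (self.coeffs_start, self.coeffs_end):
            if np.asarray(arr).shape != (N_CHANNELS, N_HARMONICS):
                raise ValueError(
                    f"harmonic coefficients must be {N_CHANNELS} x {N_HARMONICS}")
        if self.swing_fraction * self.cycle_frames < WINDOW_FRAMES:
            warnings.warn(
                f"swing of {self.swing_fraction * self.cycle_frames:.0f} "
                f"frames cannot hold a full {WINDOW_FRAMES}-frame window",
                stacklevel=2)

    def mean_cycle(self) -> np.ndarray:
        """(18, cycle_frames) noise-free waveform of one cycle."""
        return _waveform(self, self.cycle_frames, 1.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject variation: scaling, subject effect and noise level.

    ``noise_sd`` multiplies the per-channel noise floors; ``coeff_sd``
    scales a subject-specific perturbation of the state templates (the
    between-subject effect).  Reproducible given ``seed``.
    """

    subject_id: str
    amplitude_scale: float = 1.0
    cycle_scale: float = 1.0
    noise_sd: float = 1.0
    coeff_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0 or self.cycle_scale <= 0:
            raise ValueError("subject scales must be positive")


def _draw_coeffs(rng: np.random.Generator):
    k = np.arange(1, N_HARMONICS + 1)
    scale = CHANNEL_AMPLITUDE[:, None] / k[None, :]
    coeffs = scale * (rng.standard_normal((N_CHANNELS, N_HARMONICS))
                      + 1j * rng.standard_normal((N_CHANNELS, N_HARMONICS)))
    offset = _GRAVITY_OFFSET + 0.2 * CHANNEL_AMPLITUDE * \
        rng.standard_normal(N_CHANNELS)
    return coeffs, offset


def make_default_templates(seed: int = 20210) -> dict[str, GaitTemplate]:
    """The 13 default state templates.

    Steady states get independent seeded harmonic draws except ramp
    descent, which is stair descent plus a small perturbation (their real
    counterparts are the most similar pair).  Transitional templates
    interpolate their steady endpoints.
    """
    rng = np.random.default_rng(seed)
    steady: dict[str, tuple] = {}
    for code in ("LW", "SA", "SD", "RA"):
        steady[code] = _draw_coeffs(rng)
    sd_c, sd_o = steady["SD"]
    pert_c, pert_o = _draw_coeffs(rng)
    steady["RD"] = (sd_c + 0.30 * pert_c,
                    sd_o + 0.30 * (pert_o - _GRAVITY_OFFSET))

    templates = {}
    for code in STEADY_LABELS:
        c, o = steady[code]
        templates[code] = GaitTemplate(label=code, coeffs_start=c,
                                       coeffs_end=c, offset_start=o,
                                       offset_end=o)
    for code in ALL_LABELS:
        if code in STEADY_LABELS:
            continue
        a, b = code.split("-")
        ca, oa = steady[a]
        cb, ob = steady[b]
        templates[code] = GaitTemplate(label=code, coeffs_start=ca,
                                       coeffs_end=cb, offset_start=oa,
                                       offset_end=ob)
    _assert_distinct(templates)
    return templates


def _assert_distinct(templates: dict[str, GaitTemplate]) -> None:
    codes = list(templates)
    cycles = {c: templates[c].mean_cycle() for c in codes}
    dmin = np.inf
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            dmin = min(dmin, float(np.linalg.norm(cycles[a] - cycles[b])))
    if dmin <= 0.0:
        raise ValueError("default templates are not pairwise distinct")


def _waveform(template: GaitTemplate, cycle_frames: int,
              amplitude_scale: float,
              coeff_pert=None, offset_pert=None) -> np.ndarray:
    """One noise-free cycle, shape (18, cycle_frames)."""
    u = np.arange(cycle_frames) / cycle_frames
    cs, ce = template.coeffs_start, template.coeffs_end
    os_, oe = template.offset_start, template.offset_end
    if coeff_pert is not None:
        cs = cs + coeff_pert
        ce = ce + coeff_pert
    if offset_pert is not None:
        os_ = os_ + offset_pert
        oe = oe + offset_pert
    k = np.arange(1, N_HARMONICS + 1)
    phases = np.exp(2j * np.pi * np.outer(k, u))          # (H, F)
    c_u = cs[:, :, None] * (1.0 - u) + ce[:, :, None] * u  # (18, H, F)
    wave = np.real(np.einsum("chf,hf->cf", c_u, phases))
    wave += os_[:, None] * (1.0 - u) + oe[:, None] * u
    return amplitude_scale * wave


def _subject_perturbation(subject: SubjectProfile, state_index: int):
    rng = np.random.default_rng([subject.seed, state_index, 7919])
    k = np.arange(1, N_HARMONICS + 1)
    scale = subject.coeff_sd * CHANNEL_AMPLITUDE[:, None] / k[None, :]
    coeff = scale * (rng.standard_normal((N_CHANNELS, N_HARMONICS))
                     + 1j * rng.standard_normal((N_CHANNELS, N_HARMONICS)))
    offset = subject.coeff_sd * 0.2 * CHANNEL_AMPLITUDE * \
        rng.standard_normal(N_CHANNELS)
    return coeff, offset


def generate_recording(template: GaitTemplate, subject: SubjectProfile,
                       n_cycles: int, seed: int = 0
                       ) -> tuple[MultiChannelRecording, list[int]]:
    """Emit ``n_cycles`` repetitions of the subject-adapted state cycle.

    Returns the recording together with the scheduled toe-off frames (one
    per cycle, at the stance-to-swing transition).  Fully reproducible for
    fixed template, subject and seed.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    state_index = ALL_LABELS.index(template.label)
    cf = int(round(template.cycle_frames * subject.cycle_scale))
    stance = int(round(cf * (1.0 - template.swing_fraction)))
    if not 0 < stance < cf:
        raise ValueError("degenerate stance/swing split")
    coeff_pert, offset_pert = _subject_perturbation(subject, state_index)
    cycle = _waveform(template, cf, subject.amplitude_scale,
                      coeff_pert, offset_pert)           # (18, cf)
    clean = np.tile(cycle, (1, n_cycles)).T              # frames x 18
    noise_rng = np.random.default_rng([seed, subject.seed, state_index])
    noise = noise_rng.standard_normal(clean.shape) * \
        (subject.noise_sd * CHANNEL_NOISE_FLOOR)[None, :]
    contact_cycle = np.concatenate([np.ones(stance, dtype=np.int8),
                                    np.zeros(cf - stance, dtype=np.int8)])
    contact = np.tile(contact_cycle, n_cycles)
    rec = MultiChannelRecording(samples=clean + noise, contact=contact,
                                subject_id=subject.subject_id,
                                label=template.label)
    toe_offs = [c * cf + stance for c in range(n_cycles)]
    return rec, toe_offs


def generate_dataset(n_subjects: int = 10, windows_per_state: int = 6,
                     seed: int = 0, noise_sd: float = 1.0,
                     subject_sd: float = 0.15,
                     templates: dict[str, GaitTemplate] | None = None):
    """Balanced synthetic cohort: every subject performs all 13 states.

    Returns ``(recordings, manifest)`` where the manifest lists, per
    recording, the subject, label and true toe-off frames.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    templates = templates or make_default_templates()
    master = np.random.default_rng(seed)
    recordings, manifest = [], []
    for s in range(n_subjects):
        profile = SubjectProfile(
            subject_id=f"S{s + 1:02d}",
            amplitude_scale=float(np.exp(master.normal(0.0, 0.08))),
            cycle_scale=float(np.clip(np.exp(master.normal(0.0, 0.04)),
                                      0.93, 1.12)),
            noise_sd=noise_sd,
            coeff_sd=subject_sd,
            seed=int(master.integers(2 ** 31)))
        for code in ALL_LABELS:
            rec_seed = int(master.integers(2 ** 31))
            rec, toe_offs = generate_recording(templates[code], profile,
                                               n_cycles=windows_per_state,
                                               seed=rec_seed)
            recordings.append(rec)
            manifest.append({"subject": profile.subject_id, "label": code,
                             "toe_offs": toe_offs, "seed": rec_seed,
                             "n_frames": rec.n_frames})
    return recordings, manifest
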