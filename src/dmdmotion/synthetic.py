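"""Ground-truth-known synthetic trajectories.

These generators replace recorded motion capture for testing: they produce
trajectories whose dynamics are known in closed form, so every claim about
reconstruction and forecasting can be checked against an exact answer.

Three families:

* :func:`linear_system_series` — iterates x_{k+1} = A x_k, the model class
  DMD recovers exactly; used as the oracle for the decomposition itself.
* :func:`sinusoid_series` — sums of (optionally damped, noisy) sinusoids
  per channel; a scalar sum of q incommensurate sinusoids is the canonical
  quasi-periodic signal that plain DMD cannot represent but delay-embedded
  DMD can.
* :func:`synthetic_skeleton` — a 17-joint, 51-channel, 50 Hz walking-like
  stand-in for marker-position data: limb channels are phase-offset
  harmonic oscillations around anatomical offsets, the root translates
  slowly through space.  Noise-free, every channel is a sum of at most 7
  complex exponentials, so the whole skeleton is exactly low-rank in the
  delay-embedded sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .sequence import MotionSequence

__all__ = [
    "SinusoidSpec",
    "linear_system_series",
    "sinusoid_series",
    "quasi_periodic_scalar",
    "synthetic_skeleton",
    "demo_corpus",
    "partial_observation",
    "planar_rotation",
    "SKELETON_JOINTS",
]


@dataclass(frozen=True)
class SinusoidSpec:
    """One sinusoidal component: amp * damping**k * sin(2*pi*f*k/fps + phase)."""

    frequency: float  # Hz
    amplitude: float  # mm
    phase: float = 0.0  # radians
    damping: float = 1.0  # per-frame decay factor in (0, 1]

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidInputError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0 < self.damping <= 1:
            raise InvalidInputError(f"damping must be in (0, 1], got {self.damping}")


def planar_rotation(theta: float) -> np.ndarray:
    """2x2 rotation matrix by angle theta (unit-modulus eigenvalues e^{+-i theta})."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def linear_system_series(
    A: np.ndarray, x0: np.ndarray, n: int, fps: float = 50.0
) -> MotionSequence:
    """Trajectory of the linear system x_k = A^{k-1} x0, k = 1..n."""
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidInputError(f"A must be square, got shape {A.shape}")
    if A.shape[0] != x0.size:
        raise InvalidInputError(f"x0 length {x0.size} does not match A shape {A.shape}")
    if n < 2:
        raise InvalidInputError(f"need n >= 2 frames, got {n}")
    frames = np.empty((n, x0.size))
    x = x0.copy()
    for k in range(n):
        frames[k] = x
        x = A @ x
    return MotionSequence(frames, fps=fps)


def sinusoid_series(
    m: int,
    specs: list[list[SinusoidSpec]],
    fps: float = 50.0,
    n: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MotionSequence:
    """Multi-channel sum-of-sinusoids series with i.i.d. Gaussian noise.

    ``specs[c]`` lists the components of channel c; frame index k runs from
    0, so the first frame realises the bare phases.  Deterministic given
    ``seed``.
    """
    if len(specs) != m:
        raise InvalidInputError(f"got specs for {len(specs)} channels, expected m={m}")
    for c, chan in enumerate(specs):
        for s in chan:
            if s.frequency >= fps / 2:
                raise InvalidInputError(
                    f"channel {c}: frequency {s.frequency} Hz is at or above "
                    f"the Nyquist limit {fps / 2} Hz"
                )
    k = np.arange(n)
    values = np.zeros((n, m))
    for c, chan in enumerate(specs):
        for s in chan:
            values[:, c] += (
                s.amplitude * s.damping**k * np.sin(2 * np.pi * s.frequency * k / fps + s.phase)
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, noise_sd, size=values.shape)
    return MotionSequence(values, fps=fps)


#: Default incommensurate frequency set (Hz) for quasi-periodic test signals.
INCOMMENSURATE_FREQS = (1.0, np.sqrt(2.0), np.sqrt(3.0), np.sqrt(5.0), np.sqrt(7.0))


def quasi_periodic_scalar(
    n: int,
    fps: float = 50.0,
    q: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 50.0,
) -> MotionSequence:
    """Scalar sum of q incommensurate sinusoids (2q complex exponentials).

    The standard hard case for plain DMD on a single observable: the signal
    needs a delay embedding of at least 2q-1 delays before a linear
    one-step model can represent it.
    """
    if not 1 <= q <= len(INCOMMENSURATE_FREQS):
        raise InvalidInputError(f"q must be in [1, {len(INCOMMENSURATE_FREQS)}], got {q}")
    specs = [
        [
            SinusoidSpec(
                frequency=INCOMMENSURATE_FREQS[i],
                amplitude=amplitude / (i + 1),
                phase=0.4 * (i + 1),
            )
            for i in range(q)
        ]
    ]
    return sinusoid_series(1, specs, fps=fps, n=n, noise_sd=noise_sd, seed=seed)


# 17-joint skeleton: root plus spine chain, two arms, two legs.
SKELETON_JOINTS = (
    "root",
    "spine",
    "thorax",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_hand",
    "right_shoulder",
    "right_elbow",
    "right_hand",
    "left_hip",
    "left_knee",
    "left_foot",
    "right_hip",
    "right_knee",
    "right_foot",
)

# Millimetre-scale oscillation amplitude per joint (hands/feet swing the most).
_JOINT_AMP = {
    "spine": 25.0,
    "thorax": 30.0,
    "neck": 20.0,
    "head": 15.0,
    "left_shoulder": 40.0,
    "left_elbow": 120.0,
    "left_hand": 220.0,
    "right_shoulder": 40.0,
    "right_elbow": 120.0,
    "right_hand": 220.0,
    "left_hip": 40.0,
    "left_knee": 150.0,
    "left_foot": 280.0,
    "right_hip": 40.0,
    "right_knee": 150.0,
    "right_foot": 280.0,
}

# Static anatomical offsets (x forward, y lateral, z up), mm.
_JOINT_OFFSET = {
    "root": (0.0, 0.0, 900.0),
    "spine": (0.0, 0.0, 1050.0),
    "thorax": (0.0, 0.0, 1250.0),
    "neck": (0.0, 0.0, 1400.0),
    "head": (0.0, 0.0, 1600.0),
    "left_shoulder": (0.0, 180.0, 1350.0),
    "left_elbow": (0.0, 220.0, 1100.0),
    "left_hand": (0.0, 240.0, 850.0),
    "right_shoulder": (0.0, -180.0, 1350.0),
    "right_elbow": (0.0, -220.0, 1100.0),
    "right_hand": (0.0, -240.0, 850.0),
    "left_hip": (0.0, 100.0, 880.0),
    "left_knee": (0.0, 110.0, 480.0),
    "left_foot": (0.0, 120.0, 80.0),
    "right_hip": (0.0, -100.0, 880.0),
    "right_knee": (0.0, -110.0, 480.0),
    "right_foot": (0.0, -120.0, 80.0),
}

# Relative strength of the fundamental and its first two harmonics.  The
# even harmonic is kept weak so that a half-cycle time shift (the
# left/right gait offset) yields near-perfect anticorrelation.
_HARMONIC_RATIOS = (1.0, 0.2, 0.3)

# Per-axis amplitude scaling and phase offsets (limbs swing mostly forward).
_AXIS_SCALE = (1.0, 0.35, 0.6)
_AXIS_PHASE = (0.0, 0.9, 2.1)


def synthetic_skeleton(
    n: int,
    fps: float = 50.0,
    gait_freq: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MotionSequence:
    """Walking-like 17-marker (51-channel) trajectory at mm scale.

    Limb channels oscillate at ``gait_freq`` and its first two harmonics
    around anatomical offsets; right-side joints are shifted by half a gait
    cycle relative to the left side, so paired left/right channels are
    strongly anticorrelated.  The root translates forward along x as a
    very-low-frequency oscillation (period far beyond any clip length, so
    it is linear drift for all practical purposes) and bounces gently at
    the gait frequency.  Noise-free, each channel is a sum of at most 7
    complex exponentials (a constant plus three damped-free harmonic
    pairs), which makes the exact low-rank structure of the whole series
    known by construction.

    ``n >= 150`` is recommended when feeding the evaluation protocol.
    """
    if gait_freq * 3 >= fps / 2:
        raise InvalidInputError(
            f"third harmonic of gait_freq={gait_freq} Hz exceeds Nyquist at fps={fps}"
        )
    k = np.arange(n)
    t = k / fps
    labels: list[str] = []
    columns: list[np.ndarray] = []

    drift_freq = 0.05  # Hz; quarter period 5 s >> clip length
    drift_amp = 2000.0  # mm; forward speed ~ 2*pi*0.05*2000 ~ 0.6 m/s

    for joint in SKELETON_JOINTS:
        off = _JOINT_OFFSET[joint]
        side_phase = np.pi if joint.startswith("right") else 0.0
        # Distinct base phase per joint so channels are not collinear;
        # left/right partners share it so the half-cycle shift relates them.
        base_name = joint.removeprefix("left_").removeprefix("right_")
        joint_phase = 0.7 * sorted({j.removeprefix("left_").removeprefix("right_") for j in SKELETON_JOINTS}).index(base_name)
        for axis_i, axis in enumerate("xyz"):
            labels.append(f"{joint}_{axis}")
            if joint == "root":
                if axis == "x":  # forward travel: locally linear drift
                    col = off[0] + drift_amp * np.sin(2 * np.pi * drift_freq * t)
                elif axis == "y":  # lateral sway at the gait frequency
                    col = off[1] + 25.0 * np.sin(2 * np.pi * gait_freq * t)
                else:  # vertical bounce, twice per stride
                    col = off[2] + 15.0 * np.sin(2 * np.pi * 2 * gait_freq * t + 0.5)
                columns.append(col)
                continue
            amp = _JOINT_AMP[joint] * _AXIS_SCALE[axis_i]
            col = np.full(n, off[axis_i], dtype=float)
            for h, ratio in enumerate(_HARMONIC_RATIOS, start=1):
                # A half-cycle time shift between body sides multiplies the
                # phase of harmonic h by h.
                phase = joint_phase + _AXIS_PHASE[axis_i] + h * side_phase
                col += amp * ratio * np.sin(2 * np.pi * h * gait_freq * t + phase)
            columns.append(col)

    values = np.column_stack(columns)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return MotionSequence(values, fps=fps, channel_labels=labels, units="mm")


def demo_corpus(
    n: int = 450, noise_sd: float = 1.0, seed: int = 0, fps: float = 50.0
) -> dict[str, MotionSequence]:
    """A three-class labelled corpus for protocol experiments.

    Two walking-like skeleton classes at different cadences plus one
    3-channel quasi-periodic oscillation class, each ``n`` frames with
    ``noise_sd`` mm of Gaussian measurement noise.  The default length
    yields three non-overlapping 150-frame sub-sequences per class.
    """
    specs = [
        [
            SinusoidSpec(f, 60.0 / (i + 1), 0.3 * i + 0.2 * c)
            for i, f in enumerate(INCOMMENSURATE_FREQS[:4])
        ]
        for c in range(3)
    ]
    return {
        "walk": synthetic_skeleton(n, fps=fps, gait_freq=1.0, noise_sd=noise_sd, seed=seed + 1),
        "march": synthetic_skeleton(n, fps=fps, gait_freq=0.7, noise_sd=noise_sd, seed=seed + 2),
        "sway": sinusoid_series(3, specs, fps=fps, n=n, noise_sd=noise_sd, seed=seed + 3),
    }


def partial_observation(series: MotionSequence, channel_indices: list[int]) -> MotionSequence:
    """Project the series onto a subset of channels (labels preserved).

    Models observing only a low-dimensional projection of the full state —
    the situation in which delay embedding earns its keep.
    """
    return series.select_channels(list(channel_indices))
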