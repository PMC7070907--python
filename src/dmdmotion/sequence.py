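"""Multivariate motion time series container.

A :class:`MotionSequence` stores a trajectory as a frames-by-observables
matrix together with its sampling rate, per-channel labels and physical
units.  Rows are time (frame 1 first); the numerical core of the package
works with the transposed, columns-are-time convention internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["MotionSequence"]


@dataclass
class MotionSequence:
    """A frames x observables trajectory.

    Parameters
    ----------
    values : ndarray of shape (n_frames, m_observables)
        Channel values per frame.  Millimetres for marker positions,
        mm/s^2 for simulated accelerations.
    fps : float
        Sampling rate in frames per second.
    channel_labels : list of str
        One label per observable, conventionally ``"<joint>_<axis>"``.
    units : str
        Physical unit of ``values`` (``"mm"`` or ``"mm/s^2"``).
    """

    values: np.ndarray
    fps: float = 50.0
    channel_labels: list[str] = field(default_factory=list)
    units: str = "mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(
                f"values must be 2-D (frames x observables), got ndim={self.values.ndim}"
            )
        n, m = self.values.shape
        if n < 2:
            raise InvalidInputError(f"a motion sequence needs at least 2 frames, got {n}")
        if m < 1:
            raise InvalidInputError("a motion sequence needs at least 1 observable")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("motion values must all be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(m)]
        if len(self.channel_labels) != m:
            raise InvalidInputError(
                f"got {len(self.channel_labels)} labels for {m} observables"
            )
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        """Length of the clip in seconds."""
        return self.n_frames / self.fps

    def head(self, n_frames: int) -> "MotionSequence":
        """First ``n_frames`` frames as a new sequence."""
        if not 2 <= n_frames <= self.n_frames:
            raise InvalidInputError(
                f"head length must be in [2, {self.n_frames}], got {n_frames}"
            )
        return MotionSequence(
            self.values[:n_frames].copy(), self.fps, list(self.channel_labels), self.units
        )

    def select_channels(self, indices: list[int]) -> "MotionSequence":
        """Sub-series of the given channels, labels preserved."""
        m = self.n_channels
        for i in indices:
            if not -m <= i < m:
                raise InvalidInputError(f"channel index {i} out of range for m={m}")
        return MotionSequence(
            self.values[:, indices].copy(),
            self.fps,
            [self.channel_labels[i] for i in indices],
            self.units,
        )
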