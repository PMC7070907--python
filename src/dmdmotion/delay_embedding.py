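"""Delay-coordinate (Hankel) embedding and delay-augmented DMD (DMDd).

A partially observed system rarely exposes enough state in a single frame
for a linear one-step model to capture its dynamics — a scalar sample of an
oscillation, for instance, carries no phase information.  Takens-style
delay embedding fixes this by stacking d+1 consecutive frames into one
augmented state vector:

    z_j = (x_j; x_{j+1}; ...; x_{j+d})        j = 1, ..., n-d

so the augmented matrix has (d+1)*m rows and n-d columns.  Exact DMD
applied to this matrix ("DMDd") sees a richer, higher-rank state and can
both reconstruct quasi-periodic signals almost perfectly and extrapolate
them for short horizons.

Forecasting advances the *augmented* state with eigenvalue powers and then
reads a base frame out of the stacked blocks; it never feeds predictions
back into a new embedding, so there is no error feedback loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import dmd_core
from .dmd_core import DEFAULT_EIG_TOL, DEFAULT_SVD_TOL, DMDModel
from .errors import InvalidDelayError, InvalidInputError
from .sequence import MotionSequence

__all__ = [
    "AugmentedSeries",
    "DMDdFit",
    "delay_embed",
    "dmdd_fit",
    "dmdd_forecast",
    "dmdd_reconstruct",
    "dmdd_reconstruct_array",
    "admissible_delays",
]

logger = logging.getLogger(__name__)

READOUT_POLICIES = ("bottom_block", "average_blocks")


@dataclass
class AugmentedSeries:
    """The delay-stacked matrix plus bookkeeping.

    ``stacked`` is (d+1)*m x (n-d), columns are augmented time steps; block
    row b (1-based, m rows each) of column j holds base frame x_{j+b-1}, so
    the bottom block of column j is the newest frame, x_{j+d}.
    """

    stacked: np.ndarray
    d: int
    m: int
    n: int

    def __post_init__(self) -> None:
        expect = ((self.d + 1) * self.m, self.n - self.d)
        if self.stacked.shape != expect:
            raise InvalidInputError(
                f"stacked matrix has shape {self.stacked.shape}, expected {expect}"
            )

    def block(self, b: int) -> np.ndarray:
        """Block row b (1-based) as an m x (n-d) matrix."""
        if not 1 <= b <= self.d + 1:
            raise InvalidInputError(f"block index must be in [1, {self.d + 1}], got {b}")
        return self.stacked[(b - 1) * self.m : b * self.m, :]


@dataclass
class DMDdFit:
    """Exact DMD fitted on a delay-embedded series.

    Keeps the base series and embedding geometry so forecasts and
    reconstructions can be mapped back to base frames.
    """

    model: DMDModel
    series: MotionSequence
    d: int
    readout_policy: str = "bottom_block"

    def __post_init__(self) -> None:
        if self.readout_policy not in READOUT_POLICIES:
            raise InvalidInputError(
                f"readout_policy must be one of {READOUT_POLICIES}, got {self.readout_policy!r}"
            )
        m, n = self.series.n_channels, self.series.n_frames
        if self.model.m != (self.d + 1) * m or self.model.n != n - self.d:
            raise InvalidInputError("model dimensions do not match the embedding")

    @property
    def m_base(self) -> int:
        return self.series.n_channels

    @property
    def n_base(self) -> int:
        return self.series.n_frames


def admissible_delays(n: int) -> tuple[int, int]:
    """Admissible delay interval [0, n-3] for an n-frame series.

    d = n-3 leaves a 3-column window, the smallest for which the embedded
    snapshot pair still has two columns; d = 0 is the identity embedding
    (plain DMD).
    """
    return 0, n - 3


def delay_embed(series: MotionSequence, d: int) -> AugmentedSeries:
    """Stack d+1 shifted copies of the series into the augmented matrix.

    A sliding window of n-d frames is copied at offsets 0..d and the copies
    are stacked one above the other, giving (d+1)*m rows and n-d columns.
    ``d=0`` returns the original (transposed) matrix.
    """
    n, m = series.n_frames, series.n_channels
    lo, hi = admissible_delays(n)
    if not lo <= d <= hi:
        raise InvalidDelayError(
            f"delay d={d} inadmissible for n={n} frames; admissible interval is [{lo}, {hi}]"
        )
    data = series.values.T  # m x n
    cols = n - d
    stacked = np.empty(((d + 1) * m, cols))
    for b in range(d + 1):
        stacked[b * m : (b + 1) * m, :] = data[:, b : b + cols]
    return AugmentedSeries(stacked=stacked, d=d, m=m, n=n)


def dmdd_fit(
    series: MotionSequence,
    d: int,
    svd_tol: float = DEFAULT_SVD_TOL,
    eig_tol: float = DEFAULT_EIG_TOL,
    readout_policy: str = "bottom_block",
) -> DMDdFit:
    """Delay-embed the series and fit exact DMD on the augmented matrix."""
    aug = delay_embed(series, d)
    pair = dmd_core.snapshot_pair_from_matrix(aug.stacked)
    model = dmd_core.exact_dmd(pair, svd_tol=svd_tol, eig_tol=eig_tol)
    logger.debug(
        "dmdd_fit: d=%d base m=%d n=%d -> aug %dx%d rank_r=%d r0=%d",
        d, aug.m, aug.n, *aug.stacked.shape, model.rank_r, model.r0,
    )
    return DMDdFit(model=model, series=series, d=d, readout_policy=readout_policy)


def _augmented_state(fit: DMDdFit, k: int) -> np.ndarray:
    """Real augmented column z_hat_k (1-based augmented index, k >= 2)."""
    return dmd_core.dmd_reconstruct(fit.model, k)


def dmdd_forecast(fit: DMDdFit, horizon: int) -> np.ndarray:
    """Forecast base frames x_hat_{n+1..n+horizon}, shape (horizon, m_base).

    The augmented state is advanced to columns (n-d)+1 .. (n-d)+horizon via
    eigenvalue powers.  Under the default ``bottom_block`` policy the newest
    block (last m rows) of forecast column (n-d)+h is frame n+h.  Under
    ``average_blocks`` every forecast column whose window covers frame n+h
    contributes its estimate and the estimates are averaged.
    """
    if horizon < 1:
        raise InvalidInputError(f"horizon must be >= 1, got {horizon}")
    d, m, n = fit.d, fit.m_base, fit.n_base
    n_aug = n - d
    # Forecast columns of the augmented series, shape (horizon, (d+1)*m).
    aug_cols = np.vstack([_augmented_state(fit, n_aug + h) for h in range(1, horizon + 1)])

    out = np.empty((horizon, m))
    if fit.readout_policy == "bottom_block":
        out[:] = aug_cols[:, d * m :]
        return out
    # average_blocks: frame n+h appears in forecast column c = (n-d)+h' at
    # block b = (n+h) - (c-1) - d + d = n+h-c+1 whenever 1 <= b <= d+1.
    for h in range(1, horizon + 1):
        frame = n + h
        estimates = []
        for hp in range(1, horizon + 1):
            c = n_aug + hp
            b = frame - c + 1  # 1-based block index
            if 1 <= b <= d + 1:
                est = aug_cols[hp - 1, (b - 1) * m : b * m]
                estimates.append(est)
        out[h - 1] = np.mean(estimates, axis=0)
    return out


def dmdd_reconstruct_array(fit: DMDdFit) -> np.ndarray:
    """Reconstructed base frames 2..n as a raw (n-1) x m array.

    Unlike :func:`dmdd_reconstruct` this never validates finiteness, so
    overflowing reconstructions of unstable fits can still be scored
    (as +inf error) by the metrics layer.
    """
    d, m, n = fit.d, fit.m_base, fit.n_base
    n_aug = n - d
    # Reconstruct augmented columns 2..n_aug once.
    aug = {k: _augmented_state(fit, k) for k in range(2, n_aug + 1)}

    out = np.empty((n - 1, m))
    for frame in range(2, n + 1):
        if frame >= d + 2:
            col, b = frame - d, d + 1  # bottom block
        else:
            col, b = 2, frame - 1  # deepest block of column 2 holding this frame
        out[frame - 2] = aug[col][(b - 1) * m : b * m]
    return out


def dmdd_reconstruct(fit: DMDdFit) -> MotionSequence:
    """Reconstruct base frames 2..n from the fitted augmented columns.

    Returns an (n-1) x m sequence whose row i is the reconstruction of base
    frame i+2.  Frame 1 is not reconstructible (amplitudes are fitted to the
    second augmented column).  Frame j for j >= d+2 is read from the bottom
    block of augmented column j-d; the early frames 2..d+1 are read from the
    deepest available block of augmented column 2.
    """
    out = dmdd_reconstruct_array(fit)
    return MotionSequence(out, fit.series.fps, list(fit.series.channel_labels), fit.series.units)
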