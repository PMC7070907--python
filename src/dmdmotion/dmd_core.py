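"""Exact dynamic mode decomposition (DMD) of snapshot sequences.

Given snapshots x_1, ..., x_n in R^m the method finds complex eigenvalues
lambda_j (per-step multipliers), spatial modes theta_j and amplitudes a_j
such that

    x_k  ~=  sum_j  theta_j * lambda_j**(k-1) * a_j,      k = 2, ..., n,

i.e. a best linear-dynamics explanation of the data.  The eigenvalues are
those of the least-squares propagator A = Y X^+ mapping each snapshot to
its successor, but they are computed through the reduced SVD of X so that
only rank(X) dimensions are ever touched.  Amplitudes are fitted to the
second snapshot x_2 (the first snapshot is deliberately not reconstructed).

The same model extrapolates: x_hat_{n+h} = Theta Lambda**(n+h-1) a gives a
forecast h frames past the end of the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSpectrumError, InvalidInputError
from .sequence import MotionSequence

__all__ = [
    "SnapshotPair",
    "DMDModel",
    "build_snapshot_pair",
    "exact_dmd",
    "dmd_reconstruct",
    "dmd_forecast",
    "full_operator_oracle",
]

logger = logging.getLogger(__name__)

DEFAULT_SVD_TOL = 1e-12  # relative to the largest singular value
DEFAULT_EIG_TOL = 1e-12  # absolute eigenvalue modulus


@dataclass
class SnapshotPair:
    """Time-shifted snapshot matrices: column j of Y is column j+1 of X.

    Both are m x (n-1), columns are time.
    """

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise InvalidInputError(
                f"X and Y must share a shape, got {self.X.shape} vs {self.Y.shape}"
            )
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise InvalidInputError("snapshot matrices must be m x (n-1) with n >= 2")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        """Number of snapshots in the underlying series."""
        return self.X.shape[1] + 1


@dataclass
class DMDModel:
    """A fitted exact-DMD decomposition.

    ``eigenvalues`` (length r0), ``modes`` (m x r0) and ``amplitudes``
    (length r0) parameterise the rank-r0 linear model; ``rank_r`` is the
    numerical rank of X, ``r0 <= rank_r`` the number of eigenvalues kept
    above ``eig_tol``.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    amplitudes: np.ndarray
    rank_r: int
    r0: int
    m: int
    n: int
    svd_tol: float = DEFAULT_SVD_TOL
    eig_tol: float = DEFAULT_EIG_TOL
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=complex)
        self.modes = np.asarray(self.modes, dtype=complex)
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if not (self.r0 == len(self.eigenvalues) == len(self.amplitudes) == self.modes.shape[1]):
            raise InvalidInputError("r0, eigenvalues, amplitudes and mode columns disagree")
        if self.r0 > self.rank_r:
            raise InvalidInputError(f"r0={self.r0} exceeds rank_r={self.rank_r}")

    # -- evaluation ---------------------------------------------------------

    def frame(self, k: int) -> np.ndarray:
        """Complex model state Theta Lambda**(k-1) a at 1-based frame k."""
        with np.errstate(over="ignore", invalid="ignore"):
            powers = self.eigenvalues ** (k - 1)
            return self.modes @ (powers * self.amplitudes)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def c2pair(z: complex) -> list[float]:
            return [float(z.real), float(z.imag)]

        payload = {
            "eigenvalues": [c2pair(z) for z in self.eigenvalues],
            "amplitudes": [c2pair(z) for z in self.amplitudes],
            "modes": [[c2pair(z) for z in row] for row in self.modes],
            "m": self.m,
            "n": self.n,
            "rank_r": self.rank_r,
            "r0": self.r0,
            "svd_tol": self.svd_tol,
            "eig_tol": self.eig_tol,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "DMDModel":
        obj = json.loads(text)

        def pair2c(p):
            return complex(p[0], p[1])

        return cls(
            eigenvalues=np.array([pair2c(p) for p in obj["eigenvalues"]]),
            modes=np.array([[pair2c(p) for p in row] for row in obj["modes"]]),
            amplitudes=np.array([pair2c(p) for p in obj["amplitudes"]]),
            rank_r=obj["rank_r"],
            r0=obj["r0"],
            m=obj["m"],
            n=obj["n"],
            svd_tol=obj["svd_tol"],
            eig_tol=obj["eig_tol"],
        )


def build_snapshot_pair(series: MotionSequence) -> SnapshotPair:
    """Snapshot matrices X = [x_1 ... x_{n-1}], Y = [x_2 ... x_n].

    The sequence stores rows-as-time; the pair stores columns-as-time.
    """
    data = series.values.T  # m x n
    if data.shape[1] < 2:
        raise InvalidInputError("need at least 2 frames to form a snapshot pair")
    return SnapshotPair(X=data[:, :-1], Y=data[:, 1:])


def snapshot_pair_from_matrix(data: np.ndarray) -> SnapshotPair:
    """Snapshot pair from an m x n columns-are-time matrix."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise InvalidInputError("need an m x n matrix with n >= 2 columns")
    return SnapshotPair(X=data[:, :-1], Y=data[:, 1:])


def exact_dmd(
    pair: SnapshotPair,
    svd_tol: float = DEFAULT_SVD_TOL,
    eig_tol: float = DEFAULT_EIG_TOL,
) -> DMDModel:
    """Fit an exact-DMD model to a snapshot pair.

    Steps: reduced SVD X = U S V*; low-dimensional propagator
    S_hat = U* Y V S^-1; its eigenpairs (lambda_i, v_i); modes
    theta_i = (1/lambda_i) Y V S^-1 v_i for eigenvalues with modulus above
    ``eig_tol``; amplitudes a = Lambda^-1 Theta^+ x_2, fitted so that the
    model reproduces the second snapshot.

    Raises
    ------
    InvalidInputError
        If X is identically zero.
    DegenerateSpectrumError
        If every eigenvalue modulus falls below ``eig_tol``.
    """
    X, Y = pair.X, pair.Y
    if not np.any(X):
        raise InvalidInputError("snapshot matrix X is identically zero")

    U, sv, Vh = np.linalg.svd(X, full_matrices=False)
    rank_r = int(np.count_nonzero(sv > svd_tol * sv[0]))
    U = U[:, :rank_r]
    sv = sv[:rank_r]
    Vh = Vh[:rank_r, :]

    # Y V S^-1 appears in both the reduced operator and the modes.
    YVSinv = Y @ Vh.conj().T / sv  # m x r
    S_hat = U.conj().T @ YVSinv  # r x r
    lam, W = np.linalg.eig(S_hat)

    keep = np.abs(lam) > eig_tol
    if not np.any(keep):
        raise DegenerateSpectrumError(
            f"all {len(lam)} eigenvalues have modulus <= eig_tol={eig_tol}"
        )
    lam = lam[keep]
    W = W[:, keep]
    r0 = int(lam.size)

    modes = (YVSinv @ W) / lam  # theta_i = (1/lambda_i) Y V S^-1 v_i
    x2 = Y[:, 0]
    amplitudes = (np.linalg.pinv(modes, rcond=svd_tol) @ x2) / lam

    model = DMDModel(
        eigenvalues=lam,
        modes=modes,
        amplitudes=amplitudes,
        rank_r=rank_r,
        r0=r0,
        m=pair.m,
        n=pair.n,
        svd_tol=svd_tol,
        eig_tol=eig_tol,
        diagnostics={"singular_values": sv.tolist()},
    )
    logger.debug("exact_dmd: m=%d n=%d rank_r=%d r0=%d", pair.m, pair.n, rank_r, r0)
    return model


def _real_with_residue(model: DMDModel, z: np.ndarray) -> np.ndarray:
    """Real part of a model state; track the worst imaginary residue seen."""
    re = np.real(z)
    with np.errstate(invalid="ignore"):
        scale = np.max(np.abs(z)) if z.size else 0.0
        residue = float(np.max(np.abs(np.imag(z))) / scale) if scale > 0 else 0.0
    prev = model.diagnostics.get("max_imag_residue", 0.0)
    if np.isfinite(residue) and residue > prev:
        model.diagnostics["max_imag_residue"] = residue
        if residue > 1e-6:
            logger.debug("imaginary residue %.3e in real readout", residue)
    return re


def dmd_reconstruct(model: DMDModel, k: int) -> np.ndarray:
    """Reconstructed frame x_hat_k (1-based), for k >= 2.

    Returns the real part of Theta Lambda**(k-1) a; the relative imaginary
    residue is recorded in ``model.diagnostics['max_imag_residue']``.  k = 1
    is not reconstructible because the amplitudes are fitted to x_2.
    """
    if k < 2:
        raise InvalidInputError(f"reconstruction is defined for k >= 2, got k={k}")
    return _real_with_residue(model, model.frame(k))


def dmd_forecast(model: DMDModel, horizon: int) -> np.ndarray:
    """Forecast matrix of shape (horizon, m): rows are x_hat_{n+1..n+horizon}.

    Forecasts of unstable models may overflow; non-finite values propagate
    rather than raising, so downstream error tables can report them.
    """
    if horizon < 1:
        raise InvalidInputError(f"horizon must be >= 1, got {horizon}")
    out = np.empty((horizon, model.m))
    for h in range(1, horizon + 1):
        out[h - 1] = _real_with_residue(model, model.frame(model.n + h))
    return out


def full_operator_oracle(pair: SnapshotPair, eig_tol: float = DEFAULT_EIG_TOL) -> np.ndarray:
    """Nonzero eigenvalues of the full least-squares propagator A = Y X^+.

    Brute-force reference for the SVD-projected spectrum of
    :func:`exact_dmd`: builds the m x m operator explicitly and keeps
    eigenvalues with modulus above ``eig_tol``.  Intended for testing, not
    for large m.
    """
    A = pair.Y @ np.linalg.pinv(pair.X)
    lam = np.linalg.eigvals(A)
    return lam[np.abs(lam) > eig_tol]


def sorted_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """Canonical eigenvalue ordering: by modulus, then phase."""
    lam = np.asarray(lam, dtype=complex)
    order = np.lexsort((np.angle(lam), np.abs(lam)))
    return lam[order]
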