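"""Error measures between ground-truth and predicted pose sequences.

Two measures are provided.  The mean squared error over a batch of K
sequences, each p frames of m observables,

    L(GT, P) = (1/K) sum_k (1/(m p)) sum_{i,j} (GT_ijk - P_ijk)^2,

in mm^2 for positional data; and a Kullback-Leibler divergence between the
pooled value distributions of ground truth and prediction.  The KL variant
histograms *all* coordinate values of the batch (ground truth and
prediction share a common bin range), smooths both histograms with a small
epsilon, renormalises, and returns KL(GT || P).  This pooled-histogram
construction is one of several plausible readings of "KL divergence between
pose sequences" used in the motion-anticipation literature; see the methods
note for a discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["PredictionBatch", "pose_mse", "pose_kl"]


@dataclass
class PredictionBatch:
    """K ground-truth/prediction pairs of matching p x m shape.

    Ground truth must be finite; predictions may contain non-finite values
    (forecasts of unstable models), which score +inf error.
    """

    ground_truth: list[np.ndarray]
    predictions: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.ground_truth) != len(self.predictions):
            raise InvalidInputError(
                f"{len(self.ground_truth)} ground-truth vs "
                f"{len(self.predictions)} prediction sequences"
            )
        if not self.ground_truth:
            raise InvalidInputError("empty prediction batch")
        self.ground_truth = [np.atleast_2d(np.asarray(g, dtype=float)) for g in self.ground_truth]
        self.predictions = [np.atleast_2d(np.asarray(p, dtype=float)) for p in self.predictions]
        for i, (g, p) in enumerate(zip(self.ground_truth, self.predictions)):
            if g.shape != p.shape:
                raise InvalidInputError(
                    f"sequence {i}: ground truth shape {g.shape} != prediction shape {p.shape}"
                )
            if not np.all(np.isfinite(g)):
                raise InvalidInputError(f"sequence {i}: ground truth contains non-finite values")

    @property
    def K(self) -> int:
        return len(self.ground_truth)


def pose_mse(batch: PredictionBatch) -> float:
    """Batch MSE: inner mean over the m*p entries, outer mean over K.

    Non-finite prediction entries make the whole batch score +inf.
    """
    per_seq = []
    for g, p in zip(batch.ground_truth, batch.predictions):
        if not np.all(np.isfinite(p)):
            per_seq.append(np.inf)
            continue
        with np.errstate(over="ignore"):
            per_seq.append(float(np.mean((g - p) ** 2)))
    return float(np.mean(per_seq))


def pose_kl(batch: PredictionBatch, bins: int = 100, eps: float = 1e-10) -> float:
    """KL(GT || P) between pooled-coordinate-value histograms.

    All ground-truth values form distribution Q, all predicted values form
    distribution R, binned over their joint min/max range; eps is added to
    every bin before renormalising so the divergence stays finite on
    disjoint supports.  Always >= 0; 0 for identical histograms.
    """
    if bins < 2:
        raise InvalidInputError(f"need at least 2 bins, got {bins}")
    if eps <= 0:
        raise InvalidInputError(f"eps must be positive, got {eps}")
    gt = np.concatenate([g.ravel() for g in batch.ground_truth])
    pr = np.concatenate([p.ravel() for p in batch.predictions])
    if not np.all(np.isfinite(pr)):
        return np.inf
    lo = min(gt.min(), pr.min())
    hi = max(gt.max(), pr.max())
    if lo == hi:  # all values equal: identical single-bin histograms
        return 0.0
    q, edges = np.histogram(gt, bins=bins, range=(lo, hi))
    r, _ = np.histogram(pr, bins=bins, range=(lo, hi))
    q = q.astype(float) + eps
    r = r.astype(float) + eps
    q /= q.sum()
    r /= r.sum()
    return float(np.sum(q * np.log(q / r)))
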