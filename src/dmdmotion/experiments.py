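"""The evaluation protocol: sub-sequencing, marker subsets, simulated
accelerometers, anticipation runs and delay sweeps.

The protocol mirrors how short-term pose anticipation is benchmarked on
motion-capture corpora: each labelled action sequence is divided into
sub-sequences of fixed length (100 or 150 frames at 50 Hz); the first
``input_len`` frames of each sub-sequence are the model input; forecasts
over horizons of 5, 10 and 20 frames (0.1/0.2/0.4 s) are scored against
the held-out continuation with the batch MSE or a KL divergence, averaged
over the K sub-sequences of each class.  Delay sweeps repeat this (or the
reconstruction analogue) over a list of delay counts, producing the
error-versus-delay tables in machine form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .delay_embedding import dmdd_fit, dmdd_forecast, dmdd_reconstruct_array
from .errors import ConfigError, InvalidInputError
from .io import read_motion_csv, write_motion_csv  # noqa: F401  (module surface)
from .metrics import PredictionBatch, pose_kl, pose_mse
from .sequence import MotionSequence

__all__ = [
    "ExperimentConfig",
    "ErrorTable",
    "split_subsequences",
    "select_markers",
    "simulate_accelerations",
    "run_anticipation",
    "run_delay_sweep",
    "read_motion_csv",
    "write_motion_csv",
]

logger = logging.getLogger(__name__)

MARKER_SUBSETS = ("M1", "M5", "M17")
#: The sparse subset: root plus the four end effectors.
M5_JOINTS = ("root", "left_hand", "right_hand", "left_foot", "right_foot")


@dataclass
class ExperimentConfig:
    """Parameters of one protocol run.

    ``delays`` is a single delay count for anticipation runs and a list for
    sweeps.  ``input_len + max(horizons)`` must fit inside ``subseq_len``,
    and every delay must satisfy ``d <= input_len - 3`` so the embedded
    window still yields a snapshot pair.
    """

    subseq_len: int = 150
    input_len: int = 100
    horizons: list[int] = field(default_factory=lambda: [5, 10, 20])
    delays: int | list[int] = 20
    marker_subset: str = "M17"
    target_joint: str = "right_hand"
    accel: bool = False
    fps: float = 50.0
    metric: str = "mse"
    seed: int = 0
    stride: int | None = None  # None: non-overlapping sub-sequences
    readout: str = "bottom_block"
    svd_tol: float = 1e-12
    eig_tol: float = 1e-12
    kl_bins: int = 100
    kl_eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.metric not in ("mse", "kl"):
            raise ConfigError(f"metric must be 'mse' or 'kl', got {self.metric!r}")
        if self.marker_subset not in MARKER_SUBSETS:
            raise ConfigError(f"marker_subset must be one of {MARKER_SUBSETS}")
        if not self.horizons or any(h < 1 for h in self.horizons):
            raise ConfigError("horizons must be a non-empty list of positive frame counts")
        if self.input_len + max(self.horizons) > self.subseq_len:
            raise ConfigError(
                f"input_len ({self.input_len}) + max horizon ({max(self.horizons)}) "
                f"exceeds subseq_len ({self.subseq_len})"
            )
        for d in self.delay_list:
            if not 0 <= d <= self.input_len - 3:
                raise ConfigError(
                    f"delay {d} inadmissible for input_len={self.input_len}; "
                    f"admissible interval is [0, {self.input_len - 3}]"
                )

    @property
    def delay_list(self) -> list[int]:
        return list(self.delays) if isinstance(self.delays, (list, tuple)) else [self.delays]

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["horizons"] = list(self.horizons)
        out["delays"] = self.delay_list
        return out


@dataclass
class ErrorTable:
    """Per-class, per-delay, per-horizon error values.

    Rows are ordered class-alphabetical, then delay ascending, then horizon
    ascending, so repeated runs diff cleanly.  Reconstruction rows use
    horizon 0.
    """

    frame: pd.DataFrame
    config: dict = field(default_factory=dict)

    COLUMNS = ["class", "delay", "horizon_frames", "horizon_s", "metric", "value", "K"]

    @classmethod
    def from_records(cls, records: list[dict], config: dict | None = None) -> "ErrorTable":
        df = pd.DataFrame.from_records(records, columns=cls.COLUMNS)
        df = df.sort_values(["class", "delay", "horizon_frames"], kind="stable")
        df = df.reset_index(drop=True)
        dupes = df.duplicated(subset=["class", "delay", "horizon_frames", "metric"])
        if dupes.any():
            raise InvalidInputError("duplicate (class, delay, horizon, metric) rows")
        return cls(frame=df, config=dict(config or {}))

    def value(self, class_label: str, delay: int, horizon: int) -> float:
        sel = self.frame[
            (self.frame["class"] == class_label)
            & (self.frame["delay"] == delay)
            & (self.frame["horizon_frames"] == horizon)
        ]
        if len(sel) != 1:
            raise KeyError((class_label, delay, horizon))
        return float(sel["value"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        """Write a byte-reproducible CSV with a config echo comment."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            if self.config:
                fh.write("# config=" + json.dumps(self.config, sort_keys=True) + "\n")
            fh.write(",".join(self.COLUMNS) + "\n")
            for row in self.frame.itertuples(index=False):
                fh.write(
                    f"{row[0]},{row[1]},{row[2]},{format(row[3], '.17g')},"
                    f"{row[4]},{format(row[5], '.17g')},{row[6]}\n"
                )


def split_subsequences(series: MotionSequence, subseq_len: int, stride: int | None = None):
    """Consecutive sub-sequences of ``subseq_len`` frames.

    Non-overlapping by default (stride = subseq_len); a trailing remainder
    shorter than ``subseq_len`` is dropped.
    """
    if subseq_len < 2:
        raise InvalidInputError(f"subseq_len must be >= 2, got {subseq_len}")
    n = series.n_frames
    if n < subseq_len:
        raise InvalidInputError(
            f"series has {n} frames, shorter than subseq_len={subseq_len}: empty split"
        )
    stride = subseq_len if stride is None else stride
    if stride < 1:
        raise InvalidInputError(f"stride must be >= 1, got {stride}")
    out = []
    for start in range(0, n - subseq_len + 1, stride):
        out.append(
            MotionSequence(
                series.values[start : start + subseq_len].copy(),
                series.fps,
                list(series.channel_labels),
                series.units,
            )
        )
    return out


def _joint_channels(series: MotionSequence, joint: str) -> list[int]:
    idx = [i for i, lab in enumerate(series.channel_labels) if lab.rsplit("_", 1)[0] == joint]
    if not idx:
        raise InvalidInputError(
            f"joint {joint!r} not found among labels {series.channel_labels[:6]}..."
        )
    return idx


def select_markers(
    series: MotionSequence, subset: str, target_joint: str = "right_hand"
) -> MotionSequence:
    """Restrict to a marker subset: M1 (one joint), M5 (root + end
    effectors), or M17 (everything)."""
    if subset == "M17":
        return series
    if subset == "M1":
        return series.select_channels(_joint_channels(series, target_joint))
    if subset == "M5":
        idx: list[int] = []
        for joint in M5_JOINTS:
            idx.extend(_joint_channels(series, joint))
        return series.select_channels(idx)
    raise InvalidInputError(f"unknown marker subset {subset!r}")


def simulate_accelerations(series: MotionSequence, scheme: str = "central") -> MotionSequence:
    """Second time derivatives of the positions, emulating accelerometers.

    Central differences a_k = (x_{k+1} - 2 x_k + x_{k-1}) * fps^2 for
    frames 2..n-1 (output is two frames shorter); ``scheme='forward'`` or
    ``'backward'`` use the same stencil shifted to the interval ends for
    boundary studies.  Units become mm/s^2.
    """
    n = series.n_frames
    if n < 3:
        raise InvalidInputError(f"need at least 3 frames to differentiate twice, got {n}")
    x = series.values
    second = (x[2:] - 2 * x[1:-1] + x[:-2]) * series.fps**2
    if scheme not in ("central", "forward", "backward"):
        raise InvalidInputError(f"unknown differencing scheme {scheme!r}")
    # central/forward/backward share the stencil; they differ only in which
    # frame the value is attributed to, which the protocol never uses.
    return MotionSequence(second, series.fps, list(series.channel_labels), units="mm/s^2")


def prepare_class_data(series: MotionSequence, config: ExperimentConfig) -> MotionSequence:
    """Apply marker selection and optional accelerometer simulation."""
    out = select_markers(series, config.marker_subset, config.target_joint)
    if config.accel:
        out = simulate_accelerations(out)
    return out


def _score(config: ExperimentConfig, batch: PredictionBatch) -> float:
    if config.metric == "mse":
        return pose_mse(batch)
    return pose_kl(batch, bins=config.kl_bins, eps=config.kl_eps)


def _forecast_errors(
    subs: list[MotionSequence], config: ExperimentConfig, d: int
) -> dict[int, float]:
    """Per-horizon class error for one delay count."""
    max_h = max(config.horizons)
    gts: dict[int, list[np.ndarray]] = {h: [] for h in config.horizons}
    preds: dict[int, list[np.ndarray]] = {h: [] for h in config.horizons}
    for sub in subs:
        inp = sub.head(config.input_len)
        fit = dmdd_fit(
            inp, d, svd_tol=config.svd_tol, eig_tol=config.eig_tol,
            readout_policy=config.readout,
        )
        forecast = dmdd_forecast(fit, max_h)
        for h in config.horizons:
            gts[h].append(sub.values[config.input_len : config.input_len + h])
            preds[h].append(forecast[:h])
    return {
        h: _score(config, PredictionBatch(gts[h], preds[h])) for h in config.horizons
    }


def run_anticipation(data: dict[str, MotionSequence], config: ExperimentConfig) -> ErrorTable:
    """Anticipation protocol over a labelled corpus.

    For every class: prepare channels, split into sub-sequences, fit a
    delay-embedded model on the first ``input_len`` frames of each,
    forecast ``max(horizons)`` frames, and score each horizon prefix
    against the ground-truth continuation (outer mean over the class's K
    sub-sequences).
    """
    if isinstance(config.delays, (list, tuple)):
        if len(config.delays) != 1:
            raise ConfigError("run_anticipation expects a single delay; use run_delay_sweep")
        d = config.delays[0]
    else:
        d = config.delays
    records = []
    for label in sorted(data):
        series = prepare_class_data(data[label], config)
        subs = split_subsequences(series, config.subseq_len, config.stride)
        errs = _forecast_errors(subs, config, d)
        for h in sorted(config.horizons):
            records.append(
                {
                    "class": label,
                    "delay": d,
                    "horizon_frames": h,
                    "horizon_s": h / config.fps,
                    "metric": config.metric,
                    "value": errs[h],
                    "K": len(subs),
                }
            )
        logger.info("anticipation %s: K=%d delay=%d", label, len(subs), d)
    return ErrorTable.from_records(records, config.to_dict())


def run_delay_sweep(
    data: dict[str, MotionSequence], config: ExperimentConfig, mode: str = "reconstruction"
) -> ErrorTable:
    """Error versus delay count, per class.

    ``mode='reconstruction'`` scores the model's reproduction of its own
    input frames 2..input_len; ``mode='anticipation'`` scores the forecast
    at the largest configured horizon.  One row per (class, delay).
    """
    if mode not in ("reconstruction", "anticipation"):
        raise ConfigError(f"mode must be 'reconstruction' or 'anticipation', got {mode!r}")
    records = []
    for label in sorted(data):
        series = prepare_class_data(data[label], config)
        subs = split_subsequences(series, config.subseq_len, config.stride)
        for d in config.delay_list:
            if mode == "anticipation":
                h = max(config.horizons)
                err = _forecast_errors(subs, config, d)[h]
            else:
                h = 0
                gts, preds = [], []
                for sub in subs:
                    inp = sub.head(config.input_len)
                    fit = dmdd_fit(
                        inp, d, svd_tol=config.svd_tol, eig_tol=config.eig_tol,
                        readout_policy=config.readout,
                    )
                    preds.append(dmdd_reconstruct_array(fit))
                    gts.append(inp.values[1:])
                err = _score(config, PredictionBatch(gts, preds))
            records.append(
                {
                    "class": label,
                    "delay": d,
                    "horizon_frames": h,
                    "horizon_s": h / config.fps,
                    "metric": config.metric,
                    "value": err,
                    "K": len(subs),
                }
            )
        logger.info("sweep %s (%s): K=%d delays=%s", label, mode, len(subs), config.delay_list)
    return ErrorTable.from_records(records, config.to_dict())
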