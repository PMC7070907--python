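"""Motion CSV reading and writing.

Format: an optional metadata comment line ``# fps=50 units=mm``, then a
header ``frame,<label>,...`` and one numeric row per frame.  Values are
written with 17 significant digits so a write/read round trip is lossless
well below 1e-9.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .sequence import MotionSequence

__all__ = ["read_motion_csv", "write_motion_csv"]


def write_motion_csv(series: MotionSequence, path: str | Path) -> None:
    """Write a motion sequence with its fps/units metadata."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# fps={series.fps:g} units={series.units}\n")
        fh.write("frame," + ",".join(series.channel_labels) + "\n")
        for i, row in enumerate(series.values):
            fh.write(str(i) + "," + ",".join(format(v, ".17g") for v in row) + "\n")


def read_motion_csv(path: str | Path) -> MotionSequence:
    """Read a motion CSV written by :func:`write_motion_csv`.

    Raises :class:`ParseError` with a line number for ragged rows,
    non-numeric cells or a missing header.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    fps, units = 50.0, "mm"
    idx = 0
    if lines and lines[0].startswith("#"):
        for token in lines[0].lstrip("#").split():
            if token.startswith("fps="):
                try:
                    fps = float(token[4:])
                except ValueError as exc:
                    raise ParseError(f"{path}:1: bad fps value {token[4:]!r}") from exc
            elif token.startswith("units="):
                units = token[6:]
        idx = 1
    if idx >= len(lines) or not lines[idx].strip():
        raise ParseError(f"{path}:{idx + 1}: missing header line")
    header = [h.strip() for h in lines[idx].split(",")]
    if header[0] != "frame" or len(header) < 2:
        raise ParseError(
            f"{path}:{idx + 1}: header must start with 'frame' and name at least one channel"
        )
    labels = header[1:]
    body = "\n".join(lines[idx + 1 :])
    try:
        df = pd.read_csv(_io.StringIO(body), header=None, names=header)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    values = df[labels].to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for line_no, row in enumerate(df[labels].itertuples(index=False), start=idx + 2):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(f"{path}:{line_no}: non-numeric cell {cell!r}") from None
        raise ParseError(f"{path}: non-numeric data")
    if np.isnan(values).any():
        bad = int(np.argwhere(np.isnan(values).any(axis=1))[0][0])
        raise ParseError(f"{path}:{idx + 2 + bad}: ragged or missing cells")
    return MotionSequence(values.astype(float), fps=fps, channel_labels=labels, units=units)
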