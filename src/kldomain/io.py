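"""Reading and writing curve data.

Three text dialects:

* ``wide-csv`` — one row per curve; optional label column (first column)
  and optional header row of grid times.
* ``long-csv`` — columns ``curve_id, time, value`` plus optional ``label``;
  irregular designs, projected onto a common grid by kernel smoothing.
* ``ucr-text`` — UCR/UEA-archive style: first column is an integer class
  label, the remaining columns are values on an implicit 1..p grid
  (comma or whitespace separated).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .divergence import GridDomain
from .estimation import CurveSet, smooth_to_common_grid
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["read_curves", "write_curves"]


def _wide_grid(p: int, times: np.ndarray | None) -> GridDomain:
    if times is None:
        return GridDomain.regular(1.0, float(p + 1), p)
    if times.size != p:
        raise InvalidInputError(
            f"header declares {times.size} grid times but rows have {p} values"
        )
    step = times[-1] - times[-2] if p > 1 else 1.0
    return GridDomain(float(times[0]), float(times[-1] + step), p, times)


def _read_wide(path: Path, label_col: bool, times_header: bool):
    df = pd.read_csv(
        path, header=0 if times_header else None, float_precision="round_trip"
    )
    if label_col:
        labels = df.iloc[:, 0].astype(str).to_numpy()
        values = df.iloc[:, 1:]
    else:
        labels = None
        values = df
    try:
        matrix = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: non-numeric cell ({exc})") from exc
    p = matrix.shape[1]
    times = None
    if times_header:
        cols = values.columns
        try:
            times = np.asarray([float(c) for c in cols])
        except ValueError as exc:
            raise InvalidInputError(
                f"{path}: header is not a numeric grid ({exc})"
            ) from exc
    grid = _wide_grid(p, times)
    if labels is None:
        return CurveSet(grid=grid, values=matrix)
    return {
        lab: CurveSet(grid=grid, values=matrix[labels == lab], label=lab)
        for lab in sorted(set(labels))
    }


def _read_long(path: Path, grid: GridDomain | None, p: int, bandwidth):
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"curve_id", "time", "value"}
    if not required <= set(df.columns):
        raise InvalidInputError(
            f"{path}: long-csv needs columns {sorted(required)}, got {list(df.columns)}"
        )
    has_label = "label" in df.columns
    if grid is None:
        t = df["time"].to_numpy(dtype=float)
        grid = GridDomain.regular(float(t.min()), float(t.max()) + 1e-9, p)
    out = {}
    groups = df.groupby("label") if has_label else [("", df)]
    for lab, sub in groups:
        raw = [
            (g["time"].to_numpy(dtype=float), g["value"].to_numpy(dtype=float))
            for _, g in sub.groupby("curve_id", sort=True)
        ]
        out[str(lab)] = smooth_to_common_grid(raw, grid, bandwidth=bandwidth, label=str(lab))
    return out if has_label else out[""]


def _read_ucr(path: Path):
    rows = []
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(v) for v in parts]
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
            if len(values) < 2:
                raise InvalidInputError(f"{path}:{lineno}: row has no values")
            labels.append(str(int(values[0])))
            rows.append(values[1:])
    if not rows:
        raise InvalidInputError(f"{path}: empty file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise InvalidInputError(f"{path}: ragged rows, lengths {sorted(lengths)}")
    matrix = np.asarray(rows, dtype=float)
    labels = np.asarray(labels)
    p = matrix.shape[1]
    grid = GridDomain.regular(1.0, float(p + 1), p)  # 1..p in grid units (dcs)
    return {
        lab: CurveSet(grid=grid, values=matrix[labels == lab], label=lab)
        for lab in sorted(set(labels))
    }


def read_curves(
    path,
    dialect: str = "wide-csv",
    label_col: bool = False,
    times_header: bool = False,
    grid: GridDomain | None = None,
    p: int = 50,
    bandwidth="auto",
):
    """Load curves from a delimited-text file.

    Returns a single :class:`CurveSet` for unlabeled input, or a dict
    ``{label: CurveSet}`` when a label column is present (always a dict for
    ``ucr-text``).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if dialect == "wide-csv":
        return _read_wide(path, label_col=label_col, times_header=times_header)
    if dialect == "long-csv":
        return _read_long(path, grid=grid, p=p, bandwidth=bandwidth)
    if dialect == "ucr-text":
        return _read_ucr(path)
    raise InvalidParameterError(f"unknown dialect {dialect!r}")


def write_curves(path, curves, times_header: bool = False) -> None:
    """Write one CurveSet (or a dict of them) as wide CSV.

    A dict is written with a leading label column; ``times_header`` adds a
    header row of grid times.
    """
    path = Path(path)
    if isinstance(curves, dict):
        frames = []
        grid = None
        for lab in sorted(curves):
            cs = curves[lab]
            grid = cs.grid
            df = pd.DataFrame(cs.values)
            df.insert(0, "label", lab)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        header = ["label"] + [repr(float(t)) for t in grid.points] if times_header else False
    else:
        out = pd.DataFrame(curves.values)
        header = [repr(float(t)) for t in curves.grid.points] if times_header else False
    out.to_csv(path, index=False, header=header)
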