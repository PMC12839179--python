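"""Reading/writing OpenSim-style .sto/.mot text tables and plain CSV.

The dialect: header lines ``name``, ``nRows=``, ``nColumns=``,
``inDegrees=yes|no``, terminated by ``endheader``, then a tab-delimited
column-label row starting with ``time`` and one row per sample. Round
trips are lossless to (at least) 12 significant digits; values are
written with 17 significant digits.

Gait trials are stored with their metadata (side, subject mass/height)
packed into the table ``name`` line so one file is self-describing; the
stance events are re-derived from the data on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .gait import GaitTrial

__all__ = [
    "write_sto", "read_sto", "write_trial", "read_trial",
    "trial_to_frame", "trial_from_frame",
]

_FLOAT_FMT = "%.17g"
_DEG_SUFFIX = "_angle"  # columns converted when inDegrees=yes


def write_sto(path: str | Path, frame: pd.DataFrame, name: str = "table",
              in_degrees: bool = False) -> None:
    """Write a time-series DataFrame (first column ``time``) as .sto/.mot."""
    if frame.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    out = frame.copy()
    if in_degrees:
        for col in out.columns:
            if col.endswith(_DEG_SUFFIX):
                out[col] = np.degrees(out[col])
    lines = [
        name,
        f"nRows={len(out)}",
        f"nColumns={out.shape[1]}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "\t".join(out.columns),
    ]
    for row in out.itertuples(index=False):
        lines.append("\t".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sto(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a .sto/.mot table; returns (frame, name). Degrees are converted
    back to radians for ``*_angle`` columns when the header says yes."""
    text = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    name = "table"
    i = 0
    for i, line in enumerate(text):
        if line.strip() == "endheader":
            break
        m = re.match(r"^(nRows|nColumns|inDegrees)=(.*)$", line.strip())
        if m:
            meta[m.group(1)] = m.group(2)
        elif line.strip():
            name = line.strip()
    else:
        raise ValueError(f"{path}: no endheader line")
    columns = text[i + 1].split("\t")
    if columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    rows = [[float(v) for v in line.split("\t")]
            for line in text[i + 2:] if line.strip()]
    frame = pd.DataFrame(rows, columns=columns)
    if meta.get("nRows") is not None and int(meta["nRows"]) != len(frame):
        raise ValueError(f"{path}: nRows header does not match data")
    if meta.get("inDegrees", "no") == "yes":
        for col in frame.columns:
            if col.endswith(_DEG_SUFFIX):
                frame[col] = np.radians(frame[col])
    return frame, name


_TRIAL_COLUMNS = ["time", "stance_fraction", "ankle_angle", "knee_angle",
                  "hip_angle", "ankle_moment", "knee_moment", "hip_moment"]


def trial_to_frame(trial: GaitTrial) -> pd.DataFrame:
    return pd.DataFrame({c: getattr(trial, c) for c in _TRIAL_COLUMNS})


def trial_from_frame(frame: pd.DataFrame, side: str, subject_mass: float,
                     subject_height: float) -> GaitTrial:
    return GaitTrial(
        **{c: frame[c].to_numpy() for c in _TRIAL_COLUMNS},
        side=side, subject_mass=subject_mass, subject_height=subject_height,
    )


def _trial_name(trial: GaitTrial) -> str:
    return (f"gait_trial side={trial.side} mass={trial.subject_mass!r} "
            f"height={trial.subject_height!r}")


def _parse_trial_name(name: str) -> dict:
    m = re.match(r"gait_trial side=(\w+) mass=([\d.eE+-]+) height=([\d.eE+-]+)",
                 name)
    if not m:
        raise ValueError(f"not a gait trial table: {name!r}")
    return {"side": m.group(1), "subject_mass": float(m.group(2)),
            "subject_height": float(m.group(3))}


def write_trial(path: str | Path, trial: GaitTrial,
                in_degrees: bool = False) -> None:
    """Write a GaitTrial as .sto/.mot (or CSV when the suffix is .csv)."""
    path = Path(path)
    frame = trial_to_frame(trial)
    if path.suffix.lower() == ".csv":
        header = f"# {_trial_name(trial)}\n"
        path.write_text(header + frame.to_csv(index=False,
                                              float_format=_FLOAT_FMT))
    else:
        write_sto(path, frame, name=_trial_name(trial), in_degrees=in_degrees)


def read_trial(path: str | Path) -> GaitTrial:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        first = path.read_text().splitlines()[0]
        meta = _parse_trial_name(first.lstrip("# "))
        frame = pd.read_csv(path, comment="#")
    else:
        frame, name = read_sto(path)
        meta = _parse_trial_name(name)
    return trial_from_frame(frame, **meta)
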