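"""File formats: delimited EMG tables, OpenSim STO/MOT storage files.

EMG tables are plain CSV/TSV with either a leading ``time`` column (s)
or a caller-supplied sample rate, one column per muscle.  The STO/MOT
writer and reader implement the minimal OpenSim storage dialect (name
line, ``nRows=``/``nColumns=`` keys, ``endheader``, tab-delimited data
with a leading ``time`` column); unknown header keys are ignored on
read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .emg import RawEMGRecording
from .scenarios import ActivationSet


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Delimited EMG tables

def read_emg_table(path: str | Path, sample_rate: float | None = None,
                   sep: str | None = None) -> RawEMGRecording:
    """Read a delimited EMG table into a :class:`RawEMGRecording`.

    Needs either a ``time`` column (uniform, strictly increasing) or an
    explicit ``sample_rate``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse delimited table: {exc}") from exc
    if df.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise FormatError(f"{path}: ragged or missing values near line {bad}")
    cols = list(df.columns)
    if cols and cols[0].strip().lower() == "time":
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dts = np.diff(t)
        if np.any(dts <= 0):
            bad = int(np.argmax(dts <= 0)) + 2
            raise FormatError(f"{path}: non-monotone time column near line {bad}")
        fs = 1.0 / float(np.median(dts))
        t0 = float(t[0])
        data = df.iloc[:, 1:]
    elif sample_rate is not None:
        fs, t0 = float(sample_rate), 0.0
        data = df
    else:
        raise FormatError(f"{path}: no 'time' column and no sample_rate given")
    return RawEMGRecording(
        muscle_names=tuple(str(c).strip() for c in data.columns),
        sample_rate=fs,
        samples=data.to_numpy(dtype=float),
        t0=t0,
    )


def write_emg_table(rec: RawEMGRecording, path: str | Path) -> None:
    """Write a recording as CSV with a leading ``time`` column."""
    df = pd.DataFrame(rec.samples, columns=list(rec.muscle_names))
    df.insert(0, "time", rec.time)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# OpenSim storage (STO / MOT)

def write_sto(time: np.ndarray, columns: dict[str, np.ndarray],
              path: str | Path, name: str = "emgsim") -> None:
    """Write a column set in the OpenSim storage dialect."""
    time = np.asarray(time, dtype=float)
    for label, vals in columns.items():
        if np.asarray(vals).shape != time.shape:
            raise ValueError(f"column {label!r} not on the common time grid")
    n_rows = time.size
    n_cols = 1 + len(columns)
    lines = [name, "version=1", f"nRows={n_rows}", f"nColumns={n_cols}",
             "inDegrees=no", "endheader",
             "\t".join(["time", *columns.keys()])]
    data = np.column_stack([time, *columns.values()])
    for row in data:
        lines.append("\t".join(f"{v:.8g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sto(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read an OpenSim storage file; returns (time, {label: values})."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header_end = None
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            header_end = i
            break
    if header_end is None:
        raise FormatError(f"{path}: missing 'endheader' line")
    labels = lines[header_end + 1].split("\t")
    if not labels or labels[0].strip() != "time":
        raise FormatError(f"{path}: first data column must be 'time'")
    rows = []
    for ln in lines[header_end + 2:]:
        if ln.strip():
            rows.append([float(v) for v in ln.split()])
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(labels):
        raise FormatError(f"{path}: data width does not match header labels")
    time = data[:, 0]
    return time, {lab.strip(): data[:, j + 1] for j, lab in enumerate(labels[1:])}


def write_activation_sto(acts: ActivationSet, path: str | Path) -> None:
    """Write an activation set as an OpenSim control (.sto) file."""
    write_sto(acts.grid, acts.activations, path, name="controls")


def read_activation_sto(path: str | Path) -> ActivationSet:
    """Read an activation set back from a control (.sto) file."""
    time, cols = read_sto(path)
    return ActivationSet(grid=time, activations=cols)
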