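"""On-disk formats: delimited behavioral tables and ROI series matrices.

All outputs are plain text. Behavioral and result tables are tab-separated
with a header. ROI series are stored one subject per file as a CSV matrix
(rows = samples, columns = ROIs) with a JSON sidecar recording subject_id,
sampling rate and column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from painattn.spectral import ROITimeSeries

ES_COLUMNS = ["subject_id", "trial", "response"]
NI_COLUMNS = ["subject_id", "block", "condition", "rt_ms"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns {missing}")


def read_es_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, ES_COLUMNS, "experience-sampling")
    return df


def read_ni_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, NI_COLUMNS, "NI-trial")
    return df


def write_subject_series(
    series_list: Iterable[ROITimeSeries], out_dir: str | Path
) -> Path:
    """Write one subject's ROI series as <subject>.csv + <subject>.json."""
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no series to write")
    subject_ids = {s.subject_id for s in series_list}
    if len(subject_ids) != 1:
        raise ValueError("series span multiple subjects")
    fs_values = {s.fs for s in series_list}
    if len(fs_values) != 1:
        raise ValueError("series have inconsistent sampling rates")
    lengths = {s.n_samples for s in series_list}
    if len(lengths) != 1:
        raise ValueError("series have inconsistent lengths")
    subject_id = series_list[0].subject_id
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = np.column_stack([s.samples for s in series_list])
    csv_path = out_dir / f"{subject_id}.csv"
    np.savetxt(csv_path, matrix, delimiter=",", fmt="%.6g")
    sidecar = {
        "subject_id": subject_id,
        "fs": series_list[0].fs,
        "rois": [s.roi for s in series_list],
        "n_samples": series_list[0].n_samples,
    }
    (out_dir / f"{subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_subject_series(
    csv_path: str | Path,
) -> Iterator[ROITimeSeries]:
    """Yield the ROI series stored in a matrix + sidecar pair."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    matrix = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    rois = sidecar["rois"]
    if matrix.shape[1] != len(rois):
        raise ValueError(
            f"{csv_path}: {matrix.shape[1]} columns but sidecar lists "
            f"{len(rois)} ROIs"
        )
    for j, roi in enumerate(rois):
        yield ROITimeSeries(
            sidecar["subject_id"], roi, float(sidecar["fs"]), matrix[:, j]
        )


def iter_series_dir(series_dir: str | Path) -> Iterator[ROITimeSeries]:
    """Yield every ROI series in a directory of matrix + sidecar pairs."""
    series_dir = Path(series_dir)
    csv_paths = sorted(series_dir.glob("*.csv"))
    if not csv_paths:
        raise FileNotFoundError(f"no series files in {series_dir}")
    for path in csv_paths:
        yield from read_subject_series(path)
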