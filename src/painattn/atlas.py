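"""The 16-ROI dynamic pain connectome (DPC) atlas.

Sixteen regions spanning four networks — the ascending nociceptive pathway,
the descending antinociceptive pathway, the salience network (SN), and the
default mode network (DMN) — with MNI152 coordinates in mm. These are the
regions whose source-space resting-state time series the spectral pipeline
consumes; the coordinates are metadata (beamforming happens upstream).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

ASCENDING = "ascending nociceptive"
DESCENDING = "descending antinociceptive"
SALIENCE = "salience"
DEFAULT_MODE = "default mode"

NETWORKS = (ASCENDING, DESCENDING, SALIENCE, DEFAULT_MODE)


@dataclass(frozen=True)
class ROIInfo:
    name: str
    network: str
    mni_x: float
    mni_y: float
    mni_z: float


DPC_ATLAS: tuple[ROIInfo, ...] = (
    ROIInfo("left_thalamus", ASCENDING, -12, -18, 8),
    ROIInfo("right_thalamus", ASCENDING, 12, -18, 8),
    ROIInfo("left_S1", ASCENDING, -34, -30, 54),
    ROIInfo("right_S1", ASCENDING, 34, -28, 54),
    ROIInfo("left_S2", ASCENDING, -60, -30, 20),
    ROIInfo("right_S2", ASCENDING, 60, -22, 18),
    ROIInfo("left_posterior_insula", ASCENDING, -34, -20, 18),
    ROIInfo("right_posterior_insula", ASCENDING, 34, -20, 18),
    ROIInfo("sgACC", DESCENDING, 4, 26, -8),
    ROIInfo("right_TPJ", SALIENCE, 50, -32, 28),
    ROIInfo("right_anterior_insula", SALIENCE, 34, 18, 4),
    ROIInfo("MCC", SALIENCE, 2, 12, 34),
    ROIInfo("right_dlPFC", SALIENCE, 34, 46, 22),
    ROIInfo("PCC", DEFAULT_MODE, -2, -46, 28),
    ROIInfo("mPFC", DEFAULT_MODE, -2, 50, 2),
    ROIInfo("precuneus", DEFAULT_MODE, 2, -61, 48),
)

ROI_NAMES: tuple[str, ...] = tuple(r.name for r in DPC_ATLAS)

_BY_NAME = {r.name: r for r in DPC_ATLAS}


def roi_network(name: str) -> str:
    """Network label for an atlas ROI; unknown names map to 'unknown'."""
    roi = _BY_NAME.get(name)
    return roi.network if roi is not None else "unknown"


def load_atlas(path: str | Path | None = None) -> tuple[ROIInfo, ...]:
    """Return the built-in DPC atlas, or read one from a delimited file.

    A custom atlas file must be comma- or tab-delimited with a header row
    ``name,network,mni_x,mni_y,mni_z``.
    """
    if path is None:
        return DPC_ATLAS
    path = Path(path)
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        rois = tuple(
            ROIInfo(
                row["name"],
                row["network"],
                float(row["mni_x"]),
                float(row["mni_y"]),
                float(row["mni_z"]),
            )
            for row in reader
        )
    if not rois:
        raise ValueError(f"atlas file {path} contains no ROIs")
    return rois
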