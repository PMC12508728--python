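"""Circular-ROI extraction from 2-D parametric maps.

The acquisition protocol places small circular regions of interest on each
parametric map (two in the right hepatic lobe, one in the left lobe when
visible, one in the posterior spleen) and averages them.  This module
reproduces that convention on maps supplied as NIfTI files, CSV grids or
in-memory arrays: per-ROI arithmetic mean of finite pixels, then an
unweighted mean across ROIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RoiSpec", "roi_mean", "aggregate_rois", "load_map", "load_roi_specs"]

KNOWN_LABELS = (
    "liver_right_posterior",
    "liver_right_anterior",
    "liver_left",
    "spleen_posterior",
)


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI: 0-based centre (row, col) in pixels and radius > 0."""

    label: str
    center_row: float
    center_col: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")


def roi_mean(map2d: np.ndarray, roi: RoiSpec) -> tuple[float, int]:
    """Arithmetic mean of finite map pixels inside the ROI disc.

    Pixel membership uses the centre-of-pixel Euclidean distance from the ROI
    centre, inclusive of the radius.  Returns ``(mean, n_pixels_used)``.
    """
    map2d = np.asarray(map2d, dtype=float)
    if map2d.ndim != 2:
        raise ValueError("map must be 2-D")
    nr, nc = map2d.shape
    if not (0 <= roi.center_row < nr and 0 <= roi.center_col < nc):
        raise ValueError("ROI centre lies outside the map bounds")
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    inside = (rows - roi.center_row) ** 2 + (cols - roi.center_col) ** 2 <= roi.radius**2
    vals = map2d[inside]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite pixels inside the ROI")
    return float(np.mean(vals)), int(len(vals))


def aggregate_rois(means) -> float:
    """Unweighted arithmetic mean of per-ROI means (the organ value).

    Unweighted (rather than pixel-pooled) so that each ROI contributes
    equally regardless of its size, matching per-ROI reporting practice.
    """
    means = np.asarray(list(means), dtype=float)
    if len(means) == 0:
        raise ValueError("need at least one ROI mean")
    return float(np.mean(means))


def load_map(path, slice_index: int | None = None) -> np.ndarray:
    """Load a 2-D parametric map from a NIfTI file or a CSV grid.

    3-D NIfTI volumes require ``slice_index`` (axial slice along the last
    axis); single-slice volumes squeeze automatically.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).get_fdata())
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("3-D volume: a slice_index is required")
            data = data[:, :, slice_index]
        if data.ndim != 2:
            raise ValueError(f"cannot reduce map of shape {data.shape} to 2-D")
        return data
    return np.loadtxt(path, delimiter=",", ndmin=2)


def load_roi_specs(path) -> list[RoiSpec]:
    """Read ROI specifications from a JSON file.

    Expected layout: a list of objects with keys ``label``, ``center_row``,
    ``center_col``, ``radius`` (pixels).
    """
    with open(path) as fh:
        raw = json.load(fh)
    return [
        RoiSpec(
            label=d["label"],
            center_row=d["center_row"],
            center_col=d["center_col"],
            radius=d["radius"],
        )
        for d in raw
    ]
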