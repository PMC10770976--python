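"""Per-cell probe-fluorescence quantification and suspicious-cell selection.

Workflow steps after segmentation: convert the RGB probe image to a
single-channel grayscale FL-intensity image, average it over each detected
cell's mask, flag cells whose mean exceeds the threshold (default 10;
a mean exactly equal to the threshold is *not* suspicious), and export
per-cell crops for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import CellInstance

DEFAULT_THRESHOLD = 10.0

GRAY_MODES = ("mean", "max", "luma")
_LUMA = np.array([0.299, 0.587, 0.114])


def probe_to_gray(rgb_image: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Collapse a 3-channel probe image to per-pixel FL intensity.

    ``mean`` averages the channels (default), ``max`` takes the channel
    maximum, ``luma`` applies Rec.601 weights.  The probe signal is
    red-dominant, so luma reads systematically low; it is provided for
    comparison only.
    """
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("probe image must have exactly 3 channels")
    if mode == "mean":
        return img.mean(axis=2)
    if mode == "max":
        return img.max(axis=2)
    if mode == "luma":
        return img @ _LUMA
    raise ValueError(f"unknown grayscale mode {mode!r}; choose from {GRAY_MODES}")


def cell_mean_intensity(cell_mask: np.ndarray, gray_image: np.ndarray) -> float:
    """Arithmetic mean of the gray values over the cell's pixels."""
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != gray_image.shape:
        raise ValueError("mask and image dimensions differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cell mask is empty; a detected cell must cover >= 1 px")
    return float(np.asarray(gray_image, dtype=float)[mask].sum() / n)


@dataclass
class IntensityReport:
    per_cell: pd.DataFrame  # cell_id, center_x, center_y, area_px, mean_fl, suspicious
    threshold: float
    total_cells: int
    n_suspicious: int
    n_normal: int
    mean_of_means: float

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "total_cells": self.total_cells,
            "n_above_threshold": self.n_suspicious,
            "n_at_or_below_threshold": self.n_normal,
            "mean_of_cell_means": self.mean_of_means,
        }


def classify_cells(
    instances: list[CellInstance],
    gray_image: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> IntensityReport:
    """Fill ``mean_fl``/``suspicious`` on each instance and build the report.

    A cell is suspicious iff its mean FL strictly exceeds the threshold;
    a mean exactly at the threshold falls in the normal bin.  Pixels claimed
    by several detections are assigned to the highest-scoring one.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    claimed = np.zeros(gray_image.shape, dtype=bool)
    rows = []
    for i, inst in enumerate(sorted(instances, key=lambda c: -c.score)):
        mask = inst.mask & ~claimed
        if not mask.any():  # fully occluded by higher-score cells; fall back
            mask = inst.mask
        claimed |= inst.mask
        inst.mean_fl = cell_mean_intensity(mask, gray_image)
        inst.suspicious = bool(inst.mean_fl > threshold)
        rows.append({
            "cell_id": i + 1,
            "center_x": inst.center[0],
            "center_y": inst.center[1],
            "area_px": int(mask.sum()),
            "mean_fl": inst.mean_fl,
            "suspicious": inst.suspicious,
        })
    df = pd.DataFrame(
        rows, columns=["cell_id", "center_x", "center_y",
                       "area_px", "mean_fl", "suspicious"])
    n_susp = int(df["suspicious"].sum()) if len(df) else 0
    return IntensityReport(
        per_cell=df,
        threshold=float(threshold),
        total_cells=len(df),
        n_suspicious=n_susp,
        n_normal=len(df) - n_susp,
        mean_of_means=float(df["mean_fl"].mean()) if len(df) else 0.0,
    )


def crop_cell(
    images: dict[str, np.ndarray],
    instance: CellInstance,
    margin: int = 2,
    zoom: int = 1,
) -> dict[str, np.ndarray]:
    """Crop the cell's bounding box (+margin) from each channel and enlarge.

    The box is clipped to the image bounds; ``zoom`` is an integer
    nearest-neighbor upscale factor.
    """
    if zoom < 1:
        raise ValueError("zoom must be >= 1")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    ys, xs = np.nonzero(instance.mask)
    if ys.size == 0:
        raise ValueError("instance mask is empty")
    out = {}
    for name, img in images.items():
        h, w = img.shape[:2]
        y0 = max(int(ys.min()) - margin, 0)
        y1 = min(int(ys.max()) + margin + 1, h)
        x0 = max(int(xs.min()) - margin, 0)
        x1 = min(int(xs.max()) + margin + 1, w)
        crop = img[y0:y1, x0:x1]
        crop = crop.repeat(zoom, axis=0).repeat(zoom, axis=1)
        out[name] = crop
    return out
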