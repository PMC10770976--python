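"""Synthetic two-channel micrograph generator with exact ground truth.

Scenes contain elliptical, mildly deformed nuclei.  Shapes are sampled
directly in elliptic-Fourier coefficient space (harmonic 1 = a rotated
ellipse, harmonics 2-4 = small perturbations), so every generated cell
carries an exact descriptor alongside its rasterized mask.

Two channels are rendered:

* a DAPI-like nucleus channel (grayscale) used for segmentation, and
* an RGB probe channel whose grayscale level encodes per-cell fluorescence.
  The probe signal is red-dominant; channels are painted so that the mean
  of (R, G, B) recovers the cell's drawn fluorescence value exactly.

Cells belong to one of two intensity populations: "normal-like" (mean
fluorescence near zero, default 3) and "tumor-like" (default mean 45),
straddling the classification threshold of 10.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as fio
from .efd import Contour, EFDescriptor, efd_decode, rasterize_contour

logger = logging.getLogger(__name__)

# channel weights: mean(R, G, B) == drawn fluorescence value
_PROBE_R = 2.5
_PROBE_GB = 0.25


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene family."""

    height: int = 256
    width: int = 256
    n_cells_lambda: float = 12.0        # Poisson rate for the cell count
    semi_axis_range: tuple[float, float] = (7.0, 13.0)
    irregularity: float = 0.05          # relative amplitude of harmonics 2-4
    max_overlap_iou: float = 0.05       # pairwise mask IoU cap
    tumor_fraction: float = 0.5
    normal_fl_mean: float = 3.0
    normal_fl_sd: float = 2.0
    tumor_fl_mean: float = 45.0
    tumor_fl_sd: float = 8.0
    dapi_fg_mean: float = 180.0
    dapi_fg_sd: float = 12.0
    dapi_bg_mean: float = 8.0
    noise_sd: float = 3.0               # background / per-pixel Gaussian noise
    probe_noise_sd: float = 1.0
    max_retries: int = 40
    border_margin: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.semi_axis_range
        if lo <= 0 or hi < lo:
            raise ValueError("semi-axis range must be positive and ordered")
        if self.n_cells_lambda < 0:
            raise ValueError("n_cells_lambda must be >= 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")

    def noiseless(self) -> "SceneSpec":
        """Copy with all stochastic intensity spread removed."""
        return replace(
            self,
            normal_fl_sd=0.0,
            tumor_fl_sd=0.0,
            dapi_fg_sd=0.0,
            noise_sd=0.0,
            probe_noise_sd=0.0,
        )


@dataclass
class Scene:
    dapi: np.ndarray          # (H, W) uint8
    probe_rgb: np.ndarray     # (H, W, 3) uint8
    instance_mask: np.ndarray  # (H, W) int32, 0 = background
    class_labels: dict[int, bool]  # label -> tumor-like?
    planted_fl: dict[int, float]   # label -> drawn fluorescence value
    efd_truth: list[tuple[int, EFDescriptor]]

    @property
    def n_cells(self) -> int:
        return len(self.efd_truth)


def _sample_cell_efd(spec: SceneSpec, rng: np.random.Generator,
                     cx: float, cy: float) -> EFDescriptor:
    lo, hi = spec.semi_axis_range
    a_ax = rng.uniform(lo, hi)
    b_ax = rng.uniform(lo, hi)
    phi = rng.uniform(0.0, np.pi)
    h1 = np.array([
        a_ax * np.cos(phi), -b_ax * np.sin(phi),
        a_ax * np.sin(phi), b_ax * np.cos(phi),
    ])
    mean_ax = 0.5 * (a_ax + b_ax)
    harmonics = [h1]
    for k in range(2, 5):
        amp = spec.irregularity * mean_ax / k
        harmonics.append(rng.normal(0.0, amp, size=4))
    return EFDescriptor(cx, cy, np.stack(harmonics))


def generate_scene(spec: SceneSpec, rng: np.random.Generator) -> Scene:
    """Render one scene; fully determined by ``spec`` and ``rng`` state."""
    h, w = spec.height, spec.width
    n_target = int(rng.poisson(spec.n_cells_lambda))

    mask = np.zeros((h, w), dtype=np.int32)
    placed_masks: list[np.ndarray] = []
    efd_truth: list[tuple[int, EFDescriptor]] = []
    class_labels: dict[int, bool] = {}
    planted_fl: dict[int, float] = {}

    r_max = spec.semi_axis_range[1] * (1.0 + 3.0 * spec.irregularity)
    margin = r_max + spec.border_margin
    label = 0
    for _ in range(n_target):
        placed = False
        for _ in range(spec.max_retries):
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            efd = _sample_cell_efd(spec, rng, cx, cy)
            cell = rasterize_contour(efd_decode(efd, 128), (h, w))
            if not cell.any():
                continue
            area = cell.sum()
            ok = True
            for other in placed_masks:
                inter = np.logical_and(cell, other).sum()
                if inter:
                    iou = inter / (area + other.sum() - inter)
                    if iou > spec.max_overlap_iou:
                        ok = False
                        break
            if ok:
                placed = True
                break
        if not placed:
            logger.warning("could not place a cell within retry budget; skipping")
            continue
        label += 1
        placed_masks.append(cell)
        # earlier cells keep contested pixels
        mask[np.logical_and(cell, mask == 0)] = label
        is_tumor = bool(rng.random() < spec.tumor_fraction)
        if is_tumor:
            fl = rng.normal(spec.tumor_fl_mean, spec.tumor_fl_sd)
        else:
            fl = rng.normal(spec.normal_fl_mean, spec.normal_fl_sd)
        fl = float(max(fl, 0.0))
        class_labels[label] = is_tumor
        planted_fl[label] = fl
        efd_truth.append((label, efd))

    dapi = rng.normal(spec.dapi_bg_mean, spec.noise_sd, size=(h, w))
    probe = np.zeros((h, w, 3), dtype=float)
    if spec.probe_noise_sd > 0 or spec.noise_sd > 0:
        probe += rng.normal(1.0, max(spec.probe_noise_sd, 0.0), size=(h, w, 3))
    for lab, cell in zip(range(1, label + 1), placed_masks):
        region = mask == lab
        n_px = int(region.sum())
        if n_px == 0:
            continue
        dapi[region] = rng.normal(spec.dapi_fg_mean, spec.dapi_fg_sd, size=n_px)
        fl = planted_fl[lab]
        probe[region, 0] = _PROBE_R * fl
        probe[region, 1] = _PROBE_GB * fl
        probe[region, 2] = _PROBE_GB * fl
        if spec.probe_noise_sd > 0:
            # zero-mean across channels so the pixel gray mean is preserved
            noise = rng.normal(0.0, spec.probe_noise_sd, size=(n_px, 3))
            probe[region] += noise - noise.mean(axis=1, keepdims=True)

    dapi8 = np.clip(np.rint(dapi), 0, 255).astype(np.uint8)
    probe8 = np.clip(np.rint(probe), 0, 255).astype(np.uint8)
    return Scene(dapi8, probe8, mask, class_labels, planted_fl, efd_truth)


def generate_dataset(spec: SceneSpec, n_images: int, out_dir: str | Path,
                     seed: int, force: bool = False) -> dict:
    """Write ``n_images`` scenes plus ground truth and return the manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(seed)
    entries = []
    for i, child in enumerate(root.spawn(max(n_images, 0))):
        rng = np.random.default_rng(child)
        scene = generate_scene(spec, rng)
        stem = f"scene_{i:04d}"
        fio.write_image(out / f"{stem}_dapi.png", scene.dapi)
        fio.write_image(out / f"{stem}_probe.png", scene.probe_rgb)
        fio.write_mask(out / f"{stem}_mask.png", scene.instance_mask)
        truth_rows = "label,tumor,planted_fl,center_x,center_y\n" + "".join(
            f"{lab},{int(scene.class_labels[lab])},{scene.planted_fl[lab]:.6f},"
            f"{efd.a0:.6f},{efd.c0:.6f}\n"
            for lab, efd in scene.efd_truth
        )
        (out / f"{stem}_truth.csv").write_text(truth_rows)
        entries.append({
            "stem": stem,
            "dapi": f"{stem}_dapi.png",
            "probe": f"{stem}_probe.png",
            "mask": f"{stem}_mask.png",
            "truth": f"{stem}_truth.csv",
            "n_cells": scene.n_cells,
            "n_tumor": int(sum(scene.class_labels.values())),
        })

    manifest = {
        "spec": asdict(spec),
        "seed": seed,
        "n_images": n_images,
        "total_cells": int(sum(e["n_cells"] for e in entries)),
        "images": entries,
    }
    text = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["sha256"] = hashlib.sha256(text.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
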