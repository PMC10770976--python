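"""Training-target construction: center heatmaps plus EFD regression maps.

Each ground-truth cell contributes a Gaussian bump (peak value exactly 1 at
the cell's center pixel) to the heatmap, and a regression vector of length
``2 + 4 N`` stored at that pixel: the sub-pixel center offset ``(dx, dy)``
followed by the ``N`` harmonic quadruples divided by a scale constant so
all regression targets are O(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .efd import Contour, EFDescriptor, efd_encode, trace_contours

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 256.0


@dataclass
class TrainingTarget:
    heatmap: np.ndarray      # (H, W) float32 in [0, 1]
    efd_map: np.ndarray      # (2 + 4N, H, W) float32, defined at peaks
    valid_mask: np.ndarray   # (H, W) bool, True at center-peak pixels
    scale: float
    n_harmonics: int

    @property
    def n_cells(self) -> int:
        return int(self.valid_mask.sum())

    def copy(self) -> "TrainingTarget":
        return TrainingTarget(
            self.heatmap.copy(), self.efd_map.copy(), self.valid_mask.copy(),
            self.scale, self.n_harmonics,
        )


def _encode_padded(contour: Contour, n_harmonics: int) -> EFDescriptor:
    """Encode with at most floor(M/2) harmonics, zero-padding the rest."""
    n_avail = min(n_harmonics, len(contour) // 2)
    efd = efd_encode(contour, max(n_avail, 1))
    if efd.n_harmonics < n_harmonics:
        pad = np.zeros((n_harmonics - efd.n_harmonics, 4))
        efd = EFDescriptor(efd.a0, efd.c0,
                           np.concatenate([efd.harmonics, pad], axis=0))
    return efd


def make_targets(
    instance_mask: np.ndarray,
    n_harmonics: int = 6,
    gaussian_sigma: float | None = None,
    scale: float = DEFAULT_SCALE,
) -> TrainingTarget:
    """Build the supervision maps for one instance-labeled image.

    ``gaussian_sigma`` defaults to 0.1 x the mean cell equivalent diameter
    (clamped to >= 1 px).  An empty mask yields an all-zero heatmap and an
    empty valid mask, which is legal and supports negative examples.
    """
    mask = np.asarray(instance_mask)
    h, w = mask.shape
    n_ch = 2 + 4 * n_harmonics
    heat = np.zeros((h, w), dtype=np.float32)
    efd_map = np.zeros((n_ch, h, w), dtype=np.float32)
    valid = np.zeros((h, w), dtype=bool)

    contours = trace_contours(mask)
    if not contours:
        return TrainingTarget(heat, efd_map, valid, scale, n_harmonics)

    if gaussian_sigma is None:
        areas = np.array([(mask == lab).sum() for lab, _ in contours], dtype=float)
        eq_diam = 2.0 * np.sqrt(areas / np.pi)
        gaussian_sigma = max(0.1 * float(eq_diam.mean()), 1.0)
    if gaussian_sigma <= 0:
        raise ValueError("gaussian_sigma must be positive")

    ys, xs = np.mgrid[0:h, 0:w]
    for lab, contour in contours:
        efd = _encode_padded(contour, n_harmonics)
        px = int(np.clip(np.rint(efd.a0), 0, w - 1))
        py = int(np.clip(np.rint(efd.c0), 0, h - 1))
        bump = np.exp(-((xs - px) ** 2 + (ys - py) ** 2)
                      / (2.0 * gaussian_sigma**2)).astype(np.float32)
        np.maximum(heat, bump, out=heat)
        vec = np.empty(n_ch, dtype=np.float32)
        vec[0] = efd.a0 - px
        vec[1] = efd.c0 - py
        vec[2:] = efd.harmonics.ravel() / scale
        if valid[py, px]:
            logger.warning("two cells share center pixel (%d, %d); keeping last", px, py)
        efd_map[:, py, px] = vec
        valid[py, px] = True
    return TrainingTarget(heat, efd_map, valid, scale, n_harmonics)


def target_vector_to_efd(vec: np.ndarray, peak_xy: tuple[int, int],
                         scale: float) -> EFDescriptor:
    """De-normalize one regression vector read at a peak pixel."""
    vec = np.asarray(vec, dtype=float)
    px, py = peak_xy
    return EFDescriptor(
        px + vec[0], py + vec[1], (vec[2:] * scale).reshape(-1, 4))


# ---------------------------------------------------------------------------
# caching
# ---------------------------------------------------------------------------

def save_target(path, target: TrainingTarget) -> None:
    """Cache one image's targets as a compressed array archive."""
    np.savez_compressed(
        path, heatmap=target.heatmap, efd_map=target.efd_map,
        valid_mask=target.valid_mask,
        meta=np.array([target.scale, target.n_harmonics]))


def load_target(path) -> TrainingTarget:
    with np.load(path) as z:
        return TrainingTarget(z["heatmap"], z["efd_map"], z["valid_mask"],
                              float(z["meta"][0]), int(z["meta"][1]))


def cache_path(cache_dir, image_filename) -> "Path":
    """Cache location for an image's targets, keyed by its filename."""
    from pathlib import Path

    return Path(cache_dir) / (Path(image_filename).stem + "_targets.npz")


# ---------------------------------------------------------------------------
# flip rules (shared with data augmentation)
# ---------------------------------------------------------------------------
# Mirroring x and restoring counterclockwise orientation negates the a_n and
# d_n coefficients.  Mirroring y negates b_n and c_n AND moves the canonical
# start vertex (topmost point) half a period along the contour, which
# multiplies harmonic n by (-1)^n; the composition keeps augmented targets
# consistent with contours traced from the flipped mask.  Sub-pixel offsets
# flip sign along the mirrored axis.

def _flip_vec_signs(efd_map: np.ndarray, valid: np.ndarray, axis: str) -> None:
    n_harm = (efd_map.shape[0] - 2) // 4
    if axis == "h":
        rows = [0] + [2 + 4 * k + j for k in range(n_harm) for j in (0, 3)]
    else:
        rows = [1]
        for k in range(n_harm):  # harmonic k+1
            if (k + 1) % 2:  # odd harmonic: mirror signs then phase-shift pi
                rows += [2 + 4 * k, 2 + 4 * k + 3]
            else:
                rows += [2 + 4 * k + 1, 2 + 4 * k + 2]
    efd_map[np.ix_(rows)] *= np.where(valid, -1.0, 1.0)


def flip_target(target: TrainingTarget, horizontal: bool, vertical: bool) -> TrainingTarget:
    """Mirror the supervision maps; an involution for each axis."""
    t = target.copy()
    if horizontal:
        t.heatmap = t.heatmap[:, ::-1].copy()
        t.valid_mask = t.valid_mask[:, ::-1].copy()
        t.efd_map = t.efd_map[:, :, ::-1].copy()
        _flip_vec_signs(t.efd_map, t.valid_mask, "h")
    if vertical:
        t.heatmap = t.heatmap[::-1].copy()
        t.valid_mask = t.valid_mask[::-1].copy()
        t.efd_map = t.efd_map[:, ::-1].copy()
        _flip_vec_signs(t.efd_map, t.valid_mask, "v")
    return t
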