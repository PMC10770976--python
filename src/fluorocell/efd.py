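"""Elliptic Fourier descriptors (EFD) for closed cell contours.

A closed contour is represented by its arc-length-parametrized truncated
Fourier series: DC terms ``(A0, C0)`` — the contour center — plus ``N``
harmonics of four coefficients ``(a_n, b_n, c_n, d_n)`` each, so that

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

with ``T`` the contour perimeter.  Coordinates are 0-based pixel
coordinates, ``x`` = column, ``y`` = row, origin at the top-left.

This module provides contour tracing from integer-labeled instance masks,
exact encode/decode between contours and descriptors, and the boundary-
inclusive rasterization used everywhere downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EDGE_EPS = 1e-9


class EncodingError(ValueError):
    """Raised when a contour cannot be Fourier-encoded (e.g. zero perimeter)."""


@dataclass
class Contour:
    """Ordered closed polygon of one cell boundary.

    ``points`` is an ``(M, 2)`` float array of ``(x, y)`` vertices with the
    closing edge from the last vertex back to the first implied.  ``ccw`` is
    True when the polygon has positive signed area in (x, y) coordinates.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (M, 2) array")
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 vertices")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour coordinates must be finite")
        if np.any(np.all(pts == np.roll(pts, -1, axis=0), axis=1)):
            raise ValueError("consecutive duplicate vertices (closing edge included)")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yn - xn * y))

    @property
    def ccw(self) -> bool:
        return self.signed_area > 0

    @property
    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def reversed(self) -> "Contour":
        """Same polygon traversed in the opposite direction, same start vertex."""
        pts = np.concatenate([self.points[:1], self.points[:0:-1]], axis=0)
        return Contour(pts)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]))

    def oriented_ccw(self) -> "Contour":
        return self if self.signed_area >= 0 else self.reversed()


@dataclass
class EFDescriptor:
    """DC terms plus harmonic coefficient quadruples of one contour."""

    a0: float
    c0: float
    harmonics: np.ndarray  # (N, 4) rows (a_n, b_n, c_n, d_n)

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (N, 4) array with N >= 1")
        if not (np.isfinite(self.a0) and np.isfinite(self.c0) and np.all(np.isfinite(h))):
            raise ValueError("descriptor coefficients must be finite")
        self.harmonics = h

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def to_vector(self) -> np.ndarray:
        """Flatten to ``[A0, C0, a1, b1, c1, d1, ..., dN]``."""
        return np.concatenate([[self.a0, self.c0], self.harmonics.ravel()])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "EFDescriptor":
        vec = np.asarray(vec, dtype=float)
        if vec.size < 6 or (vec.size - 2) % 4:
            raise ValueError("vector length must be 2 + 4N")
        return cls(float(vec[0]), float(vec[1]), vec[2:].reshape(-1, 4))


def contour_center(efd: EFDescriptor) -> tuple[float, float]:
    """Contour center ``(x, y)`` — the DC terms, i.e. the arc-length centroid."""
    return (efd.a0, efd.c0)


# ---------------------------------------------------------------------------
# encode / decode
# ---------------------------------------------------------------------------

def efd_encode(contour: Contour, n_harmonics: int) -> EFDescriptor:
    """Elliptic Fourier expansion of a closed polygon (chain-length form).

    The polygon is traversed at unit speed along its edges; harmonic
    integrals are evaluated exactly for the piecewise-linear traversal.
    ``(A0, C0)`` is the arc-length-averaged boundary centroid.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics > len(contour) // 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} exceeds floor(n_vertices/2)="
            f"{len(contour) // 2}"
        )
    pts = contour.points
    d = np.roll(pts, -1, axis=0) - pts  # edge vectors, closing edge included
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        raise EncodingError("contour has a zero-length edge")
    T = float(dt.sum())
    if T <= 0:
        raise EncodingError("contour has zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(dt)])  # cumulative arc length, t[-1] = T

    # DC terms: line integral of the linear segments, exact.
    mid = 0.5 * (pts + np.roll(pts, -1, axis=0))
    a0, c0 = (mid * dt[:, None]).sum(axis=0) / T

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    w = 2.0 * np.pi * n / T
    cos1, cos0 = np.cos(w * t[1:]), np.cos(w * t[:-1])
    sin1, sin0 = np.sin(w * t[1:]), np.sin(w * t[:-1])
    scale = T / (2.0 * n.ravel() ** 2 * np.pi**2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = scale * ((cos1 - cos0) * dxdt).sum(axis=1)
    b = scale * ((sin1 - sin0) * dxdt).sum(axis=1)
    c = scale * ((cos1 - cos0) * dydt).sum(axis=1)
    dd = scale * ((sin1 - sin0) * dydt).sum(axis=1)
    return EFDescriptor(float(a0), float(c0), np.stack([a, b, c, dd], axis=1))


def efd_decode(efd: EFDescriptor, n_points: int) -> Contour:
    """Evaluate the Fourier series at ``n_points`` uniform parameter steps."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, efd.n_harmonics + 1)[:, None]
    cos, sin = np.cos(n * t), np.sin(n * t)
    a, b, c, d = efd.harmonics.T
    x = efd.a0 + a @ cos + b @ sin
    y = efd.c0 + c @ cos + d @ sin
    return Contour(np.stack([x, y], axis=1))


# ---------------------------------------------------------------------------
# mask <-> contour
# ---------------------------------------------------------------------------

def _region_contour(region: np.ndarray) -> Contour:
    """Outer 0.5-level contour of a binary region.

    Vertices sit midway between foreground and background pixel centers
    (marching squares), so every region pixel center lies strictly inside
    the polygon with a ~0.5 px margin — this makes the mask -> contour ->
    rasterize roundtrip exact and robust to Fourier smoothing.  The vertex
    list is rotated to start at the topmost-then-leftmost vertex and
    oriented counterclockwise, making traced labels deterministic.
    """
    from skimage import measure

    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:  # cannot happen for a nonempty region
        raise ValueError("no boundary found for nonempty region")
    rc = max(contours, key=len)  # outer contour is the longest
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    rc = rc - 1.0  # undo padding offset
    # drop consecutive duplicates
    keep = np.ones(len(rc), dtype=bool)
    keep[1:] = np.any(np.abs(rc[1:] - rc[:-1]) > 1e-12, axis=1)
    rc = rc[keep]
    start = int(np.lexsort((rc[:, 1], rc[:, 0]))[0])  # topmost then leftmost
    rc = np.roll(rc, -start, axis=0)
    pts = np.stack([rc[:, 1], rc[:, 0]], axis=1)  # (x, y)
    return Contour(pts).oriented_ccw()


def trace_contours(instance_mask: np.ndarray) -> list[tuple[int, Contour]]:
    """Extract one closed contour per positive label of an instance mask.

    If a label is fragmented into several connected components, the largest
    component (by pixel count) is kept and a warning is logged.  Contours
    are returned ordered by ascending label; each starts at the
    topmost-then-leftmost boundary pixel and is oriented counterclockwise
    (positive signed area with y pointing down the rows).
    """
    mask = np.asarray(instance_mask)
    if mask.ndim != 2:
        raise ValueError("instance mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        if np.issubdtype(mask.dtype, np.bool_):
            mask = mask.astype(np.int32)
        else:
            raise ValueError("instance mask must have an integer dtype")
    if np.any(mask < 0):
        raise ValueError("instance mask labels must be non-negative")

    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        logger.warning("trace_contours: empty mask, no contours extracted")
        return []

    from scipy import ndimage

    out: list[tuple[int, Contour]] = []
    for lab in labels:
        region = mask == lab
        comp, n_comp = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
        if n_comp > 1:
            logger.warning(
                "label %d is fragmented into %d components; keeping the largest",
                lab, n_comp,
            )
            sizes = ndimage.sum_labels(region, comp, index=np.arange(1, n_comp + 1))
            region = comp == (int(np.argmax(sizes)) + 1)
        out.append((int(lab), _region_contour(region)))
    return out


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels belonging to the contour's region.

    A pixel (pixel centers sit at integer coordinates) is inside iff its
    center is inside the polygon under the even-odd rule, or lies on the
    polygon boundary — boundary pixels count as inside, which makes the
    square mask -> trace -> rasterize roundtrip exact.
    """
    h, w = shape
    pts = contour.points
    x0 = max(int(np.floor(pts[:, 0].min())), 0)
    x1 = min(int(np.ceil(pts[:, 0].max())), w - 1)
    y0 = max(int(np.floor(pts[:, 1].min())), 0)
    y1 = min(int(np.ceil(pts[:, 1].max())), h - 1)
    out = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return out

    gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px = gx.ravel().astype(float)
    py = gy.ravel().astype(float)

    ax, ay = pts[:, 0], pts[:, 1]
    bx, by = np.roll(ax, -1), np.roll(ay, -1)

    # even-odd ray casting, vectorized points x edges
    cond = (ay[None, :] > py[:, None]) != (by[None, :] > py[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = ax[None, :] + (py[:, None] - ay[None, :]) * (
            (bx - ax)[None, :] / np.where(by - ay == 0, np.inf, by - ay)[None, :]
        )
    inside = (np.sum(cond & (px[:, None] < xint), axis=1) % 2).astype(bool)

    # boundary pixels: distance from pixel center to any edge ~ 0
    ex, ey = bx - ax, by - ay
    elen2 = ex**2 + ey**2
    tproj = ((px[:, None] - ax[None, :]) * ex[None, :]
             + (py[:, None] - ay[None, :]) * ey[None, :]) / elen2[None, :]
    tproj = np.clip(tproj, 0.0, 1.0)
    dx = px[:, None] - (ax[None, :] + tproj * ex[None, :])
    dy = py[:, None] - (ay[None, :] + tproj * ey[None, :])
    on_edge = np.any(dx**2 + dy**2 <= _EDGE_EPS, axis=1)

    out[gy.ravel(), gx.ravel()] = inside | on_edge
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def descriptors_to_frame(items: list[tuple[int, EFDescriptor]]) -> pd.DataFrame:
    """One row per cell: label, A0, C0, a1, b1, c1, d1, ..., dN."""
    if not items:
        return pd.DataFrame(columns=["label", "A0", "C0"])
    n = items[0][1].n_harmonics
    cols = ["label", "A0", "C0"] + [
        f"{ch}{k}" for k in range(1, n + 1) for ch in ("a", "b", "c", "d")
    ]
    rows = [[lab, *efd.to_vector()] for lab, efd in items]
    return pd.DataFrame(rows, columns=cols)


def frame_to_descriptors(df: pd.DataFrame) -> list[tuple[int, EFDescriptor]]:
    out = []
    coef_cols = [c for c in df.columns if c not in ("label",)]
    for _, row in df.iterrows():
        vec = row[coef_cols].to_numpy(dtype=float)
        out.append((int(row["label"]), EFDescriptor.from_vector(vec)))
    return out


def descriptors_to_json(items: list[tuple[int, EFDescriptor]]) -> str:
    payload = [
        {
            "label": lab,
            "A0": efd.a0,
            "C0": efd.c0,
            "harmonics": efd.harmonics.tolist(),
        }
        for lab, efd in items
    ]
    return json.dumps(payload, indent=2)


def descriptors_from_json(text: str) -> list[tuple[int, EFDescriptor]]:
    return [
        (int(d["label"]), EFDescriptor(d["A0"], d["C0"], np.array(d["harmonics"])))
        for d in json.loads(text)
    ]
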