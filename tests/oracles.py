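"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: Fourier coefficients
come from dense numerical quadrature of the arc-length parametrization,
and detection matching comes from exhaustive assignment enumeration.
"""

from itertools import permutations

import numpy as np


def resample_by_arclength(points: np.ndarray, n: int) -> np.ndarray:
    """Sample a closed polygon at n points uniform in arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    total = s[-1]
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.stack([x, y], axis=1)


def fourier_coeffs_quadrature(points: np.ndarray, n_harmonics: int,
                              n_samples: int = 200_000):
    """(A0, C0, harmonics) by rectangle-rule quadrature over arc length."""
    samp = resample_by_arclength(points, n_samples)
    x, y = samp[:, 0], samp[:, 1]
    t = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    a0 = x.mean()
    c0 = y.mean()
    harmonics = []
    for k in range(1, n_harmonics + 1):
        ck, sk = np.cos(k * t), np.sin(k * t)
        harmonics.append([
            2.0 * np.mean(x * ck), 2.0 * np.mean(x * sk),
            2.0 * np.mean(y * ck), 2.0 * np.mean(y * sk),
        ])
    return float(a0), float(c0), np.array(harmonics)


def iou_sets(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def match_bruteforce(iou_matrix: np.ndarray, tau: float) -> tuple[int, int, int]:
    """Max-cardinality matching by exhaustive assignment enumeration."""
    n_pred, n_gt = iou_matrix.shape
    feas = iou_matrix >= tau
    best = 0
    k = min(n_pred, n_gt)
    preds = range(n_pred)
    for gt_subset in permutations(range(n_gt), k):
        count = sum(1 for p, g in zip(preds, gt_subset) if feas[p, g])
        best = max(best, count)
    # permutations over which preds map when n_pred > n_gt
    if n_pred > n_gt:
        best = 0
        for pred_subset in permutations(range(n_pred), n_gt):
            count = sum(1 for p, g in zip(pred_subset, range(n_gt)) if feas[p, g])
            best = max(best, count)
    return best, n_pred - best, n_gt - best


def f1_bruteforce(iou_matrix: np.ndarray, taus) -> float:
    f1s = []
    for tau in taus:
        tp, fp, fn = match_bruteforce(iou_matrix, tau)
        if tp == 0:
            f1s.append(0.0 if (fp or fn) else 1.0)
        else:
            p = tp / (tp + fp)
            r = tp / (tp + fn)
            f1s.append(2 * p * r / (p + r))
    return float(np.mean(f1s))


def random_simple_polygon(rng: np.random.Generator, n_vertices: int,
                          center=(40.0, 40.0), base_radius=14.0,
                          n_modes: int = 5) -> np.ndarray:
    """Smooth star-shaped (hence simple) polygon: band-limited radius."""
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    angles += np.linspace(0, 1e-6, n_vertices)  # enforce distinct angles
    radii = np.full(n_vertices, float(base_radius))
    for k in range(1, n_modes + 1):
        amp = rng.uniform(0.0, 0.18 / k) * base_radius
        phase = rng.uniform(0.0, 2.0 * np.pi)
        radii += amp * np.cos(k * angles + phase)
    x = center[0] + radii * np.cos(angles)
    y = center[1] + radii * np.sin(angles)
    return np.stack([x, y], axis=1)
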