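"""Global camera-motion estimation and bounding-box compensation.

Camera pan/zoom between consecutive frames displaces every predicted box.
Given matched image points ``(p_i, q_i)`` — ``p_i`` in the current frame,
``q_i`` in the previous frame — a 2x3 affine ``A`` with ``q = A [p; 1]``
is estimated robustly with RANSAC.  Predicted boxes (which live in
previous-frame coordinates) are then brought into the current frame by
applying the inverse of ``A`` to their centers; widths and heights are
rescaled by the column norms ``(s_x, s_y)`` of the linear part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RansacConfig

logger = logging.getLogger(__name__)

__all__ = ["AffineTransform", "RansacParams", "estimate_affine", "compensate_box", "apply_affine"]

RansacParams = RansacConfig  # parameter set shared with the run config

_DET_EPS = 1e-9


@dataclass(frozen=True)
class AffineTransform:
    """A 2x3 affine map with its column-norm scale factors."""

    M: np.ndarray  # shape (2, 3)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {M.shape}")
        object.__setattr__(self, "M", M)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]))

    @property
    def linear(self) -> np.ndarray:
        return self.M[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.M[:, 2]

    @property
    def s_x(self) -> float:
        return float(np.linalg.norm(self.M[:, 0]))

    @property
    def s_y(self) -> float:
        return float(np.linalg.norm(self.M[:, 1]))

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.M, AffineTransform.identity().M))

    def invertible(self) -> bool:
        return abs(float(np.linalg.det(self.linear))) > _DET_EPS


def apply_affine(A: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Forward map: points (n, 2) -> A [p; 1]."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ A.linear.T + A.translation


def _fit_affine_lstsq(p: np.ndarray, q: np.ndarray) -> AffineTransform | None:
    """Least-squares affine q ~= A [p; 1] from >= 3 pairs; None if degenerate."""
    n = p.shape[0]
    X = np.hstack([p, np.ones((n, 1))])  # (n, 3)
    if np.linalg.matrix_rank(X) < 3:  # collinear sample
        return None
    coef, *_ = np.linalg.lstsq(X, q, rcond=None)  # (3, 2)
    return AffineTransform(coef.T)


def estimate_affine(
    pairs: np.ndarray | list,
    rp: RansacParams | None = None,
    seed: int | np.random.Generator = 0,
) -> AffineTransform:
    """RANSAC estimate of the global affine from point correspondences.

    ``pairs`` is an ``(n, 4)`` array of ``(px, py, qx, qy)`` rows (or a list
    of ``((px, py), (qx, qy))``).  Returns the least-squares refit on the
    best consensus set, or the identity transform when there are fewer than
    ``min_samples`` pairs or the consensus fraction stays below
    ``min_inlier_frac`` (logged, never raised).  Deterministic for a fixed
    seed.
    """
    rp = rp or RansacParams()
    if isinstance(pairs, np.ndarray):
        arr = pairs.astype(float).reshape(-1, 4)
    else:
        rows = [np.asarray(item, dtype=float).ravel() for item in pairs]
        arr = np.array(rows).reshape(-1, 4) if rows else np.empty((0, 4))
    n = arr.shape[0]
    if n < rp.min_samples:
        logger.debug("estimate_affine: %d pairs < min_samples=%d, identity fallback", n, rp.min_samples)
        return AffineTransform.identity()
    p, q = arr[:, :2], arr[:, 2:]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_count = 0
    tol_sq = rp.inlier_tol**2
    for _ in range(rp.max_iters):
        idx = rng.choice(n, size=3, replace=False)
        cand = _fit_affine_lstsq(p[idx], q[idx])
        if cand is None:
            continue
        err = np.sum((apply_affine(cand, p) - q) ** 2, axis=1)
        inliers = err <= tol_sq
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
            if count == n:
                break
    if best_inliers is None or best_count < max(rp.min_samples, rp.min_inlier_frac * n):
        logger.debug("estimate_affine: consensus %d/%d below threshold, identity fallback", best_count, n)
        return AffineTransform.identity()
    refit = _fit_affine_lstsq(p[best_inliers], q[best_inliers])
    if refit is None or not refit.invertible():
        logger.debug("estimate_affine: degenerate consensus refit, identity fallback")
        return AffineTransform.identity()
    return refit


def compensate_box(
    box: tuple[float, float, float, float],
    A: AffineTransform,
    inverse_scale: bool = False,
) -> tuple[float, float, float, float]:
    """Undo camera motion on a predicted center-form box.

    The center is mapped by the homogeneous inverse of ``A``; width and
    height are multiplied by the scale factors ``(s_x, s_y)`` (or divided,
    with ``inverse_scale=True``, which is the dimensionally consistent
    choice under zoom — see the methods note).  A singular linear part
    leaves the box unchanged with a warning.
    """
    x, y, w, h = box
    if A.is_identity:
        return (x, y, w, h)
    if not A.invertible():
        logger.warning("compensate_box: singular affine, identity compensation")
        return (x, y, w, h)
    center = np.linalg.solve(A.linear, np.array([x, y]) - A.translation)
    sx, sy = A.s_x, A.s_y
    if inverse_scale:
        w_c, h_c = w / sx, h / sy
    else:
        w_c, h_c = sx * w, sy * h
    return (float(center[0]), float(center[1]), w_c, h_c)


def mutual_nearest_pairs(
    prev_centers: np.ndarray, curr_centers: np.ndarray, max_dist: float = 50.0
) -> np.ndarray:
    """Mutual-nearest-neighbour prematch of detection centers across frames.

    Used as a correspondence fallback when no sidecar is available: returns
    ``(n, 4)`` rows ``(px, py, qx, qy)`` with ``p`` from the current frame
    and ``q`` from the previous one.
    """
    prev_centers = np.atleast_2d(prev_centers)
    curr_centers = np.atleast_2d(curr_centers)
    if prev_centers.size == 0 or curr_centers.size == 0:
        return np.empty((0, 4))
    d = np.linalg.norm(curr_centers[:, None, :] - prev_centers[None, :, :], axis=2)
    fwd = np.argmin(d, axis=1)   # current -> previous
    bwd = np.argmin(d, axis=0)   # previous -> current
    rows = [
        np.concatenate([curr_centers[i], prev_centers[fwd[i]]])
        for i in range(curr_centers.shape[0])
        if bwd[fwd[i]] == i and d[i, fwd[i]] <= max_dist
    ]
    return np.array(rows) if rows else np.empty((0, 4))
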