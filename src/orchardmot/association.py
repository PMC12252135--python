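"""IoU / Re-ID fused data association.

Spatial affinity is the IoU distance ``1 - |A ∩ B| / |A ∪ B|`` between
center-form boxes; appearance affinity is the cosine distance between
appearance embeddings.  The fused cost follows the minimum-value rule
``d_fused = min(d_IoU, d_ReID)`` after two filters: a spatial gate that
marks pairs with ``d_IoU > theta_iou`` inadmissible, and a Re-ID filter
that removes low-relevance appearance candidates (``d_ReID > theta_reid``)
from the fusion — such pairs keep their motion-only IoU cost (or are
dropped entirely in strict mode).  The assignment itself is the
minimum-total-cost bipartite matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "INF_COST", "Assignment",
    "iou_distance", "reid_distance", "smooth_feature",
    "iou_cost_matrix", "reid_cost_matrix", "fuse_costs", "assign",
]

#: sentinel for gated-out (inadmissible) pairs
INF_COST = np.inf


@dataclass
class Assignment:
    """Solved frame-to-frame assignment: matches plus leftovers."""

    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def _iou(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        return 0.0
    ix = min(ax + aw / 2, bx + bw / 2) - max(ax - aw / 2, bx - bw / 2)
    iy = min(ay + ah / 2, by + bh / 2) - max(ay - ah / 2, by - bh / 2)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter)


def iou_distance(a, b) -> float:
    """IoU distance between two center-form boxes, in [0, 1]; degenerate boxes -> 1."""
    return min(max(1.0 - _iou(a, b), 0.0), 1.0)


def iou_cost_matrix(track_boxes, det_boxes) -> np.ndarray:
    """Vectorized (T, D) matrix of IoU distances between center-form boxes."""
    if len(track_boxes) == 0 or len(det_boxes) == 0:
        return np.ones((len(track_boxes), len(det_boxes)))
    tb = np.atleast_2d(np.asarray(track_boxes, dtype=float))
    db = np.atleast_2d(np.asarray(det_boxes, dtype=float))
    tl_t, br_t = tb[:, :2] - tb[:, 2:] / 2, tb[:, :2] + tb[:, 2:] / 2
    tl_d, br_d = db[:, :2] - db[:, 2:] / 2, db[:, :2] + db[:, 2:] / 2
    wh = np.clip(
        np.minimum(br_t[:, None, :], br_d[None, :, :])
        - np.maximum(tl_t[:, None, :], tl_d[None, :, :]),
        0.0, None,
    )
    inter = wh[..., 0] * wh[..., 1]
    area_t = np.clip(tb[:, 2] * tb[:, 3], 0.0, None)
    area_d = np.clip(db[:, 2] * db[:, 3], 0.0, None)
    union = area_t[:, None] + area_d[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return np.clip(1.0 - iou, 0.0, 1.0)


def reid_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine distance 1 - a.b / (|a||b|), in [0, 2]; zero vectors -> 1 (uninformative)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"feature dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.debug("reid_distance: zero feature vector, returning neutral distance 1")
        return 1.0
    return float(1.0 - (a @ b) / (na * nb))


def reid_cost_matrix(track_feats, det_feats) -> np.ndarray:
    """(T, D) cosine-distance matrix; rows/cols with missing features get 1."""
    T, D = len(track_feats), len(det_feats)
    out = np.ones((T, D))
    for i, f in enumerate(track_feats):
        if f is None:
            continue
        for j, g in enumerate(det_feats):
            if g is None:
                continue
            out[i, j] = reid_distance(f, g)
    return out


def smooth_feature(f_bar: np.ndarray, f_new: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average of a track's appearance feature.

    ``alpha * f_bar + (1 - alpha) * f_new``, then L2-renormalized so cosine
    distances stay calibrated (the bare average shrinks the norm whenever
    the two vectors disagree).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    f_bar = np.asarray(f_bar, dtype=float)
    f_new = np.asarray(f_new, dtype=float)
    if f_bar.shape != f_new.shape:
        raise ValueError(f"feature dimension mismatch: {f_bar.shape} vs {f_new.shape}")
    mixed = alpha * f_bar + (1.0 - alpha) * f_new
    norm = np.linalg.norm(mixed)
    return mixed / norm if norm > 0 else mixed


def fuse_costs(
    d_iou: np.ndarray,
    d_reid: np.ndarray | None,
    theta_iou: float = 0.7,
    theta_reid: float = 0.25,
    strict_reid_filter: bool = False,
) -> np.ndarray:
    """Fuse IoU and Re-ID distance matrices under the minimum-value rule.

    Pairs failing the spatial gate (``d_iou > theta_iou``) become
    inadmissible.  Among admissible pairs, those whose appearance distance
    exceeds ``theta_reid`` are filtered out of the appearance fusion and
    keep the motion-only cost (or become inadmissible in strict mode);
    the rest take ``min(d_iou, d_reid)``.  Without features the result is
    simply the gated IoU matrix.
    """
    d_iou = np.asarray(d_iou, dtype=float)
    fused = np.where(d_iou > theta_iou, INF_COST, d_iou)
    if d_reid is None:
        return fused
    d_reid = np.asarray(d_reid, dtype=float)
    if d_reid.shape != d_iou.shape:
        raise ValueError(f"cost matrix shapes differ: {d_iou.shape} vs {d_reid.shape}")
    admissible = np.isfinite(fused)
    vetoed = admissible & (d_reid > theta_reid)
    fusable = admissible & ~vetoed
    fused = np.where(fusable, np.minimum(d_iou, d_reid), fused)
    if strict_reid_filter:
        fused = np.where(vetoed, INF_COST, fused)
    return fused


def assign(costs: np.ndarray, match_gate: float = 0.8) -> Assignment:
    """Minimum-total-cost bipartite assignment with gating.

    Inadmissible (infinite) entries never match; any solved pair with cost
    above ``match_gate`` is demoted to unmatched.  Deterministic for a
    given matrix.
    """
    costs = np.atleast_2d(np.asarray(costs, dtype=float))
    T, D = costs.shape
    if T == 0 or D == 0:
        return Assignment([], list(range(T)), list(range(D)))
    finite = np.isfinite(costs)
    # large-but-finite stand-in keeps the LAP solvable while making
    # inadmissible pairs strictly worse than any admissible completion
    big = (np.max(costs[finite]) if finite.any() else 1.0) * (max(T, D) + 1) + 1.0
    solv = np.where(finite, costs, big)
    rows, cols = linear_sum_assignment(solv)
    matches, um_t, um_d = [], set(range(T)), set(range(D))
    for i, j in zip(rows, cols):
        if finite[i, j] and costs[i, j] <= match_gate:
            matches.append((int(i), int(j)))
            um_t.discard(int(i))
            um_d.discard(int(j))
    matches.sort()
    return Assignment(matches, sorted(um_t), sorted(um_d))
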