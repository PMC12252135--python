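"""MOT evaluation: MOTA, IDF1, HOTA, counting regression, Fréchet distance.

Ground truth and results are per-frame lists of ``(id, center_box)``.
Per-frame GT↔result matching follows the MOTChallenge convention: a
minimum-IoU-distance bipartite assignment among pairs with IoU at or above
the threshold (default 0.5), with a continuation preference — a pair
matched in an earlier frame is kept while it stays admissible, so identity
switches are counted against the last known correspondence of each
ground-truth identity.

The scores:

* ``MOTA = 1 - (FN + FP + IDSW) / GT`` — overall accuracy; can be negative.
* ``IDF1 = 2 IDTP / (2 IDTP + IDFP + IDFN)`` — identity precision/recall
  under the optimal global trajectory bipartite matching.
* ``HOTA`` — two variants: a single-threshold form
  ``sum_c A(c) / (TP + FN + FP)`` where ``A(c)`` is the association
  accuracy of each true-positive match (see :func:`hota_paper`), and the
  standard multi-threshold geometric-mean form (:func:`hota_standard`).
* counting ``R^2`` / RMSE and the discrete Fréchet distance between
  counting curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .association import iou_cost_matrix

__all__ = [
    "MatchCounts", "MetricReport", "match_frames", "mota", "idf1",
    "hota_paper", "hota_standard", "count_regression", "frechet", "evaluate",
]

FramesOf = dict[int, list]


def _norm(seq: FramesOf) -> dict[int, list[tuple[int, tuple]]]:
    """Accept (id, box) or (id, box, conf) rows; keep (id, box)."""
    return {f: [(r[0], tuple(r[1])) for r in rows] for f, rows in seq.items()}


@dataclass
class MatchCounts:
    """Tallies of the per-frame and identity-level GT↔result matching."""

    n_GT: int = 0
    n_TP: int = 0
    n_FN: int = 0
    n_FP: int = 0
    n_IDSW: int = 0
    n_IDTP: int = 0
    n_IDFP: int = 0
    n_IDFN: int = 0
    #: per-frame provenance: frame -> list of matched (gt_id, res_id)
    frame_matches: dict[int, list[tuple[int, int]]] = field(default_factory=dict, repr=False)
    #: per-frame id presence (for the association metrics)
    gt_frames: dict[int, list[int]] = field(default_factory=dict, repr=False)
    res_frames: dict[int, list[int]] = field(default_factory=dict, repr=False)


def _frame_matching(g_rows, r_rows, max_dist, prev_map):
    """One frame of MOTChallenge matching: continuation first, then LAP."""
    matches: list[tuple[int, int]] = []
    if not g_rows or not r_rows:
        return matches
    d = iou_cost_matrix([b for _, b in g_rows], [b for _, b in r_rows])
    admissible = d <= max_dist + 1e-12
    taken_g: set[int] = set()
    taken_r: set[int] = set()
    rid_to_idx = {}
    for j, (rid, _) in enumerate(r_rows):
        rid_to_idx.setdefault(rid, j)
    for i, (gid, _) in enumerate(g_rows):
        j = rid_to_idx.get(prev_map.get(gid))
        if j is not None and j not in taken_r and admissible[i, j]:
            matches.append((i, j))
            taken_g.add(i)
            taken_r.add(j)
    free_g = [i for i in range(len(g_rows)) if i not in taken_g]
    free_r = [j for j in range(len(r_rows)) if j not in taken_r]
    if free_g and free_r:
        sub = d[np.ix_(free_g, free_r)]
        big = 1e6
        solv = np.where(admissible[np.ix_(free_g, free_r)], sub, big)
        rows, cols = linear_sum_assignment(solv)
        for a, b in zip(rows, cols):
            if solv[a, b] < big:
                matches.append((free_g[a], free_r[b]))
    return matches


def match_frames(gt: FramesOf, res: FramesOf, iou_threshold: float = 0.5) -> MatchCounts:
    """Match GT and result boxes per frame and tally all metric counts.

    Matches require IoU >= ``iou_threshold``; an identity switch is counted
    whenever a ground-truth id's matched result id differs from its
    previous matched result id (gaps do not reset the memory).  Identity
    counts (IDTP/IDFP/IDFN) come from the optimal global trajectory
    bipartite matching.
    """
    gt = _norm(gt)
    res = _norm(res)
    g_max = max(gt, default=0)
    r_max = max(res, default=0)
    if res and gt and (r_max > g_max or min(res) < 1):
        raise ValueError(
            f"result frames [{min(res)}, {r_max}] exceed ground-truth range [1, {g_max}]"
        )
    n_frames = max(g_max, r_max)
    max_dist = 1.0 - iou_threshold

    mc = MatchCounts()
    prev_map: dict[int, int] = {}
    pair_frames: dict[tuple[int, int], int] = {}
    for frame in range(1, n_frames + 1):
        g_rows = gt.get(frame, [])
        r_rows = res.get(frame, [])
        matches = _frame_matching(g_rows, r_rows, max_dist, prev_map)
        mc.n_GT += len(g_rows)
        mc.n_TP += len(matches)
        mc.n_FN += len(g_rows) - len(matches)
        mc.n_FP += len(r_rows) - len(matches)
        fm = []
        for i, j in matches:
            gid, rid = g_rows[i][0], r_rows[j][0]
            if gid in prev_map and prev_map[gid] != rid:
                mc.n_IDSW += 1
            prev_map[gid] = rid
            fm.append((gid, rid))
            pair_frames[(gid, rid)] = pair_frames.get((gid, rid), 0) + 1
        mc.frame_matches[frame] = fm
        mc.gt_frames[frame] = [gid for gid, _ in g_rows]
        mc.res_frames[frame] = [rid for rid, _ in r_rows]

    mc.n_IDTP, mc.n_IDFP, mc.n_IDFN = _id_counts(gt, res, max_dist)
    return mc


def _id_counts(gt, res, max_dist):
    """Identity-level counts from the global trajectory bipartite matching.

    Trajectory pair overlap counts frames in which the two boxes meet the
    IoU threshold; the assignment (with dummy rows/columns for unmatched
    trajectories) maximizes total overlap, i.e. IDTP.
    """
    g_ids = sorted({gid for rows in gt.values() for gid, _ in rows})
    r_ids = sorted({rid for rows in res.values() for rid, _ in rows})
    g_len = {gid: 0 for gid in g_ids}
    r_len = {rid: 0 for rid in r_ids}
    overlap = np.zeros((len(g_ids), len(r_ids)))
    g_idx = {gid: i for i, gid in enumerate(g_ids)}
    r_idx = {rid: j for j, rid in enumerate(r_ids)}
    for frame in set(gt) | set(res):
        g_rows = gt.get(frame, [])
        r_rows = res.get(frame, [])
        for gid, _ in g_rows:
            g_len[gid] += 1
        for rid, _ in r_rows:
            r_len[rid] += 1
        if g_rows and r_rows:
            d = iou_cost_matrix([b for _, b in g_rows], [b for _, b in r_rows])
            ok = d <= max_dist + 1e-12
            for i, (gid, _) in enumerate(g_rows):
                for j, (rid, _) in enumerate(r_rows):
                    if ok[i, j]:
                        overlap[g_idx[gid], r_idx[rid]] += 1
    total_g = sum(g_len.values())
    total_r = sum(r_len.values())
    if not g_ids or not r_ids:
        return 0, total_r, total_g
    # maximize overlap == minimize (-overlap); dummies are implicit since
    # rectangular LAP leaves extras unmatched at zero overlap
    n = max(len(g_ids), len(r_ids))
    cost = np.zeros((n, n))
    cost[: len(g_ids), : len(r_ids)] = -overlap
    rows, cols = linear_sum_assignment(cost)
    idtp = int(-cost[rows, cols].sum())
    return idtp, total_r - idtp, total_g - idtp


def mota(c: MatchCounts) -> float:
    """Multiple Object Tracking Accuracy; NaN when there is no ground truth."""
    if c.n_GT == 0:
        return float("nan")
    return 1.0 - (c.n_FN + c.n_FP + c.n_IDSW) / c.n_GT


def idf1(c: MatchCounts) -> float:
    """Identity F1 score; NaN when both sequences are empty."""
    denom = 2 * c.n_IDTP + c.n_IDFP + c.n_IDFN
    if denom == 0:
        return float("nan")
    return 2.0 * c.n_IDTP / denom


def _pair_tallies(mc: MatchCounts):
    pair: dict[tuple[int, int], int] = {}
    g_tp: dict[int, int] = {}
    r_tp: dict[int, int] = {}
    for fm in mc.frame_matches.values():
        for gid, rid in fm:
            pair[(gid, rid)] = pair.get((gid, rid), 0) + 1
            g_tp[gid] = g_tp.get(gid, 0) + 1
            r_tp[rid] = r_tp.get(rid, 0) + 1
    return pair, g_tp, r_tp


def hota_paper(gt: FramesOf, res: FramesOf, iou_threshold: float = 0.5) -> float:
    """Single-threshold HOTA: sum of per-match association accuracies over all errors.

    Each true-positive match ``c`` between gt id ``g`` and result id ``r``
    scores ``A(c) = TPA / (TPA + FNA + FPA)``, where TPA counts matched
    frames of the same (g, r) pair and FNA / FPA count matched frames in
    which g (resp. r) is paired with a different partner.  The score is
    ``sum_c A(c) / (TP + FN + FP)`` — 1 exactly for perfect tracking, 0 for
    an empty result.
    """
    mc = match_frames(gt, res, iou_threshold)
    denom = mc.n_TP + mc.n_FN + mc.n_FP
    if denom == 0:
        return float("nan")
    pair, g_tp, r_tp = _pair_tallies(mc)
    total = 0.0
    for (gid, rid), tpa in pair.items():
        fna = g_tp[gid] - tpa
        fpa = r_tp[rid] - tpa
        total += tpa * (tpa / (tpa + fna + fpa))
    return total / denom


def hota_standard(gt: FramesOf, res: FramesOf,
                  alphas: np.ndarray | None = None) -> float:
    """Multi-threshold HOTA: mean over alpha of sqrt(DetA * AssA).

    At each IoU threshold alpha the frames are matched by a plain
    minimum-distance assignment; ``DetA = TP/(TP+FN+FP)`` and ``AssA`` is
    the mean over true positives of ``TPA / (|g| + |r| - TPA)`` with
    trajectory lengths in the denominator (misses and false alarms count
    as association errors here, unlike the single-threshold form).
    """
    gt = _norm(gt)
    res = _norm(res)
    if alphas is None:
        alphas = np.arange(0.05, 0.96, 0.05)
    n_frames = max(max(gt, default=0), max(res, default=0))
    g_len: dict[int, int] = {}
    r_len: dict[int, int] = {}
    for rows in gt.values():
        for gid, _ in rows:
            g_len[gid] = g_len.get(gid, 0) + 1
    for rows in res.values():
        for rid, _ in rows:
            r_len[rid] = r_len.get(rid, 0) + 1

    scores = []
    for alpha in alphas:
        tp = fn = fp = 0
        pair: dict[tuple[int, int], int] = {}
        for frame in range(1, n_frames + 1):
            g_rows = gt.get(frame, [])
            r_rows = res.get(frame, [])
            matches = _frame_matching(g_rows, r_rows, 1.0 - alpha, {})
            tp += len(matches)
            fn += len(g_rows) - len(matches)
            fp += len(r_rows) - len(matches)
            for i, j in matches:
                key = (g_rows[i][0], r_rows[j][0])
                pair[key] = pair.get(key, 0) + 1
        if tp + fn + fp == 0:
            scores.append(float("nan"))
            continue
        det_a = tp / (tp + fn + fp)
        if tp == 0:
            scores.append(0.0)
            continue
        ass_sum = sum(
            tpa * (tpa / (g_len[g] + r_len[r] - tpa)) for (g, r), tpa in pair.items()
        )
        ass_a = ass_sum / tp
        scores.append(float(np.sqrt(det_a * ass_a)))
    return float(np.nanmean(scores))


def count_regression(n_true, n_est) -> tuple[float, float, float, float]:
    """Counting agreement: (R^2, RMSE, OLS slope, OLS intercept).

    ``R^2 = 1 - sum (n - n_hat)^2 / sum (n - n_bar)^2`` measures how well
    the estimated per-frame counts track the true ones directly (not the
    regression fit); slope/intercept are the least-squares line of the
    estimate on the truth.  Zero-variance truth gives R^2 = NaN while RMSE
    is still returned.
    """
    n_true = np.asarray(n_true, dtype=float)
    n_est = np.asarray(n_est, dtype=float)
    if n_true.shape != n_est.shape or n_true.ndim != 1 or n_true.size < 2:
        raise ValueError("count series must be equal-length 1-D with N >= 2")
    sse = float(np.sum((n_true - n_est) ** 2))
    rmse = float(np.sqrt(sse / n_true.size))
    sst = float(np.sum((n_true - n_true.mean()) ** 2))
    r2 = float("nan") if sst == 0 else 1.0 - sse / sst
    if sst == 0:
        slope, intercept = float("nan"), float("nan")
    else:
        slope, intercept = (float(v) for v in np.polyfit(n_true, n_est, 1))
    return r2, rmse, slope, intercept


def frechet(curve_a, curve_b) -> float:
    """Discrete Fréchet distance between two polygonal curves.

    Standard O(mn) dynamic program over the coupling recurrence; curves
    are (n, d) point arrays (1-D input is treated as points on a line).
    Symmetric, zero iff the curves coincide pointwise under the optimal
    coupling.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Fréchet distance requires nonempty curves")
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    d = cdist(a, b)
    m, n = d.shape
    ca = np.empty((m, n))
    ca[0, 0] = d[0, 0]
    for i in range(1, m):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, n):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, m):
        for j in range(1, n):
            ca[i, j] = max(min(ca[i - 1, j], ca[i, j - 1], ca[i - 1, j - 1]), d[i, j])
    return float(ca[-1, -1])


def count_curve_points(counts) -> np.ndarray:
    """Lift a count series to raw (frame_index, count) curve points."""
    counts = np.asarray(counts, dtype=float)
    return np.column_stack([np.arange(1, counts.size + 1, dtype=float), counts])


@dataclass
class MetricReport:
    """Full evaluation summary for one sequence."""

    mota: float
    idf1: float
    hota: float
    hota_standard: float
    counts: MatchCounts
    r2: float = float("nan")
    rmse: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    frechet: float = float("nan")

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "MOTA": self.mota, "IDF1": self.idf1,
            "HOTA": self.hota, "HOTA_standard": self.hota_standard,
            "R2": self.r2, "RMSE": self.rmse,
            "slope": self.slope, "intercept": self.intercept,
            "frechet": self.frechet,
            "counts": {
                "GT": c.n_GT, "TP": c.n_TP, "FN": c.n_FN, "FP": c.n_FP,
                "IDSW": c.n_IDSW, "IDTP": c.n_IDTP, "IDFP": c.n_IDFP, "IDFN": c.n_IDFN,
            },
        }


def evaluate(
    gt: FramesOf,
    res: FramesOf,
    counts_est=None,
    counts_true=None,
    iou_threshold: float = 0.5,
) -> MetricReport:
    """Compute the full tracking + counting report for one sequence."""
    mc = match_frames(gt, res, iou_threshold)
    report = MetricReport(
        mota=mota(mc),
        idf1=idf1(mc),
        hota=hota_paper(gt, res, iou_threshold),
        hota_standard=hota_standard(gt, res),
        counts=mc,
    )
    if counts_est is not None and counts_true is not None:
        r2, rmse, slope, intercept = count_regression(counts_true, counts_est)
        report.r2, report.rmse = r2, rmse
        report.slope, report.intercept = slope, intercept
        report.frechet = frechet(
            count_curve_points(counts_true), count_curve_points(counts_est)
        )
    return report
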