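"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the textbook definitions with
its own arithmetic (plain loops, top-left boxes, explicit matrix inverses)
so it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment


# ---------------------------------------------------------------------------
# textbook Kalman filter (standard predict/update, no fading memory)

class TextbookKF:
    """Plain linear Kalman filter over the 8-state constant-velocity model."""

    def __init__(self, box, w_p, w_v, dt=1.0):
        x, y, w, h = box
        self.x = np.array([x, y, w, h, 0.0, 0.0, 0.0, 0.0])
        spx, spy = 2 * w_p * w, 2 * w_p * h
        svx, svy = 10 * w_v * w, 10 * w_v * h
        sp2 = spx * spx + spy * spy
        sv2 = svx * svx + svy * svy
        self.P = np.diag([sp2, sp2, sp2, sp2, sv2, sv2, sv2, sv2])
        self.F = np.eye(8)
        for i in range(4):
            self.F[i, i + 4] = dt
        self.H = np.zeros((4, 8))
        for i in range(4):
            self.H[i, i] = 1.0
        self.w_p, self.w_v = w_p, w_v

    def _Q(self):
        w, h = self.x[2], self.x[3]
        d = [self.w_p * w, self.w_p * h, self.w_p * w, self.w_p * h,
             self.w_v * w, self.w_v * h, self.w_v * w, self.w_v * h]
        return np.diag(np.square(d))

    def _S(self):
        w, h = self.x[2], self.x[3]
        sp2 = (2 * self.w_p * w) ** 2 + (2 * self.w_p * h) ** 2
        return sp2 * np.eye(4)

    def predict(self):
        Q = self._Q()
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + Q
        return self.x.copy(), self.P.copy()

    def update(self, z):
        S_obs = self._S()
        innov_cov = self.H @ self.P @ self.H.T + S_obs
        K = self.P @ self.H.T @ np.linalg.inv(innov_cov)
        self.x = self.x + K @ (np.asarray(z, float) - self.H @ self.x)
        self.P = (np.eye(8) - K @ self.H) @ self.P
        return self.x.copy(), self.P.copy()


# ---------------------------------------------------------------------------
# brute-force assignment

def brute_force_assign(costs: np.ndarray, gate: float):
    """Exhaustive optimal assignment: enumerate every complete injection.

    The optimum minimizes (number of inadmissible pairs, total admissible
    cost) lexicographically — i.e. inadmissible pairs are avoided whenever
    possible, then total cost is minimized — and the returned matches are
    the assigned pairs that are admissible and within the gate.  Unique for
    generic (tie-free) random matrices.  Feasible up to ~6x6.
    """
    costs = np.asarray(costs, float)
    T, D = costs.shape
    best_key, best_pairs = None, []
    if T <= D:
        candidates = (tuple(zip(range(T), cols))
                      for cols in itertools.permutations(range(D), T))
    else:
        candidates = (tuple(zip(rows, range(D)))
                      for rows in itertools.permutations(range(T), D))
    for pairs in candidates:
        n_inf = sum(1 for i, j in pairs if not np.isfinite(costs[i, j]))
        total = sum(costs[i, j] for i, j in pairs if np.isfinite(costs[i, j]))
        key = (n_inf, total)
        if best_key is None or key < best_key:
            best_key = key
            best_pairs = pairs
    matches = sorted(
        (i, j) for i, j in best_pairs
        if np.isfinite(costs[i, j]) and costs[i, j] <= gate
    )
    return matches


# ---------------------------------------------------------------------------
# CLEAR-MOT + identity metrics, written from the published definitions

def _iou_tl(a, b):
    """IoU of two (left, top, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    x1, y1 = max(ax, bx), max(ay, by)
    x2, y2 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    if x2 <= x1 or y2 <= y1:
        return 0.0
    inter = (x2 - x1) * (y2 - y1)
    return inter / (aw * ah + bw * bh - inter)


def _to_tl(center_box):
    x, y, w, h = center_box
    return (x - w / 2, y - h / 2, w, h)


def clear_mot(gt, res, iou_threshold=0.5):
    """CLEAR-MOT tallies (GT, TP, FN, FP, IDSW, MOTA) from per-frame dicts.

    Per frame: correspondences from the previous frame are kept while they
    remain valid (IoU >= threshold); remaining objects are matched by a
    minimum-distance assignment.  An identity switch is counted when a
    ground-truth object's match differs from its last known match.
    """
    frames = sorted(set(gt) | set(res))
    last = {}
    GT = TP = FN = FP = IDSW = 0
    for f in frames:
        g_rows = [(i, _to_tl(b)) for i, b in gt.get(f, [])]
        r_rows = [(r[0], _to_tl(r[1])) for r in res.get(f, [])]
        GT += len(g_rows)
        matched_g, matched_r, frame_pairs = set(), set(), {}
        # carry over still-valid correspondences
        r_by_id = {rid: k for k, (rid, _) in enumerate(r_rows)}
        for gi, (gid, gbox) in enumerate(g_rows):
            rid = last.get(gid)
            if rid in r_by_id:
                k = r_by_id[rid]
                if k not in matched_r and _iou_tl(gbox, r_rows[k][1]) >= iou_threshold:
                    matched_g.add(gi)
                    matched_r.add(k)
                    frame_pairs[gid] = rid
        # LAP on the rest
        free_g = [i for i in range(len(g_rows)) if i not in matched_g]
        free_r = [k for k in range(len(r_rows)) if k not in matched_r]
        if free_g and free_r:
            BIG = 1e9
            cost = np.full((len(free_g), len(free_r)), BIG)
            for a, gi in enumerate(free_g):
                for b, k in enumerate(free_r):
                    iou = _iou_tl(g_rows[gi][1], r_rows[k][1])
                    if iou >= iou_threshold:
                        cost[a, b] = 1.0 - iou
            ri, ci = linear_sum_assignment(cost)
            for a, b in zip(ri, ci):
                if cost[a, b] < BIG:
                    gid = g_rows[free_g[a]][0]
                    rid = r_rows[free_r[b]][0]
                    frame_pairs[gid] = rid
        TP += len(frame_pairs)
        FN += len(g_rows) - len(frame_pairs)
        FP += len(r_rows) - len(frame_pairs)
        for gid, rid in frame_pairs.items():
            if gid in last and last[gid] != rid:
                IDSW += 1
            last[gid] = rid
    mota = 1.0 - (FN + FP + IDSW) / GT if GT else float("nan")
    return dict(GT=GT, TP=TP, FN=FN, FP=FP, IDSW=IDSW, MOTA=mota)


def id_scores(gt, res, iou_threshold=0.5):
    """IDTP/IDFP/IDFN and IDF1 via the explicit square bipartite construction.

    Builds the (n_gt + n_res) x (n_res + n_gt) cost matrix with dummy
    rows/columns whose cost equals trajectory length, then minimizes total
    mismatches.
    """
    g_ids = sorted({i for rows in gt.values() for i, _ in rows})
    r_ids = sorted({r[0] for rows in res.values() for r in rows})
    g_len = {i: 0 for i in g_ids}
    r_len = {i: 0 for i in r_ids}
    overlap = {}
    frames = sorted(set(gt) | set(res))
    for f in frames:
        g_rows = [(i, _to_tl(b)) for i, b in gt.get(f, [])]
        r_rows = [(r[0], _to_tl(r[1])) for r in res.get(f, [])]
        for gid, _ in g_rows:
            g_len[gid] += 1
        for rid, _ in r_rows:
            r_len[rid] += 1
        for gid, gbox in g_rows:
            for rid, rbox in r_rows:
                if _iou_tl(gbox, rbox) >= iou_threshold:
                    overlap[(gid, rid)] = overlap.get((gid, rid), 0) + 1
    ng, nr = len(g_ids), len(r_ids)
    N = ng + nr
    BIG = 1e9
    cost = np.full((N, N), 0.0)
    for a in range(ng):
        for b in range(nr):
            m = overlap.get((g_ids[a], r_ids[b]), 0)
            cost[a, b] = (g_len[g_ids[a]] - m) + (r_len[r_ids[b]] - m)
        for b in range(nr, N):
            cost[a, b] = g_len[g_ids[a]] if b - nr == a else BIG
    for a in range(ng, N):
        for b in range(nr):
            cost[a, b] = r_len[r_ids[b]] if a - ng == b else BIG
        # dummy-dummy cost stays 0
    ri, ci = linear_sum_assignment(cost)
    idtp = 0
    for a, b in zip(ri, ci):
        if a < ng and b < nr:
            idtp += overlap.get((g_ids[a], r_ids[b]), 0)
    total_g = sum(g_len.values())
    total_r = sum(r_len.values())
    idfn = total_g - idtp
    idfp = total_r - idtp
    denom = 2 * idtp + idfp + idfn
    idf1 = 2 * idtp / denom if denom else float("nan")
    return dict(IDTP=idtp, IDFP=idfp, IDFN=idfn, IDF1=idf1)


# ---------------------------------------------------------------------------
# least-squares affine fit (closed form, no RANSAC)

def affine_lstsq(p, q):
    """2x3 affine minimizing sum ||A [p;1] - q||^2 via the normal equations."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    X = np.column_stack([p, np.ones(len(p))])
    coef = np.linalg.solve(X.T @ X, X.T @ q)
    return coef.T  # (2, 3)


# ---------------------------------------------------------------------------
# plain IoU + Kalman baseline tracker (no fading memory, camera, or features)

class SimpleIoUTracker:
    """Reference tracker: textbook KF + gated IoU Hungarian + the same lifecycle.

    Mirrors the documented lifecycle semantics with straightforward loops:
    n_init consecutive hits confirm, tentative tracks die on a miss,
    confirmed tracks coast until max_age misses.
    """

    def __init__(self, w_p, w_v, theta_iou, match_gate, n_init, max_age):
        self.params = (w_p, w_v)
        self.theta_iou = theta_iou
        self.match_gate = match_gate
        self.n_init = n_init
        self.max_age = max_age
        self.tracks = []  # dicts: id, kf, hits, misses, confirmed, dead
        self.next_id = 1
        self.rows = {}
        self.frame = 0

    def _alive(self):
        return [t for t in self.tracks if not t["dead"]]

    def step(self, det_boxes):
        self.frame += 1
        alive = self._alive()
        for t in alive:
            t["kf"].predict()
        cost = np.full((len(alive), len(det_boxes)), np.inf)
        for i, t in enumerate(alive):
            for j, b in enumerate(det_boxes):
                d = 1.0 - _iou_tl(_to_tl(t["kf"].x[:4]), _to_tl(b))
                if d <= self.theta_iou:
                    cost[i, j] = d
        matches = []
        if cost.size:
            BIG = 1e6
            ri, ci = linear_sum_assignment(np.where(np.isfinite(cost), cost, BIG))
            for i, j in zip(ri, ci):
                if np.isfinite(cost[i, j]) and cost[i, j] <= self.match_gate:
                    matches.append((i, j))
        matched_t = {i for i, _ in matches}
        matched_d = {j for _, j in matches}
        out = []
        for i, j in matches:
            t = alive[i]
            t["kf"].update(det_boxes[j])
            t["hits"] += 1
            t["misses"] = 0
            if not t["confirmed"] and t["hits"] >= self.n_init:
                t["confirmed"] = True
            if t["confirmed"]:
                out.append((t["id"], tuple(t["kf"].x[:4]), 1.0))
        for i, t in enumerate(alive):
            if i in matched_t:
                continue
            t["misses"] += 1
            if not t["confirmed"] or t["misses"] > self.max_age:
                t["dead"] = True
        for j, b in enumerate(det_boxes):
            if j in matched_d:
                continue
            kf = TextbookKF(b, *self.params)
            confirmed = self.n_init <= 1
            self.tracks.append(dict(id=self.next_id, kf=kf, hits=1, misses=0,
                                    confirmed=confirmed, dead=False))
            if confirmed:
                out.append((self.next_id, tuple(kf.x[:4]), 1.0))
            self.next_id += 1
        self.rows[self.frame] = sorted(out, key=lambda r: r[0])
        return out
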