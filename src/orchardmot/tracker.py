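"""Per-frame tracking loop and fruit counting.

Each frame runs predict → camera compensation → fused association →
update → lifecycle bookkeeping.  Identities follow the usual
tentative / confirmed / lost / removed lifecycle: a new detection spawns a
tentative track, ``n_init`` consecutive hits confirm it, a confirmed track
that misses coasts as *lost* (still predicted, compensated, and eligible
for re-association) until ``max_age`` consecutive misses remove it.
Fruit counts are derived from confirmed identities: the cumulative curve
counts distinct ids ever confirmed, the active curve counts confirmed ids
currently matched or coasting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import kalman
from .association import assign, fuse_costs, iou_cost_matrix, reid_cost_matrix, smooth_feature
from .camera import AffineTransform, compensate_box, estimate_affine, mutual_nearest_pairs
from .config import TrackerConfig
from .io import Detection, SequenceBundle
from .kalman import MotionModel, NoiseModel, TrackState

__all__ = ["TrackStatus", "Track", "Tracker", "TrackingResult", "run", "count_curves"]


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    LOST = "lost"
    REMOVED = "removed"


@dataclass
class Track:
    """A tracked identity with filter state, appearance, and lifecycle counters."""

    id: int
    state: TrackState
    f_bar: np.ndarray | None = None
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    misses: int = 0
    first_frame: int = 0
    last_frame: int = 0
    confirmed_frame: int | None = None

    @property
    def ever_confirmed(self) -> bool:
        return self.confirmed_frame is not None


@dataclass
class TrackingResult:
    """Per-frame confirmed-track rows plus the two counting curves."""

    n_frames: int
    rows: dict[int, list[tuple[int, tuple[float, float, float, float], float]]] = field(default_factory=dict)
    cumulative: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    active: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


class Tracker:
    """Stateful multi-object tracker; call :meth:`step` once per frame."""

    def __init__(self, config: TrackerConfig | None = None, seed: int | None = None):
        self.config = (config or TrackerConfig()).validate()
        self.nm = NoiseModel.from_config(self.config.kalman)
        self.mm = MotionModel(self.nm)
        self.tracks: list[Track] = []
        self._next_id = 1
        self._frame = 0
        self.rng = np.random.default_rng(self.config.seed if seed is None else seed)
        self._confirmed_ids: set[int] = set()

    # -- lifecycle helpers -------------------------------------------------

    def _spawn(self, det: Detection, frame: int) -> Track:
        t = Track(
            id=self._next_id,
            state=kalman.init_track(det, self.nm),
            f_bar=None if det.feature is None else det.feature.copy(),
            first_frame=frame,
            last_frame=frame,
        )
        self._next_id += 1
        if self.config.tracker.n_init <= 1:
            t.status = TrackStatus.CONFIRMED
            t.confirmed_frame = frame
            self._confirmed_ids.add(t.id)
        self.tracks.append(t)
        return t

    def _alive(self) -> list[Track]:
        return [t for t in self.tracks if t.status is not TrackStatus.REMOVED]

    # -- the per-frame loop ------------------------------------------------

    def step(self, frame_dets: list[Detection], A: AffineTransform | None = None) -> list[Track]:
        """Advance one frame; returns the tracks matched in this frame."""
        self._frame += 1
        frame = self._frame
        cfg = self.config
        alive = self._alive()

        # 1) predict, 2) compensate predicted boxes into the current frame
        prev_states = {t.id: t.state for t in alive}
        predicted: dict[int, TrackState] = {}
        for t in alive:
            s_minus = kalman.predict(t.state, self.mm)
            if A is not None and cfg.camera.enabled and not A.is_identity:
                s_minus.X[:4] = compensate_box(
                    tuple(s_minus.X[:4]), A, inverse_scale=cfg.camera.inverse_scale
                )
            predicted[t.id] = s_minus

        if cfg.tracker.two_stage:
            high = [d for d in frame_dets if d.confidence >= cfg.tracker.high_conf]
            low = [d for d in frame_dets if d.confidence < cfg.tracker.high_conf]
        else:
            high, low = list(frame_dets), []

        # 3) fused association
        matches, um_tracks, um_dets = self._associate(alive, predicted, high)
        matched_pairs = [(alive[i], high[j]) for i, j in matches]

        # optional second stage: motion-only on low-confidence detections
        if low and um_tracks:
            rem = [alive[i] for i in um_tracks]
            d_iou = iou_cost_matrix(
                [predicted[t.id].box for t in rem], [d.box for d in low]
            )
            fused = fuse_costs(d_iou, None, theta_iou=0.5)
            a2 = assign(fused, match_gate=0.5)
            matched_pairs += [(rem[i], low[j]) for i, j in a2.matches]
            um_tracks = [um_tracks[i] for i in a2.unmatched_tracks]

        matched_ids = set()
        for t, det in matched_pairs:
            # 4) fading-memory update + appearance smoothing
            t.state = kalman.update(
                predicted[t.id], np.asarray(det.box, dtype=float),
                prev_states[t.id], self.mm, self.nm,
            )
            if det.feature is not None:
                t.f_bar = (
                    det.feature.copy() if t.f_bar is None
                    else smooth_feature(t.f_bar, det.feature, cfg.assoc.alpha)
                )
            t.hits += 1
            t.misses = 0
            t.last_frame = frame
            if t.status is TrackStatus.LOST:
                t.status = TrackStatus.CONFIRMED
            elif t.status is TrackStatus.TENTATIVE and t.hits >= cfg.tracker.n_init:
                t.status = TrackStatus.CONFIRMED
                t.confirmed_frame = frame
                self._confirmed_ids.add(t.id)
            matched_ids.add(t.id)

        # 6) unmatched tracks miss, coast, or die
        for t in alive:
            if t.id in matched_ids:
                continue
            t.state = kalman.coast(predicted[t.id])
            t.misses += 1
            if t.status is TrackStatus.TENTATIVE:
                t.status = TrackStatus.REMOVED
            else:
                t.status = TrackStatus.LOST
                if t.misses > cfg.tracker.max_age:
                    t.status = TrackStatus.REMOVED

        # 5) unmatched detections spawn tentative tracks
        spawned = []
        for j in um_dets:
            spawned.append(self._spawn(high[j], frame))
        # low-confidence leftovers never spawn tracks (they only sustain)

        return [t for t, _ in matched_pairs] + [
            t for t in spawned if t.status is TrackStatus.CONFIRMED
        ]

    def _associate(self, alive, predicted, dets):
        cfg = self.config
        track_boxes = [predicted[t.id].box for t in alive]
        det_boxes = [d.box for d in dets]
        d_iou = iou_cost_matrix(track_boxes, det_boxes)
        track_feats = [t.f_bar for t in alive]
        det_feats = [d.feature for d in dets]
        use_reid = any(f is not None for f in track_feats) and any(
            f is not None for f in det_feats
        )
        d_reid = reid_cost_matrix(track_feats, det_feats) if use_reid else None
        fused = fuse_costs(
            d_iou, d_reid,
            theta_iou=cfg.assoc.theta_iou,
            theta_reid=cfg.assoc.theta_reid,
            strict_reid_filter=cfg.assoc.strict_reid_filter,
        )
        a = assign(fused, match_gate=cfg.assoc.match_gate)
        return a.matches, a.unmatched_tracks, a.unmatched_detections

    # -- bookkeeping -------------------------------------------------------

    @property
    def cumulative_count(self) -> int:
        return len(self._confirmed_ids)

    def active_count(self) -> int:
        return sum(
            1 for t in self.tracks
            if t.ever_confirmed and t.status in (TrackStatus.CONFIRMED, TrackStatus.LOST)
        )


def _frame_pairs(bundle: SequenceBundle, frame: int, cfg: TrackerConfig) -> np.ndarray:
    """Point correspondences for camera estimation at ``frame``."""
    source = cfg.camera.source
    if source in ("sidecar", "auto") and bundle.correspondences:
        pairs = bundle.correspondences.get(frame)
        if pairs is not None and len(pairs) > 0:
            return pairs
        if source == "sidecar":
            return np.empty((0, 4))
    if source in ("detections", "auto"):
        prev = np.array([d.box[:2] for d in bundle.dets_at(frame - 1)], dtype=float)
        curr = np.array([d.box[:2] for d in bundle.dets_at(frame)], dtype=float)
        return mutual_nearest_pairs(prev.reshape(-1, 2), curr.reshape(-1, 2))
    return np.empty((0, 4))


def run(bundle: SequenceBundle, config: TrackerConfig | None = None,
        seed: int | None = None) -> TrackingResult:
    """Track a whole sequence and derive counting curves.

    The global affine is re-estimated every frame from the bundle's
    correspondences (sidecar, detection-center prematch, or both —
    ``camera.source``); identities and output are fully deterministic for
    a fixed seed.  Result rows contain confirmed tracks matched in the
    frame.
    """
    config = (config or TrackerConfig()).validate()
    tracker = Tracker(config, seed=seed)
    n = bundle.n_frames
    result = TrackingResult(n_frames=n)
    cumulative = np.zeros(n, dtype=int)
    active = np.zeros(n, dtype=int)
    for frame in bundle.frames():
        dets = bundle.dets_at(frame)
        A = None
        if config.camera.enabled and frame > 1:
            pairs = _frame_pairs(bundle, frame, config)
            A = estimate_affine(pairs, config.camera.ransac, seed=tracker.rng)
        matched = tracker.step(dets, A)
        result.rows[frame] = [
            (t.id, t.state.box, 1.0)
            for t in sorted(matched, key=lambda t: t.id)
            if t.status is TrackStatus.CONFIRMED
        ]
        cumulative[frame - 1] = tracker.cumulative_count
        active[frame - 1] = tracker.active_count()
    result.cumulative = cumulative
    result.active = active
    return result


def count_curves(result: TrackingResult) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative, active) per-frame counting curves of a tracking run."""
    return result.cumulative, result.active
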