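"""Tracker loop: lifecycle, counting, occlusion robustness, baseline equivalence."""

import numpy as np
import pytest

from orchardmot import (
    Detection,
    ScenarioConfig,
    SequenceBundle,
    Tracker,
    count_curves,
    generate,
    run,
    write_tracks,
)
from orchardmot.config import config_from_dict
from orchardmot.metrics import match_frames
from orchardmot.tracker import TrackStatus

from .conftest import res_rows_to_seq
from .reference import SimpleIoUTracker


def bundle_from_boxes(frames_boxes, features=None, n_frames=None):
    """frames_boxes: {frame: [box, ...]}; features: {frame: [vec|None, ...]}."""
    dets = {}
    for f, boxes in frames_boxes.items():
        feats = (features or {}).get(f, [None] * len(boxes))
        dets[f] = [Detection(f, b, 0.9, feat) for b, feat in zip(boxes, feats)]
    return SequenceBundle(detections=dets,
                          n_frames=n_frames or max(frames_boxes, default=0))


def no_camera_config(**tracker_kw):
    return config_from_dict({"camera": {"enabled": False},
                             "tracker": tracker_kw})


class TestStep:
    def test_first_detection_spawns_tentative_zero_velocity(self):
        t = Tracker(no_camera_config())
        t.step([Detection(1, (10, 10, 8, 8), 0.9)])
        (trk,) = t.tracks
        assert trk.status is TrackStatus.TENTATIVE
        np.testing.assert_array_equal(trk.state.X[4:], 0.0)
        assert trk.id == 1

    def test_confirmed_track_coasts_on_empty_frame(self):
        t = Tracker(no_camera_config(n_init=1, max_age=5))
        t.step([Detection(1, (10, 10, 8, 8), 0.9)])
        t.step([Detection(2, (12, 10, 8, 8), 0.9)])
        before = t.tracks[0].state.X.copy()
        t.step([])
        trk = t.tracks[0]
        assert trk.misses == 1 and trk.status is TrackStatus.LOST
        # box is the (uncompensated) prediction: position advanced by velocity
        np.testing.assert_allclose(trk.state.X[:4], before[:4] + before[4:], atol=1e-9)

    def test_confirmation_at_n_init_keeps_id(self):
        t = Tracker(no_camera_config(n_init=2))
        t.step([Detection(1, (10, 10, 8, 8), 0.9)])
        assert t.tracks[0].status is TrackStatus.TENTATIVE
        t.step([Detection(2, (10, 10, 8, 8), 0.9)])
        assert t.tracks[0].status is TrackStatus.CONFIRMED
        assert t.tracks[0].id == 1 and len(t.tracks) == 1
        assert t.tracks[0].confirmed_frame == 2

    def test_tentative_track_dies_on_first_miss(self):
        t = Tracker(no_camera_config(n_init=3))
        t.step([Detection(1, (10, 10, 8, 8), 0.9)])
        t.step([])
        assert t.tracks[0].status is TrackStatus.REMOVED

    def test_lost_track_removed_after_max_age(self):
        t = Tracker(no_camera_config(n_init=1, max_age=2))
        t.step([Detection(1, (10, 10, 8, 8), 0.9)])
        for _ in range(2):
            t.step([])
            assert t.tracks[0].status is TrackStatus.LOST
        t.step([])
        assert t.tracks[0].status is TrackStatus.REMOVED


class TestRun:
    def test_empty_sequence(self):
        res = run(SequenceBundle(n_frames=0), no_camera_config())
        assert res.rows == {} and res.cumulative.size == 0

    def test_five_clean_fruits_five_ids(self):
        frames = {
            f: [(100 + 120 * k + 2.0 * f, 100 + 40 * k, 20, 20) for k in range(5)]
            for f in range(1, 31)
        }
        res = run(bundle_from_boxes(frames), no_camera_config())
        ids = {i for rows in res.rows.values() for i, _, _ in rows}
        assert len(ids) == 5
        assert res.cumulative[-1] == 5
        gt = {f: [(k + 1, b) for k, b in enumerate(boxes)] for f, boxes in frames.items()}
        mc = match_frames(gt, res_rows_to_seq(res.rows))
        assert mc.n_IDSW == 0

    def test_counting_curve_hand_trace(self):
        # single target present frames 1..5, n_init=3: confirmed at frame 3
        frames = {f: [(50, 50, 10, 10)] for f in range(1, 6)}
        res = run(bundle_from_boxes(frames), no_camera_config(n_init=3))
        cum, active = count_curves(res)
        np.testing.assert_array_equal(cum, [0, 0, 1, 1, 1])
        np.testing.assert_array_equal(active, [0, 0, 1, 1, 1])

    def test_counting_curves_with_staggered_tracks(self):
        # two targets from frame 1, a third from frame 4; first two confirmed
        # immediately (n_init=1); target B vanishes after frame 2 and is
        # removed once its misses exceed max_age=1 (i.e. at frame 4)
        frames = {
            1: [(50, 50, 10, 10), (200, 50, 10, 10)],
            2: [(50, 50, 10, 10), (200, 50, 10, 10)],
            3: [(50, 50, 10, 10)],
            4: [(50, 50, 10, 10), (400, 200, 10, 10)],
            5: [(50, 50, 10, 10), (400, 200, 10, 10)],
        }
        res = run(bundle_from_boxes(frames), no_camera_config(n_init=1, max_age=1))
        cum, active = count_curves(res)
        np.testing.assert_array_equal(cum, [2, 2, 2, 3, 3])
        np.testing.assert_array_equal(active, [2, 2, 2, 2, 2])
        # at frame 3 target B is lost but still active; at 4 it is removed
        # while the new target C enters

    def test_cumulative_nondecreasing_and_ids_never_reused(self, small_scene):
        _, bundle, _ = small_scene
        res = run(bundle, seed=0)
        assert np.all(np.diff(res.cumulative) >= 0)
        assert np.all(res.active <= res.cumulative)
        first_seen = {}
        for f in sorted(res.rows):
            for i, _, _ in res.rows[f]:
                first_seen.setdefault(i, f)
        # an id's appearances form one contiguous-in-creation-order block:
        # creation order matches first appearance order
        order = [i for i, _ in sorted(first_seen.items(), key=lambda kv: kv[1])]
        assert order == sorted(order)

    def test_determinism_byte_identical_outputs(self, tmp_path, small_scene):
        _, bundle, _ = small_scene
        paths = []
        for name in ("r1.txt", "r2.txt"):
            res = run(bundle, seed=123)
            p = tmp_path / name
            write_tracks(res.rows, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestOcclusion:
    @staticmethod
    def _scene_with_gap(gap):
        cfg = ScenarioConfig(n_frames=90, miss_rate=0.0, clutter_rate=0.0,
                             box_noise=0.5, occlusion_prob=1.0,
                             occlusion_len=(gap, gap), seed=31)
        return generate(cfg)

    def test_gaps_within_max_age_zero_fragmentation(self):
        bundle, truth = self._scene_with_gap(gap=10)
        res = run(bundle, config_from_dict({"tracker": {"max_age": 30}}), seed=1)
        mc = match_frames(bundle.ground_truth, res_rows_to_seq(res.rows))
        mapping = {}
        for fm in mc.frame_matches.values():
            for g, r in fm:
                mapping.setdefault(g, set()).add(r)
        assert all(len(v) == 1 for v in mapping.values())
        assert res.cumulative[-1] == truth.n_fruits

    def test_gaps_beyond_max_age_fragment(self):
        bundle, truth = self._scene_with_gap(gap=25)
        res = run(bundle, config_from_dict({"tracker": {"max_age": 8}}), seed=1)
        mc = match_frames(bundle.ground_truth, res_rows_to_seq(res.rows))
        mapping = {}
        for fm in mc.frame_matches.values():
            for g, r in fm:
                mapping.setdefault(g, set()).add(r)
        assert any(len(v) > 1 for v in mapping.values())


def crossing_bundle(with_features):
    """Two equal-size targets approach, bounce apart, and separate.

    Embeddings are orthogonal (inter-identity cosine distance 1.0) while
    box noise keeps intra-identity appearance nearly exact — the regime in
    which appearance should disambiguate the spatially ambiguous bounce.
    """
    rng = np.random.default_rng(8)
    n, mid, speed, dy, side = 40, 20, 3.0, 4.0, 24.0
    meet = speed * (mid - 1)
    frames, feats = {}, {}
    fa = np.zeros(8)
    fa[0] = 1.0
    fb = np.zeros(8)
    fb[1] = 1.0
    for f in range(1, n + 1):
        t = f - 1
        xa = speed * t if t < mid else meet - speed * (t - mid + 1)
        xb = 2 * meet - speed * t if t < mid else meet + speed * (t - mid + 1)
        frames[f] = [
            (xa + rng.normal(0, 0.3), 100.0 + rng.normal(0, 0.3), side, side),
            (xb + rng.normal(0, 0.3), 100.0 + dy + rng.normal(0, 0.3), side, side),
        ]
        feats[f] = [fa, fb] if with_features else [None, None]
    gt = {f: [(1, b[0]), (2, b[1])] for f, b in frames.items()}
    return bundle_from_boxes(frames, feats), gt


def test_reid_fusion_prevents_crossing_id_switch():
    cfg = no_camera_config(n_init=1)
    bundle_iou, gt = crossing_bundle(with_features=False)
    bundle_fused, _ = crossing_bundle(with_features=True)
    sw_iou = match_frames(gt, res_rows_to_seq(run(bundle_iou, cfg).rows)).n_IDSW
    sw_fused = match_frames(gt, res_rows_to_seq(run(bundle_fused, cfg).rows)).n_IDSW
    assert sw_iou >= 1
    assert sw_fused == 0


def test_camera_compensation_reduces_id_switches():
    """A camera pan that reverses during a detection dropout.

    Constant-velocity coasting extrapolates the old apparent motion and
    drifts away from the targets; per-frame affine compensation follows the
    reversal through the dropout and keeps every identity.
    """
    rng = np.random.default_rng(3)
    n = 60
    world = np.array([[100.0 + 150 * k, 100.0 + 37 * (k % 3)] for k in range(6)])
    pans = np.where(np.arange(1, n + 1) < 22, 6.0, -6.0)  # reversal mid-dropout
    offs = np.concatenate([[0.0], np.cumsum(pans[1:])])
    frames, corr = {}, {}
    for f in range(1, n + 1):
        off = offs[f - 1]
        if 20 <= f <= 26:  # dropout: tracks must coast through camera motion
            frames[f] = []
        else:
            frames[f] = [(x - off, y, 22, 22) for x, y in world]
        if f > 1:
            pts = rng.uniform((0, 0), (800, 400), size=(10, 2))
            corr[f] = np.hstack([pts, pts + [pans[f - 1], 0.0]])
    bundle = bundle_from_boxes(frames, n_frames=n)
    bundle.correspondences = corr
    gt = {f: [(k + 1, b) for k, b in enumerate(boxes)] for f, boxes in frames.items()}

    cfg_on = config_from_dict({"camera": {"source": "sidecar"}})
    cfg_off = config_from_dict({"camera": {"enabled": False}})
    frag = {}
    for name, cfg in (("on", cfg_on), ("off", cfg_off)):
        res = run(bundle, cfg, seed=2)
        mc = match_frames(gt, res_rows_to_seq(res.rows))
        mapping = {}
        for fm in mc.frame_matches.values():
            for g, r in fm:
                mapping.setdefault(g, set()).add(r)
        frag[name] = sum(len(v) - 1 for v in mapping.values()) + mc.n_IDSW
    assert frag["on"] < frag["off"]


def test_baseline_equivalence_reduces_to_plain_iou_kf_tracker(small_scene):
    """gamma=0, camera off, no features: run() equals an independent IoU+KF tracker."""
    _, bundle, _ = small_scene
    stripped = SequenceBundle(
        detections={
            f: [Detection(d.frame, d.box, d.confidence) for d in dets]
            for f, dets in bundle.detections.items()
        },
        n_frames=bundle.n_frames,
    )
    cfg = config_from_dict({
        "kalman": {"gamma": 0.0},
        "camera": {"enabled": False},
    })
    res = run(stripped, cfg, seed=0)

    ref = SimpleIoUTracker(
        w_p=cfg.kalman.w_p, w_v=cfg.kalman.w_v,
        theta_iou=cfg.assoc.theta_iou, match_gate=cfg.assoc.match_gate,
        n_init=cfg.tracker.n_init, max_age=cfg.tracker.max_age,
    )
    for f in stripped.frames():
        ref.step([d.box for d in stripped.dets_at(f)])

    assert set(res.rows) == set(ref.rows)
    for f in stripped.frames():
        got = res.rows[f]
        want = ref.rows[f]
        assert [i for i, _, _ in got] == [i for i, _, _ in want], f"frame {f}"
        np.testing.assert_allclose(
            np.array([b for _, b, _ in got]).reshape(-1, 4),
            np.array([b for _, b, _ in want]).reshape(-1, 4),
            rtol=1e-6, atol=1e-6,
        )
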