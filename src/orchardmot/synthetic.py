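"""Seeded synthetic orchard scenarios for offline testing of the pipeline.

The generator emulates the structure of a fruit-counting fly-by video:
~10 fps, a few hundred frames, several trees whose fruits are near-static
in the world while a panning (optionally zooming) camera sweeps past, so
apparent motion is dominated by global camera translation.  On top of the
clean geometry it simulates an imperfect detector (Gaussian box noise,
missed detections, clutter false positives with realistic sizes), per-fruit
occlusion gaps, and appearance embeddings (a fixed unit vector per identity
plus intra-identity noise, with a minimum inter-identity separation).

One global seed fans out to independent per-component substreams, so e.g.
toggling clutter does not change trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Detection, SequenceBundle, center_to_tlwh, format_result_line

__all__ = ["ScenarioConfig", "ScenarioTruth", "generate", "inject_maneuver", "write_scenario"]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic sequence."""

    n_frames: int = 250
    frame_rate: float = 10.0  # Hz
    n_trees: int = 5
    fruits_per_tree: tuple[int, int] = (5, 5)  # inclusive range
    image_size: tuple[int, int] = (1280, 720)  # (W, H) px
    fruit_size: tuple[float, float] = (24.0, 40.0)  # box side range, px

    # intrinsic fruit motion (world frame); fruits are near-static by default,
    # wind adds a constant drift velocity per fruit
    wind: bool = False
    base_speed: tuple[float, float] = (0.1, 0.5)  # px/frame when wind is on
    motion_jitter: float = 0.05  # px, zero-mean positional jitter per frame
    maneuver_prob: float = 0.0  # per-fruit chance of one discrete velocity jump
    maneuver_mag: float = 2.0  # px/frame magnitude of the jump

    # occlusion gaps: a fruit's detections vanish for a contiguous stretch
    occlusion_prob: float = 0.3
    occlusion_len: tuple[int, int] = (3, 10)  # frames, inclusive

    # detector imperfections
    miss_rate: float = 0.05
    clutter_rate: float = 0.02  # expected clutter per emitted detection
    box_noise: float = 1.0  # px, sigma on box center and size
    conf_range: tuple[float, float] = (0.6, 1.0)

    # camera: constant pan (px/frame in world units) and per-frame zoom rate
    camera_pan: tuple[float, float] = (4.0, 0.0)
    camera_zoom: float = 0.0
    n_corr_points: int = 12  # background correspondences written per frame
    corr_noise: float = 0.2  # px, noise on correspondence points

    # appearance embeddings
    feat_dim: int = 16
    feat_noise: float = 0.05
    feat_min_sep: float = 0.3  # minimum inter-identity cosine distance

    #: fruits are only placed where they stay in view at least this long
    min_visible_frames: int = 40

    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        for name in ("miss_rate", "clutter_rate", "occlusion_prob", "maneuver_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v}: rates must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_trees < 1 or self.fruits_per_tree[0] < 1:
            raise ValueError("need at least one tree with at least one fruit")
        if self.occlusion_len[0] < 1 or self.occlusion_len[0] > self.occlusion_len[1]:
            raise ValueError(f"bad occlusion_len range {self.occlusion_len}")
        return self


@dataclass
class ScenarioTruth:
    """Everything the generator knows: trajectories, camera, detection identities."""

    #: id -> list of (frame, center_box) in image coordinates
    trajectories: dict[int, list[tuple[int, tuple[float, float, float, float]]]]
    #: frame -> true forward camera transform (maps frame-1 coords to frame coords)
    camera: dict[int, np.ndarray]
    #: frame -> true id per emitted detection (-1 marks clutter), aligned with
    #: the detection order in the bundle
    det_ids: dict[int, list[int]]
    #: id -> true appearance embedding (unit vector)
    embeddings: dict[int, np.ndarray] = field(default_factory=dict)
    n_fruits: int = 0


def inject_maneuver(positions: np.ndarray, velocities: np.ndarray,
                    frame: int, dv) -> tuple[np.ndarray, np.ndarray]:
    """Apply a discrete velocity jump at ``frame`` and re-integrate positions.

    ``positions`` and ``velocities`` are per-frame arrays of equal length;
    velocities from ``frame`` onward are shifted by ``dv`` and positions
    after ``frame`` re-integrated from the shifted velocities.
    """
    positions = np.asarray(positions, dtype=float).copy()
    velocities = np.asarray(velocities, dtype=float).copy()
    n = positions.shape[0]
    if velocities.shape[0] != n:
        raise ValueError("positions and velocities must have the same length")
    if not 0 <= frame < n:
        raise IndexError(f"maneuver frame {frame} outside trajectory of length {n}")
    velocities[frame:] += np.asarray(dv, dtype=float)
    for t in range(frame + 1, n):
        positions[t] = positions[t - 1] + velocities[t - 1]
    return positions, velocities


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _separated_embeddings(n: int, dim: int, min_sep: float, rng) -> list[np.ndarray]:
    """Random unit vectors with pairwise cosine distance >= min_sep (rejection)."""
    vecs: list[np.ndarray] = []
    tries = 0
    while len(vecs) < n:
        cand = _unit(rng.normal(size=dim))
        tries += 1
        if all(1.0 - cand @ v >= min_sep for v in vecs) or tries > 200 * n:
            vecs.append(cand)
            tries = 0
    return vecs


def generate(cfg: ScenarioConfig) -> tuple[SequenceBundle, ScenarioTruth]:
    """Generate one scenario: detections + sidecars + ground truth + truth record."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (r_layout, r_motion, r_occl, r_det, r_clutter, r_feat, r_cam) = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )
    W, H = cfg.image_size
    pan = np.asarray(cfg.camera_pan, dtype=float)
    n = cfg.n_frames

    # camera offset and zoom per frame (frame index 1..n -> array index 0..n-1)
    offsets = np.outer(np.arange(n), pan)
    scales = (1.0 + cfg.camera_zoom) ** np.arange(n)

    # ---- world layout: trees along the swept strip, fruits clustered on trees
    counts = r_layout.integers(cfg.fruits_per_tree[0], cfg.fruits_per_tree[1] + 1,
                               size=cfg.n_trees)
    n_fruits = int(counts.sum())
    pan_norm = float(np.linalg.norm(pan))
    # keep every fruit in view for at least min_visible_frames
    margin = pan_norm * cfg.min_visible_frames
    x_lo, x_hi = margin, W + pan_norm * max(n - cfg.min_visible_frames, 0)
    if pan_norm == 0:
        x_lo, x_hi = 0.1 * W, 0.9 * W
    tree_x = np.linspace(x_lo, x_hi, cfg.n_trees + 2)[1:-1] if pan_norm > 0 else (
        r_layout.uniform(x_lo, x_hi, size=cfg.n_trees)
    )
    fruit_world = []  # (x, y, w, h) world boxes at frame 1
    for t_idx, cnt in enumerate(counts):
        cy = r_layout.uniform(0.25 * H, 0.75 * H)
        for _ in range(cnt):
            fx = tree_x[t_idx] + r_layout.normal(0, 90)
            fy = cy + r_layout.normal(0, 110)
            fx = float(np.clip(fx, x_lo, x_hi))
            fy = float(np.clip(fy, 0.08 * H, 0.92 * H))
            side = r_layout.uniform(*cfg.fruit_size)
            aspect = r_layout.uniform(0.9, 1.1)
            fruit_world.append((fx, fy, side, side * aspect))

    # ---- world trajectories: near-static + optional wind + jitter + maneuvers
    pos = np.zeros((n_fruits, n, 2))
    vel = np.zeros((n_fruits, n, 2))
    for i, (fx, fy, _, _) in enumerate(fruit_world):
        if cfg.wind:
            speed = r_motion.uniform(*cfg.base_speed)
            ang = r_motion.uniform(0, 2 * np.pi)
            v0 = speed * np.array([np.cos(ang), np.sin(ang)])
        else:
            v0 = np.zeros(2)
        p = np.empty((n, 2))
        p[0] = (fx, fy)
        for t in range(1, n):
            p[t] = p[t - 1] + v0
        v = np.tile(v0, (n, 1))
        if cfg.maneuver_prob > 0 and r_motion.uniform() < cfg.maneuver_prob:
            mf = int(r_motion.integers(n // 4, 3 * n // 4)) if n >= 4 else 0
            ang = r_motion.uniform(0, 2 * np.pi)
            dv = cfg.maneuver_mag * np.array([np.cos(ang), np.sin(ang)])
            p, v = inject_maneuver(p, v, mf, dv)
        if cfg.motion_jitter > 0:
            p = p + r_motion.normal(0, cfg.motion_jitter, size=p.shape)
        pos[i], vel[i] = p, v

    # ---- occlusion gaps (in frame indices 1..n)
    gaps: dict[int, tuple[int, int]] = {}
    for i in range(n_fruits):
        if r_occl.uniform() < cfg.occlusion_prob:
            length = int(r_occl.integers(cfg.occlusion_len[0], cfg.occlusion_len[1] + 1))
            if length < n:
                start = int(r_occl.integers(2, max(n - length, 3)))
                gaps[i] = (start, start + length - 1)

    # ---- appearance embeddings
    embeds = _separated_embeddings(n_fruits, cfg.feat_dim, cfg.feat_min_sep, r_feat)

    # ---- project to image, emit GT and detections
    trajectories: dict[int, list] = {i + 1: [] for i in range(n_fruits)}
    ground_truth: dict[int, list] = {}
    detections: dict[int, list[Detection]] = {}
    det_ids: dict[int, list[int]] = {}
    correspondences: dict[int, np.ndarray] = {}
    camera_truth: dict[int, np.ndarray] = {}

    for t in range(n):  # array index; frame = t + 1
        frame = t + 1
        s = scales[t]
        img_boxes = []
        for i in range(n_fruits):
            cx, cy = s * (pos[i, t] - offsets[t])
            w = s * fruit_world[i][2]
            h = s * fruit_world[i][3]
            img_boxes.append((float(cx), float(cy), float(w), float(h)))

        # ground truth: fruits whose center is in view (annotation continues
        # through occlusion gaps)
        visible = [
            i for i, (cx, cy, _, _) in enumerate(img_boxes)
            if 0 <= cx <= W and 0 <= cy <= H
        ]
        for i in visible:
            trajectories[i + 1].append((frame, img_boxes[i]))
        ground_truth[frame] = [(i + 1, img_boxes[i]) for i in visible]

        # detections: visible, not occluded, not missed
        frame_dets: list[Detection] = []
        frame_ids: list[int] = []
        for i in visible:
            g = gaps.get(i)
            if g is not None and g[0] <= frame <= g[1]:
                continue
            if r_det.uniform() < cfg.miss_rate:
                continue
            cx, cy, w, h = img_boxes[i]
            noise = r_det.normal(0, cfg.box_noise, size=4)
            box = (cx + noise[0], cy + noise[1],
                   max(w + noise[2], 2.0), max(h + noise[3], 2.0))
            feat = _unit(embeds[i] + r_feat.normal(0, cfg.feat_noise, size=cfg.feat_dim))
            conf = float(r_det.uniform(*cfg.conf_range))
            frame_dets.append(Detection(frame=frame, box=box, confidence=conf, feature=feat))
            frame_ids.append(i + 1)

        # clutter false positives with realistic sizes
        n_clutter = int(r_clutter.poisson(cfg.clutter_rate * max(len(frame_dets), 1)))
        for _ in range(n_clutter):
            side = r_clutter.uniform(*cfg.fruit_size)
            box = (float(r_clutter.uniform(0, W)), float(r_clutter.uniform(0, H)),
                   side, side * r_clutter.uniform(0.9, 1.1))
            feat = _unit(r_feat.normal(size=cfg.feat_dim))
            conf = float(r_clutter.uniform(*cfg.conf_range))
            frame_dets.append(Detection(frame=frame, box=box, confidence=conf, feature=feat))
            frame_ids.append(-1)

        # shuffle within the frame so detection order carries no identity hint
        order = r_det.permutation(len(frame_dets))
        detections[frame] = [frame_dets[k] for k in order]
        det_ids[frame] = [frame_ids[k] for k in order]

        # true camera transform (frame-1 -> frame) and correspondence points
        if t > 0:
            ratio = scales[t] / scales[t - 1]
            shift = scales[t] * (offsets[t - 1] - offsets[t])
            T = np.hstack([ratio * np.eye(2), shift[:, None]])
            camera_truth[frame] = T
            # points p in the current frame, q = T^-1(p) in the previous one
            p_pts = r_cam.uniform((0, 0), (W, H), size=(cfg.n_corr_points, 2))
            q_pts = (p_pts - shift) / ratio
            noise = r_cam.normal(0, cfg.corr_noise, size=q_pts.shape)
            correspondences[frame] = np.hstack([p_pts, q_pts + noise])

    bundle = SequenceBundle(
        detections=detections,
        ground_truth=ground_truth,
        correspondences=correspondences,
        frame_rate=cfg.frame_rate,
        n_frames=n,
    )
    truth = ScenarioTruth(
        trajectories={i: traj for i, traj in trajectories.items() if traj},
        camera=camera_truth,
        det_ids=det_ids,
        embeddings={i + 1: embeds[i] for i in range(n_fruits)},
        n_fruits=n_fruits,
    )
    return bundle, truth


def true_counts(truth: ScenarioTruth, n_frames: int, cumulative: bool = True) -> np.ndarray:
    """Ground-truth counting curve: distinct fruits seen up to each frame
    (or currently visible fruits with ``cumulative=False``)."""
    counts = np.zeros(n_frames, dtype=int)
    if cumulative:
        firsts = [min(f for f, _ in traj) for traj in truth.trajectories.values()]
        for f in firsts:
            counts[f - 1:] += 1
    else:
        for traj in truth.trajectories.values():
            for f, _ in traj:
                counts[f - 1] += 1
    return counts


def write_scenario(bundle: SequenceBundle, truth: ScenarioTruth,
                   out_dir: str | Path) -> None:
    """Write det.txt, gt.txt, features.csv, corr.csv, truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    det_lines, feat_lines = [], []
    for frame in sorted(bundle.detections):
        for idx, d in enumerate(bundle.detections[frame]):
            bb_left, bb_top, w, h = center_to_tlwh(*d.box)
            det_lines.append(
                f"{frame},-1,{bb_left:.2f},{bb_top:.2f},{w:.2f},{h:.2f},{d.confidence:.2f},-1,-1,-1"
            )
            if d.feature is not None:
                feat_lines.append(
                    f"{frame},{idx}," + ",".join(f"{v:.6f}" for v in d.feature)
                )
    (out / "det.txt").write_text("".join(l + "\n" for l in det_lines))
    if feat_lines:
        (out / "features.csv").write_text("".join(l + "\n" for l in feat_lines))

    gt_lines = []
    for frame in sorted(bundle.ground_truth or {}):
        for obj_id, box in bundle.ground_truth[frame]:
            gt_lines.append(format_result_line(frame, obj_id, box, 1.0))
    (out / "gt.txt").write_text("".join(l + "\n" for l in gt_lines))

    if bundle.correspondences:
        corr_lines = []
        for frame in sorted(bundle.correspondences):
            for px, py, qx, qy in bundle.correspondences[frame]:
                corr_lines.append(f"{frame},{px:.4f},{py:.4f},{qx:.4f},{qy:.4f}")
        (out / "corr.csv").write_text("".join(l + "\n" for l in corr_lines))

    payload = {
        "n_fruits": truth.n_fruits,
        "trajectories": {
            str(i): [[f, *[round(v, 4) for v in box]] for f, box in traj]
            for i, traj in truth.trajectories.items()
        },
        "camera": {str(f): np.round(m, 6).tolist() for f, m in truth.camera.items()},
        "det_ids": {str(f): ids for f, ids in truth.det_ids.items()},
    }
    (out / "truth.json").write_text(json.dumps(payload))
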