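"""MOTChallenge-format text I/O and sidecar files.

Detections, ground truth, and tracking results all use the MOTChallenge
line format ``frame,id,bb_left,bb_top,w,h,conf,x,y,z`` (1-based frames,
top-left boxes).  Internally every box is center-form continuous pixels
``(x, y, w, h)``; conversion happens only at the I/O boundary.

Sidecars:

* features: CSV ``frame,det_index,f1..fD`` — one appearance embedding per
  detection, ``det_index`` being the 0-based order of the detection within
  its frame in the detection file.  Vectors are L2-normalized at ingest.
* correspondences: CSV ``frame,px,py,qx,qy`` — matched image points, with
  ``(px, py)`` in the named frame and ``(qx, qy)`` its match in the
  previous frame, for camera-motion estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ParseError(ValueError):
    """A line in a MOT or sidecar file could not be parsed."""


@dataclass
class Detection:
    """One detector output: a center-form box with confidence and optional embedding."""

    frame: int
    box: tuple[float, float, float, float]  # (x, y, w, h), center form, px
    confidence: float = 1.0
    feature: np.ndarray | None = None

    def __post_init__(self):
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError(f"detection box must have positive size, got {self.box}")
        if self.feature is not None:
            f = np.asarray(self.feature, dtype=float)
            norm = np.linalg.norm(f)
            if norm == 0:
                raise ValueError("zero appearance feature vector")
            self.feature = f / norm


@dataclass
class SequenceBundle:
    """A full sequence: per-frame detections plus optional GT, correspondences, meta."""

    detections: dict[int, list[Detection]] = field(default_factory=dict)
    ground_truth: dict[int, list[tuple[int, tuple[float, float, float, float]]]] | None = None
    correspondences: dict[int, np.ndarray] | None = None
    frame_rate: float = 10.0
    n_frames: int = 0

    def frames(self):
        """Iterate frame indices 1..n_frames."""
        return range(1, self.n_frames + 1)

    def dets_at(self, frame: int) -> list[Detection]:
        return self.detections.get(frame, [])


def tlwh_to_center(bb_left: float, bb_top: float, w: float, h: float):
    """Top-left MOT box -> center-form box."""
    return (bb_left + w / 2.0, bb_top + h / 2.0, w, h)


def center_to_tlwh(x: float, y: float, w: float, h: float):
    """Center-form box -> top-left MOT box (exact inverse of :func:`tlwh_to_center`)."""
    return (x - w / 2.0, y - h / 2.0, w, h)


def _parse_mot_line(line: str, lineno: int, path) -> tuple[int, int, float, float, float, float, float]:
    parts = line.split(",")
    if len(parts) < 7:
        raise ParseError(f"{path}:{lineno}: expected >=7 comma-separated fields, got {len(parts)}")
    try:
        frame = int(float(parts[0]))
        obj_id = int(float(parts[1]))
        bb_left, bb_top, w, h, conf = (float(v) for v in parts[2:7])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if frame < 1:
        raise ParseError(f"{path}:{lineno}: frame index must be >= 1, got {frame}")
    return frame, obj_id, bb_left, bb_top, w, h, conf


def _read_features(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    feats: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected frame,det_index,f1..fD")
            try:
                frame = int(float(parts[0]))
                det_index = int(float(parts[1]))
                vec = np.array([float(v) for v in parts[2:]], dtype=float)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            feats[(frame, det_index)] = vec
    return feats


def read_detections(
    path: str | Path,
    feature_path: str | Path | None = None,
    conf_floor: float = 0.1,
    frame_rate: float = 10.0,
) -> SequenceBundle:
    """Read a MOT detection file (and optional feature sidecar) into a bundle.

    Top-left boxes are converted to center form; detections are grouped and
    ordered by frame; features are joined by ``(frame, row-order-index)``
    and L2-normalized.  Detections with confidence below ``conf_floor`` are
    dropped (after the feature join, so indices stay aligned with the file).
    """
    rows: dict[int, list[tuple[float, ...]]] = {}
    max_frame = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame, _id, bb_left, bb_top, w, h, conf = _parse_mot_line(line, lineno, path)
            if w <= 0 or h <= 0:
                raise ParseError(f"{path}:{lineno}: nonpositive box size {w}x{h}")
            rows.setdefault(frame, []).append((bb_left, bb_top, w, h, conf))
            max_frame = max(max_frame, frame)

    feats = _read_features(feature_path) if feature_path is not None else None
    if feats is not None:
        n_dets = sum(len(v) for v in rows.values())
        if len(feats) != n_dets:
            raise ParseError(
                f"feature sidecar {feature_path} has {len(feats)} vectors "
                f"for {n_dets} detections"
            )

    detections: dict[int, list[Detection]] = {}
    for frame in sorted(rows):
        dets = []
        for idx, (bb_left, bb_top, w, h, conf) in enumerate(rows[frame]):
            feature = None
            if feats is not None:
                try:
                    feature = feats[(frame, idx)]
                except KeyError:
                    raise ParseError(
                        f"feature sidecar {feature_path} missing vector for "
                        f"frame {frame}, det_index {idx}"
                    ) from None
            if conf < conf_floor:
                continue
            dets.append(
                Detection(frame=frame, box=tlwh_to_center(bb_left, bb_top, w, h),
                          confidence=conf, feature=feature)
            )
        detections[frame] = dets
    return SequenceBundle(detections=detections, frame_rate=frame_rate, n_frames=max_frame)


def read_ground_truth(path: str | Path) -> dict[int, list[tuple[int, tuple[float, float, float, float]]]]:
    """Read a MOT ground-truth file into per-frame ``(id, center_box)`` lists."""
    gt: dict[int, list[tuple[int, tuple[float, float, float, float]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame, obj_id, bb_left, bb_top, w, h, _conf = _parse_mot_line(line, lineno, path)
            gt.setdefault(frame, []).append((obj_id, tlwh_to_center(bb_left, bb_top, w, h)))
    return gt


def read_correspondences(path: str | Path) -> dict[int, np.ndarray]:
    """Read the point-correspondence sidecar into per-frame ``(n, 4)`` arrays.

    Each row is ``(px, py, qx, qy)``: a point in the keyed frame and its
    match in the previous frame.
    """
    rows: dict[int, list[list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected frame,px,py,qx,qy")
            try:
                frame = int(float(parts[0]))
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            rows.setdefault(frame, []).append(vals)
    return {f: np.array(v, dtype=float) for f, v in rows.items()}


def format_result_line(frame: int, track_id: int, box, conf: float) -> str:
    bb_left, bb_top, w, h = center_to_tlwh(*box)
    return f"{frame},{track_id},{bb_left:.2f},{bb_top:.2f},{w:.2f},{h:.2f},{conf:.2f},-1,-1,-1"


def write_tracks(result, path: str | Path) -> None:
    """Write per-frame ``(track_id, center_box, conf)`` rows as a MOT result file.

    ``result`` maps frame index -> list of ``(id, box, conf)``.  Output is
    frame-major, then id-ascending, boxes converted back to top-left.
    """
    lines = []
    for frame in sorted(result):
        for track_id, box, conf in sorted(result[frame], key=lambda r: r[0]):
            if track_id < 1:
                raise ValueError(f"track ids must be positive integers, got {track_id}")
            lines.append(format_result_line(frame, track_id, box, conf))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_result(path: str | Path) -> dict[int, list[tuple[int, tuple[float, float, float, float], float]]]:
    """Read a MOT result file back into the :func:`write_tracks` mapping."""
    res: dict[int, list[tuple[int, tuple[float, float, float, float], float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame, obj_id, bb_left, bb_top, w, h, conf = _parse_mot_line(line, lineno, path)
            res.setdefault(frame, []).append((obj_id, tlwh_to_center(bb_left, bb_top, w, h), conf))
    return res
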