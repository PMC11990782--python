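"""Readers and writers for MOTChallenge-style CSV files.

File coordinates are 1-based (MOTChallenge convention); everything in
memory is 0-based pixels.  Readers reject malformed rows with the
offending line number rather than skipping them.

Formats:

- detections:  ``frame,id,left,top,width,height,conf[,x,y,z]`` (id ignored)
- ground truth: ``frame,id,left,top,width,height,flag,class,visibility``
- results:      ``frame,id,left,top,width,height,conf,-1,-1,-1``
- descriptor sidecar: ``frame,det_index,v1,...,vD`` (det_index 0-based
  within its frame, matching the detection file's row order)
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np

from .association import Detection
from .tracker import FrameResult

__all__ = [
    "MOTFileError",
    "read_mot_detections",
    "read_mot_gt",
    "read_descriptors",
    "attach_descriptors",
    "write_detections",
    "write_gt",
    "write_results",
    "write_descriptors",
    "read_results_as_annotations",
]


class MOTFileError(ValueError):
    """A MOT CSV file could not be parsed."""


def _parse_rows(path, min_fields: int) -> Iterable[tuple[int, list[float]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < min_fields:
                raise MOTFileError(
                    f"{path}:{lineno}: expected >= {min_fields} fields, got {len(parts)}"
                )
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise MOTFileError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            yield lineno, values


def read_mot_detections(path) -> dict[int, list[Detection]]:
    """Load a det file into per-frame Detection lists (0-based coords)."""
    frames: dict[int, list[Detection]] = {}
    for lineno, v in _parse_rows(path, 7):
        frame = int(v[0])
        left, top, w, h, conf = v[2] - 1.0, v[3] - 1.0, v[4], v[5], v[6]
        if w <= 0 or h <= 0:
            raise MOTFileError(f"{path}:{lineno}: non-positive box size {w}x{h}")
        frames.setdefault(frame, []).append(
            Detection(box=np.array([left, top, w, h]), confidence=conf)
        )
    return dict(sorted(frames.items()))


def read_mot_gt(path) -> dict[int, list[tuple[int, np.ndarray]]]:
    """Load a gt (or result) file into per-frame (id, box) lists."""
    frames: dict[int, list[tuple[int, np.ndarray]]] = {}
    for lineno, v in _parse_rows(path, 6):
        frame, tid = int(v[0]), int(v[1])
        left, top, w, h = v[2] - 1.0, v[3] - 1.0, v[4], v[5]
        if w <= 0 or h <= 0:
            raise MOTFileError(f"{path}:{lineno}: non-positive box size {w}x{h}")
        frames.setdefault(frame, []).append((tid, np.array([left, top, w, h])))
    return dict(sorted(frames.items()))


read_results_as_annotations = read_mot_gt


def read_descriptors(path) -> dict[tuple[int, int], np.ndarray]:
    """Load the sidecar CSV keyed by (frame, det_index)."""
    out: dict[tuple[int, int], np.ndarray] = {}
    for lineno, v in _parse_rows(path, 3):
        key = (int(v[0]), int(v[1]))
        vec = np.array(v[2:])
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise MOTFileError(f"{path}:{lineno}: zero descriptor")
        out[key] = vec / norm
    return out


def attach_descriptors(
    detections: dict[int, list[Detection]],
    descriptors: dict[tuple[int, int], np.ndarray],
) -> None:
    """Attach sidecar descriptors to detections in place."""
    for frame, dets in detections.items():
        for idx, det in enumerate(dets):
            vec = descriptors.get((frame, idx))
            if vec is not None:
                det.descriptor = vec


def write_detections(path, detections: dict[int, list[Detection]]) -> None:
    with open(path, "w") as fh:
        for frame in sorted(detections):
            for det in detections[frame]:
                l, t, w, h = det.box
                fh.write(
                    f"{frame},-1,{l + 1:.2f},{t + 1:.2f},{w:.2f},{h:.2f},"
                    f"{det.confidence:.4f},-1,-1,-1\n"
                )


def write_gt(path, gt_frames: dict[int, list[tuple[int, np.ndarray]]]) -> None:
    with open(path, "w") as fh:
        for frame in sorted(gt_frames):
            for tid, box in sorted(gt_frames[frame], key=lambda x: x[0]):
                l, t, w, h = box
                fh.write(
                    f"{frame},{tid},{l + 1:.2f},{t + 1:.2f},{w:.2f},{h:.2f},1,1,1.0\n"
                )


def write_results(path, results: list[FrameResult]) -> None:
    """Write tracker output in MOTChallenge result format."""
    with open(path, "w") as fh:
        for res in sorted(results, key=lambda r: r.frame_index):
            for tid, box, conf in sorted(res.tracks, key=lambda x: x[0]):
                l, t, w, h = box
                fh.write(
                    f"{res.frame_index},{tid},{l + 1:.2f},{t + 1:.2f},"
                    f"{w:.2f},{h:.2f},{conf:.4f},-1,-1,-1\n"
                )


def write_descriptors(path, detections: dict[int, list[Detection]]) -> None:
    with open(path, "w") as fh:
        for frame in sorted(detections):
            for idx, det in enumerate(detections[frame]):
                if det.descriptor is None:
                    continue
                vec = ",".join(f"{v:.6f}" for v in det.descriptor)
                fh.write(f"{frame},{idx},{vec}\n")
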