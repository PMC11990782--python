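"""Tracking and detection evaluation: CLEAR-MOT, identity F1, AP/mAP.

Ground truth and predictions are per-frame lists of identity-labelled
boxes.  The CLEAR protocol matches boxes frame by frame — persisting the
previous frame's correspondences when they still overlap, then resolving
the remainder with a Hungarian assignment on 1 - IoU — and accumulates
false positives (FP), false negatives (FN) and identity switches (IDSW):

    MOTA = 1 - (sum FN + FP + IDSW) / (sum GT_t)

MOTP here is the mean IoU of matched pairs (higher is better), so both
headline numbers read as percentages where larger means better.  IDF1
solves a single global bipartite matching between ground-truth and
predicted trajectories and reports the identity-level F1 score

    IDF1 = 2 IDTP / (2 IDTP + IDFP + IDFN).

Detection quality is scored with average precision (all-point
interpolation of the precision-recall curve) and its mean over classes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cos import iou_matrix

__all__ = [
    "MetricReport",
    "match_frame",
    "compute_clear",
    "compute_idf1",
    "average_precision",
    "mean_ap",
    "evaluate_tracking",
    "write_report_csv",
    "format_report",
]

logger = logging.getLogger(__name__)

GTFrame = Sequence[tuple[int, np.ndarray]]
PredFrame = Sequence[tuple]  # (id, box) or (id, box, confidence)


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given input (e.g. no ground truth)."""


@dataclass
class MetricReport:
    """Summary of one evaluated sequence (fractions in [0, 1])."""

    mota: float
    motp: float
    idf1: float
    fp: int
    fn: int
    idsw: int
    n_gt: int
    n_matches: int
    ap: dict[str, float] = field(default_factory=dict)
    map: float | None = None

    def as_dict(self) -> dict:
        d = {
            "MOTA": self.mota,
            "MOTP": self.motp,
            "IDF1": self.idf1,
            "FP": self.fp,
            "FN": self.fn,
            "IDs": self.idsw,
            "GT": self.n_gt,
        }
        if self.map is not None:
            d["mAP"] = self.map
        return d


def match_frame(
    gt: GTFrame,
    pred: PredFrame,
    prev_mapping: Mapping[int, int],
    iou_min: float = 0.5,
) -> tuple[list[tuple[int, int, float]], int, int, int, dict[int, int]]:
    """CLEAR matching for one frame.

    Returns ``(pairs, fp, fn, idsw, mapping)`` where ``pairs`` holds
    (gt_id, pred_id, iou) for this frame's correspondences and ``mapping``
    is the updated last-known gt->pred correspondence (persisting across
    frames where a track is absent, as the switch definition requires).
    """
    gt_ids = [g[0] for g in gt]
    gt_boxes = np.array([g[1] for g in gt], dtype=float).reshape(-1, 4)
    pred_ids = [p[0] for p in pred]
    pred_boxes = np.array([p[1] for p in pred], dtype=float).reshape(-1, 4)
    iou = iou_matrix(gt_boxes, pred_boxes)

    pairs: list[tuple[int, int, float]] = []
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pred_pos = {pid: k for k, pid in enumerate(pred_ids)}
    # 1. persist still-valid correspondences from the previous frames
    for gi, gid in enumerate(gt_ids):
        pid = prev_mapping.get(gid)
        if pid is None or pid not in pred_pos:
            continue
        pj = pred_pos[pid]
        if iou[gi, pj] >= iou_min:
            pairs.append((gid, pid, float(iou[gi, pj])))
            used_gt.add(gi)
            used_pred.add(pj)
    # 2. Hungarian on the remainder
    free_gt = [i for i in range(len(gt_ids)) if i not in used_gt]
    free_pred = [j for j in range(len(pred_ids)) if j not in used_pred]
    if free_gt and free_pred:
        sub = 1.0 - iou[np.ix_(free_gt, free_pred)]
        feasible = sub <= 1.0 - iou_min
        if feasible.any():
            filled = np.where(feasible, sub, 2.0)
            rows, cols = linear_sum_assignment(filled)
            for r, c in zip(rows, cols):
                if feasible[r, c]:
                    gi, pj = free_gt[r], free_pred[c]
                    pairs.append(
                        (gt_ids[gi], pred_ids[pj], float(iou[gi, pj]))
                    )
                    used_gt.add(gi)
                    used_pred.add(pj)
    fn = len(gt_ids) - len(pairs)
    fp = len(pred_ids) - len(pairs)
    idsw = 0
    mapping = dict(prev_mapping)
    for gid, pid, _ in pairs:
        if gid in mapping and mapping[gid] != pid:
            idsw += 1
        mapping[gid] = pid
    return pairs, fp, fn, idsw, mapping


def _aligned_frames(
    gt_frames: Mapping[int, GTFrame], pred_frames: Mapping[int, PredFrame]
) -> list[int]:
    return sorted(set(gt_frames) | set(pred_frames))


def compute_clear(
    gt_frames: Mapping[int, GTFrame],
    pred_frames: Mapping[int, PredFrame],
    iou_min: float = 0.5,
) -> tuple[float, float, int, int, int]:
    """Sequence-level CLEAR metrics: (MOTA, MOTP, FP, FN, IDSW)."""
    total_gt = sum(len(v) for v in gt_frames.values())
    if total_gt == 0:
        raise UndefinedMetricError("CLEAR metrics undefined: no ground-truth boxes")
    fp = fn = idsw = 0
    iou_sum = 0.0
    n_matches = 0
    mapping: dict[int, int] = {}
    for f in _aligned_frames(gt_frames, pred_frames):
        pairs, f_fp, f_fn, f_idsw, mapping = match_frame(
            gt_frames.get(f, []), pred_frames.get(f, []), mapping, iou_min
        )
        fp += f_fp
        fn += f_fn
        idsw += f_idsw
        iou_sum += sum(p[2] for p in pairs)
        n_matches += len(pairs)
    mota = 1.0 - (fn + fp + idsw) / total_gt
    motp = iou_sum / n_matches if n_matches else 0.0
    return mota, motp, fp, fn, idsw


def compute_idf1(
    gt_frames: Mapping[int, GTFrame],
    pred_frames: Mapping[int, PredFrame],
    iou_min: float = 0.5,
) -> float:
    """Identity F1 from a single global trajectory-to-trajectory matching.

    The bipartite matching between ground-truth and predicted trajectories
    maximises the number of frame-level box overlaps (IoU >= iou_min)
    credited to consistently paired identities; that count is IDTP, and
    the unmatched remainders on each side are IDFN and IDFP.
    """
    total_gt = sum(len(v) for v in gt_frames.values())
    total_pred = sum(len(v) for v in pred_frames.values())
    if total_gt == 0 and total_pred == 0:
        raise UndefinedMetricError("IDF1 undefined: both sequences empty")
    gt_traj: dict[int, dict[int, np.ndarray]] = {}
    for f, boxes in gt_frames.items():
        for gid, box in boxes:
            gt_traj.setdefault(gid, {})[f] = np.asarray(box, dtype=float)
    pred_traj: dict[int, dict[int, np.ndarray]] = {}
    for f, boxes in pred_frames.items():
        for entry in boxes:
            pid, box = entry[0], entry[1]
            pred_traj.setdefault(pid, {})[f] = np.asarray(box, dtype=float)
    g_ids = sorted(gt_traj)
    p_ids = sorted(pred_traj)
    overlap = np.zeros((len(g_ids), len(p_ids)))
    for a, gid in enumerate(g_ids):
        gtr = gt_traj[gid]
        for b, pid in enumerate(p_ids):
            ptr = pred_traj[pid]
            common = set(gtr) & set(ptr)
            if not common:
                continue
            frames = sorted(common)
            ga = np.stack([gtr[f] for f in frames])
            pa = np.stack([ptr[f] for f in frames])
            ious = np.diag(iou_matrix(ga, pa))
            overlap[a, b] = int((ious >= iou_min).sum())
    idtp = 0.0
    if overlap.size:
        rows, cols = linear_sum_assignment(-overlap)
        idtp = float(overlap[rows, cols].sum())
    idfn = total_gt - idtp
    idfp = total_pred - idtp
    denom = 2 * idtp + idfp + idfn
    return 2 * idtp / denom if denom else 0.0


def average_precision(
    detections: Sequence[tuple[int, np.ndarray, float]],
    gt_frames: Mapping[int, Sequence[np.ndarray]],
    iou_min: float = 0.5,
) -> float:
    """All-point average precision of scored detections against gt boxes.

    Detections are (frame, box, confidence) triples, swept in descending
    confidence; each ground-truth box may be credited once.
    """
    n_gt = sum(len(v) for v in gt_frames.values())
    if n_gt == 0:
        raise UndefinedMetricError("AP undefined: no ground-truth boxes")
    order = sorted(
        range(len(detections)),
        key=lambda k: (-detections[k][2], detections[k][0], k),
    )
    used: dict[int, set[int]] = {f: set() for f in gt_frames}
    tp = np.zeros(len(detections))
    for rank, k in enumerate(order):
        frame, box, _conf = detections[k]
        gts = gt_frames.get(frame, [])
        if len(gts) == 0:
            continue
        ious = iou_matrix(
            np.asarray(box, dtype=float).reshape(1, 4), np.stack(gts)
        )[0]
        best, best_iou = -1, iou_min
        for gi, v in enumerate(ious):
            if gi not in used[frame] and v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            used[frame].add(best)
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / (np.arange(len(tp)) + 1)
    recall = cum_tp / n_gt
    # all-point interpolation: area under the monotone precision envelope
    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    changed = np.where(np.diff(mrec) > 0)[0]
    return float(np.sum((mrec[changed + 1] - mrec[changed]) * mpre[changed + 1]))


def mean_ap(per_class_ap: Mapping[str, float]) -> float:
    """Mean of per-class AP values."""
    if not per_class_ap:
        raise UndefinedMetricError("mAP undefined: no classes with ground truth")
    return float(np.mean(list(per_class_ap.values())))


def evaluate_tracking(
    gt_frames: Mapping[int, GTFrame],
    pred_frames: Mapping[int, PredFrame],
    iou_min: float = 0.5,
) -> MetricReport:
    """One-stop CLEAR + IDF1 evaluation of a tracked sequence."""
    mota, motp, fp, fn, idsw = compute_clear(gt_frames, pred_frames, iou_min)
    idf1 = compute_idf1(gt_frames, pred_frames, iou_min)
    n_gt = sum(len(v) for v in gt_frames.values())
    n_matches = n_gt - fn
    return MetricReport(
        mota=mota,
        motp=motp,
        idf1=idf1,
        fp=fp,
        fn=fn,
        idsw=idsw,
        n_gt=n_gt,
        n_matches=n_matches,
    )


def write_report_csv(path, report: MetricReport) -> None:
    d = report.as_dict()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(d))
        w.writerow([f"{v:.6f}" if isinstance(v, float) else v for v in d.values()])


def format_report(report: MetricReport) -> str:
    """Human-readable metric table (percentages for the fractional scores)."""
    lines = [
        f"{'MOTA':>6}: {report.mota * 100:6.1f} %",
        f"{'MOTP':>6}: {report.motp * 100:6.1f} %",
        f"{'IDF1':>6}: {report.idf1 * 100:6.1f} %",
        f"{'FP':>6}: {report.fp:6d}",
        f"{'FN':>6}: {report.fn:6d}",
        f"{'IDs':>6}: {report.idsw:6d}",
        f"{'GT':>6}: {report.n_gt:6d}",
    ]
    if report.map is not None:
        lines.append(f"{'mAP':>6}: {report.map * 100:6.1f} %")
    return "\n".join(lines)
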