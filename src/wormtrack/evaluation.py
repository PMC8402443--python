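"""IoU-based scoring of tracker output against ground-truth skeletons.

Skeletons (predicted and reference alike) are turned back into bodies
with a radius-2 disk dilation, and each pose is scored by the Jaccard
index of the two bodies.  Track accuracy is the fraction of poses with
non-zero IoU — a zero means the predicted body misses the true worm
entirely, i.e. an identity or localization failure.

Worm identities are matched once, at the tracker's start frame, and
held fixed: re-matching per frame would hide exactly the identity
swaps this evaluation exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, EvaluationError
from .skeleton import SkeletonPath
from .tracker import TrackResult

BODY_RADIUS = 2.0  # half of the typical worm width, in px

_DISK_OFFSETS = [(dr, dc) for dr in range(-2, 3) for dc in range(-2, 3)
                 if dr * dr + dc * dc <= BODY_RADIUS ** 2]


def body_from_skeleton(path: SkeletonPath, shape: tuple[int, int]) -> np.ndarray:
    """Union of Euclidean disks of radius 2 centered on path pixels."""
    if path is None or len(getattr(path, "pixels", [])) == 0:
        raise EmptyMaskError("cannot reconstruct a body from an empty path")
    mask = np.zeros(shape, bool)
    H, W = shape
    for dr, dc in _DISK_OFFSETS:
        rr = path.pixels[:, 0] + dr
        cc = path.pixels[:, 1] + dc
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        mask[rr[keep], cc[keep]] = True
    return mask


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; 0 when both masks are empty."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


@dataclass
class EvalReport:
    per_pose: pd.DataFrame          # columns: frame, worm, iou
    track_accuracy: dict[int, float]
    accuracy: float                 # pooled over all poses
    mean_iou: float
    sd_iou: float
    id_map: dict[int, int] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_pose.to_csv(path, index=False)


def _match_identities(result: TrackResult,
                      truth: dict[int, dict[int, SkeletonPath]]
                      ) -> dict[int, int]:
    """Map result worm id -> truth worm id by IoU at the start frame."""
    k = result.start_frame
    if k not in truth:
        raise EvaluationError(f"ground truth has no frame {k}")
    truth_ids = sorted(truth[k])
    if len(truth_ids) != len(result.worms):
        raise EvaluationError(
            f"worm id sets differ: result has {len(result.worms)}, "
            f"truth has {len(truth_ids)}")
    mapping: dict[int, int] = {}
    taken: set[int] = set()
    for w in result.worms:
        pose = result.poses[k][w]
        if pose is None:
            raise EvaluationError(f"worm {w} has no pose at start frame {k}")
        pb = body_from_skeleton(pose, result.shape)
        scores = [(iou(pb, body_from_skeleton(truth[k][t], result.shape)), -t)
                  for t in truth_ids if t not in taken]
        best = max(scores)
        if best[0] <= 0:
            raise EvaluationError(
                f"worm {w} matches no ground-truth worm at frame {k}")
        mapping[w] = -best[1]
        taken.add(-best[1])
    return mapping


def score_tracks(result: TrackResult,
                 truth: dict[int, dict[int, SkeletonPath]]) -> EvalReport:
    """Per-pose IoU, per-track non-zero-IoU accuracy, pooled statistics."""
    id_map = _match_identities(result, truth)
    rows = []
    for f in sorted(result.poses):
        if f not in truth:
            raise EvaluationError(f"ground truth missing frame {f}")
        for w in result.worms:
            t = id_map[w]
            if t not in truth[f]:
                raise EvaluationError(f"ground truth missing worm {t} "
                                      f"at frame {f}")
            pose = result.poses[f][w]
            if pose is None:
                rows.append((f, w, 0.0))
                continue
            pb = body_from_skeleton(pose, result.shape)
            tb = body_from_skeleton(truth[f][t], result.shape)
            rows.append((f, w, iou(pb, tb)))
    per_pose = pd.DataFrame(rows, columns=["frame", "worm", "iou"])
    track_acc = {
        int(w): float((grp["iou"] > 0).mean())
        for w, grp in per_pose.groupby("worm")
    }
    return EvalReport(
        per_pose=per_pose,
        track_accuracy=track_acc,
        accuracy=float((per_pose["iou"] > 0).mean()),
        mean_iou=float(per_pose["iou"].mean()),
        sd_iou=float(per_pose["iou"].std(ddof=0)),
        id_map=id_map,
    )
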