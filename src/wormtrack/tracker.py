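"""Full tracking pipeline over one image sequence.

The pipeline finds the dish ROI and worm-track components at the
original scale, picks the start frame k where every worm is separate
and unbranched, then works at 3x resolution from model building onward
(worms are only a few pixels wide at acquisition scale).  Models are
sampled at k; tracking runs frame by frame forward (k+1 .. end) and
backward (k-1 .. start), each step re-segmenting, building the
width-constrained skeleton per component, enumerating candidates
against each worm's previous body, and taking the minimum-cost
combination under the chosen criterion configuration.  Results are
converted back to the original pixel scale.

Both passes start from an identical snapshot of the frame-k state, so
tracking a reversed sequence forward reproduces the backward pass of
the original frame for frame.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rescale

from . import candidates as cand_mod
from .costs import CONFIGS, FrameContext, ModelConfig
from .errors import BranchedSkeletonError, NoSeparableFrameError
from .segmentation import (DEFAULT_LEVELS, DEFAULT_MIN_AREA,
                           DEFAULT_MIN_SKELETON_LENGTH, GraySequence, RoiMask,
                           build_track_matrix, rank_start_frames, segment_roi,
                           segment_tracks)
from .skeleton import SkeletonPath, modified_skeleton, path_from_points
from .optimizer import optimize
from .worm_model import WormModel, build_model, reconstruct_body, update_length

STATUS_TRACKED = "tracked"
STATUS_AGGREGATED = "aggregated"
STATUS_LOST = "lost"


@dataclass
class TrackParams:
    background_threshold: int = 35
    levels: tuple[int, ...] = DEFAULT_LEVELS
    min_area: int = DEFAULT_MIN_AREA
    min_skeleton_length: int = DEFAULT_MIN_SKELETON_LENGTH
    scale: int = 3
    smoothness_window: int = 3
    color_threshold: float = 1.0
    max_candidates: int = 12
    length_window: tuple[float, float] = (0.5, 1.5)
    candidate_dilation: int = 3      # px at original scale
    overlap_width_factor: float = 1.2  # margin on width_max before a region
    #                                    counts as an overlap zone


@dataclass
class TrackResult:
    """Per-frame, per-worm poses at the original image scale."""

    shape: tuple[int, int]
    n_frames: int
    worms: list[int]
    start_frame: int
    config: str
    poses: dict[int, dict[int, SkeletonPath | None]]
    status: dict[int, dict[int, str]]

    def to_json(self) -> str:
        payload = {
            "shape": list(self.shape),
            "n_frames": self.n_frames,
            "worms": self.worms,
            "start_frame": self.start_frame,
            "config": self.config,
            "poses": {
                str(f): {
                    str(w): (None if p is None else p.as_list())
                    for w, p in sorted(self.poses[f].items())
                }
                for f in sorted(self.poses)
            },
            "status": {
                str(f): {str(w): s for w, s in sorted(self.status[f].items())}
                for f in sorted(self.status)
            },
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrackResult":
        d = json.loads(text)
        poses = {
            int(f): {int(w): (None if p is None
                              else SkeletonPath(np.array(p, int)))
                     for w, p in worms.items()}
            for f, worms in d["poses"].items()
        }
        status = {int(f): {int(w): s for w, s in worms.items()}
                  for f, worms in d["status"].items()}
        return cls(tuple(d["shape"]), d["n_frames"], list(d["worms"]),
                   d["start_frame"], d["config"], poses, status)


def upscale_path(path: SkeletonPath, scale: int) -> SkeletonPath:
    """Scale coordinates up, interpolating so the path stays connected."""
    pts = path.pixels.astype(float) * scale
    dense = [pts[0]]
    for p in pts[1:]:
        prev = dense[-1]
        steps = int(np.ceil(np.abs(p - prev).max()))
        for s in range(1, steps + 1):
            dense.append(prev + (p - prev) * s / steps)
    return path_from_points(np.array(dense), head_first=path.head_first)


def downscale_path(path: SkeletonPath, scale: int) -> SkeletonPath:
    return path_from_points(path.pixels.astype(float) / scale,
                            head_first=path.head_first)


@dataclass
class _WormState:
    path: SkeletonPath
    body: object  # BodyReconstruction
    status: str = STATUS_TRACKED


def _upscale_gray(frame: np.ndarray, scale: int) -> np.ndarray:
    return rescale(np.asarray(frame, float), scale, order=1,
                   preserve_range=True, anti_aliasing=False)


def _step(frame_gray: np.ndarray, roi_up: RoiMask, worm_ids: list[int],
          models: dict[int, WormModel], state: dict[int, _WormState],
          config: ModelConfig, p: TrackParams) -> None:
    """Advance all worm states through one frame (in place)."""
    s = p.scale
    comps, noise = segment_tracks(
        frame_gray, roi_up, p.levels,
        min_area=p.min_area * s * s,
        min_skeleton_length=p.min_skeleton_length * s)
    noise_mask = np.zeros(frame_gray.shape, bool)
    for nz in noise:
        noise_mask |= nz

    # component membership: whichever component the previous body
    # overlaps the most; no overlap -> lost this frame
    groups: dict[int, list[int]] = {}
    for wid in worm_ids:
        overlaps = [int(np.count_nonzero(state[wid].body.mask & comp))
                    for comp in comps]
        if not overlaps or max(overlaps) == 0:
            state[wid].status = STATUS_LOST
            continue
        groups.setdefault(int(np.argmax(overlaps)), []).append(wid)

    for ci, ws in sorted(groups.items()):
        comp = comps[ci]
        wmin = min(models[w].width_min for w in ws)
        wmax = max(models[w].width_max for w in ws) * p.overlap_width_factor
        graph = modified_skeleton(comp, wmin, wmax, prune_px=3 * s,
                                  stub_reach=3.0 * s)
        cs = cand_mod.extract_candidates(
            graph,
            {w: state[w].body for w in ws},
            {w: models[w].length_model for w in ws},
            window=p.length_window,
            max_candidates=p.max_candidates,
            dilate_px=p.candidate_dilation * s)
        live = [w for w in ws if cs.paths.get(w)]
        for w in ws:
            if w not in live:
                state[w].status = STATUS_LOST
        if not live:
            continue
        cs.paths = {w: cs.paths[w] for w in live}
        cs.provenance = {w: cs.provenance[w] for w in live}
        cs = cand_mod.orient_to_previous(
            cs, {w: tuple(state[w].path.pixels[0]) for w in live})
        ctx = FrameContext(
            gray=frame_gray, as_mask=comp, noise_mask=noise_mask,
            prev_bodies={w: state[w].body.mask for w in live},
            models={w: models[w] for w in live},
            smoothness_window=p.smoothness_window,
            color_threshold=p.color_threshold)
        asn = optimize(cs, ctx, config)
        separate = len(ws) == 1
        for w in live:
            state[w].path = asn.paths[w]
            state[w].body = asn.bodies[w]
            state[w].status = STATUS_TRACKED if separate else STATUS_AGGREGATED
            update_length(models[w], len(asn.paths[w]), is_separate=separate)


def track_sequence(seq: GraySequence, config: ModelConfig | str = "OCpCl",
                   params: TrackParams | None = None) -> TrackResult:
    """Track every worm through a sequence; see the module docstring."""
    if isinstance(config, str):
        config = CONFIGS.get(config) or ModelConfig.parse(config)
    p = params or TrackParams()
    s = p.scale

    roi = segment_roi(seq, p.background_threshold)
    tm = build_track_matrix(seq, roi, levels=p.levels, min_area=p.min_area,
                            min_skeleton_length=p.min_skeleton_length)
    roi_up = RoiMask(rescale(roi.mask.astype(float), s, order=0,
                             preserve_range=True) > 0.5)

    # eligibility is judged at the original scale; a worm can still turn
    # out branched after upscaling, so fall through the ranked frames
    k = models0 = None
    for cand_k in rank_start_frames(tm):
        up_k = _upscale_gray(seq.frames[cand_k], s)
        comps_k, _ = segment_tracks(up_k, roi_up, p.levels,
                                    min_area=p.min_area * s * s,
                                    min_skeleton_length=p.min_skeleton_length * s)
        if not comps_k:
            continue
        comps_k.sort(key=lambda m: tuple(np.argwhere(m).mean(axis=0)))
        try:
            models0 = {i: build_model(up_k, comp, i, prune_px=3 * s)
                       for i, comp in enumerate(comps_k)}
        except BranchedSkeletonError:
            continue
        k = cand_k
        break
    if k is None:
        raise NoSeparableFrameError(
            "no start frame with clean skeletons at working scale")
    worm_ids = sorted(models0)
    state0 = {}
    for w in worm_ids:
        path = _model_path(up_k, comps_k[w], models0[w], prune_px=3 * s)
        body = reconstruct_body(path, models0[w], up_k.shape)
        state0[w] = _WormState(path, body, STATUS_TRACKED)

    n = len(seq)
    poses: dict[int, dict[int, SkeletonPath | None]] = {}
    status: dict[int, dict[int, str]] = {}

    def record(f: int, state: dict[int, _WormState]) -> None:
        poses[f] = {w: downscale_path(state[w].path, s) for w in worm_ids}
        status[f] = {w: state[w].status for w in worm_ids}

    record(k, state0)

    for frames_iter in (range(k + 1, n), range(k - 1, -1, -1)):
        models = copy.deepcopy(models0)
        state = copy.deepcopy(state0)
        for f in frames_iter:
            _step(_upscale_gray(seq.frames[f], s), roi_up, worm_ids, models,
                  state, config, p)
            record(f, state)

    return TrackResult(shape=seq.shape, n_frames=n, worms=worm_ids,
                       start_frame=k, config=config.name, poses=poses,
                       status=status)


def _model_path(gray: np.ndarray, mask: np.ndarray, model: WormModel,
                prune_px: int = 3) -> SkeletonPath:
    """The worm's skeleton at the model frame, oriented head first."""
    from .skeleton import classical_skeleton

    path = classical_skeleton(mask, prune_px=prune_px).single_path()
    colors = np.asarray(gray, float)[path.pixels[:, 0], path.pixels[:, 1]]
    kk = min(5, len(colors))
    if colors[:kk].mean() > colors[-kk:].mean():
        path = SkeletonPath(path.pixels[::-1].copy())
    return path
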