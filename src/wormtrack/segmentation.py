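"""Dish ROI extraction and per-frame worm-track segmentation.

The imaging rig holds the dish background above gray level 48 and worm
bodies below 35 in every frame, so segmentation is fixed-threshold
throughout: the ROI is the largest hole-filled connected component of
the AND across frames of the above-threshold masks, and worm tracks are
dark connected components inside it.  Components are filtered by a
minimum area and a minimum thinning-skeleton length; those failing the
skeleton filter are kept separately as plate noise (they feed the
optimizer's noise criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .errors import EmptyMaskError, NoSeparableFrameError
from .skeleton import classical_skeleton

_STRUCT8 = np.ones((3, 3), bool)

BACKGROUND_THRESHOLD = 35  # gray level separating dish background from bodies
DEFAULT_LEVELS = (35, 30, 25, 20)
DEFAULT_MIN_AREA = 40  # px^2, below the area of the smallest worm
DEFAULT_MIN_SKELETON_LENGTH = 20  # px, below the shortest worm midline


@dataclass
class GraySequence:
    """Ordered stack of same-shape 8-bit grayscale frames at a fixed period."""

    frames: np.ndarray  # (n, H, W)
    frame_period: float = 1.0
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3 or len(f) < 2:
            raise ValueError("a sequence needs >= 2 frames of identical shape")
        self.frames = f

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def reversed(self) -> "GraySequence":
        return GraySequence(self.frames[::-1].copy(), self.frame_period,
                            self.pixel_pitch)

    @classmethod
    def from_directory(cls, directory: str | Path, frame_period: float = 1.0
                       ) -> "GraySequence":
        import imageio.v3 as iio

        paths = sorted(p for p in Path(directory).iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if len(paths) < 2:
            raise ValueError(f"need >= 2 frames in {directory}")
        frames = np.stack([np.asarray(iio.imread(p)) for p in paths])
        if frames.ndim == 4:  # RGB(A) -> gray by first channel (fixtures are gray)
            frames = frames[..., 0]
        return cls(frames, frame_period=frame_period)


@dataclass
class RoiMask:
    """The dish interior: one filled connected component."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)


def segment_roi(seq: GraySequence,
                background_threshold: int = BACKGROUND_THRESHOLD) -> RoiMask:
    """Largest hole-filled component of the per-frame AND of bright masks.

    A pixel enters the AND only if it stays above threshold in *every*
    frame, so moving dark objects (worms) only punch interior holes,
    which the fill removes — the ROI is invariant to worm motion.
    """
    acc = np.all(seq.frames > background_threshold, axis=0)
    acc = ndi.binary_fill_holes(acc)
    lab, n = ndi.label(acc, structure=_STRUCT8)
    if n == 0:
        raise EmptyMaskError("no above-threshold component: blank sequence")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return RoiMask(lab == (1 + int(np.argmax(sizes))))


def _skeleton_px_count(mask: np.ndarray) -> int:
    sub = mask[tuple(slice(s.start, s.stop) for s in ndi.find_objects(
        mask.astype(np.int8))[0])]
    return int(skeletonize(sub).sum())


def segment_tracks(frame: np.ndarray, roi: RoiMask,
                   levels: tuple[int, ...] = DEFAULT_LEVELS,
                   min_area: int = DEFAULT_MIN_AREA,
                   min_skeleton_length: int = DEFAULT_MIN_SKELETON_LENGTH,
                   ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Segment worm-track components in one frame.

    Components are pixels below ``levels[0]`` inside the ROI.  A
    component is a worm track if its area passes ``min_area``, it has a
    dark core below ``levels[-1]`` (multi-level stability), and its
    thinning skeleton has at least ``min_skeleton_length`` pixels.
    Components passing the area filter but failing either of the other
    two are returned as plate-noise masks.

    Returns ``(track_masks, noise_masks)``, full-frame boolean arrays.
    """
    if any(lv > 35 for lv in levels):
        raise ValueError("threshold levels must be at or below gray level 35")
    dark = (np.asarray(frame) < levels[0]) & roi.mask
    lab, n = ndi.label(dark, structure=_STRUCT8)
    tracks: list[np.ndarray] = []
    noise: list[np.ndarray] = []
    core = np.asarray(frame) < levels[-1]
    for i in range(1, n + 1):
        comp = lab == i
        area = int(comp.sum())
        if area < min_area:
            continue
        if not (comp & core).any() or _skeleton_px_count(comp) < min_skeleton_length:
            noise.append(comp)
        else:
            tracks.append(comp)
    return tracks, noise


@dataclass
class TrackMatrix:
    """Per-frame component counts for each spatially linked track.

    ``counts[f, j]`` is how many segmentation components (hence how many
    classical skeletons) track ``j`` contributes in frame ``f``; a
    merged aggregation counts once.  ``component_refs[f][j]`` lists the
    indices into ``frame_components[f]`` backing that cell.
    """

    counts: np.ndarray  # (n_frames, n_tracks) int
    component_refs: list[list[list[int]]]
    frame_components: list[list[np.ndarray]] = field(repr=False, default_factory=list)
    frame_noise: list[list[np.ndarray]] = field(repr=False, default_factory=list)

    @property
    def n_tracks(self) -> int:
        return self.counts.shape[1]


def build_track_matrix(seq: GraySequence, roi: RoiMask, *,
                       levels: tuple[int, ...] = DEFAULT_LEVELS,
                       min_area: int = DEFAULT_MIN_AREA,
                       min_skeleton_length: int = DEFAULT_MIN_SKELETON_LENGTH,
                       ) -> TrackMatrix:
    """Segment every frame and link components into tracks by mask overlap.

    Components in consecutive frames sharing any pixel belong to the
    same track (the weakest sufficient rule at 1 Hz); tracks are the
    transitive closure of that relation, ordered by first appearance.
    """
    per_frame: list[list[np.ndarray]] = []
    per_noise: list[list[np.ndarray]] = []
    for f in seq.frames:
        t, nz = segment_tracks(f, roi, levels, min_area, min_skeleton_length)
        per_frame.append(t)
        per_noise.append(nz)

    # union-find over (frame, comp index)
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for fi, comps in enumerate(per_frame):
        for ci in range(len(comps)):
            parent[(fi, ci)] = (fi, ci)
    for fi in range(1, len(per_frame)):
        for ci, comp in enumerate(per_frame[fi]):
            for pj, pcomp in enumerate(per_frame[fi - 1]):
                if (comp & pcomp).any():
                    union((fi - 1, pj), (fi, ci))

    roots: list[tuple[int, int]] = []
    root_col: dict[tuple[int, int], int] = {}
    for key in sorted(parent):
        r = find(key)
        if r not in root_col:
            root_col[r] = len(roots)
            roots.append(r)

    n_frames, n_tracks = len(seq), len(roots)
    counts = np.zeros((n_frames, n_tracks), int)
    refs: list[list[list[int]]] = [[[] for _ in range(n_tracks)]
                                   for _ in range(n_frames)]
    for (fi, ci) in sorted(parent):
        col = root_col[find((fi, ci))]
        counts[fi, col] += 1
        refs[fi][col].append(ci)
    return TrackMatrix(counts, refs, per_frame, per_noise)


def _pairwise_min_distance(masks: list[np.ndarray]) -> float:
    """Smallest boundary-to-boundary Euclidean distance between any two masks."""
    best = np.inf
    for i in range(len(masks)):
        dist_i = ndi.distance_transform_edt(~masks[i])
        for j in range(i + 1, len(masks)):
            d = float(dist_i[masks[j]].min())
            best = min(best, d)
    return best


def rank_start_frames(tm: TrackMatrix,
                      frame_components: list[list[np.ndarray]] | None = None
                      ) -> list[int]:
    """Eligible start frames, best (worms furthest apart) first.

    Eligible frames have every track at its maximal component count and
    every component's classical skeleton showing exactly 2 endpoints and
    no branch points; they are ordered by decreasing minimum pairwise
    mask distance (earliest frame on ties).
    """
    comps_by_frame = frame_components if frame_components is not None \
        else tm.frame_components
    if tm.n_tracks == 0:
        raise NoSeparableFrameError("no separable frame: no tracks found")
    expected = tm.counts.max(axis=0)
    scored: list[tuple[float, int]] = []
    for f in range(tm.counts.shape[0]):
        if not np.array_equal(tm.counts[f], expected):
            continue
        comps = comps_by_frame[f]
        ok = True
        for comp in comps:
            g = classical_skeleton(comp)
            if g.n_endpoints != 2 or g.n_branch_points != 0:
                ok = False
                break
        if not ok:
            continue
        score = _pairwise_min_distance(comps) if len(comps) > 1 else np.inf
        scored.append((-score, f))
    if not scored:
        raise NoSeparableFrameError("no separable frame")
    return [f for _, f in sorted(scored)]


def select_start_frame(tm: TrackMatrix,
                       frame_components: list[list[np.ndarray]] | None = None
                       ) -> int:
    """Frame k where all worms are separate, unbranched, and furthest apart."""
    return rank_start_frames(tm, frame_components)[0]
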