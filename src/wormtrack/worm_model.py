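"""Per-worm appearance models and body reconstruction.

A worm's model is sampled once, at the start frame where it is isolated
and unbranched: half-widths from the distance transform and gray levels
from the raw frame, both along the classical skeleton ordered head
first, plus a running-average length.  The tail is brighter than the
head, which fixes the head end at model time.

Any candidate skeleton can then be turned back into a body: the model
widths are linearly resampled onto the candidate's arclength and
stamped as Euclidean disks; colors are carried by nearest skeleton
pixel.  These reconstructions are what every optimizer criterion sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMaskError
from .skeleton import SkeletonPath, classical_skeleton

_HEAD_SAMPLE = 5  # skeleton pixels averaged at each end to find the head


@dataclass
class WormModel:
    widths: np.ndarray        # half-width per skeleton pixel, head first
    colors: np.ndarray        # gray level per skeleton pixel, head first
    length_model: float       # running-average skeleton pixel count
    identity: int
    _length_sum: float = 0.0
    _length_count: int = 0

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, float)
        self.colors = np.asarray(self.colors, float)
        if len(self.widths) != len(self.colors):
            raise ValueError("widths and colors must have equal length")
        if (self.widths <= 0).any() or self.length_model <= 0:
            raise ValueError("widths and length_model must be positive")
        if self._length_count == 0:
            self._length_sum = float(self.length_model)
            self._length_count = 1

    @property
    def width_min(self) -> float:
        return float(self.widths.min())

    @property
    def width_max(self) -> float:
        return float(self.widths.max())

    def to_dict(self) -> dict:
        return {
            "identity": int(self.identity),
            "widths": [float(w) for w in self.widths],
            "colors": [float(c) for c in self.colors],
            "length_model": float(self.length_model),
        }


@dataclass
class BodyReconstruction:
    """Disk-stamped body of a skeleton path under a width/color model."""

    mask: np.ndarray          # bool, full frame
    colored: np.ndarray       # float gray levels on mask, 0 elsewhere
    source_path: SkeletonPath


def build_model(gray_frame: np.ndarray, mask: np.ndarray,
                worm_id: int, prune_px: int = 3) -> WormModel:
    """Sample a worm model from a clean single-worm mask.

    Raises if the mask's classical skeleton has branch points — model
    frames must show an isolated, uncoiled worm.  ``prune_px`` is the
    spur-pruning threshold and should scale with the working resolution.
    """
    mask = np.asarray(mask, bool)
    graph = classical_skeleton(mask, prune_px=prune_px)
    path = graph.single_path()  # raises BranchedSkeletonError if not clean
    dist = ndi.distance_transform_edt(mask)
    rows, cols = path.pixels[:, 0], path.pixels[:, 1]
    widths = np.maximum(dist[rows, cols], 0.5)
    colors = np.asarray(gray_frame, float)[rows, cols]
    k = min(_HEAD_SAMPLE, len(colors))
    if colors[:k].mean() > colors[-k:].mean():
        # darker end is the head; store everything head first
        path = SkeletonPath(path.pixels[::-1].copy())
        widths, colors = widths[::-1], colors[::-1]
    return WormModel(widths, colors, float(len(path)), worm_id)


def update_length(model: WormModel, observed_length: float,
                  is_separate: bool) -> WormModel:
    """Fold one length observation into the running mean.

    Lengths measured during aggregation are unreliable (bodies merge),
    so the mean only advances while the worm is separate.
    """
    if observed_length <= 0:
        raise ValueError("observed_length must be positive")
    if is_separate:
        model._length_sum += float(observed_length)
        model._length_count += 1
        model.length_model = model._length_sum / model._length_count
    return model


def _resample(values: np.ndarray, n: int) -> np.ndarray:
    if len(values) == n:
        return np.asarray(values, float)
    return np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(values)),
                     np.asarray(values, float))


def oriented_profiles(model: WormModel, n: int, head_first: bool
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Model widths/colors resampled to n samples in the path's order."""
    w = _resample(model.widths, n)
    c = _resample(model.colors, n)
    if not head_first:
        w, c = w[::-1], c[::-1]
    return w, c


def body_support(path: SkeletonPath, widths: np.ndarray, shape: tuple[int, int]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stamp disks of per-pixel radius along the path.

    Returns ``(mask, rows, cols, ...)`` style data: the boolean body
    mask plus, for every body pixel, the index of the nearest path
    pixel (ties resolved by the distance transform's deterministic
    feature choice).  Work is confined to the path's bounding box.
    """
    px = path.pixels
    radii = np.asarray(widths, float)
    pad = int(np.ceil(radii.max())) + 2
    r0 = max(0, px[:, 0].min() - pad)
    c0 = max(0, px[:, 1].min() - pad)
    r1 = min(shape[0], px[:, 0].max() + pad + 1)
    c1 = min(shape[1], px[:, 1].max() + pad + 1)
    h, w = r1 - r0, c1 - c0
    local = np.zeros((h, w), bool)
    lr, lc = px[:, 0] - r0, px[:, 1] - c0
    rrg, ccg = np.mgrid[0:h, 0:w]
    # stamp per unique radius to keep it vectorized; the radius comes
    # from the distance transform (distance to the nearest background
    # pixel), so the disk is strict: offsets at exactly that distance
    # are background
    for rad in np.unique(np.round(radii, 3)):
        sel = np.round(radii, 3) == rad
        ir = int(np.ceil(rad))
        offs = [(dr, dc) for dr in range(-ir, ir + 1)
                for dc in range(-ir, ir + 1)
                if dr * dr + dc * dc < rad * rad - 1e-9]
        if not offs:
            offs = [(0, 0)]
        for dr, dc in offs:
            rr = lr[sel] + dr
            cc = lc[sel] + dc
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            local[rr[keep], cc[keep]] = True
    seed = np.ones((h, w), bool)
    seed[lr, lc] = False
    _, (ir_idx, ic_idx) = ndi.distance_transform_edt(seed, return_indices=True)
    # map nearest path-pixel coordinates to path indices
    order = np.full((h, w), -1, int)
    order[lr, lc] = np.arange(len(px))
    nearest = order[ir_idx, ic_idx]
    return local, nearest, (r0, c0, r1, c1)


def reconstruct_body(path: SkeletonPath, model: WormModel,
                     shape: tuple[int, int]) -> BodyReconstruction:
    """Stamp the model's widths and colors along a candidate path."""
    if path is None or len(path) < 2:
        raise EmptyMaskError("cannot reconstruct from an empty path")
    widths, colors = oriented_profiles(model, len(path), path.head_first)
    local, nearest, (r0, c0, r1, c1) = body_support(path, widths, shape)
    mask = np.zeros(shape, bool)
    mask[r0:r1, c0:c1] = local
    colored = np.zeros(shape, float)
    block = np.zeros_like(local, float)
    block[local] = colors[nearest[local]]
    colored[r0:r1, c0:c1] = block
    return BodyReconstruction(mask, colored, path)
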