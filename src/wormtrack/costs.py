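"""The six optimizer criteria and their bookkeeping.

Every criterion scores the *body reconstructions* of one combination of
candidate skeletons (one per worm in the aggregation) and is additive
over worms:

* length ``CL`` — |model length − candidate pixel count| scaled by the
  model's mean squared width, which puts a length error of one pixel on
  the same footing as the pixel-count criteria below;
* overlap ``CO`` — symmetric difference with the worm's previous body,
  the criterion that anchors identity through an aggregation;
* completeness ``CCp`` — symmetric difference between the component's
  current segmentation and each worm's body (each worm is compared to
  the full segmentation, so two worms swapping identities can tie);
* smoothness ``CS`` — mean absolute windowed turning angle (degrees)
  along the candidate skeleton;
* noise ``CN`` — intersection with the plate-noise segmentation;
* color ``CCl`` — count of body pixels whose current gray level differs
  from the model's by more than a threshold (U = 1), comparing two
  reconstructions stamped on the identical path and widths, pixel to
  pixel.

Criteria are combined by plain summation; model configurations name the
enabled subset ("O", "OL", "OCp", "ON", "OS", "OCl", "OCpCl").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import SkeletonPath
from .worm_model import WormModel, body_support, oriented_profiles

CRITERIA = ("L", "O", "Cp", "S", "N", "Cl")
COLOR_THRESHOLD = 1.0
SMOOTHNESS_WINDOW = 3


@dataclass(frozen=True)
class ModelConfig:
    """Named subset of enabled criteria."""

    name: str
    enabled: frozenset

    @classmethod
    def parse(cls, name: str) -> "ModelConfig":
        tokens, rest = [], name
        while rest:
            for tok in ("Cp", "Cl", "O", "L", "N", "S"):
                if rest.startswith(tok):
                    tokens.append(tok)
                    rest = rest[len(tok):]
                    break
            else:
                raise ValueError(f"unknown criterion in config {name!r}")
        return cls(name, frozenset(tokens))


CONFIGS = {n: ModelConfig.parse(n)
           for n in ("O", "OL", "OCp", "ON", "OS", "OCl", "OCpCl")}


@dataclass
class CostBreakdown:
    CL: float = 0.0
    CO: float = 0.0
    CCp: float = 0.0
    CS: float = 0.0
    CN: float = 0.0
    CCl: float = 0.0
    combination_id: int = -1
    enabled: frozenset = field(default_factory=frozenset)

    _FIELD = {"L": "CL", "O": "CO", "Cp": "CCp", "S": "CS", "N": "CN",
              "Cl": "CCl"}

    @property
    def total(self) -> float:
        keys = self.enabled or frozenset(CRITERIA)
        return float(sum(getattr(self, self._FIELD[k]) for k in keys))


# ---------------------------------------------------------------------------
# individual criteria (additive over worms)
# ---------------------------------------------------------------------------

def cost_length(models: dict[int, WormModel],
                paths: dict[int, SkeletonPath]) -> float:
    total = 0.0
    for wid, path in paths.items():
        m = models[wid]
        total += abs(m.length_model - len(path)) * float(np.mean(m.widths ** 2))
    return total


def cost_overlap(prev_bodies: dict[int, np.ndarray],
                 curr_bodies: dict[int, np.ndarray]) -> int:
    """Per-worm symmetric difference between previous and current bodies."""
    total = 0
    for wid, curr in curr_bodies.items():
        total += int(np.count_nonzero(prev_bodies[wid] ^ curr))
    return total


def cost_completeness(as_mask: np.ndarray,
                      curr_bodies: dict[int, np.ndarray]) -> int:
    """Pixels where the union of reconstructions disagrees with AS.

    The criterion's job is to keep the current segmentation fully
    explained: segmentation pixels no worm covers, and body pixels
    outside the segmentation, both count.  Identity swaps leave the
    union unchanged, so (unlike the overlap criterion) completeness
    cannot tell worms apart — but it forbids combinations that abandon
    part of an aggregation.  Note this couples the worms of a
    combination: completeness is not additive over worms.
    """
    union = np.zeros_like(np.asarray(as_mask, bool))
    for curr in curr_bodies.values():
        union |= curr
    return int(np.count_nonzero(np.asarray(as_mask, bool) ^ union))


def turning_angles(pixels: np.ndarray) -> np.ndarray:
    """Signed direction change (degrees) at each interior path pixel."""
    steps = np.diff(np.asarray(pixels, float), axis=0)
    ang = np.degrees(np.arctan2(steps[:, 0], steps[:, 1]))
    d = np.diff(ang)
    return (d + 180.0) % 360.0 - 180.0


def cost_smoothness(paths: dict[int, SkeletonPath],
                    n_window: int = SMOOTHNESS_WINDOW) -> float:
    """Mean absolute windowed turning angle, summed over worms.

    At pixel x the local angle is the mean of the turning angles of up
    to ``n_window`` neighbors on each side (the center excluded),
    normalized by the number actually found.
    """
    total = 0.0
    for path in paths.values():
        n = len(path)
        theta = turning_angles(path.pixels)  # angle at interior pixel a+1
        angle_at = np.full(n, np.nan)
        angle_at[1:n - 1] = theta
        acc = 0.0
        for x in range(n):
            lo = max(0, x - n_window)
            hi = min(n - 1, x + n_window)
            window = [angle_at[a] for a in range(lo, hi + 1)
                      if a != x and not np.isnan(angle_at[a])]
            if window:
                acc += abs(sum(window) / len(window))
        total += acc / n
    return total


def cost_noise(noise_mask: np.ndarray,
               curr_bodies: dict[int, np.ndarray]) -> int:
    total = 0
    for curr in curr_bodies.values():
        total += int(np.count_nonzero(noise_mask & curr))
    return total


def cost_color(models: dict[int, WormModel],
               paths: dict[int, SkeletonPath],
               gray_frame: np.ndarray,
               threshold: float = COLOR_THRESHOLD) -> int:
    """Pixels where the model-colored and frame-colored bodies disagree.

    Both bodies are stamped on the candidate's own path with the model
    widths, so the comparison is pixel to pixel.
    """
    gray = np.asarray(gray_frame, float)
    total = 0
    for wid, path in paths.items():
        m = models[wid]
        widths, mcolors = oriented_profiles(m, len(path), path.head_first)
        local, nearest, _ = body_support(path, widths, gray.shape)
        fcolors = gray[path.pixels[:, 0], path.pixels[:, 1]]
        idx = nearest[local]
        total += int(np.count_nonzero(
            np.abs(mcolors[idx] - fcolors[idx]) > threshold))
    return total


# ---------------------------------------------------------------------------
# combined evaluation
# ---------------------------------------------------------------------------

@dataclass
class FrameContext:
    """Everything one component's cost evaluation needs."""

    gray: np.ndarray
    as_mask: np.ndarray
    noise_mask: np.ndarray
    prev_bodies: dict[int, np.ndarray]
    models: dict[int, WormModel]
    smoothness_window: int = SMOOTHNESS_WINDOW
    color_threshold: float = COLOR_THRESHOLD


def criterion_values(wid: int, path: SkeletonPath, body_mask: np.ndarray,
                     ctx: FrameContext, enabled: frozenset) -> dict[str, float]:
    """Separable (per-worm) criterion values for one candidate.

    Completeness is excluded: it depends on the whole combination's
    union and is evaluated by the optimizer per combination.
    """
    single_path = {wid: path}
    single_body = {wid: body_mask}
    out: dict[str, float] = {}
    if "L" in enabled:
        out["L"] = cost_length(ctx.models, single_path)
    if "O" in enabled:
        out["O"] = cost_overlap(ctx.prev_bodies, single_body)
    if "S" in enabled:
        out["S"] = cost_smoothness(single_path, ctx.smoothness_window)
    if "N" in enabled:
        out["N"] = cost_noise(ctx.noise_mask, single_body)
    if "Cl" in enabled:
        out["Cl"] = cost_color(ctx.models, single_path, ctx.gray,
                               ctx.color_threshold)
    return out


def evaluate(paths: dict[int, SkeletonPath],
             bodies: dict[int, np.ndarray],
             ctx: FrameContext, config: ModelConfig,
             combination_id: int = -1) -> CostBreakdown:
    """Cost breakdown for one full combination (one path per worm)."""
    bd = CostBreakdown(combination_id=combination_id, enabled=config.enabled)
    if "L" in config.enabled:
        bd.CL = cost_length(ctx.models, paths)
    if "O" in config.enabled:
        bd.CO = cost_overlap(ctx.prev_bodies, bodies)
    if "Cp" in config.enabled:
        bd.CCp = cost_completeness(ctx.as_mask, bodies)
    if "S" in config.enabled:
        bd.CS = cost_smoothness(paths, ctx.smoothness_window)
    if "N" in config.enabled:
        bd.CN = cost_noise(ctx.noise_mask, bodies)
    if "Cl" in config.enabled:
        bd.CCl = cost_color(ctx.models, paths, ctx.gray, ctx.color_threshold)
    return bd
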