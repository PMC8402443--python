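"""Minimum-cost selection over candidate combinations.

The prediction for a frame is the combination of candidate skeletons
(one per worm sharing a segmentation component) with the smallest sum
of enabled criteria.  The search is an exhaustive scan of the Cartesian
product of the candidate lists — the per-worm candidate cap keeps the
product small, and exhaustive search guarantees the global argmin with
a deterministic tie-break (the lexicographically smallest index tuple
encountered first wins).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .candidates import CandidateSet
from .costs import CostBreakdown, FrameContext, ModelConfig, criterion_values, evaluate
from .errors import NoCandidatesError
from .skeleton import SkeletonPath
from .worm_model import reconstruct_body


@dataclass
class Assignment:
    paths: dict[int, SkeletonPath]
    bodies: dict[int, object] = field(repr=False, default_factory=dict)
    total_cost: float = 0.0
    breakdown: CostBreakdown | None = None
    indices: tuple[int, ...] = ()


def minimize_over_product(counts: Sequence[int],
                          cost_fn: Callable[[tuple[int, ...]], float]
                          ) -> tuple[tuple[int, ...], float]:
    """Exhaustive argmin over the index product; first strict minimum wins."""
    if any(c <= 0 for c in counts):
        raise NoCandidatesError("every worm needs at least one candidate")
    best_combo, best_cost = None, None
    for combo in itertools.product(*(range(c) for c in counts)):
        cost = cost_fn(combo)
        if best_cost is None or cost < best_cost:
            best_combo, best_cost = combo, cost
    return best_combo, float(best_cost)


def optimize(cands: CandidateSet, ctx: FrameContext,
             config: ModelConfig) -> Assignment:
    """Pick the minimum-cost combination of candidates for one component.

    All enabled criteria are additive over worms, so per-worm values are
    precomputed once per candidate and combination totals are sums; the
    scan itself is still the full product (no pruning).
    """
    worm_ids = sorted(cands.paths)
    if not worm_ids:
        raise NoCandidatesError("empty candidate set")
    counts = [len(cands.paths[w]) for w in worm_ids]
    if any(c == 0 for c in counts):
        missing = [w for w in worm_ids if not cands.paths[w]]
        raise NoCandidatesError(f"no candidates for worm(s) {missing}")

    shape = ctx.as_mask.shape
    bodies = {
        w: [reconstruct_body(p, ctx.models[w], shape) for p in cands.paths[w]]
        for w in worm_ids
    }
    per_worm_totals = []
    for w in worm_ids:
        vals = []
        for p, b in zip(cands.paths[w], bodies[w]):
            crit = criterion_values(w, p, b.mask, ctx, config.enabled)
            vals.append(sum(crit.values()))
        per_worm_totals.append(vals)

    if "Cp" in config.enabled:
        # completeness couples the worms of a combination (it scores the
        # union of their bodies against AS), so it is evaluated inside
        # the product scan, on the component's bounding box
        all_masks = [ctx.as_mask] + [b.mask for bs in bodies.values()
                                     for b in bs]
        rows = np.any([m.any(axis=1) for m in all_masks], axis=0)
        cols = np.any([m.any(axis=0) for m in all_masks], axis=0)
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        box = (slice(r0, r1 + 1), slice(c0, c1 + 1))
        as_crop = ctx.as_mask[box]
        crops = {w: [b.mask[box] for b in bodies[w]] for w in worm_ids}

        def completeness(idx: tuple[int, ...]) -> int:
            union = np.zeros_like(as_crop)
            for i, j in enumerate(idx):
                union |= crops[worm_ids[i]][j]
            return int(np.count_nonzero(as_crop ^ union))
    else:
        def completeness(idx: tuple[int, ...]) -> int:
            return 0

    combo, cost = minimize_over_product(
        counts,
        lambda idx: sum(per_worm_totals[i][j] for i, j in enumerate(idx))
        + completeness(idx),
    )

    chosen_paths = {w: cands.paths[w][j] for w, j in zip(worm_ids, combo)}
    chosen_bodies = {w: bodies[w][j] for w, j in zip(worm_ids, combo)}
    breakdown = evaluate(chosen_paths,
                         {w: b.mask for w, b in chosen_bodies.items()},
                         ctx, config)
    return Assignment(paths=chosen_paths, bodies=chosen_bodies,
                      total_cost=cost, breakdown=breakdown, indices=combo)
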