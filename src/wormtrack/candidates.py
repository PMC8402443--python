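"""Candidate pose enumeration on the (modified) skeleton graph.

For each worm, a depth-first traversal starts at every graph node —
endpoint or branch point — lying inside the worm's dilated previous
body, and walks edge chains without repeating nodes or edges.  A branch
terminates either when the accumulated pixel path reaches the worm's
model length (the path is truncated there and kept) or at a graph
endpoint (kept if at least half the model length).  Duplicate pixel
sets are removed and the candidate list is capped, keeping the paths
that overlap the previous body the most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .skeleton import SkeletonGraph, SkeletonPath
from .worm_model import BodyReconstruction

_STRUCT8 = np.ones((3, 3), bool)

LENGTH_WINDOW = (0.5, 1.5)   # candidate pixel count relative to length model
MAX_CANDIDATES = 12
PREV_BODY_DILATION = 3       # px, tolerance when matching start nodes


@dataclass
class CandidateSet:
    """Per-worm candidate paths plus the start node each grew from."""

    paths: dict[int, list[SkeletonPath]] = field(default_factory=dict)
    provenance: dict[int, list[int]] = field(default_factory=dict)

    def counts(self) -> dict[int, int]:
        return {w: len(p) for w, p in self.paths.items()}


def _append_chain(path: list[tuple[int, int]],
                  chain: np.ndarray) -> list[tuple[int, int]] | None:
    """Concatenate an edge chain onto a pixel path; None if they collide.

    Crossing a multi-pixel branch cluster can leave a 2-px gap between
    the incoming and outgoing chains; such gaps are bridged with
    stepwise pixels so the result stays 8-connected.
    """
    out = list(path)
    pts = [tuple(int(x) for x in p) for p in chain]
    if out and pts and pts[0] == out[-1]:
        pts = pts[1:]
    seen = set(out)
    for p in pts:
        while out and max(abs(out[-1][0] - p[0]), abs(out[-1][1] - p[1])) > 1:
            q = (out[-1][0] + int(np.sign(p[0] - out[-1][0])),
                 out[-1][1] + int(np.sign(p[1] - out[-1][1])))
            if q in seen:
                return None
            out.append(q)
            seen.add(q)
        if p in seen:
            return None
        out.append(p)
        seen.add(p)
    return out


def _truncate(path: list[tuple[int, int]], target: int) -> list[tuple[int, int]]:
    return path[:target]


def enumerate_from_node(graph: SkeletonGraph, start: int, length_model: float,
                        window: tuple[float, float] = LENGTH_WINDOW,
                        ) -> list[list[tuple[int, int]]]:
    """All simple traversals from one node under the length rule."""
    g = graph.graph
    target = int(round(length_model))
    lo = window[0] * length_model
    results: list[list[tuple[int, int]]] = []

    def dfs(node: int, pixel_path: list[tuple[int, int]],
            used_edges: set, used_nodes: set) -> None:
        edges = sorted(g.edges(node, keys=True),
                       key=lambda e: (min(e[0], e[1]), max(e[0], e[1]), e[2]))
        extended = False
        for (u, v, key) in edges:
            ekey = (min(u, v), max(u, v), key)
            if ekey in used_edges or (v in used_nodes and v != u):
                continue
            chain = g.edges[u, v, key]["pixels"]
            if tuple(chain[0]) not in {tuple(p) for p in
                                       graph.nodes[node].pixels}:
                chain = chain[::-1]
            new_path = _append_chain(pixel_path, chain)
            if new_path is None:
                continue
            extended = True
            if len(new_path) >= target:
                results.append(_truncate(new_path, target))
                continue
            dfs(v, new_path, used_edges | {ekey}, used_nodes | {v})
        if not extended and len(pixel_path) >= max(lo, 2):
            results.append(pixel_path)

    # start with an empty pixel path: the first chain contributes its own
    # terminal pixel, so branch-cluster starts carry no stray seed pixel
    dfs(start, [], set(), {start})
    return results


def extract_candidates(graph: SkeletonGraph,
                       prev_bodies: dict[int, BodyReconstruction],
                       length_models: dict[int, float],
                       *,
                       window: tuple[float, float] = LENGTH_WINDOW,
                       max_candidates: int = MAX_CANDIDATES,
                       dilate_px: int = PREV_BODY_DILATION) -> CandidateSet:
    """Enumerate candidate skeletons for every worm on one component.

    A worm whose previous body overlaps no graph node gets an empty
    list — the caller marks its track lost for this frame.
    """
    cs = CandidateSet()
    for wid in sorted(prev_bodies):
        body = prev_bodies[wid]
        region = ndi.binary_dilation(body.mask, _STRUCT8, iterations=dilate_px)
        L = float(length_models[wid])
        lo = window[0] * L
        starts = [
            nid for nid, node in sorted(graph.nodes.items())
            if any(region[r, c] for r, c in node.pixels)
        ]
        seen: set[frozenset] = set()
        found: list[tuple[SkeletonPath, int, int]] = []  # path, start, overlap
        for nid in starts:
            for pix in enumerate_from_node(graph, nid, L, window):
                if len(pix) < max(lo, 2):
                    continue
                key = frozenset(pix)
                if key in seen:
                    continue
                seen.add(key)
                path = SkeletonPath(np.array(pix, int))
                overlap = int(body.mask[path.pixels[:, 0],
                                        path.pixels[:, 1]].sum())
                found.append((path, nid, overlap))
        found.sort(key=lambda t: -t[2])  # stable: discovery order on ties
        found = found[:max_candidates]
        cs.paths[wid] = [f[0] for f in found]
        cs.provenance[wid] = [f[1] for f in found]
    return cs


def orient_to_previous(cs: CandidateSet,
                       prev_heads: dict[int, tuple[int, int]]) -> CandidateSet:
    """Point each candidate head-first using the previous head position.

    The end nearer the worm's previous head becomes the head; the pixel
    order is flipped when needed so ``pixels[0]`` is always the head.
    """
    for wid, paths in cs.paths.items():
        head = np.asarray(prev_heads[wid], float)
        oriented = []
        for p in paths:
            d_first = np.linalg.norm(p.pixels[0] - head)
            d_last = np.linalg.norm(p.pixels[-1] - head)
            if d_last < d_first:
                p = SkeletonPath(p.pixels[::-1].copy())
            oriented.append(p)
        cs.paths[wid] = oriented
    return cs
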