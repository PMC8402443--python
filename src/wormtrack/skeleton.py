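"""Skeleton extraction and its graph representation.

Two skeletonization routes are provided:

* :func:`classical_skeleton` — plain topology-preserving thinning, the
  standard midline of an isolated worm.
* :func:`modified_skeleton` — a width-constrained variant for aggregated
  masks.  Regions of the Euclidean distance transform that are wider than
  any single tracked worm are treated as overlap zones; the mask outside
  the zones is thinned normally and the zones are re-traversed with
  ridge-following shortest paths between the surrounding skeleton stubs.
  Where two worms lie side by side this produces two (or more) parallel
  traversable midlines instead of the single merged one thinning gives.

Both return a :class:`SkeletonGraph`: endpoints and branch-point clusters
as nodes, 1-px pixel chains as edges.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .errors import BranchedSkeletonError, EmptyMaskError

_N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_STRUCT8 = np.ones((3, 3), bool)


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

@dataclass
class SkeletonPath:
    """Ordered 8-connected pixel path, nominally head-first.

    Parameters
    ----------
    pixels : (n, 2) int array of (row, col) coordinates, n >= 2.
    head_first : whether ``pixels[0]`` is the head end.
    """

    pixels: np.ndarray
    head_first: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or len(px) < 2:
            raise ValueError("a skeleton path needs >= 2 (row, col) pixels")
        steps = np.abs(np.diff(px, axis=0))
        if steps.max() > 1:
            raise ValueError("consecutive path pixels must be 8-connected")
        if len({tuple(p) for p in px}) != len(px):
            raise ValueError("path revisits a pixel")
        self.pixels = px

    def __len__(self) -> int:
        return len(self.pixels)

    def reversed(self) -> "SkeletonPath":
        return SkeletonPath(self.pixels[::-1].copy(), head_first=self.head_first)

    def as_list(self) -> list[list[int]]:
        return [[int(r), int(c)] for r, c in self.pixels]


def path_from_points(points: np.ndarray, head_first: bool = True) -> SkeletonPath:
    """Build a SkeletonPath from dense float samples of a curve.

    Rounds to pixels, drops consecutive duplicates and immediate
    backtracks, then validates connectivity.
    """
    pts = np.round(np.asarray(points, float)).astype(int)
    out: list[tuple[int, int]] = []
    index: dict[tuple[int, int], int] = {}
    for p in map(tuple, pts):
        if out and p == out[-1]:
            continue
        if p in index:
            # revisit (wobble or self-crossing after rounding): collapse
            # the loop back to the first occurrence, keeping connectivity
            pos = index[p]
            for q in out[pos + 1:]:
                del index[q]
            out = out[:pos + 1]
            continue
        index[p] = len(out)
        out.append(p)
    return SkeletonPath(np.array(out, int), head_first=head_first)


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

@dataclass
class SkeletonNode:
    id: int
    pixels: tuple[tuple[int, int], ...]
    kind: str  # "end" | "branch"

    @property
    def pos(self) -> tuple[int, int]:
        return self.pixels[0]


@dataclass
class SkeletonGraph:
    """Condensed graph over a 1-px skeleton image.

    Nodes are endpoints (degree-1 pixels) and branch clusters
    (8-connected groups of degree>=3 pixels); edges carry the ordered
    pixel chain joining their incident nodes.
    """

    shape: tuple[int, int]
    nodes: dict[int, SkeletonNode] = field(default_factory=dict)
    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    pixel_set: frozenset = frozenset()

    # -- queries ------------------------------------------------------

    def endpoints(self) -> list[int]:
        return sorted(n for n, node in self.nodes.items() if node.kind == "end")

    def branch_points(self) -> list[int]:
        return sorted(n for n, node in self.nodes.items() if node.kind == "branch")

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoints())

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points())

    def edge_pixels(self, u: int, v: int, key: int) -> np.ndarray:
        return self.graph.edges[u, v, key]["pixels"]

    def skeleton_image(self) -> np.ndarray:
        img = np.zeros(self.shape, bool)
        for r, c in self.pixel_set:
            img[r, c] = True
        return img

    def single_path(self) -> SkeletonPath:
        """Return the unique end-to-end path; raise if the graph branches."""
        if self.n_branch_points or self.graph.number_of_edges() != 1:
            raise BranchedSkeletonError(
                "skeleton is not a single unbranched path "
                f"({self.n_endpoints} endpoints, {self.n_branch_points} branch nodes)"
            )
        (u, v, key) = next(iter(self.graph.edges(keys=True)))
        return SkeletonPath(self.edge_pixels(u, v, key).copy())


def _build_graph(skel: np.ndarray) -> SkeletonGraph:
    pts = {(int(r), int(c)) for r, c in zip(*np.nonzero(skel))}
    g = SkeletonGraph(shape=skel.shape, pixel_set=frozenset(pts))
    if not pts:
        return g

    def nbrs(p):
        r, c = p
        for dr, dc in _N8:
            q = (r + dr, c + dc)
            if q in pts:
                yield q

    deg = {p: sum(1 for _ in nbrs(p)) for p in pts}
    node_px = {p for p in pts if deg[p] != 2}
    if not node_px:  # pure cycle: seed one node so edges exist
        node_px = {min(pts)}

    # cluster adjacent node pixels
    px2node: dict[tuple[int, int], int] = {}
    nid = 0
    for seed in sorted(node_px):
        if seed in px2node:
            continue
        stack, cluster = [seed], []
        px2node[seed] = nid
        while stack:
            p = stack.pop()
            cluster.append(p)
            for q in nbrs(p):
                if q in node_px and q not in px2node:
                    px2node[q] = nid
                    stack.append(q)
        cluster.sort()
        kind = "branch" if (len(cluster) > 1 or deg[cluster[0]] >= 3) else "end"
        g.nodes[nid] = SkeletonNode(nid, tuple(cluster), kind)
        g.graph.add_node(nid)
        nid += 1

    # trace chains of degree-2 pixels between node clusters
    seen_interior: set[tuple[int, int]] = set()
    seen_direct: set[frozenset] = set()
    for p in sorted(node_px):
        for q in sorted(nbrs(p)):
            if q in node_px:
                if px2node[q] != px2node[p]:
                    key = frozenset((p, q))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        g.graph.add_edge(px2node[p], px2node[q],
                                         pixels=np.array([p, q], int))
                continue
            if q in seen_interior:
                continue
            chain = [p, q]
            seen_interior.add(q)
            prev, cur = p, q
            while cur not in node_px:
                nxts = [x for x in nbrs(cur) if x != prev]
                if not nxts:  # dead-end interior pixel (shouldn't happen)
                    break
                prev, cur = cur, nxts[0]
                chain.append(cur)
                if cur not in node_px:
                    seen_interior.add(cur)
            if chain[-1] in node_px:
                g.graph.add_edge(px2node[p], px2node[chain[-1]],
                                 pixels=np.array(chain, int))
    _merge_through_nodes(g)
    return g


def _cluster_route(cluster: tuple, a, b) -> list:
    """BFS pixel route from a to b inside a (tiny) node cluster."""
    if a == b:
        return [a]
    cset = set(cluster)
    prev = {a: None}
    queue = [a]
    while queue:
        p = queue.pop(0)
        for dr, dc in _N8:
            q = (p[0] + dr, p[1] + dc)
            if q in cset and q not in prev:
                prev[q] = p
                if q == b:
                    path = [q]
                    while prev[path[-1]] is not None:
                        path.append(prev[path[-1]])
                    return path[::-1]
                queue.append(q)
    return [a, b]  # disconnected cluster: fall back to a direct jump


def _merge_through_nodes(g: SkeletonGraph) -> None:
    """Collapse 'branch' clusters with only two incident chains.

    Thinning leaves 2x2 clumps along otherwise simple paths; such a
    cluster has pixel degree >= 3 but only two chains attached, so it
    belongs inside an edge, not at a junction.
    """
    changed = True
    while changed:
        changed = False
        for nid in list(g.nodes):
            node = g.nodes[nid]
            if node.kind != "branch":
                continue
            inc = list(g.graph.edges(nid, keys=True))
            if len(inc) != 2 or any(u == v for u, v, _ in inc):
                continue
            (u1, v1, k1), (u2, v2, k2) = inc
            cset = set(node.pixels)
            c1 = g.graph.edges[u1, v1, k1]["pixels"]
            c2 = g.graph.edges[u2, v2, k2]["pixels"]
            if tuple(c1[-1]) not in cset:
                c1 = c1[::-1]
            if tuple(c2[0]) not in cset:
                c2 = c2[::-1]
            o1 = v1 if u1 == nid else u1
            o2 = v2 if u2 == nid else u2
            bridge = _cluster_route(node.pixels, tuple(c1[-1]), tuple(c2[0]))
            merged = [tuple(p) for p in c1] + bridge[1:] \
                + [tuple(p) for p in c2[1:]]
            # drop accidental duplicates introduced by the bridge
            seen, clean = set(), []
            dup = False
            for p in merged:
                if p in seen:
                    dup = True
                    break
                seen.add(p)
                clean.append(p)
            if dup:
                continue
            g.graph.remove_edge(u1, v1, k1)
            g.graph.remove_edge(u2, v2, k2)
            g.graph.remove_node(nid)
            del g.nodes[nid]
            g.graph.add_edge(o1, o2, pixels=np.array(clean, int))
            changed = True
            break


def _prune_spurs(pts: set[tuple[int, int]], shape, min_len: int) -> set:
    """Drop terminal chains of <= min_len pixels hanging off branch nodes."""
    img = np.zeros(shape, bool)
    for r, c in pts:
        img[r, c] = True
    for _ in range(2):
        g = _build_graph(img)
        if g.graph.number_of_edges() <= 1:
            break
        removed = False
        for u, v, key, data in list(g.graph.edges(keys=True, data=True)):
            chain = data["pixels"]
            if u == v:  # tiny thinning loop: drop its interior pixels
                if len(chain) <= 2 * min_len + 2:
                    drop = chain[1:-1]
                else:
                    continue
            elif len(chain) > min_len:
                continue
            else:
                ku, kv = g.nodes[u].kind, g.nodes[v].kind
                if ku == "end" and kv == "branch":
                    drop = chain[:-1]
                elif kv == "end" and ku == "branch":
                    drop = chain[1:]
                else:
                    continue
            for r, c in drop:
                img[r, c] = False
            removed = True
        if not removed:
            break
    return {(int(r), int(c)) for r, c in zip(*np.nonzero(img))}


def skeleton_graph_from_image(skel: np.ndarray, prune_px: int = 3) -> SkeletonGraph:
    pts = {(int(r), int(c)) for r, c in zip(*np.nonzero(skel))}
    if prune_px:
        pts = _prune_spurs(pts, skel.shape, prune_px)
    img = np.zeros(skel.shape, bool)
    for r, c in pts:
        img[r, c] = True
    return _build_graph(img)


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def classical_skeleton(mask: np.ndarray, prune_px: int = 3) -> SkeletonGraph:
    """Topology-preserving thinning skeleton as a graph.

    Spurs up to ``prune_px`` pixels (thinning artifacts at 3-5 px body
    widths) are removed.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyMaskError("cannot skeletonize an empty mask")
    return skeleton_graph_from_image(skeletonize(mask), prune_px=prune_px)


def _ridge_path(allowed: np.ndarray, dist: np.ndarray, width_min: float,
                start: tuple[int, int], goal: tuple[int, int]):
    """Deterministic Dijkstra from start to goal over allowed pixels.

    Step cost is the Euclidean step length plus a small penalty for
    pixels shallower than width_min, so routes prefer the distance-
    transform ridge of the overlap zone.
    """
    if not (allowed[start] and allowed[goal]):
        return None
    best: dict[tuple[int, int], float] = {start: 0.0}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    pq = [(0.0, start)]
    H, W = allowed.shape
    while pq:
        cost, p = heapq.heappop(pq)
        if p == goal:
            path = [p]
            while p in prev:
                p = prev[p]
                path.append(p)
            return path[::-1]
        if cost > best.get(p, np.inf):
            continue
        r, c = p
        for dr, dc in _N8:
            q = (r + dr, c + dc)
            if not (0 <= q[0] < H and 0 <= q[1] < W) or not allowed[q]:
                continue
            step = 1.4142135623730951 if dr and dc else 1.0
            w = cost + step + 0.25 * max(0.0, width_min - dist[q])
            if w < best.get(q, np.inf) - 1e-12:
                best[q] = w
                prev[q] = p
                heapq.heappush(pq, (w, q))
    return None


def modified_skeleton(mask: np.ndarray, width_min: float, width_max: float,
                      prune_px: int = 3, stub_reach: float = 3.0) -> SkeletonGraph:
    """Width-constrained skeleton creating separating paths in overlaps.

    ``width_min`` / ``width_max`` are the extremes of the active worm
    width (half-width) models.  Where the distance transform never
    exceeds ``width_max`` the mask cannot contain stacked bodies and the
    classical skeleton is returned unchanged.  Otherwise each overlap
    zone (connected region of distance > width_max / 1.5 containing a
    distance-transform peak above width_max) is cut out, the remainder
    is thinned, and the stub endpoints around each zone are reconnected
    pairwise with ridge-following paths through the zone.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyMaskError("cannot skeletonize an empty mask")
    if width_min > width_max:
        raise ValueError("width_min must not exceed width_max")
    dist = ndi.distance_transform_edt(mask)
    if dist.max() <= width_max:
        return classical_skeleton(mask, prune_px=prune_px)

    # overlap zones: only where the mask is wider than any single worm
    # can be (stacked bodies).  A laxer threshold such as width_max/1.5
    # floods the normal body interior too (its own ridge depth is about
    # one worm width) and destroys the stub geometry around the overlap.
    zone = dist > width_max
    if not zone.any():
        return classical_skeleton(mask, prune_px=prune_px)

    core = mask & ~zone
    core_pts: set[tuple[int, int]] = set()
    if core.any():
        core_graph = skeleton_graph_from_image(skeletonize(core), prune_px=prune_px)
        core_pts = set(core_graph.pixel_set)
        stub_ends = [core_graph.nodes[i].pos for i in core_graph.endpoints()]
    else:
        core_graph = None
        stub_ends = []

    out_pts = set(core_pts)
    zlab, zn = ndi.label(zone, structure=_STRUCT8)
    # nearest zone pixel for each stub endpoint
    _, (ir, ic) = ndi.distance_transform_edt(~zone, return_indices=True)
    zdist = ndi.distance_transform_edt(~zone)
    for zi in range(1, zn + 1):
        zmask = zlab == zi
        entries = sorted(
            p for p in stub_ends
            if zdist[p] <= stub_reach and zlab[ir[p], ic[p]] == zi
        )
        if len(entries) < 2:
            # nothing to reconnect: keep the zone's own midline for coverage
            zskel = skeletonize(zmask)
            out_pts |= {(int(r), int(c)) for r, c in zip(*np.nonzero(zskel))}
            continue
        allowed = mask & ndi.binary_dilation(zmask, _STRUCT8,
                                             iterations=int(np.ceil(stub_reach)) + 1)
        for a, b in itertools.combinations(entries, 2):
            allowed_ab = allowed.copy()
            allowed_ab[a] = True
            allowed_ab[b] = True
            path = _ridge_path(allowed_ab, dist, width_min, a, b)
            if path is not None:
                out_pts |= set(path)

    img = np.zeros(mask.shape, bool)
    for r, c in out_pts:
        img[r, c] = True
    return skeleton_graph_from_image(img, prune_px=prune_px)
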