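"""Crossing-node detection, branch pairing and FWHM crossing-order calls.

Skeleton pixels with three or more neighbours mark junction/crossing
candidates; connected candidate pixels are grouped into nodes, nodes
within ~double the tip-convolved DNA width are merged (they belong to one
crossing that the thinning split), and remaining odd-branch nodes are
joined pairwise along the skeleton so every crossing has even parity.

At each crossing the emanating branches are paired by their propagation
vectors (most anti-parallel pair continues through the node), a height
profile is read along each paired through-path, and the duplex whose
profile has the greatest full width at half maximum is called over-passing
— an intact over-passing strand forms a wide "humpback bridge" while the
under-passing profile rises and falls steeply.  The spread of the FWHMs
gives the average crossing order reliability

    COR = (1/N) * sum over FWHM pairs of [1 - min(pair)/max(pair)]

which is 0 for equal widths (uninformative) and approaches 1 for a
confident call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ParityError, ValidationError
from .imgproc import HeightMap
from .skeleton import Skeleton

#: default threshold on COR above which a crossing call is considered
#: reliable for downstream topology reporting
DEFAULT_RELIABILITY_THRESHOLD = 0.263


@dataclass
class BranchPair:
    """Two branches that continue through a crossing as one duplex."""

    branch_a: int
    branch_b: int
    path: list[tuple[int, int]] = field(default_factory=list)
    profile: np.ndarray | None = None
    arc_nm: np.ndarray | None = None
    fwhm_nm: float = 0.0
    is_over: bool = False
    pseudo_z: int = 0


@dataclass
class CrossingNode:
    """A merged crossing region with its emanating branches."""

    node_id: int
    pixels: set[tuple[int, int]]
    branches: list[list[tuple[int, int]]] = field(default_factory=list)
    pairs: list[BranchPair] = field(default_factory=list)
    degenerate: bool = False
    cor: float | None = None

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def parity(self) -> str:
        return "even" if self.n_branches % 2 == 0 else "odd"

    @property
    def is_junction(self) -> bool:
        """3-branch nodes are replication-fork junctions, not crossings."""
        return self.n_branches == 3

    def centroid(self) -> np.ndarray:
        return np.mean(np.array(sorted(self.pixels)), axis=0)


@dataclass
class CrossingReliability:
    fwhms: list[float]
    n_pairs: int
    cor: float


# ---------------------------------------------------------------------------
# node detection and merging
# ---------------------------------------------------------------------------

def detect_nodes(sk: Skeleton) -> list[CrossingNode]:
    """Group junction pixels (degree >= 3) into crossing/junction nodes."""
    junction = {p for p in sk.pixels if sk.graph.degree[p] >= 3}
    if not junction:
        return []
    sub = sk.graph.subgraph(junction)
    nodes = []
    for i, comp in enumerate(
        sorted(nx.connected_components(sub), key=lambda s: min(s))
    ):
        nodes.append(CrossingNode(i, set(comp)))
    for node in nodes:
        node.branches = _node_branches(sk, node.pixels)
    return nodes


def _region_distance_nm(sk, a: set, b: set) -> tuple[float, tuple, tuple]:
    pa = np.array(sorted(a), dtype=float)
    pb = np.array(sorted(b), dtype=float)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return (
        float(d[i, j]) * sk.pixel_size_nm,
        tuple(int(v) for v in pa[i]),
        tuple(int(v) for v in pb[j]),
    )


def _skeleton_path(sk: Skeleton, a: tuple, b: tuple) -> list[tuple[int, int]]:
    try:
        return nx.shortest_path(sk.graph, a, b)
    except nx.NetworkXNoPath:
        return []


def merge_close_nodes(
    nodes: list[CrossingNode],
    sk: Skeleton,
    merge_dist_nm: float = 7.0,
    odd_connect_max_nm: float = 40.0,
) -> list[CrossingNode]:
    """Merge nodes that belong to one crossing region.

    Nodes whose pixel sets come within ``merge_dist_nm`` (about twice the
    tip-convolved DNA width) are unioned together with the connecting
    skeleton path.  Remaining odd-branch nodes — typically the two
    3-branch halves of a shallow-angle crossing that thinning pulled apart
    — are joined pairwise along the shortest skeleton path, provided it is no
    longer than ``odd_connect_max_nm`` — generous enough for the split
    halves of shallow-angle crossings while genuine replication-fork
    junctions, separated by whole segments, are left alone.
    """
    groups = [dict(pixels=set(n.pixels)) for n in nodes]
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if groups[i] is None or groups[j] is None:
                continue
            d, pi, pj = _region_distance_nm(
                sk, groups[i]["pixels"], groups[j]["pixels"]
            )
            if d <= merge_dist_nm:
                path = _skeleton_path(sk, pi, pj)
                groups[i]["pixels"] |= groups[j]["pixels"] | set(path)
                groups[j] = None
                merged = True
        groups = [g for g in groups if g is not None]

    # connect odd-parity nodes pairwise along short skeleton paths
    def branch_count(g):
        return len(_node_branches(sk, g["pixels"]))

    changed = True
    while changed:
        changed = False
        odd = [g for g in groups if branch_count(g) % 2 == 1]
        best = None
        for gi, gj in itertools.combinations(odd, 2):
            d, pi, pj = _region_distance_nm(sk, gi["pixels"], gj["pixels"])
            if d > odd_connect_max_nm or (best is not None and d >= best[0]):
                continue
            path = _skeleton_path(sk, pi, pj)
            others = set().union(
                *(g["pixels"] for g in groups if g is not gi and g is not gj)
            ) if len(groups) > 2 else set()
            if others & set(path[1:-1]):
                continue  # would swallow a third node: not the same crossing
            best = (d, gi, gj, path)
        if best is not None:
            _, gi, gj, path = best
            gi["pixels"] |= gj["pixels"] | set(path)
            groups.remove(gj)
            changed = True

    out = []
    for i, g in enumerate(sorted(groups, key=lambda g: min(g["pixels"]))):
        node = CrossingNode(i, g["pixels"])
        node.branches = _node_branches(sk, node.pixels)
        out.append(node)
    return out


def _node_branches(
    sk: Skeleton, region: set, region_nm: float = 20.0
) -> list[list[tuple[int, int]]]:
    """Ordered pixel paths emanating from a node region, clipped to half
    the crossing-region size measured from the region boundary."""
    clip_nm = region_nm / 2.0
    starts: list[tuple[int, int]] = []
    for p in region:
        for q in sk.graph.neighbors(p):
            if q not in region and q not in starts:
                starts.append(q)
    # stubs that connect within two steps outside the region are the same
    # branch (staircase pixels can both touch the node region)
    outside = sk.graph.subgraph([p for p in sk.pixels if p not in region])
    near: dict[tuple[int, int], set] = {
        s: set(nx.single_source_shortest_path_length(outside, s, cutoff=2))
        for s in starts
    }
    start_groups: list[list[tuple[int, int]]] = []
    for s in sorted(starts):
        for grp in start_groups:
            if any(t in near[s] for t in grp):
                grp.append(s)
                break
        else:
            start_groups.append([s])

    branches = []
    for grp in sorted(start_groups):
        start = grp[0]
        path = [start]
        used = set(grp) | region
        cur = start
        length = 0.0
        while length < clip_nm:
            nxts = [
                q for q in sk.graph.neighbors(cur)
                if q not in used and q not in region
            ]
            if not nxts:
                break
            nxt = min(nxts)
            if sk.graph.degree[nxt] >= 3:
                break  # ran into another junction
            step = np.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
            length += step * sk.pixel_size_nm
            path.append(nxt)
            used.add(nxt)
            cur = nxt
        branches.append(path)
    return branches


# ---------------------------------------------------------------------------
# branch pairing
# ---------------------------------------------------------------------------

def _branch_direction(node: CrossingNode, path: list) -> np.ndarray:
    """Unit propagation vector of a branch, oriented away from the node."""
    pts = np.array(path, dtype=float)
    centroid = node.centroid()
    if len(pts) == 1:
        v = pts[0] - centroid
    else:
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        v = vt[0]
        # orient away from the node (toward the branch's far end)
        if np.dot(v, pts[-1] - centroid) < 0:
            v = -v
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _perfect_matchings(indices: list[int]):
    if not indices:
        yield []
        return
    first, rest = indices[0], indices[1:]
    for k, other in enumerate(rest):
        for sub in _perfect_matchings(rest[:k] + rest[k + 1:]):
            yield [(first, other)] + sub


def pair_branches(node: CrossingNode, region_nm: float = 20.0) -> CrossingNode:
    """Pair emanating branches so each duplex continues through the node.

    Each branch gets a least-squares propagation vector over its clipped
    path; branches are paired by the maximum-weight perfect matching with
    weight -cos(angle), so the most anti-parallel branches are joined.
    The exact matching is found by enumeration (nodes have few branches).
    """
    k = node.n_branches
    if k < 4 or k % 2 == 1:
        raise ParityError(
            f"node {node.node_id} has {k} branches; only even counts >= 4 "
            "can be paired (3-branch nodes are junctions)"
        )
    dirs = [_branch_direction(node, b) for b in node.branches]
    best, best_w = None, -np.inf
    for matching in _perfect_matchings(list(range(k))):
        w = sum(-float(np.dot(dirs[i], dirs[j])) for i, j in matching)
        if w > best_w + 1e-12:
            best, best_w = matching, w
    node.pairs = [BranchPair(i, j) for i, j in sorted(best)]
    return node


# ---------------------------------------------------------------------------
# FWHM crossing-order determination
# ---------------------------------------------------------------------------

def fwhm(profile: np.ndarray, arc: np.ndarray) -> float:
    """Full width at half maximum of a height profile along an arc.

    The baseline is the profile minimum; the width is measured where the
    profile exceeds (min + max) / 2, with linear interpolation at the two
    half-maximum crossings.
    """
    profile = np.asarray(profile, dtype=float)
    arc = np.asarray(arc, dtype=float)
    lo, hi = float(profile.min()), float(profile.max())
    half = 0.5 * (lo + hi)
    above = profile >= half
    if not above.any():
        return 0.0
    idx = np.nonzero(above)[0]
    first, last = int(idx[0]), int(idx[-1])
    if first > 0:
        f = (half - profile[first - 1]) / (profile[first] - profile[first - 1])
        left = arc[first - 1] + f * (arc[first] - arc[first - 1])
    else:
        left = arc[0]
    if last < len(profile) - 1:
        f = (half - profile[last]) / (profile[last + 1] - profile[last])
        right = arc[last] + f * (arc[last + 1] - arc[last])
    else:
        right = arc[-1]
    return float(right - left)


def _through_path(sk: Skeleton, node: CrossingNode, pair: BranchPair):
    ba = node.branches[pair.branch_a]
    bb = node.branches[pair.branch_b]
    allowed = set(ba) | set(bb) | node.pixels
    sub = sk.graph.subgraph(allowed)
    try:
        mid = nx.shortest_path(sub, ba[0], bb[0])
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        mid = [ba[0], bb[0]]
    return list(reversed(ba[1:])) + mid + bb[1:]


def call_crossing_order(
    node: CrossingNode,
    sk: Skeleton,
    hm: HeightMap,
    flat_tolerance_nm: float = 0.05,
) -> CrossingNode:
    """Determine the over-passing duplex of a paired crossing by FWHM.

    The height profile along each pair's through-path (branch a -> node ->
    branch b) is sampled from the flattened image; the pair with the
    maximal FWHM is marked over-passing and pseudo-heights are assigned as
    ascending integer ranks (deepest under = 1).  Ties or flat profiles
    flag the node degenerate with reliability 0.
    """
    if not node.pairs:
        raise ParityError(f"node {node.node_id} has no paired branches")
    for pair in node.pairs:
        path = _through_path(sk, node, pair)
        heights = np.array([hm.heights[p] for p in path])
        arc = np.zeros(len(path))
        for i in range(1, len(path)):
            dr = path[i][0] - path[i - 1][0]
            dc = path[i][1] - path[i - 1][1]
            arc[i] = arc[i - 1] + np.hypot(dr, dc) * sk.pixel_size_nm
        pair.path = path
        pair.profile = heights
        pair.arc_nm = arc
        if heights.max() - heights.min() < flat_tolerance_nm:
            pair.fwhm_nm = float(arc[-1] - arc[0])
            node.degenerate = True
        else:
            pair.fwhm_nm = fwhm(heights, arc)
    fwhms = [p.fwhm_nm for p in node.pairs]
    order = np.argsort(np.array(fwhms), kind="stable")
    for rank, pidx in enumerate(order, start=1):
        node.pairs[pidx].pseudo_z = rank
        node.pairs[pidx].is_over = rank == len(fwhms)
    if max(fwhms) > 0 and min(fwhms) / max(fwhms) > 1 - 1e-6:
        node.degenerate = True
    node.cor = crossing_reliability(node).cor
    return node


def crossing_reliability(node: CrossingNode) -> CrossingReliability:
    """Average crossing order reliability over all FWHM pairings.

    For k duplexes through one crossing, all C(k,2) unordered FWHM
    pairings contribute 1 - min/max and the COR is their mean; equal
    widths give 0 (an uninformative crossing).
    """
    fwhms = [p.fwhm_nm for p in node.pairs]
    if any(f <= 0 for f in fwhms):
        raise ValidationError("crossing has a non-positive FWHM")
    pairings = list(itertools.combinations(fwhms, 2))
    vals = [1.0 - min(a, b) / max(a, b) for a, b in pairings]
    cor = float(np.mean(vals)) if vals else 0.0
    return CrossingReliability(fwhms, len(pairings), cor)


def cor_from_fwhms(fwhms: list[float]) -> float:
    """COR of a single crossing given its per-duplex FWHM values."""
    if any(f <= 0 for f in fwhms):
        raise ValidationError("FWHM values must be positive")
    pairs = list(itertools.combinations(fwhms, 2))
    if not pairs:
        return 0.0
    return float(np.mean([1.0 - min(a, b) / max(a, b) for a, b in pairs]))
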