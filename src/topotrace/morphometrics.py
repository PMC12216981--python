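"""Per-molecule measurements, replication-intermediate analysis,
conformation classes and the data-cleanup filters.

Contour lengths are measured on the traced backbone; the pixel path is
lightly smoothed (circular moving average) before summing Euclidean
steps, which removes the systematic overestimate of raw (1, sqrt 2) chain
stepping so that measured lengths track B-form expectations (0.34 nm per
base pair).  Replication intermediates are analysed by breaking the
skeleton at odd-branch junctions: a theta structure yields exactly three
segments whose most length-dissimilar member is the unreplicated arm,
and a reversed fork appears as a 4-way junction with one short (< 50 nm)
terminating branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .crossings import CrossingNode
from .errors import ConfigError, DegenerateError
from .skeleton import Skeleton
from .tracing import Molecule

RISE_NM_PER_BP = 0.34


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def _smooth_closed(pts: np.ndarray, window: int) -> np.ndarray:
    n = len(pts)
    if window <= 1 or n <= window:
        return pts
    kernel = np.ones(window) / window
    out = np.empty_like(pts, dtype=float)
    for d in range(pts.shape[1]):
        ext = np.concatenate([pts[-window:, d], pts[:, d], pts[:window, d]])
        out[:, d] = np.convolve(ext, kernel, mode="same")[window: window + n]
    return out


def _smooth_open(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(pts) <= window:
        return pts.astype(float)
    out = np.empty_like(pts, dtype=float)
    half = window // 2
    for i in range(len(pts)):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def contour_length(
    mol: Molecule, pixel_size_nm: float, smooth_px: int = 5
) -> float:
    """Contour length of a traced molecule in nm.

    With ``smooth_px`` = 0 this is the raw digital chain length (1 per
    axial step, sqrt 2 per diagonal, closing step included for closed
    molecules); the default smoothing window removes digitisation jitter.
    """
    if len(mol.pixels) < 3:
        raise DegenerateError("trace too short for a contour length")
    if smooth_px <= 1:
        return mol.length_nm(pixel_size_nm)
    pts = np.array(mol.pixels, dtype=float)
    pts = (
        _smooth_closed(pts, smooth_px)
        if mol.closed
        else _smooth_open(pts, smooth_px)
    )
    if mol.closed:
        pts = np.vstack([pts, pts[:1]])
    return float(
        np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)) * pixel_size_nm
    )


def path_length_nm(
    path: list[tuple[int, int]], pixel_size_nm: float, smooth_px: int = 5
) -> float:
    """Length of an open pixel path with the same smoothing treatment."""
    pts = np.array(path, dtype=float)
    if len(pts) < 2:
        return 0.0
    pts = _smooth_open(pts, smooth_px)
    return float(
        np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)) * pixel_size_nm
    )


def expected_length(bp: float, rise_nm_per_bp: float = RISE_NM_PER_BP) -> float:
    """Expected B-form contour length of a molecule in nm, rounded to nm
    for reporting (2260 bp -> 768 nm)."""
    if bp < 0:
        raise ValueError("base-pair count cannot be negative")
    return float(round(bp * rise_nm_per_bp))


def percentage_error(predicted: float, true: float) -> float:
    """|predicted - true| / true x 100."""
    if true <= 0:
        raise ValueError("true length must be positive")
    return abs(predicted - true) / true * 100.0


# ---------------------------------------------------------------------------
# per-object statistics
# ---------------------------------------------------------------------------

@dataclass
class MoleculeStats:
    """Morphometric feature vector of one traced object."""

    object_id: int
    contour_length_nm: float | None
    contour_lengths_nm: list[float] = field(default_factory=list)
    n_molecules: int = 0
    n_crossings: int = 0
    avg_cor: float | None = None
    min_cor: float | None = None
    bounding_area_nm2: float = 0.0
    smallest_bounding_width_nm: float = 0.0
    smallest_bounding_length_nm: float = 0.0
    aspect_ratio: float = 1.0
    max_feret_nm: float = 0.0
    grain_endpoints: int = 0
    grain_junctions: int = 0
    end_to_end_nm: float = 0.0


def grain_shape_features(pixels: np.ndarray, pixel_size_nm: float) -> dict:
    """Bounding-box and Feret features of a grain mask region.

    Computed on the mask, not the skeleton: the minimum rotated rectangle
    gives the smallest bounding width/length and their ratio; the maximum
    Feret diameter is the largest pairwise extent.
    """
    from shapely.geometry import MultiPoint

    mp = MultiPoint([(float(c), float(r)) for r, c in pixels])
    rect = mp.convex_hull.minimum_rotated_rectangle
    if rect.geom_type == "Polygon":
        xs, ys = rect.exterior.coords.xy
        sides = [
            np.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i]) for i in range(3)
        ]
        w, l = sorted(sides)[0], sorted(sides)[-1]
    else:  # degenerate (line/point) region
        w, l = 0.0, mp.length
    hull = np.array(mp.convex_hull.exterior.coords) \
        if mp.convex_hull.geom_type == "Polygon" else np.array(mp.convex_hull.coords)
    feret = max(
        np.linalg.norm(a - b) for a, b in itertools.combinations(hull, 2)
    ) if len(hull) > 1 else 0.0
    return {
        "bounding_area_nm2": w * l * pixel_size_nm**2,
        "smallest_bounding_width_nm": w * pixel_size_nm,
        "smallest_bounding_length_nm": l * pixel_size_nm,
        "aspect_ratio": (l / w) if w > 0 else np.inf,
        "max_feret_nm": float(feret) * pixel_size_nm,
    }


# ---------------------------------------------------------------------------
# replication intermediates
# ---------------------------------------------------------------------------

@dataclass
class ThetaAnalysis:
    is_theta: bool
    n_forks: int = 0
    segment_lengths_nm: list[float] = field(default_factory=list)
    unreplicated_length_nm: float | None = None
    replicated_lengths_nm: list[float] = field(default_factory=list)
    shortest_segment_nm: float | None = None
    low_confidence: bool = False
    reason: str = ""


def _junction_segments(sk: Skeleton, nodes: list[CrossingNode]):
    """Segments left after breaking the skeleton at odd-branch junctions."""
    region = set()
    for n in nodes:
        if n.n_branches % 2 == 1 or n.n_branches == 4:
            region |= n.pixels
    sub = sk.graph.subgraph([p for p in sk.pixels if p not in region])
    return [sorted(c) for c in nx.connected_components(sub)]


def analyze_theta(
    sk: Skeleton,
    nodes: list[CrossingNode],
    dissimilarity_margin: float = 0.15,
    smooth_px: int = 5,
) -> ThetaAnalysis:
    """Identify a theta structure and its unreplicated segment.

    The skeleton is broken at its junction nodes; objects with exactly
    three segments bounded by two 3-way forks qualify.  The unreplicated
    arm is the segment most dissimilar in length from the other two (the
    two replicated arms are copies of each other and should match); when
    the dissimilarity is below ``dissimilarity_margin`` (relative), the
    call is flagged low-confidence.  The shortest segment is also
    reported, since for a partially replicated molecule both conventions
    usually coincide.
    """
    forks = [n for n in nodes if n.n_branches == 3]
    segments = _junction_segments(sk, nodes)
    if len(segments) != 3 or len(forks) != 2:
        return ThetaAnalysis(
            False,
            n_forks=len(forks),
            reason=f"{len(segments)} segments, {len(forks)} forks",
        )
    comps = []
    for seg in segments:
        g = sk.graph.subgraph(seg)
        ends = [p for p in seg if g.degree[p] <= 1]
        path = seg
        if len(ends) >= 1:
            try:
                path = nx.shortest_path(
                    g, ends[0], ends[-1] if len(ends) > 1 else ends[0]
                )
            except nx.NetworkXNoPath:
                pass
        comps.append(path_length_nm(path, sk.pixel_size_nm, smooth_px))
    lens = np.array(comps)
    dissim = [
        abs(lens[i] - lens[(i + 1) % 3]) + abs(lens[i] - lens[(i + 2) % 3])
        for i in range(3)
    ]
    unrep = int(np.argmax(dissim))
    rel_margin = dissim[unrep] / max(lens.mean(), 1e-9)
    return ThetaAnalysis(
        True,
        n_forks=2,
        segment_lengths_nm=list(map(float, lens)),
        unreplicated_length_nm=float(lens[unrep]),
        replicated_lengths_nm=[float(v) for i, v in enumerate(lens) if i != unrep],
        shortest_segment_nm=float(lens.min()),
        low_confidence=rel_margin < dissimilarity_margin,
    )


def detect_reversed_fork(
    sk: Skeleton,
    nodes: list[CrossingNode],
    max_branch_nm: float = 50.0,
    smooth_px: int = 5,
) -> tuple[bool, float | None]:
    """Reversed replication forks: 4-way junctions with one short arm.

    A fork that has regressed extrudes a fourth, short (< ``max_branch_nm``)
    arm; a plain DNA crossing is also 4-way but none of its branches
    terminates, so crossings never trigger the rule.
    """
    for node in nodes:
        if node.n_branches != 4:
            continue
        short = []
        terminating = 0
        for start_branch in node.branches:
            # walk to the branch's end: endpoint or next junction
            path = list(start_branch)
            prev = path[-2] if len(path) > 1 else None
            cur = path[-1]
            while True:
                nxts = [
                    q
                    for q in sk.graph.neighbors(cur)
                    if q != prev and q not in node.pixels
                ]
                if not nxts or sk.graph.degree[cur] >= 3:
                    break
                nxt = min(nxts)
                path.append(nxt)
                prev, cur = cur, nxt
                if sk.graph.degree[cur] == 1:
                    break
            if sk.graph.degree[path[-1]] == 1:
                terminating += 1
                length = path_length_nm(path, sk.pixel_size_nm, smooth_px)
                if length < max_branch_nm:
                    short.append(length)
        if terminating >= 1 and len(short) == 1:
            return True, short[0]
    return False, None


# ---------------------------------------------------------------------------
# conformation classes
# ---------------------------------------------------------------------------

@dataclass
class ConformationRules:
    """User-editable rule table for catenane conformation classes.

    These defaults are heuristics expressed on the node statistics (the
    published rule table is supplementary material and not reproduced
    here); results that depend on them should be treated accordingly.
    """

    open_n_nodes: int = 4
    open_branches: int = 4
    clustered_min_branches: int = 6
    bowtie_min_branches: int = 8
    taut_node_range: tuple[int, int] = (2, 3)
    min_separation_nm: float = 7.0
    collinear_tol_nm: float = 14.0


def classify_conformation(
    sk: Skeleton,
    nodes: list[CrossingNode],
    rules: ConformationRules | None = None,
) -> str:
    """Assign open / taut / clustered / bow-tie / unclassified.

    Works from node counts and per-node branch counts only, so it applies
    to molecules that cannot be traced (tangled or clustered objects).
    """
    rules = rules or ConformationRules()
    if not nodes:
        return "unclassified"
    branches = [n.n_branches for n in nodes]
    if len(nodes) == 1 and branches[0] >= rules.bowtie_min_branches:
        region = nodes[0].pixels
        lobes = nx.number_connected_components(
            sk.graph.subgraph([p for p in sk.pixels if p not in region])
        )
        if lobes == 2:
            return "bow-tie"
    if any(b >= rules.clustered_min_branches for b in branches):
        return "clustered"
    cents = np.array([n.centroid() for n in nodes], dtype=float)
    if (
        len(nodes) == rules.open_n_nodes
        and all(b == rules.open_branches for b in branches)
    ):
        seps = [
            np.linalg.norm(a - b) * sk.pixel_size_nm
            for a, b in itertools.combinations(cents, 2)
        ]
        if min(seps) > rules.min_separation_nm:
            return "open"
    lo, hi = rules.taut_node_range
    if lo <= len(nodes) <= hi and all(b >= 4 for b in branches):
        if len(nodes) == 2:
            return "taut"
        centred = cents - cents.mean(axis=0)
        _, sv, vt = np.linalg.svd(centred, full_matrices=False)
        resid = np.abs(centred @ vt[1]) * sk.pixel_size_nm
        if resid.max() <= rules.collinear_tol_nm:
            return "taut"
    return "unclassified"


# ---------------------------------------------------------------------------
# data cleanup
# ---------------------------------------------------------------------------

#: cleanup steps applied per analysis mode
CLEANUP_MODES = {
    "topology": (1, 2, 3),
    "contour_length": (1, 2, 3, 4),
    "crossing_distributions": (1, 2, 4),
    "conformation": (1, 2, 3),
    "surface_compaction": (),
    "replication": (),
}


def cleanup_filter(
    records: pd.DataFrame,
    mode: str,
    expected_molecules: int | None = None,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Apply the per-analysis cleanup steps and log removal counts.

    Steps: (1) empty contour length — the tracing failed; (2) the object
    contains linear molecules — broken masking or skeletonisation;
    (3) more than two duplexes at a single crossing — unresolvable
    clustered crossing; (4) molecule count differs from the expectation
    (1 for knots, 2 for catenanes).
    """
    if mode not in CLEANUP_MODES:
        raise ConfigError(
            f"unknown cleanup mode {mode!r}; choose from {sorted(CLEANUP_MODES)}"
        )
    df = records.copy()
    removed: dict[int, int] = {}
    for step in CLEANUP_MODES[mode]:
        if step == 1:
            bad = df["contour_length_nm"].isna()
        elif step == 2:
            bad = df.get("n_linear_molecules", 0) > 0
        elif step == 3:
            bad = df.get("max_duplexes_per_crossing", 0) > 2
        elif step == 4:
            expect = (
                df["expected_molecules"]
                if "expected_molecules" in df
                else expected_molecules
            )
            if expect is None:
                raise ConfigError(
                    "cleanup step 4 needs expected_molecules (1 for knots, "
                    "2 for catenanes)"
                )
            bad = df["n_molecules"] != expect
        removed[step] = int(np.asarray(bad).sum())
        df = df[~np.asarray(bad)]
    return df, removed
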