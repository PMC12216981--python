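"""Ordering skeleton segments into continuous per-molecule NXYZ traces.

The pruned skeleton is split into crossing regions and connecting
segments.  Starting from an endpoint (linear molecules) or the
lexicographically first connecting segment (closed molecules), segments
are concatenated by following the branch pairing through every crossing
until the trace returns to its start; leftover segments seed further
molecules, which is what separates the individual circles of a catenane.
Crossing traversals write the pair's pseudo-height (ascending integer
rank, deepest under = 1) into the trace, producing the NXYZ array — index,
x, y, pseudo-height — that the topology stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .crossings import CrossingNode
from .errors import TracingError
from .skeleton import Skeleton

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class Molecule:
    """One traced molecule: ordered pixels with pseudo-heights."""

    pixels: list[tuple[int, int]]
    pseudo_z: list[int]
    closed: bool

    def length_nm(self, pixel_size_nm: float) -> float:
        pts = self.pixels + ([self.pixels[0]] if self.closed else [])
        steps = 0.0
        for a, b in zip(pts, pts[1:]):
            steps += _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0
        return steps * pixel_size_nm


@dataclass
class NXYZTrace:
    """Per-object bundle of ordered molecule traces."""

    object_id: int
    molecules: list[Molecule]
    pixel_size_nm: float
    node_cor: dict[int, float] = field(default_factory=dict)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def as_arrays(self) -> list[np.ndarray]:
        """Per-molecule (N,3) arrays of (x, y, pseudo_z); x = column."""
        out = []
        for mol in self.molecules:
            arr = np.array(
                [(c, r, z) for (r, c), z in zip(mol.pixels, mol.pseudo_z)],
                dtype=int,
            )
            out.append(arr)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for mid, mol in enumerate(self.molecules):
            for n, ((r, c), z) in enumerate(zip(mol.pixels, mol.pseudo_z)):
                rows.append(
                    (self.object_id, mid, n, c, r, z, mol.closed)
                )
        return pd.DataFrame(
            rows,
            columns=["object_id", "molecule_id", "N", "X", "Y", "Z", "closed"],
        )


def _segment_paths(sk: Skeleton, region: set) -> list[list[tuple[int, int]]]:
    """Connected components of the skeleton minus crossing regions, each
    ordered into a pixel path (or cycle)."""
    sub = sk.graph.subgraph([p for p in sk.pixels if p not in region])
    paths = []
    for comp in sorted(nx.connected_components(sub), key=min):
        g = sub.subgraph(comp)
        ends = sorted(p for p in comp if g.degree[p] <= 1)
        if ends:
            start = ends[0]
        else:  # cycle with no crossing: start at the lowest pixel
            start = min(comp)
        path = [start]
        prev = None
        cur = start
        while True:
            nxts = sorted(q for q in g.neighbors(cur) if q != prev)
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            path.append(nxt)
            prev, cur = cur, nxt
            if len(path) > len(comp):
                raise TracingError("segment ordering failed")
        paths.append(path)
    return paths


def order_trace(
    sk: Skeleton,
    nodes: list[CrossingNode],
    object_id: int = 0,
) -> NXYZTrace:
    """Order skeleton segments into molecules by following branch pairs.

    Every crossing node must be paired (odd junction nodes make an object
    untraceable and belong to the replication-intermediate analysis
    instead).  Returns one NXYZTrace whose molecules jointly cover every
    connecting segment exactly once.
    """
    for node in nodes:
        if not node.pairs:
            raise TracingError(
                f"node {node.node_id} is unpaired; cannot order the trace"
            )
    region = set().union(*(n.pixels for n in nodes)) if nodes else set()
    segments = _segment_paths(sk, region)

    # attach segment ends to (node, branch); identify by the branch start
    attach: dict[tuple[int, int], tuple[int, int]] = {}   # (seg,end)->(node,branch)
    branch_seg: dict[tuple[int, int], tuple[int, int]] = {}  # (node,branch)->(seg,end)
    for node in nodes:
        for bi, branch in enumerate(node.branches):
            start = branch[0]
            found = None
            for si, seg in enumerate(segments):
                if seg[0] == start:
                    found = (si, 0)
                elif seg[-1] == start:
                    found = (si, 1)
                if found:
                    break
            if found is None:
                for si, seg in enumerate(segments):
                    if start in seg:
                        k = seg.index(start)
                        found = (si, 0 if k < len(seg) / 2 else 1)
                        break
            if found is None:
                raise TracingError(
                    f"branch {bi} of node {node.node_id} matches no segment"
                )
            attach[found] = (node.node_id, bi)
            branch_seg[(node.node_id, bi)] = found

    node_by_id = {n.node_id: n for n in nodes}

    def partner(nid: int, bi: int) -> tuple[int, int]:
        for pair in node_by_id[nid].pairs:
            if pair.branch_a == bi:
                return pair.branch_b, pair.pseudo_z
            if pair.branch_b == bi:
                return pair.branch_a, pair.pseudo_z
        raise TracingError(f"branch {bi} of node {nid} is not in any pair")

    def through_node(nid: int, p_from, p_to) -> list[tuple[int, int]]:
        node = node_by_id[nid]
        allowed = set(node.pixels) | {p_from, p_to}
        sub = sk.graph.subgraph(allowed)
        summit = max(node.pixels, key=lambda p: (sk.heights[p], p))
        try:
            first = nx.shortest_path(sub, p_from, summit)
            second = nx.shortest_path(sub, summit, p_to)
            path = first + second[1:]
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            try:
                path = nx.shortest_path(sub, p_from, p_to)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                raise TracingError(
                    f"no through-path inside node {nid}"
                ) from None
        return path[1:-1]

    used: set[int] = set()
    molecules: list[Molecule] = []

    def seg_free_ends(si: int) -> list[int]:
        return [e for e in (0, 1) if (si, e) not in attach]

    while len(used) < len(segments):
        # prefer a segment with a free end (linear molecule), else lowest px
        start_si, start_end = None, None
        for si in range(len(segments)):
            if si in used:
                continue
            free = seg_free_ends(si)
            if free:
                start_si, start_end = si, free[0]
                break
        if start_si is None:
            remaining = [si for si in range(len(segments)) if si not in used]
            start_si = min(remaining, key=lambda si: min(segments[si]))
            start_end = 0
        pixels: list[tuple[int, int]] = []
        zvals: list[int] = []
        si, entry = start_si, start_end
        closed = False
        while True:
            if si in used:
                raise TracingError("segment revisited; inconsistent pairing")
            used.add(si)
            seg = segments[si] if entry == 0 else list(reversed(segments[si]))
            pixels.extend(seg)
            zvals.extend([0] * len(seg))
            exit_key = (si, 1 - entry)
            if exit_key not in attach:
                # open end — unless the lone segment is itself a cycle
                if len(pixels) > 3:
                    a, b = pixels[0], pixels[-1]
                    if max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1:
                        closed = True
                break
            nid, bi = attach[exit_key]
            pbi, rank = partner(nid, bi)
            nsi, nend = branch_seg[(nid, pbi)]
            nxt_seg = segments[nsi] if nend == 0 else list(
                reversed(segments[nsi])
            )
            mid = through_node(nid, seg[-1], nxt_seg[0])
            pixels.extend(mid)
            zvals.extend([rank] * len(mid))
            if nsi == start_si and nend == start_end:
                closed = True
                break
            si, entry = nsi, nend
        molecules.append(Molecule(pixels, zvals, closed))

    # deterministic order: largest molecule first, then by first pixel
    molecules.sort(key=lambda m: (-len(m.pixels), m.pixels[0]))
    cor = {n.node_id: n.cor for n in nodes if n.cor is not None}
    return NXYZTrace(object_id, molecules, sk.pixel_size_nm, cor)


def to_nxyz(traces: list[NXYZTrace]) -> pd.DataFrame:
    """Tabulate traces as an NXYZ table (one row per trace point).

    Each molecule is indexed from 0; X is the column and Y the row pixel
    coordinate; Z is the pseudo-height rank (nonzero only inside crossing
    regions).
    """
    if not traces:
        return pd.DataFrame(
            columns=["object_id", "molecule_id", "N", "X", "Y", "Z", "closed"]
        )
    return pd.concat([t.to_dataframe() for t in traces], ignore_index=True)


def nxyz_to_molecules(df: pd.DataFrame) -> dict[int, list[np.ndarray]]:
    """Group an NXYZ table back into per-object molecule arrays."""
    out: dict[int, list[np.ndarray]] = {}
    for (oid, _mid), grp in df.groupby(["object_id", "molecule_id"]):
        grp = grp.sort_values("N")
        arr = grp[["X", "Y", "Z"]].to_numpy(dtype=int)
        out.setdefault(int(oid), []).append(arr)
    return out
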