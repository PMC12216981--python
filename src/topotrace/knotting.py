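"""Knot and catenane classification from crossing diagrams.

A traced molecule is reduced to a planar crossing diagram: one or more
closed oriented curves whose projection self-intersects at a finite set of
transversal crossings, each carrying an over/under assignment (from the
measured pseudo-height) and a sign (from the 2D tangents of the over and
under strands, right-handed = +1).  The diagram's Kauffman bracket is
evaluated by the exhaustive state sum over all 2**n smoothings and
normalised by the writhe to give the Jones polynomial,

    V(D) = (-A)**(-3 w(D)) <D>,   t = A**-4,

which is looked up against a table of Jones polynomials of prime knots and
two-component links to produce a Rolfsen label (a trailing ``*`` marks the
mirror form, e.g. ``5_2*``).

The module also houses the crossing-misclassification probability model
(exhaustive over/under flip enumeration weighted by a per-crossing accuracy
p) and the discrete Gauss-integral writhe / linking-number / twist
calculators used for 3D curves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ClusteredCrossingError, ComplexityError, GeometryError
from .polynomial import Laurent

__all__ = [
    "CrossingDiagram",
    "TopologyResult",
    "diagram_from_polylines",
    "diagram_from_nxyz",
    "simplify",
    "kauffman_bracket",
    "jones_polynomial",
    "classify",
    "classification_probability",
    "writhe_gauss",
    "linking_number",
    "twist_ribbon",
]

# loop value d = -A^2 - A^-2
_LOOP = Laurent({2: -1, -2: -1})


# --------------------------------------------------------------------------
# diagram representation
# --------------------------------------------------------------------------

@dataclass
class CrossingDiagram:
    """Planar diagram of one or more closed curves.

    ``codes[k]`` is the cyclic sequence of crossing passes of component k as
    ``(crossing_id, is_over)`` pairs in traversal order.  ``signs`` maps each
    crossing id to +1/-1.  Components whose projection meets no crossing are
    counted in ``n_free_loops``.  ``cor`` optionally carries the measured
    crossing-order reliability of each crossing.
    """

    codes: list[list[tuple[int, bool]]]
    signs: dict[int, int]
    cor: dict[int, float] = field(default_factory=dict)
    n_free_loops: int = 0
    positions: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[int, list[bool]] = {}
        for code in self.codes:
            for cid, is_over in code:
                seen.setdefault(cid, []).append(is_over)
        for cid, passes in seen.items():
            if sorted(passes) != [False, True]:
                raise ValueError(
                    f"crossing {cid} must be passed exactly once over and "
                    f"once under, got {passes}"
                )
        if set(seen) != set(self.signs):
            raise ValueError("signs must cover exactly the crossings in codes")

    # -- basic properties ---------------------------------------------------

    @property
    def n_crossings(self) -> int:
        return len(self.signs)

    @property
    def n_components(self) -> int:
        return len(self.codes) + self.n_free_loops

    def writhe(self) -> int:
        return sum(self.signs.values())

    def copy(self) -> "CrossingDiagram":
        return CrossingDiagram(
            [list(c) for c in self.codes],
            dict(self.signs),
            dict(self.cor),
            self.n_free_loops,
            dict(self.positions),
        )

    def flip_crossing(self, cid: int) -> "CrossingDiagram":
        """Invert the over/under order at one crossing.

        Swapping which strand passes over also flips the crossing sign
        (the 2D tangents are unchanged but over and under trade places).
        """
        out = self.copy()
        out.codes = [
            [(c, (not o) if c == cid else o) for c, o in code]
            for code in out.codes
        ]
        out.signs[cid] = -out.signs[cid]
        return out

    def mirror(self) -> "CrossingDiagram":
        """The mirror image: every crossing flipped."""
        out = self.copy()
        out.codes = [[(c, not o) for c, o in code] for code in out.codes]
        out.signs = {c: -s for c, s in out.signs.items()}
        return out

    def component_of(self, cid: int) -> tuple[int, ...]:
        """Indices of the components passing through a crossing."""
        comps = []
        for k, code in enumerate(self.codes):
            if any(c == cid for c, _ in code):
                comps.append(k)
        return tuple(comps)


# --------------------------------------------------------------------------
# diagram construction from geometry
# --------------------------------------------------------------------------

def _segment_intersections(P: np.ndarray, Q: np.ndarray, self_pair: bool):
    """All transversal XY intersections between closed polylines P and Q.

    P, Q are (N,3) arrays of vertices; the closing segment is implicit.
    Returns a list of (sP, sQ, zP, zQ, dP, dQ) where sP/sQ are fractional
    arc positions (segment index + parameter) and dP/dQ the 2D segment
    directions.
    """
    A0 = P
    A1 = np.roll(P, -1, axis=0)
    B0 = Q
    B1 = np.roll(Q, -1, axis=0)
    r = (A1 - A0)[:, None, :2]          # (n,1,2)
    s = (B1 - B0)[None, :, :2]          # (1,m,2)
    diff = B0[None, :, :2] - A0[:, None, :2]
    rxs = r[..., 0] * s[..., 1] - r[..., 1] * s[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (diff[..., 0] * s[..., 1] - diff[..., 1] * s[..., 0]) / rxs
        u = (diff[..., 0] * r[..., 1] - diff[..., 1] * r[..., 0]) / rxs
    eps = 1e-12
    hit = (np.abs(rxs) > eps) & (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)
    if self_pair:
        n = len(P)
        i_idx, j_idx = np.nonzero(hit)
        keep = []
        for a, b in zip(i_idx, j_idx):
            if a >= b:          # count each unordered pair once
                continue
            if b == a + 1 or (a == 0 and b == n - 1):
                continue        # adjacent segments share a vertex
            keep.append((a, b))
        pairs = keep
    else:
        pairs = list(zip(*np.nonzero(hit)))
    out = []
    for a, b in pairs:
        tp, up = float(t[a, b]), float(u[a, b])
        zP = P[a, 2] + tp * (A1[a, 2] - P[a, 2])
        zQ = Q[b, 2] + up * (B1[b, 2] - Q[b, 2])
        out.append((a + tp, b + up, zP, zQ, r[a, 0], s[0, b]))
    return out


def diagram_from_polylines(
    curves: list[np.ndarray], cor: dict[int, float] | None = None
) -> CrossingDiagram:
    """Project closed 3D polylines onto XY and build the crossing diagram.

    Each curve is an (N,3) array of vertices of a closed curve (the segment
    from the last to the first vertex is implicit).  Over/under at every
    projected crossing is decided by the interpolated z of the two strands;
    equal z raises :class:`GeometryError`.
    """
    curves = [np.asarray(c, dtype=float) for c in curves]
    events: list[list[tuple[float, int, bool]]] = [[] for _ in curves]
    signs: dict[int, int] = {}
    positions: dict[int, tuple[float, float]] = {}
    cid = 0
    for i in range(len(curves)):
        for j in range(i, len(curves)):
            hits = _segment_intersections(curves[i], curves[j], self_pair=(i == j))
            for sP, sQ, zP, zQ, dP, dQ in hits:
                if abs(zP - zQ) < 1e-12:
                    raise GeometryError(
                        "strands at identical height at a projected crossing"
                    )
                p_over = zP > zQ
                d_over, d_under = (dP, dQ) if p_over else (dQ, dP)
                cross_z = d_over[0] * d_under[1] - d_over[1] * d_under[0]
                signs[cid] = 1 if cross_z > 0 else -1
                k = int(sP)
                frac = sP - k
                nxt = (k + 1) % len(curves[i])
                pt = curves[i][k, :2] + frac * (
                    curves[i][nxt, :2] - curves[i][k, :2]
                )
                positions[cid] = (float(pt[0]), float(pt[1]))
                events[i].append((sP, cid, p_over))
                events[j].append((sQ, cid, not p_over))
                cid += 1
    codes = []
    n_free = 0
    for ev in events:
        ev.sort()
        if ev:
            codes.append([(c, o) for _, c, o in ev])
        else:
            n_free += 1
    return CrossingDiagram(codes, signs, cor or {}, n_free, positions)


def diagram_from_nxyz(
    molecules: list[np.ndarray],
    merge_dist_px: float = 10.0,
    cor: dict[int, float] | None = None,
) -> CrossingDiagram:
    """Build a diagram from NXYZ traces with pseudo-height crossing ranks.

    ``molecules`` is a list of (N,3) integer arrays of (x, y, pseudo_z) in
    trace order; pseudo_z is nonzero only inside crossing regions, where it
    ranks the passing duplexes from deepest under (1) upwards.  Two
    pseudo-height runs belong to the same crossing when they share a pixel
    or their midpoints lie within ``merge_dist_px``.
    """
    runs = []  # (mol, start_order, pixels set, mean xy, direction, rank)
    for m, arr in enumerate(molecules):
        arr = np.asarray(arr)
        z = arr[:, 2]
        n = len(arr)
        nz = z != 0
        if not nz.any():
            continue
        # cyclic runs of nonzero pseudo-height
        idx = np.arange(n)
        start = int(np.argmin(nz)) if (~nz).any() else 0
        order = np.roll(idx, -start)
        run: list[int] = []
        for k in order:
            if nz[k]:
                run.append(int(k))
            elif run:
                runs.append((m, run))
                run = []
        if run:
            runs.append((m, run))

    infos = []
    for m, run in runs:
        arr = molecules[m]
        pix = {(int(arr[k, 0]), int(arr[k, 1])) for k in run}
        mid = np.mean([arr[k, :2] for k in run], axis=0)
        n = len(arr)
        before = arr[(run[0] - 1) % n, :2]
        after = arr[(run[-1] + 1) % n, :2]
        direction = (after - before).astype(float)
        rank = int(round(float(np.max([arr[k, 2] for k in run]))))
        infos.append(
            {"mol": m, "order": run[0], "pix": pix, "mid": mid,
             "dir": direction, "rank": rank}
        )

    # group runs into crossings
    parent = list(range(len(infos)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(range(len(infos)), 2):
        ia, ib = infos[a], infos[b]
        if ia["pix"] & ib["pix"] or np.linalg.norm(ia["mid"] - ib["mid"]) <= merge_dist_px:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups: dict[int, list[int]] = {}
    for k in range(len(infos)):
        groups.setdefault(find(k), []).append(k)

    signs: dict[int, int] = {}
    positions: dict[int, tuple[float, float]] = {}
    pass_of_run: dict[int, tuple[int, bool]] = {}
    for cid, members in enumerate(sorted(groups.values(), key=min)):
        if len(members) != 2:
            raise ClusteredCrossingError(
                f"{len(members)} duplexes share one crossing region"
            )
        a, b = members
        positions[cid] = tuple(
            np.mean([infos[a]["mid"], infos[b]["mid"]], axis=0)
        )
        ra, rb = infos[a]["rank"], infos[b]["rank"]
        if ra == rb:
            raise GeometryError("tied pseudo-heights at a crossing")
        over_run, under_run = (a, b) if ra > rb else (b, a)
        d_o, d_u = infos[over_run]["dir"], infos[under_run]["dir"]
        cross_z = d_o[0] * d_u[1] - d_o[1] * d_u[0]
        signs[cid] = 1 if cross_z > 0 else -1
        pass_of_run[over_run] = (cid, True)
        pass_of_run[under_run] = (cid, False)

    codes: list[list[tuple[int, bool]]] = []
    n_free = 0
    by_mol: dict[int, list[tuple[int, int]]] = {}
    for k, info in enumerate(infos):
        by_mol.setdefault(info["mol"], []).append((info["order"], k))
    for m in range(len(molecules)):
        if m not in by_mol:
            n_free += 1
            continue
        codes.append([pass_of_run[k] for _, k in sorted(by_mol[m])])
    return CrossingDiagram(codes, signs, cor or {}, n_free, positions)


# --------------------------------------------------------------------------
# Reidemeister simplification (R1 and R2, to fixpoint)
# --------------------------------------------------------------------------

def _drop_crossings(diag: CrossingDiagram, drop: set[int]) -> CrossingDiagram:
    codes = []
    n_free = diag.n_free_loops
    for code in diag.codes:
        new = [(c, o) for c, o in code if c not in drop]
        if new:
            codes.append(new)
        else:
            n_free += 1
    signs = {c: s for c, s in diag.signs.items() if c not in drop}
    cor = {c: v for c, v in diag.cor.items() if c not in drop}
    pos = {c: v for c, v in diag.positions.items() if c not in drop}
    return CrossingDiagram(codes, signs, cor, n_free, pos)


def _find_r1(diag: CrossingDiagram) -> int | None:
    for code in diag.codes:
        m = len(code)
        for i in range(m):
            c1, _ = code[i]
            c2, _ = code[(i + 1) % m]
            if c1 == c2:
                return c1
    return None


def _find_r2(diag: CrossingDiagram) -> tuple[int, int] | None:
    # collect cyclically adjacent pass pairs per component
    adj: list[tuple[int, int, bool, bool]] = []
    for code in diag.codes:
        m = len(code)
        if m < 2:
            continue
        for i in range(m):
            (c1, o1), (c2, o2) = code[i], code[(i + 1) % m]
            if c1 != c2:
                adj.append((c1, c2, o1, o2))
    for c1, c2, o1, o2 in adj:
        if not (o1 and o2):
            continue
        # need the matching under-under adjacency of the same pair
        for d1, d2, p1, p2 in adj:
            if {d1, d2} == {c1, c2} and not (p1 or p2):
                if diag.signs[c1] == -diag.signs[c2]:
                    return c1, c2
    return None


def simplify(diag: CrossingDiagram) -> CrossingDiagram:
    """Apply Reidemeister I and II reductions until no more apply.

    Removes trivial self-loops (R1) and cancelling clasp pairs (R2); the
    Jones polynomial is invariant under both, so this only shrinks the
    state space before the exact bracket evaluation.
    """
    while True:
        c = _find_r1(diag)
        if c is not None:
            diag = _drop_crossings(diag, {c})
            continue
        pair = _find_r2(diag)
        if pair is not None:
            diag = _drop_crossings(diag, set(pair))
            continue
        return diag


# --------------------------------------------------------------------------
# Kauffman bracket / Jones polynomial
# --------------------------------------------------------------------------

def _pd_tuples(diag: CrossingDiagram):
    """Edge-labelled PD tuples (counter-clockwise from the incoming under
    edge) for every crossing.

    Edges are the trace pieces between consecutive passes; edge (k, i) runs
    from pass i to pass i+1 of component k.
    """
    passes: dict[int, dict[bool, tuple[int, int]]] = {}
    for k, code in enumerate(diag.codes):
        for i, (cid, is_over) in enumerate(code):
            passes.setdefault(cid, {})[is_over] = (k, i)
    pd = {}
    for cid, by_over in passes.items():
        k_u, i_u = by_over[False]
        k_o, i_o = by_over[True]
        m_u, m_o = len(diag.codes[k_u]), len(diag.codes[k_o])
        ui = (k_u, (i_u - 1) % m_u)
        uo = (k_u, i_u)
        oi = (k_o, (i_o - 1) % m_o)
        oo = (k_o, i_o)
        if diag.signs[cid] > 0:
            pd[cid] = (ui, oo, uo, oi)
        else:
            pd[cid] = (ui, oi, uo, oo)
    return pd


def kauffman_bracket(diag: CrossingDiagram, max_crossings: int = 14) -> Laurent:
    """Exhaustive state-sum Kauffman bracket, normalised so <unknot> = 1.

    Every one of the 2**n smoothings contributes A**(a-b) d**(loops-1)
    where a/b count A/B smoothings and d = -A**2 - A**-2.
    """
    n = diag.n_crossings
    if n > max_crossings:
        raise ComplexityError(
            f"{n} crossings exceeds the exact-evaluation limit {max_crossings}"
        )
    pd = _pd_tuples(diag)
    cids = sorted(pd)
    edges = [
        (k, i) for k, code in enumerate(diag.codes) for i in range(len(code))
    ]
    index = {e: i for i, e in enumerate(edges)}
    ne = len(edges)
    total = Laurent.zero()
    free = diag.n_free_loops
    for state in range(1 << n):
        parent = list(range(ne))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry

        a_count = 0
        for bit, cid in enumerate(cids):
            p0, p1, p2, p3 = (index[e] for e in pd[cid])
            if state & (1 << bit):  # A smoothing
                a_count += 1
                union(p0, p1)
                union(p2, p3)
            else:                   # B smoothing
                union(p1, p2)
                union(p3, p0)
        loops = len({find(x) for x in range(ne)}) + free
        total = total + Laurent.monomial(2 * a_count - n) * (_LOOP ** (loops - 1))
    if ne == 0:
        total = _LOOP ** max(free - 1, 0)
    return total


def jones_polynomial(
    diag: CrossingDiagram, max_crossings: int = 14
) -> Laurent:
    """Jones polynomial V(D) in the bracket variable A (t = A**-4)."""
    bracket = kauffman_bracket(diag, max_crossings=max_crossings)
    w = diag.writhe()
    sign = -1 if (w % 2) else 1
    return (bracket * sign).shifted(-3 * w)


def _orientation_variant_jones(diag: CrossingDiagram, bracket: Laurent):
    """Jones polynomials over all relative orientations of the components.

    The bracket ignores orientation; reversing one component only flips the
    sign of every crossing shared with the others, changing the writhe
    normalisation.  Yields one polynomial per orientation class.
    """
    ncomp = len(diag.codes)
    base_w = diag.writhe()
    seen = set()
    for flip_mask in range(1 << max(ncomp - 1, 0)):
        flipped = {k + 1 for k in range(ncomp - 1) if flip_mask & (1 << k)}
        w = base_w
        for cid, s in diag.signs.items():
            comps = diag.component_of(cid)
            if len(comps) == 2 and (comps[0] in flipped) != (comps[1] in flipped):
                w -= 2 * s
        sign = -1 if (w % 2) else 1
        v = (bracket * sign).shifted(-3 * w)
        if v.key() not in seen:
            seen.add(v.key())
            yield v


# --------------------------------------------------------------------------
# classification against the shipped table
# --------------------------------------------------------------------------

@dataclass
class TopologyResult:
    """Outcome of classifying one traced object."""

    rolfsen: str
    polynomial: Laurent
    chirality: str                 # 'amphichiral', 'as-tabulated' or 'mirror'
    mirror_ambiguous: bool
    n_crossings: int
    signs: tuple[int, ...]
    cor: dict[int, float] = field(default_factory=dict)
    min_cor: float | None = None
    alternate_rolfsen: str | None = None


_TABLE: dict | None = None


def _table() -> dict:
    global _TABLE
    if _TABLE is None:
        from ._tangles import build_jones_table

        _TABLE = build_jones_table()
    return _TABLE


def minimal_diagram(label: str) -> CrossingDiagram:
    """A minimal crossing diagram of a tabulated knot or link.

    Built from the rational-tangle form recorded in the table (mirrored
    where the label is a mirror form); e.g. ``minimal_diagram("3_1")`` is
    the standard 3-crossing trefoil diagram.
    """
    if label in ("0_1",):
        return CrossingDiagram([], {}, n_free_loops=1)
    if label in ("0^2_1", "0^3_1"):
        return CrossingDiagram([], {}, n_free_loops=int(label[2]))
    table = _table()
    if label not in table["fractions"]:
        raise KeyError(f"no tabulated minimal diagram for {label!r}")
    from ._tangles import tangle_closure

    frac, mirrored = table["fractions"][label]
    diag = simplify(tangle_closure(frac))
    return diag.mirror() if mirrored else diag


def _is_split_composite(diag: CrossingDiagram) -> bool:
    """Crude connected-sum check: a knot whose Gauss sequence contains a
    proper cyclic interval closed under crossing pairing is a candidate
    composite (or has a reducible nugatory part)."""
    for code in diag.codes:
        m = len(code)
        seq = [c for c, _ in code]
        for start in range(m):
            for length in range(2, m - 1):
                window = [seq[(start + i) % m] for i in range(length)]
                counts: dict[int, int] = {}
                for c in window:
                    counts[c] = counts.get(c, 0) + 1
                if all(v == 2 for v in counts.values()) and counts:
                    return True
    return False


def lookup_label(
    diag: CrossingDiagram, max_crossings: int = 14
) -> tuple[str, Laurent]:
    """Rolfsen label for a diagram via table lookup over all component
    orientations; 'unclassified' when no entry matches."""
    bracket = kauffman_bracket(diag, max_crossings=max_crossings)
    ncomp = diag.n_components
    table = _table()
    first_v = None
    for v in _orientation_variant_jones(diag, bracket):
        if first_v is None:
            first_v = v
        hit = table["by_key"].get((ncomp, v.key()))
        if hit is not None:
            return hit, v
    label = "unclassified"
    if _is_split_composite(diag):
        label = "unclassified (composite?)"
    return label, first_v if first_v is not None else Laurent.one()


def classify(diag: CrossingDiagram, max_crossings: int = 14) -> TopologyResult:
    """Classify a diagram in Rolfsen notation.

    The diagram is Reidemeister-simplified, its Jones polynomial computed
    exactly and looked up in the shipped table (prime knots and
    two-component links; ``*`` marks mirror forms).  When crossing-order
    reliabilities are attached, the classification obtained after flipping
    the single least-reliable crossing is reported as well.
    """
    sdiag = simplify(diag)
    label, v = lookup_label(sdiag, max_crossings=max_crossings)
    table = _table()
    base = label.rstrip("*")
    if base in table["amphichiral"]:
        chirality = "amphichiral"
    elif base in table["chirality_ambiguous"]:
        chirality = "ambiguous"
    else:
        chirality = "mirror" if label.endswith("*") else "as-tabulated"
    mirror_ambiguous = chirality in ("ambiguous", "mirror", "as-tabulated") \
        and not label.startswith("unclassified")
    result = TopologyResult(
        rolfsen=label,
        polynomial=v,
        chirality=chirality,
        mirror_ambiguous=mirror_ambiguous,
        n_crossings=sdiag.n_crossings,
        signs=tuple(sdiag.signs[c] for c in sorted(sdiag.signs)),
        cor=dict(diag.cor),
        min_cor=min(diag.cor.values()) if diag.cor else None,
    )
    if diag.cor and diag.n_crossings:
        weakest = min(diag.cor, key=diag.cor.get)
        alt = simplify(diag.flip_crossing(weakest))
        result.alternate_rolfsen = lookup_label(
            alt, max_crossings=max_crossings
        )[0]
    return result


def classification_probability(
    diag: CrossingDiagram, p: float, max_crossings: int = 20
) -> dict[str, float]:
    """Distribution over topology labels under independent crossing errors.

    Every subset of crossings is flipped; each resulting diagram is
    classified and weighted p**(n-k) (1-p)**k for k flips.  The returned
    probabilities sum to 1.
    """
    if not (0 < p <= 1):
        raise ValueError("per-crossing accuracy p must be in (0, 1]")
    n = diag.n_crossings
    if n > max_crossings:
        raise ComplexityError(f"{n} crossings exceeds enumeration limit")
    cids = sorted(diag.signs)
    out: dict[str, float] = {}
    for flips in range(1 << n):
        d = diag
        k = 0
        for bit, cid in enumerate(cids):
            if flips & (1 << bit):
                d = d.flip_crossing(cid)
                k += 1
        w = p ** (n - k) * (1 - p) ** k
        if w == 0.0:
            continue  # p = 1: flipped assignments cannot occur
        label = classify(d).rolfsen
        out[label] = out.get(label, 0.0) + w
    return out


# --------------------------------------------------------------------------
# discrete Gauss-integral geometry
# --------------------------------------------------------------------------

def _segment_pair_omega(p1, p2, p3, p4):
    """Exact Gauss-integral contribution of segment pair (p1p2, p3p4).

    Solid-angle formula for polygonal curves: the contribution is the
    (signed) area of the spherical quadrilateral spanned by the four
    connecting directions, so integer quantisation of the linking number
    holds at coarse discretisation.
    """
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    norms = [np.linalg.norm(v) for v in (n1, n2, n3, n4)]
    if min(norms) < 1e-14:
        return 0.0
    n1, n2, n3, n4 = (v / nv for v, nv in zip((n1, n2, n3, n4), norms))
    s = (
        math.asin(max(-1.0, min(1.0, float(np.dot(n1, n2)))))
        + math.asin(max(-1.0, min(1.0, float(np.dot(n2, n3)))))
        + math.asin(max(-1.0, min(1.0, float(np.dot(n3, n4)))))
        + math.asin(max(-1.0, min(1.0, float(np.dot(n4, n1)))))
    )
    sign = np.dot(np.cross(p4 - p3, p2 - p1), r13)
    return s / (4 * math.pi) * (1.0 if sign > 0 else -1.0 if sign < 0 else 0.0)


def _closed_segments(curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 3:
        raise GeometryError("curve must be an (N, 3) array")
    if len(curve) < 4:
        raise GeometryError("closed curve needs at least 4 vertices")
    return curve, np.roll(curve, -1, axis=0)


def writhe_gauss(curve: np.ndarray) -> float:
    """Writhe of a closed 3D polyline by the discrete Gauss linking
    integral; positive values correspond to right-handed crossings and
    planar curves give exactly zero."""
    a0, a1 = _closed_segments(curve)
    n = len(a0)
    wr = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closing segment
            wr += _segment_pair_omega(a0[i], a1[i], a0[j], a1[j])
    return 2.0 * wr


def linking_number(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Gauss linking number of two disjoint closed 3D polylines.

    The double sum of exact per-segment-pair solid angles; for valid input
    the result is within 0.05 of an integer.
    """
    a0, a1 = _closed_segments(curve_a)
    b0, b1 = _closed_segments(curve_b)
    if (
        np.min(
            np.linalg.norm(a0[:, None, :] - b0[None, :, :], axis=-1)
        )
        < 1e-9
    ):
        raise GeometryError("curves touch or intersect")
    lk = 0.0
    for i in range(len(a0)):
        for j in range(len(b0)):
            lk += _segment_pair_omega(a0[i], a1[i], b0[j], b1[j])
    return lk


def twist_ribbon(axis: np.ndarray, edge: np.ndarray) -> float:
    """Total twist of a closed ribbon given its axis and edge curves.

    The edge vector is parallel-transported along the axis tangents; the
    accumulated signed rotation divided by 2 pi is the twist, so that
    Lk(axis, edge) = Tw + Wr(axis) (White's theorem).
    """
    axis = np.asarray(axis, dtype=float)
    edge = np.asarray(edge, dtype=float)
    if axis.shape != edge.shape:
        raise GeometryError("axis and edge must have matching shapes")
    n = len(axis)
    tangents = np.roll(axis, -1, axis=0) - axis
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    u = edge - axis
    # perpendicularise to the local tangent
    u = u - (np.sum(u * tangents, axis=1))[:, None] * tangents
    u /= np.linalg.norm(u, axis=1)[:, None]
    tw = 0.0
    for i in range(n):
        t0 = tangents[i]
        t1 = tangents[(i + 1) % n]
        ui = u[i]
        # minimal rotation taking t0 to t1 (parallel transport)
        axis_v = np.cross(t0, t1)
        sin_a = np.linalg.norm(axis_v)
        cos_a = float(np.dot(t0, t1))
        if sin_a > 1e-14:
            k = axis_v / sin_a
            ui = (
                ui * cos_a
                + np.cross(k, ui) * sin_a
                + k * np.dot(k, ui) * (1 - cos_a)
            )
        u1 = u[(i + 1) % n]
        ang = math.atan2(
            float(np.dot(np.cross(ui, u1), t1)), float(np.dot(ui, u1))
        )
        tw += ang
    return tw / (2 * math.pi)
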