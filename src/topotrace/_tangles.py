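"""Shipped Jones-polynomial lookup table, built from rational tangles.

Every prime knot with at most 7 crossings and the small two-component
catenanes are 2-bridge (rational): each is the numerator closure of a
continued-fraction tangle [a1, a2, ...] of alternating horizontal and
vertical twist blocks.  The table is generated at first use by enumerating
all positive continued fractions with crossing sum <= 7, building each
closure combinatorially, evaluating its Jones polynomial exactly and
registering it under the Rolfsen label identified by the invariant triple
(component count, Jones span, determinant) — the span of a reduced
alternating diagram equals the crossing number and the determinants of the
tabulated types are mutually distinct within each crossing number, so the
labelling is forced rather than transcribed.

Chirality convention: the plain label denotes the right-handed
(positive-crossing) form of each chiral pair — the convention used when
naming Xer recombination products such as the right-handed 4-node
catenane 4^2_1 — and ``*`` marks its mirror image.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from .knotting import CrossingDiagram, kauffman_bracket, simplify, \
    _orientation_variant_jones
from .polynomial import Laurent

# ports of a crossing, counter-clockwise: 0=NE, 1=NW, 2=SW, 3=SE
# axis 0 joins ports 0-2 (NE-SW), axis 1 joins ports 1-3 (NW-SE)
_H_OVER_AXIS = 1
_V_OVER_AXIS = 1

# (n_components, crossing number, determinant) -> Rolfsen label
_NAME_MAP = {
    (1, 3, 3): "3_1",
    (1, 4, 5): "4_1",
    (1, 5, 5): "5_1",
    (1, 5, 7): "5_2",
    (1, 6, 9): "6_1",
    (1, 6, 11): "6_2",
    (1, 6, 13): "6_3",
    (1, 7, 7): "7_1",
    (1, 7, 11): "7_2",
    (1, 7, 13): "7_3",
    (1, 7, 15): "7_4",
    (1, 7, 17): "7_5",
    (1, 7, 19): "7_6",
    (1, 7, 21): "7_7",
    (2, 2, 2): "2^2_1",
    (2, 4, 4): "4^2_1",
    (2, 5, 8): "5^2_1",
    (2, 6, 6): "6^2_3",
    (2, 6, 10): "6^2_1",
    (2, 6, 12): "6^2_2",
}


class _RationalTangle:
    """Combinatorial rational tangle under horizontal/vertical twisting.

    Endpoints are either boundary corners ('b', corner) or crossing ports
    (cid, port); ``match`` records which endpoints are joined by an arc.
    """

    def __init__(self) -> None:
        self.match: dict = {}
        self.over_axis: dict[int, int] = {}
        self._next = 0
        self._join(("b", "nw"), ("b", "ne"))
        self._join(("b", "sw"), ("b", "se"))

    def _join(self, a, b) -> None:
        self.match[a] = b
        self.match[b] = a

    def _take(self, corner: str):
        partner = self.match.pop(("b", corner))
        self.match.pop(partner, None)
        return partner

    def twist_right(self) -> None:
        ne, se = self._take("ne"), self._take("se")
        cid = self._next
        self._next += 1
        self._join(ne, (cid, 1))
        self._join(se, (cid, 2))
        self._join(("b", "ne"), (cid, 0))
        self._join(("b", "se"), (cid, 3))
        self.over_axis[cid] = _H_OVER_AXIS

    def twist_bottom(self) -> None:
        sw, se = self._take("sw"), self._take("se")
        cid = self._next
        self._next += 1
        self._join(sw, (cid, 1))
        self._join(se, (cid, 0))
        self._join(("b", "sw"), (cid, 2))
        self._join(("b", "se"), (cid, 3))
        self.over_axis[cid] = _V_OVER_AXIS

    def numerator_closure(self) -> CrossingDiagram:
        """Join NW-NE above and SW-SE below, then read off the diagram."""
        match = dict(self.match)

        def pop_pair(c1, c2):
            a = match.pop(("b", c1))
            b = match.pop(("b", c2))
            match.pop(a, None)
            match.pop(b, None)
            if a == ("b", c2):      # the two corners were directly joined
                return None
            match[a] = b
            match[b] = a
            return a

        free_loops = 0
        if pop_pair("nw", "ne") is None:
            free_loops += 1
        if pop_pair("sw", "se") is None:
            free_loops += 1

        # walk the closed strands
        entries: dict[int, dict[int, int]] = {}
        visited: set[tuple[int, int]] = set()
        codes: list[list[tuple[int, bool]]] = []
        for cid in sorted(self.over_axis):
            for start_port in (0, 1):
                if (cid, start_port % 2) in visited:
                    continue
                code: list[tuple[int, bool]] = []
                cur = (cid, start_port)
                while True:
                    ccid, port = cur
                    axis = port % 2
                    if (ccid, axis) in visited:
                        break
                    visited.add((ccid, axis))
                    entries.setdefault(ccid, {})[axis] = port
                    is_over = self.over_axis[ccid] == axis
                    code.append((ccid, is_over))
                    out_port = (port + 2) % 4
                    cur = match[(ccid, out_port)]
                if code:
                    codes.append(code)

        signs = {}
        for cid, over_axis in self.over_axis.items():
            u_in = entries[cid][1 - over_axis]
            o_in = entries[cid][over_axis]
            o_out = (o_in + 2) % 4
            signs[cid] = 1 if (o_out - u_in) % 4 == 1 else -1
        return CrossingDiagram(codes, signs, {}, free_loops)


def tangle_closure(fraction: list[int]) -> CrossingDiagram:
    """Numerator closure of the continued-fraction tangle [a1, a2, ...].

    Twist blocks alternate horizontal (right) and vertical (bottom),
    starting horizontal; all twists share one handedness so the diagram is
    alternating.
    """
    t = _RationalTangle()
    for i, a in enumerate(fraction):
        for _ in range(a):
            if i % 2 == 0:
                t.twist_right()
            else:
                t.twist_bottom()
    return t.numerator_closure()


def _skew(polys: list[Laurent]) -> int:
    return sum(p.max_degree() + p.min_degree() for p in polys)


# types isotopic to their own mirror image; for the other entries whose
# orientation-variant Jones set happens to be mirror-symmetric (e.g. the
# Hopf link, where reversing one component trades V(t) for V(1/t)) the
# polynomial cannot decide chirality and the classifier reports it as
# ambiguous instead.
_AMPHICHIRAL = {"4_1", "6_3"}


def build_jones_table() -> dict:
    """Enumerate rational closures and register Jones keys -> labels."""
    by_key: dict[tuple[int, tuple], str] = {}
    amphichiral: set[str] = set()
    ambiguous: set[str] = set()
    fractions: dict[str, tuple[list[int], bool]] = {}

    def register(label: str, variants: list[Laurent], ncomp: int) -> None:
        for v in variants:
            key = (ncomp, v.key())
            prev = by_key.get(key)
            if prev is not None and prev != label:
                raise RuntimeError(
                    f"Jones collision in knot table: {prev} vs {label}"
                )
            by_key[key] = label

    # trivial entries
    register("0_1", [Laurent.one()], 1)
    d = Laurent({2: -1, -2: -1})
    register("0^2_1", [d], 2)
    register("0^3_1", [d * d], 3)

    candidates = []
    for total in range(2, 8):
        for k in range(1, total + 1):
            for comp in itertools.product(range(1, total + 1), repeat=k):
                if sum(comp) == total:
                    candidates.append(list(comp))

    for frac in candidates:
        diag = simplify(tangle_closure(frac))
        ncomp = diag.n_components
        bracket = kauffman_bracket(diag)
        variants = list(_orientation_variant_jones(diag, bracket))
        span = variants[0].span_t()
        det = variants[0].determinant()
        if span != Fraction(diag.n_crossings):
            continue        # not a reduced alternating closure of this size
        name = _NAME_MAP.get((ncomp, diag.n_crossings, det))
        if name is None:
            continue
        mirror_variants = [v.mirror() for v in variants]
        keys = {v.key() for v in variants}
        if keys == {v.key() for v in mirror_variants}:
            (amphichiral if name in _AMPHICHIRAL else ambiguous).add(name)
            register(name, variants, ncomp)
            fractions.setdefault(name, (frac, False))
        elif _skew(variants) <= 0:
            # positive-t skew: right-handed form carries the plain label
            register(name, variants, ncomp)
            register(name + "*", mirror_variants, ncomp)
            fractions.setdefault(name, (frac, False))
            fractions.setdefault(name + "*", (frac, True))
        else:
            register(name + "*", variants, ncomp)
            register(name, mirror_variants, ncomp)
            fractions.setdefault(name + "*", (frac, False))
            fractions.setdefault(name, (frac, True))

    missing = set(_NAME_MAP.values()) - set(by_key.values()) - {"0_1"}
    if missing:
        raise RuntimeError(f"knot table incomplete: {sorted(missing)}")
    amphichiral.update({"0_1", "0^2_1", "0^3_1"})
    return {"by_key": by_key, "amphichiral": amphichiral,
            "chirality_ambiguous": ambiguous, "fractions": fractions}
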