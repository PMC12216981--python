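"""Ground-truthed pseudo-AFM image generation.

Synthetic deposited-DNA images are produced from exact 3D curves: the
curve is projected onto the XY plane, a ~2 nm high tube is rasterised with
a Gaussian cross-section whose width emulates convolution with a ~5 nm
tip, the over-passing strand at every crossing is kept continuous as a
smooth "humpback bridge" whose apex can be compressed toward
single-duplex height, and i.i.d. Gaussian instrument noise is added over a
flat zero background.  Every rendered image carries its ground truth:
exact curves, per-component contour lengths, crossing positions with true
over/under assignments and signs, and the Rolfsen label verified on the
exact projection at generation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError
from .imgproc import HeightMap
from .knotting import (CrossingDiagram, _segment_intersections, classify,
                       diagram_from_polylines)

_TOPOLOGIES = (
    "circle",
    "theta",
    "theta_reversed",
    "figure8_dimer",
    "torus_knot",
    "twist_knot",
    "torus_link",
    "catenane_4node",
)


@dataclass
class SynthSpec:
    """Parameters of one synthetic render; the seed fully determines it."""

    topology: str = "circle"
    p: int = 2                      # torus knot/link strand count
    q: int = 3                      # torus knot winding
    k: int = 2                      # torus_link(2, 2k)
    n_twists: int = 2               # twist knot half-twists (2 -> 4_1, 3 -> 5_2)
    contour_length_nm: float = 768.0
    pixel_size_nm: float = 1.0
    tip_radius_nm: float = 5.0
    ridge_height_nm: float = 2.0
    duplex_width_nm: float = 2.0
    noise_sd_nm: float = 0.1
    crossing_compression: float = 0.0   # 0 = fully raised, 1 = flattened
    lift_half_length_nm: float = 15.0
    clustered: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ConfigError(f"unknown topology {self.topology!r}")
        if not 0 <= self.crossing_compression <= 1:
            raise ConfigError("crossing_compression must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact geometry and topology carried along with a render."""

    curves: list[np.ndarray]
    open_arcs: list[np.ndarray] = field(default_factory=list)
    contour_lengths_nm: list[float] = field(default_factory=list)
    rolfsen: str | None = None
    diagram: CrossingDiagram | None = None
    crossings: list[dict] = field(default_factory=list)
    conformation: str | None = None
    n_junctions: int = 0

    @property
    def n_components(self) -> int:
        return len(self.curves)


def _polyline_length(curve: np.ndarray, closed: bool = True) -> float:
    pts = np.vstack([curve, curve[:1]]) if closed else curve
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _projected_length(curve: np.ndarray, closed: bool = True) -> float:
    """In-plane (XY) length: the physical contour of a deposited molecule,
    whose z coordinate here only encodes crossing order."""
    pts = np.vstack([curve, curve[:1]]) if closed else curve
    return float(np.sum(np.linalg.norm(np.diff(pts[:, :2], axis=0), axis=1)))


# ---------------------------------------------------------------------------
# curve constructions
# ---------------------------------------------------------------------------

def _angles(n: int, offset: float) -> np.ndarray:
    # generic-position sampling: an irrational phase keeps projected
    # crossings away from polyline vertices
    return np.linspace(0, 2 * np.pi, n, endpoint=False) + offset / n


def _circle(n=600, off=0.2371) -> np.ndarray:
    t = _angles(n, off)
    return np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])


def _torus_knot(p, q, n=800, R=3.0, r=1.35, handed=-1) -> np.ndarray:
    t = _angles(n, 0.2371)
    x = (R + r * np.cos(q * t)) * np.cos(p * t)
    y = (R + r * np.cos(q * t)) * np.sin(p * t)
    z = handed * r * np.sin(q * t)
    return np.column_stack([x, y, z])


def _torus_link(k=2, n=700, R=3.0, r=1.2, handed=-1) -> list[np.ndarray]:
    out = []
    for i, phase in enumerate((0.0, np.pi)):
        t = _angles(n, 0.137 + 0.211 * i)
        x = (R + r * np.cos(k * t + phase)) * np.cos(t)
        y = (R + r * np.cos(k * t + phase)) * np.sin(t)
        z = handed * r * np.sin(k * t + phase)
        out.append(np.column_stack([x, y, z]))
    return out


def _bumps(tt, angles, signs, amp=0.12, width=0.35):
    z = np.zeros_like(tt)
    for ang, sgn in zip(angles, signs):
        d = np.angle(np.exp(1j * (tt - ang)))
        z += sgn * amp * np.exp(-(d**2) / (2 * width**2))
    return z


def _catenane_ellipse(n=700) -> list[np.ndarray]:
    """Two orthogonal ellipses crossing four times (|Lk| = 2).

    The four steep, well-separated crossings on the diagonals give the
    open conformation of the right-handed 4-node catenane.
    """
    bumps = _bumps
    a, b = 1.35, 0.60
    t1 = _angles(n, 0.2371)
    c1 = np.column_stack([a * np.cos(t1), b * np.sin(t1), np.zeros_like(t1)])
    t2 = _angles(n, 0.1459)
    c2 = np.column_stack([b * np.cos(t2), a * np.sin(t2), np.zeros_like(t2)])
    x0 = a * b / np.hypot(a, b)
    phi1 = [
        float(np.arctan2(s * x0 / b, c * x0 / a)) % (2 * np.pi)
        for c, s in ((1, 1), (-1, 1), (-1, -1), (1, -1))
    ]
    phi2 = [
        float(np.arctan2(s * x0 / a, c * x0 / b)) % (2 * np.pi)
        for c, s in ((1, 1), (-1, 1), (-1, -1), (1, -1))
    ]
    c1[:, 2] = bumps(t1, phi1, [-1, 1, -1, 1])
    c2[:, 2] = bumps(t2, phi2, [1, -1, 1, -1])
    return [c1, c2]


def _catenane_clustered(n=700) -> list[np.ndarray]:
    """Taut conformation of the 4-node catenane.

    A circle threaded by a strongly squashed ellipse: the two crossings
    of each near-tangential pair fall within the node-merge reach of the
    tracer, which must fuse them into two collinear merged nodes.
    """
    a, b = 1.012, 0.21
    t1 = _angles(n, 0.2371)
    c1 = np.column_stack([np.cos(t1), np.sin(t1), np.zeros_like(t1)])
    t2 = _angles(n, 0.1459)
    c2 = np.column_stack(
        [a * np.cos(t2), b * np.sin(t2), np.zeros_like(t2)]
    )
    s2 = (1 - 1 / a**2) / (1 / b**2 - 1 / a**2)
    th = float(np.arcsin(np.sqrt(s2)))
    ang1 = [th, np.pi - th, np.pi + th, 2 * np.pi - th]
    c1[:, 2] = _bumps(t1, ang1, [1, -1, 1, -1])
    phi = [
        np.arctan2(np.sin(a0) / b, np.cos(a0) / a) % (2 * np.pi)
        for a0 in ang1
    ]
    c2[:, 2] = _bumps(t2, phi, [-1, 1, -1, 1], width=0.1)
    return [c1, c2]


def _diagonal(p0, p1, z_sign, eps, samples=60) -> np.ndarray:
    """Straight 2D run with a smooth z plateau so a crossing at the
    midpoint is unambiguous."""
    s = np.linspace(0.0, 1.0, samples)
    pts = (1 - s)[:, None] * np.asarray(p0, float)[None, :] \
        + s[:, None] * np.asarray(p1, float)[None, :]
    z = z_sign * eps * np.sin(np.pi * s) ** 2  # zero at both joints
    return np.column_stack([pts, z])


def _twist_knot(n_twists: int, samples_per_unit=8) -> list[np.ndarray]:
    """Closed twist-knot curve.

    A band with n alternating half-twists is clasped by one vertical and
    one final horizontal twist before the numerator closure — the
    rational form with determinant 2n + 1 (n = 2 gives 4_1, n = 3 gives
    5_2, n = 4 gives 6_1).
    """
    if n_twists < 1:
        raise ConfigError("twist knot needs at least one half-twist")
    pitch = 4.0
    G = 4.0                             # band gap: keeps ridges separated
    T = pitch * n_twists
    D = 0.8 * T + 3.0
    W = D + G
    eps = 0.45

    def band(sign):
        x = np.linspace(0, T, max(int(T * samples_per_unit), 16))
        phi = np.pi * x / pitch
        y = G / 2 + sign * (G / 2) * np.cos(phi)
        z = sign * eps * np.sin(phi)
        return np.column_stack([x, y, z])

    s1 = band(+1)                       # (0, G) -> (T, ...)
    s2 = band(-1)                       # (0, 0) -> (T, ...)
    # one vertical twist: bottom ends swap x while descending
    v1 = _diagonal((0, 0), (T, -D), +1, eps)
    v2 = _diagonal((T, 0), (0, -D), -1, eps)
    # one final horizontal twist on the right edge
    h1 = _diagonal((T, G), (T + W, -D), +1, eps)
    h2 = _diagonal((T, -D), (T + W, G), -1, eps)
    th = np.linspace(np.pi, 0, 80)
    mid = (T + W) / 2
    top = np.column_stack(
        [mid + mid * np.cos(th), G + 0.35 * (T + W) * np.sin(th),
         np.zeros_like(th)]
    )  # (0, G) -> (T + W, G)
    bottom = np.column_stack(
        [mid - mid * np.cos(th), -D - 0.35 * (T + W) * np.sin(th),
         np.zeros_like(th)]
    )  # (0, -D) -> (T + W, -D)
    loops = _stitch([s1, s2, v1, v2, h1, h2, top, bottom])
    if len(loops) != 1:
        raise GeometryError("twist-knot construction did not close")
    return loops


def _stitch(pieces: list[np.ndarray], tol=1e-6) -> list[np.ndarray]:
    """Join open polylines end-to-end into closed loops."""
    pieces = [np.asarray(p, dtype=float) for p in pieces]
    used = [False] * len(pieces)
    loops = []
    for i in range(len(pieces)):
        if used[i]:
            continue
        used[i] = True
        chain = [pieces[i]]
        head = pieces[i][0]
        tail = pieces[i][-1]
        while np.linalg.norm(head - tail) > tol:
            found = False
            for j in range(len(pieces)):
                if used[j]:
                    continue
                if np.linalg.norm(pieces[j][0] - tail) <= tol:
                    chain.append(pieces[j][1:])
                    tail = pieces[j][-1]
                elif np.linalg.norm(pieces[j][-1] - tail) <= tol:
                    chain.append(pieces[j][::-1][1:])
                    tail = pieces[j][0]
                else:
                    continue
                used[j] = True
                found = True
                break
            if not found:
                raise GeometryError("open chain while stitching polylines")
        loop = np.vstack(chain)
        # drop the duplicated closing vertex
        if np.linalg.norm(loop[0] - loop[-1]) <= tol:
            loop = loop[:-1]
        loops.append(loop)
    return loops


def _theta(reversed_fork=False, n=600) -> tuple[list, list]:
    """Circle plus a bowed chord meeting it at two 3-way junctions; the
    reversed-fork variant adds a short stub turning one junction 4-way."""
    alpha = 0.55
    t = _angles(n, 0.2371)
    circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    u = np.linspace(-alpha, alpha, int(n * alpha / np.pi))
    # chord from angle -alpha to +alpha, bowed toward the centre
    p0 = np.array([np.cos(alpha), -np.sin(alpha)])
    p1 = np.array([np.cos(alpha), np.sin(alpha)])
    s = (u + alpha) / (2 * alpha)
    bow = 0.35 * np.sin(np.pi * s)
    pts = (1 - s)[:, None] * p0 + s[:, None] * p1
    pts[:, 0] -= bow
    chord = np.column_stack([pts, np.zeros(len(pts))])
    arcs = [chord]
    if reversed_fork:
        j = chord[0, :2]  # junction at angle -alpha
        direction = j / np.linalg.norm(j)  # radially outward, clear of
        # both the circle arc and the chord
        stub_pts = j[None, :] + np.linspace(0.03, 0.27, 40)[:, None] * direction
        arcs.append(np.column_stack([stub_pts, np.zeros(len(stub_pts))]))
    return [circle], arcs


def _figure8_dimer(n=500) -> list[np.ndarray]:
    """Two equal circles sharing one point: a late replication
    intermediate (figure-of-8) with a single 4-way junction."""
    t = _angles(n, 0.2371)
    a = np.column_stack(
        [-1 + np.cos(t), np.sin(t), np.zeros_like(t)]
    )
    b = np.column_stack(
        [1 - np.cos(t), np.sin(t), np.zeros_like(t)]
    )
    return [a, b]


def make_curve(spec: SynthSpec) -> GroundTruth:
    """Build the exact 3D curve(s) for a topology and verify the label.

    For knot/catenane topologies the exact projection is classified with
    the invariant engine at generation time, so the stored Rolfsen label is
    guaranteed consistent with the curve.
    """
    open_arcs: list[np.ndarray] = []
    conformation = None
    n_junctions = 0
    if spec.topology == "circle":
        curves = [_circle()]
        conformation = "open"
    elif spec.topology == "torus_knot":
        from math import gcd

        if gcd(spec.p, spec.q) != 1:
            raise ConfigError("torus knot (p, q) must be coprime")
        curves = [_torus_knot(spec.p, spec.q)]
    elif spec.topology == "torus_link":
        curves = _torus_link(k=spec.k)
    elif spec.topology == "catenane_4node":
        if spec.clustered:
            curves = _catenane_clustered()
        else:
            curves = _catenane_ellipse()
        # the pinched-waist build packs crossing pairs into collinear
        # merged nodes: the taut conformation class
        conformation = "taut" if spec.clustered else "open"
    elif spec.topology == "twist_knot":
        curves = _twist_knot(spec.n_twists)
    elif spec.topology in ("theta", "theta_reversed"):
        curves, open_arcs = _theta(spec.topology == "theta_reversed")
        n_junctions = 2
    elif spec.topology == "figure8_dimer":
        curves = _figure8_dimer()
        n_junctions = 1
    else:  # pragma: no cover
        raise ConfigError(spec.topology)

    # scale so the first (largest) component hits the target length;
    # lengths are in-plane: the z coordinate only encodes crossing order
    f = spec.contour_length_nm / _projected_length(curves[0])
    curves = [c * f for c in curves]
    open_arcs = [a * f for a in open_arcs]

    # seeded rigid placement: a random in-plane rotation plus sub-pixel
    # offset so every seed digitises the molecule differently
    rng = np.random.default_rng(spec.seed)
    ang = rng.uniform(0, 2 * np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    rot = np.array([[ca, -sa], [sa, ca]])
    shift = rng.uniform(0, spec.pixel_size_nm, size=2)
    for c in curves + open_arcs:
        c[:, :2] = c[:, :2] @ rot.T + shift

    gt = GroundTruth(
        curves=curves,
        open_arcs=open_arcs,
        contour_lengths_nm=[_projected_length(c) for c in curves],
        conformation=conformation,
        n_junctions=n_junctions,
    )
    if not open_arcs and n_junctions == 0:
        diag = diagram_from_polylines(curves)
        gt.diagram = diag
        gt.rolfsen = classify(diag).rolfsen
    return gt


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _resample(curve: np.ndarray, step: float, closed=True) -> np.ndarray:
    pts = np.vstack([curve, curve[:1]]) if closed else curve
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step)), 8)
    si = np.linspace(0, total, n, endpoint=not closed)
    out = np.empty((len(si), pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(si, s, pts[:, d])
    return out


def render_pseudo_afm(
    gt: GroundTruth, spec: SynthSpec
) -> tuple[HeightMap, GroundTruth]:
    """Rasterise ground-truth curves into a pseudo-AFM height map.

    The tube cross-section is Gaussian with a width emulating dilation by
    the tip radius; at every crossing the over strand is lifted by a
    smooth bump whose apex interpolates between twice the duplex height
    (compression 0) and single-duplex height (compression 1); Gaussian
    noise is added last.
    """
    H = spec.ridge_height_nm
    px = spec.pixel_size_nm
    sigma_t = (2 * spec.tip_radius_nm + spec.duplex_width_nm) / 2.355
    margin = max(3 * spec.tip_radius_nm, 4 * sigma_t)

    dense = [_resample(c, 0.4 * px) for c in gt.curves]
    arcs = [_resample(a, 0.4 * px, closed=False) for a in gt.open_arcs]

    # translate into the canvas
    allpts = np.vstack(dense + arcs)
    lo = allpts[:, :2].min(axis=0) - margin
    hi = allpts[:, :2].max(axis=0) + margin
    for c in dense + arcs:
        c[:, :2] -= lo
    shape = (
        int(np.ceil((hi[1] - lo[1]) / px)) + 1,
        int(np.ceil((hi[0] - lo[0]) / px)) + 1,
    )

    # projected crossings (located on a coarser resample) -> lift profiles
    crossings = []
    lifts = [np.zeros(len(c)) for c in dense]

    def _arclen(c):
        seg = np.linalg.norm(np.diff(np.vstack([c, c[:1]]), axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    dense_s = [_arclen(c) for c in dense]
    coarse = [_resample(c, 2.0 * px) for c in dense]
    coarse_s = [_arclen(c) for c in coarse]
    L = spec.lift_half_length_nm
    amp = H * (1.0 - spec.crossing_compression)
    for i in range(len(coarse)):
        for j in range(i, len(coarse)):
            hits = _segment_intersections(
                coarse[i], coarse[j], self_pair=(i == j)
            )
            for sP, sQ, zP, zQ, dP, dQ in hits:
                if abs(zP - zQ) < 1e-12:
                    raise GeometryError("ambiguous crossing height")
                over_is_P = zP > zQ
                oi, osamp = (i, sP) if over_is_P else (j, sQ)
                ui = j if over_is_P else i
                d_over, d_under = (dP, dQ) if over_is_P else (dQ, dP)
                sign = 1 if d_over[0] * d_under[1] - d_over[1] * d_under[0] > 0 \
                    else -1
                k = int(osamp)
                frac = osamp - k
                nxt = (k + 1) % len(coarse[oi])
                pos = coarse[oi][k, :2] + frac * (
                    coarse[oi][nxt, :2] - coarse[oi][k, :2]
                )
                s_over = coarse_s[oi][k] + frac * (
                    coarse_s[oi][k + 1] - coarse_s[oi][k]
                )
                total = dense_s[oi][-1]
                ds = np.abs(dense_s[oi][:-1] - s_over)
                ds = np.minimum(ds, total - ds)
                mask = ds < L
                lifts[oi][mask] = np.maximum(
                    lifts[oi][mask],
                    amp * np.cos(np.pi * ds[mask] / (2 * L)) ** 2,
                )
                crossings.append(
                    {
                        "x_px": float(pos[0] / px),
                        "y_px": float(pos[1] / px),
                        "over_component": oi,
                        "under_component": ui,
                        "sign": sign,
                    }
                )

    # rasterise: global max of Gaussian footprints
    img = np.zeros(shape)
    win = int(np.ceil(3 * sigma_t / px))
    yy, xx = np.mgrid[-win: win + 1, -win: win + 1].astype(float)
    for ci, c in enumerate(dense + arcs):
        tops = H + (lifts[ci] if ci < len(dense) else np.zeros(len(c)))
        cols = c[:, 0] / px
        rows = c[:, 1] / px
        for s in range(len(c)):
            r0, c0 = int(round(rows[s])), int(round(cols[s]))
            if not (win <= r0 < shape[0] - win and win <= c0 < shape[1] - win):
                raise GeometryError("curve exits the canvas")
            dr = (r0 + yy) - rows[s]
            dc = (c0 + xx) - cols[s]
            foot = tops[s] * np.exp(
                -((dr * px) ** 2 + (dc * px) ** 2) / (2 * sigma_t**2)
            )
            sl = img[r0 - win: r0 + win + 1, c0 - win: c0 + win + 1]
            np.maximum(sl, foot, out=sl)

    from scipy import ndimage

    img = ndimage.gaussian_filter(img, 1.0)
    if spec.noise_sd_nm > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd_nm, size=img.shape)

    out_gt = replace(
        gt,
        curves=[c.copy() for c in dense],
        open_arcs=[a.copy() for a in arcs],
        crossings=crossings,
    )
    hm = HeightMap(img, px, source_id=f"synthetic:{spec.topology}:{spec.seed}")
    return hm, out_gt


def generate(spec: SynthSpec) -> tuple[HeightMap, GroundTruth]:
    """Convenience: make_curve + render in one call."""
    return render_pseudo_afm(make_curve(spec), spec)


# ---------------------------------------------------------------------------
# deterministic fixture suite
# ---------------------------------------------------------------------------

def suite_specs(seed: int) -> list[tuple[str, SynthSpec]]:
    """The deterministic fixture suite: every topology in clean, noisy
    and compressed variants plus a clustered catenane."""
    base = dict(pixel_size_nm=1.0)
    topo = [
        ("circle", dict(topology="circle", contour_length_nm=768.0)),
        ("trefoil", dict(topology="torus_knot", p=2, q=3,
                         contour_length_nm=768.0)),
        ("figure8", dict(topology="twist_knot", n_twists=2,
                         contour_length_nm=1000.0)),
        ("torus5", dict(topology="torus_knot", p=2, q=5,
                        contour_length_nm=1100.0)),
        ("twist5", dict(topology="twist_knot", n_twists=3,
                        contour_length_nm=1200.0)),
        ("catenane", dict(topology="catenane_4node",
                          contour_length_nm=500.0)),
        ("theta", dict(topology="theta", contour_length_nm=900.0)),
    ]
    variants = [
        ("clean", dict(noise_sd_nm=0.0, crossing_compression=0.0)),
        ("noisy", dict(noise_sd_nm=0.15, crossing_compression=0.0)),
        ("compressed", dict(noise_sd_nm=0.0, crossing_compression=0.85)),
    ]
    out = []
    s = seed
    for tname, tkw in topo:
        for vname, vkw in variants:
            s += 1
            out.append(
                (f"{tname}_{vname}", SynthSpec(**base, **tkw, **vkw, seed=s))
            )
    out.append(
        (
            "catenane_clustered",
            SynthSpec(
                **base,
                topology="catenane_4node",
                contour_length_nm=430.0,
                clustered=True,
                noise_sd_nm=0.0,
                seed=seed + 1000,
            ),
        )
    )
    return out


def fixture_suite(seed: int, out_dir=None) -> pd.DataFrame:
    """Render the full suite; optionally write TIFFs plus a manifest CSV."""
    rows = []
    renders = []
    for name, spec in suite_specs(seed):
        hm, gt = generate(spec)
        renders.append((name, hm, gt))
        rows.append(
            {
                "file": f"{name}.tif",
                "topology": spec.topology,
                "seed": spec.seed,
                "noise_sd_nm": spec.noise_sd_nm,
                "crossing_compression": spec.crossing_compression,
                "pixel_size_nm": spec.pixel_size_nm,
                "rolfsen": gt.rolfsen,
                "n_components": gt.n_components,
                "true_lengths_nm": json.dumps(
                    [round(v, 2) for v in gt.contour_lengths_nm]
                ),
                "n_crossings": len(gt.crossings),
                "crossings": json.dumps(
                    [
                        {k: round(v, 2) if isinstance(v, float) else v
                         for k, v in c.items()}
                        for c in gt.crossings
                    ]
                ),
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        import tifffile

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, hm, _ in renders:
            tifffile.imwrite(out / f"{name}.tif",
                             hm.heights.astype(np.float32))
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
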