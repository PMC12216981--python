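"""Shared fixtures: synthetic renders and pipeline products.

Everything is generated at test time from the synthetic module; the heavy
multi-seed recovery sweep runs once per session and is shared between the
property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from topotrace import crossings as cr
from topotrace import imgproc, skeleton as sk_mod, tracing
from topotrace.knotting import classify, diagram_from_nxyz
from topotrace.synthfix import SynthSpec, generate

#: the six clean-suite topologies and their generator settings
SUITE_CASES = {
    "circle": dict(topology="circle", contour_length_nm=768.0),
    "trefoil": dict(topology="torus_knot", p=2, q=3, contour_length_nm=768.0),
    "figure8": dict(topology="twist_knot", n_twists=2,
                    contour_length_nm=1000.0),
    "torus5": dict(topology="torus_knot", p=2, q=5, contour_length_nm=1100.0),
    "twist5": dict(topology="twist_knot", n_twists=3,
                   contour_length_nm=1200.0),
    "catenane": dict(topology="catenane_4node", contour_length_nm=500.0),
}


def trace_image(hm, flat=None):
    """Run one height map through mask -> skeleton -> nodes -> trace."""
    flat = flat or imgproc.flatten(hm)
    mask = imgproc.mask_grains(flat)
    sk = sk_mod.skeletonize_height_biased(mask, flat, 1)
    sk = sk_mod.prune_skeleton(sk)
    nodes = cr.merge_close_nodes(cr.detect_nodes(sk), sk)
    for n in nodes:
        cr.pair_branches(n)
        cr.call_crossing_order(n, sk, flat)
    trace = tracing.order_trace(sk, nodes)
    return flat, mask, sk, nodes, trace


@pytest.fixture(scope="session")
def clean_render():
    """One clean trefoil render with its full pipeline products."""
    spec = SynthSpec(noise_sd_nm=0.0, seed=11, **SUITE_CASES["trefoil"])
    hm, gt = generate(spec)
    flat, mask, sk, nodes, trace = trace_image(hm)
    return dict(spec=spec, hm=hm, gt=gt, flat=flat, mask=mask, sk=sk,
                nodes=nodes, trace=trace)


@pytest.fixture(scope="session")
def catenane_render():
    spec = SynthSpec(noise_sd_nm=0.0, seed=21, **SUITE_CASES["catenane"])
    hm, gt = generate(spec)
    flat, mask, sk, nodes, trace = trace_image(hm)
    return dict(spec=spec, hm=hm, gt=gt, flat=flat, mask=mask, sk=sk,
                nodes=nodes, trace=trace)


@pytest.fixture(scope="session")
def recovery_sweep():
    """Clean-suite recovery: 6 topologies x 10 distinct seeds.

    Returns one record per render with the true and recovered topology,
    molecule counts, contour lengths and crossing-call accuracy.
    """
    records = []
    seed = 100
    for name, kw in SUITE_CASES.items():
        for _ in range(10):
            seed += 1
            spec = SynthSpec(noise_sd_nm=0.0, crossing_compression=0.0,
                             seed=seed, **kw)
            hm, gt = generate(spec)
            _, _, sk, nodes, trace = trace_image(hm)
            diag = diagram_from_nxyz(trace.as_arrays())
            res = classify(diag)
            records.append(
                dict(
                    name=name, seed=seed, gt=gt, sk=sk, nodes=nodes,
                    trace=trace, diagram=diag, rolfsen=res.rolfsen,
                )
            )
    return records


def build_skeleton(paths, heights=2.0, pixel_size_nm=1.0):
    """Construct a Skeleton from explicit pixel paths (unit tests)."""
    pixels = []
    hts = {}
    default = heights if isinstance(heights, (int, float)) else None
    for k, path in enumerate(paths):
        for p in path:
            p = tuple(p)
            if p not in hts:
                pixels.append(p)
            hts[p] = (
                default if default is not None else heights[k]
            )
    return sk_mod.Skeleton(pixels, hts, pixel_size_nm)


def ring_pixels(radius, centre=(0, 0), height=2.0):
    """8-connected digital circle as an ordered pixel path."""
    n = max(int(np.ceil(2 * np.pi * radius * 2)), 16)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = []
    for a in t:
        p = (int(round(centre[0] + radius * np.sin(a))),
             int(round(centre[1] + radius * np.cos(a))))
        if not pts or p != pts[-1]:
            pts.append(p)
    # drop duplicates while keeping order
    seen = set()
    out = []
    for p in pts:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out
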