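"""End-to-end orchestration and the command-line interface.

``run`` drives the full chain per object — mask, skeleton, nodes, branch
pairing, crossing order, trace, topology, morphometrics, cleanup — and
collects one results row per grain.  Unclassifiable molecules never abort
a run; they are recorded with their failure stage so that every input
grain appears either in the results table or in the removal log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import click
import numpy as np
import pandas as pd

from . import crossings as cr
from . import imgproc, knotting, morphometrics, skeleton, synthfix, tracing
from .errors import TopotraceError

log = logging.getLogger("topotrace")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    pixel_size_nm: float = 1.0
    flatten: imgproc.FlattenConfig = field(default_factory=imgproc.FlattenConfig)
    mask: imgproc.MaskConfig = field(default_factory=imgproc.MaskConfig)
    min_grain_px: int = 60
    prune_length_fraction: float = 0.15
    prune_height_drop_nm: float = 0.85
    node_merge_nm: float = 7.0
    odd_connect_max_nm: float = 40.0
    crossing_region_nm: float = 20.0
    reliability_threshold: float = cr.DEFAULT_RELIABILITY_THRESHOLD
    max_crossings: int = 14
    contour_smooth_px: int = 5
    break_at_junctions: bool = False   # replication-intermediate mode
    cleanup_mode: str = "topology"
    expected_molecules: int | None = None
    conformation: morphometrics.ConformationRules = field(
        default_factory=morphometrics.ConformationRules
    )
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "flatten":
                val = imgproc.FlattenConfig(**val)
            elif f.name == "mask":
                val = imgproc.MaskConfig(**val)
            elif f.name == "conformation":
                val = morphometrics.ConformationRules(**val)
            kwargs[f.name] = val
        return cls(**kwargs)


def _process_grain(
    grain_id: int,
    mask: imgproc.GrainMask,
    flat: imgproc.HeightMap,
    cfg: RunConfig,
) -> dict:
    """Run one grain through the pipeline; returns a results row."""
    row: dict = {"object_id": grain_id, "disposition": "ok"}
    sk = skeleton.skeletonize_height_biased(
        mask, flat, grain_id, min_area_px=cfg.min_grain_px
    )
    # replication mode keeps short genuine arms (reversed forks) that the
    # default relative-length prune would treat as spurs
    frac = 0.02 if cfg.break_at_junctions else cfg.prune_length_fraction
    sk = skeleton.prune_skeleton(sk, frac, cfg.prune_height_drop_nm)
    nodes = cr.detect_nodes(sk)
    nodes = cr.merge_close_nodes(
        nodes,
        sk,
        merge_dist_nm=cfg.node_merge_nm,
        odd_connect_max_nm=0.0 if cfg.break_at_junctions else cfg.odd_connect_max_nm,
    )
    row["n_nodes"] = len(nodes)
    row["grain_junctions"] = sum(1 for n in nodes if n.n_branches % 2 == 1)
    row["grain_endpoints"] = len(sk.endpoints())
    row["conformation"] = morphometrics.classify_conformation(
        sk, nodes, cfg.conformation
    )
    row.update(
        morphometrics.grain_shape_features(
            mask.grain_pixels(grain_id), mask.pixel_size_nm
        )
    )
    row["max_duplexes_per_crossing"] = max(
        (n.n_branches // 2 for n in nodes), default=0
    )

    junctions = [n for n in nodes if n.n_branches % 2 == 1]
    if cfg.break_at_junctions or junctions:
        # replication-intermediate route: no through-crossing tracing
        theta = morphometrics.analyze_theta(
            sk, nodes, smooth_px=cfg.contour_smooth_px
        )
        rev, rev_len = morphometrics.detect_reversed_fork(
            sk, nodes, smooth_px=cfg.contour_smooth_px
        )
        row.update(
            {
                "disposition": "junction",
                "is_theta": theta.is_theta,
                "n_forks": theta.n_forks,
                "unreplicated_length_nm": theta.unreplicated_length_nm,
                "theta_segments_nm": json.dumps(
                    [round(v, 1) for v in theta.segment_lengths_nm]
                ),
                "reversed_fork": rev,
                "reversed_fork_length_nm": rev_len,
                "contour_length_nm": sk.total_length_nm(),
                "n_molecules": 0,
                "n_linear_molecules": 0,
            }
        )
        return row

    for node in nodes:
        cr.pair_branches(node, cfg.crossing_region_nm)
        cr.call_crossing_order(node, sk, flat)
    trace = tracing.order_trace(sk, nodes, object_id=grain_id)
    mols = trace.molecules
    lengths = [
        morphometrics.contour_length(
            m, sk.pixel_size_nm, cfg.contour_smooth_px
        )
        for m in mols
    ]
    cors = [n.cor for n in nodes if n.cor is not None]
    row.update(
        {
            "n_molecules": len(mols),
            "n_linear_molecules": sum(1 for m in mols if not m.closed),
            "contour_length_nm": float(np.sum(lengths)) if lengths else np.nan,
            "contour_lengths_nm": json.dumps(
                [round(v, 1) for v in sorted(lengths)]
            ),
            "n_crossings": len(nodes),
            "avg_cor": float(np.mean(cors)) if cors else None,
            "min_cor": float(np.min(cors)) if cors else None,
            "end_to_end_nm": float(
                np.mean(
                    [
                        0.0
                        if m.closed
                        else np.hypot(
                            m.pixels[-1][0] - m.pixels[0][0],
                            m.pixels[-1][1] - m.pixels[0][1],
                        )
                        * sk.pixel_size_nm
                        for m in mols
                    ]
                )
            ),
        }
    )

    diag = knotting.diagram_from_nxyz(
        trace.as_arrays(),
        merge_dist_px=cfg.node_merge_nm / sk.pixel_size_nm,
    )
    # attach per-crossing reliabilities: diagram positions are (x, y),
    # node centroids (row, col)
    cents = [n.centroid() for n in nodes]
    for cid, (x, y) in diag.positions.items():
        if not cents:
            break
        k = int(
            np.argmin([np.hypot(c[0] - y, c[1] - x) for c in cents])
        )
        if nodes[k].cor is not None:
            diag.cor[cid] = nodes[k].cor
    res = knotting.classify(diag, max_crossings=cfg.max_crossings)
    row.update(
        {
            "rolfsen": res.rolfsen,
            "alternate_rolfsen": res.alternate_rolfsen,
            "chirality": res.chirality,
            "jones": res.polynomial.t_string(),
            "signs": json.dumps(list(res.signs)),
            "reliable": (
                len(nodes) == 0
                or (
                    row["min_cor"] is not None
                    and row["min_cor"] >= cfg.reliability_threshold
                )
            ),
        }
    )
    row["_trace"] = trace
    return row


def run(
    images: list,
    cfg: RunConfig | None = None,
    out_dir=None,
) -> dict:
    """Process height maps end to end.

    ``images`` holds HeightMap objects or file paths.  Returns a bundle
    with the per-object results table, the NXYZ trace table, per-step
    cleanup counts and the configuration; optionally writes everything
    under ``out_dir``.
    """
    cfg = cfg or RunConfig()
    rows = []
    traces = []
    for idx, src in enumerate(images):
        hm = (
            src
            if isinstance(src, imgproc.HeightMap)
            else imgproc.load_heightmap(src, cfg.pixel_size_nm)
        )
        flat = imgproc.flatten(hm, cfg.flatten)
        mask = imgproc.mask_grains(flat, cfg.mask)
        log.info("image %s: %d grains", hm.source_id or idx, mask.n_grains)
        for gid in range(1, mask.n_grains + 1):
            try:
                row = _process_grain(gid, mask, flat, cfg)
            except TopotraceError as exc:
                row = {
                    "object_id": gid,
                    "disposition": f"failed: {type(exc).__name__}",
                    "error": str(exc),
                    "contour_length_nm": np.nan,
                    "n_molecules": 0,
                    "n_linear_molecules": 0,
                }
            row["image"] = str(hm.source_id or idx)
            trace = row.pop("_trace", None)
            if trace is not None:
                traces.append(trace)
            rows.append(row)
    results = pd.DataFrame(rows)
    nxyz = tracing.to_nxyz(traces)
    retained, removed = (results, {})
    if len(results):
        retained, removed = morphometrics.cleanup_filter(
            results, cfg.cleanup_mode, cfg.expected_molecules
        )
    bundle = {
        "results": results,
        "retained": retained,
        "removed_per_step": removed,
        "nxyz": nxyz,
        "config": cfg.to_dict(),
    }
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.drop(
            columns=[c for c in ("error",) if c in results], errors="ignore"
        ).to_csv(out / "results.csv", index=False)
        nxyz.to_csv(out / "nxyz.csv", index=False)
        summary = {
            "n_objects": int(len(results)),
            "n_retained": int(len(retained)),
            "removed_per_step": removed,
            "config": cfg.to_dict(),
        }
        if "contour_length_nm" in retained and len(retained):
            vals = retained["contour_length_nm"].dropna()
            if len(vals):
                summary["contour_length_nm"] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return bundle


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="WARNING", show_default=True)
def cli(log_level):
    """Trace DNA molecules in AFM images and classify their topology."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), 30))


@cli.command("trace")
@click.argument("images", nargs=-1, required=True,
                type=click.Path(exists=True))
@click.option("--pixel-size", type=float, default=1.0, show_default=True,
              help="pixel size in nm")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML run configuration")
@click.option("--out-dir", type=click.Path(), default="topotrace_out",
              show_default=True)
@click.option("--cleanup-mode", default=None,
              type=click.Choice(sorted(morphometrics.CLEANUP_MODES)))
@click.option("--replication", is_flag=True,
              help="break skeletons at junctions (theta-structure mode)")
def cli_trace(images, pixel_size, config_path, out_dir, cleanup_mode,
              replication):
    """Trace IMAGES (TIFF / text grids) into topology and morphometrics."""
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    cfg.pixel_size_nm = pixel_size
    if cleanup_mode:
        cfg.cleanup_mode = cleanup_mode
    if replication:
        cfg.break_at_junctions = True
        cfg.cleanup_mode = "replication"
    bundle = run(list(images), cfg, out_dir=out_dir)
    res = bundle["results"]
    click.echo(
        f"{len(res)} objects; retained {len(bundle['retained'])}; "
        f"removed per step {bundle['removed_per_step']}"
    )
    if "rolfsen" in res:
        for _, r in res.iterrows():
            click.echo(
                f"  object {r['object_id']}: {r.get('rolfsen', '-')} "
                f"(min COR {r.get('min_cor')})"
            )


@cli.command("classify")
@click.argument("nxyz_csv", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None)
def cli_classify(nxyz_csv, out):
    """Classify molecules from an NXYZ trace table (CSV)."""
    df = pd.read_csv(nxyz_csv)
    rows = []
    for oid, mols in tracing.nxyz_to_molecules(df).items():
        try:
            diag = knotting.diagram_from_nxyz(mols)
            res = knotting.classify(diag)
            rows.append(
                dict(object_id=oid, rolfsen=res.rolfsen,
                     n_crossings=res.n_crossings,
                     jones=res.polynomial.t_string())
            )
        except TopotraceError as exc:
            rows.append(dict(object_id=oid, rolfsen=f"error: {exc}"))
    table = pd.DataFrame(rows)
    click.echo(table.to_string(index=False))
    if out:
        table.to_csv(out, index=False)


@cli.command("synth")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), default="synthetic",
              show_default=True)
def cli_synth(seed, out_dir):
    """Generate the ground-truthed pseudo-AFM fixture suite."""
    manifest = synthfix.fixture_suite(seed, out_dir=out_dir)
    click.echo(f"wrote {len(manifest)} images to {out_dir}")


@cli.command("prob")
@click.option("--knot", default="3_1", show_default=True,
              help="Rolfsen label of the minimal diagram to perturb")
@click.option("--p", "p_acc", type=float, default=0.82, show_default=True,
              help="per-crossing classification accuracy")
def cli_prob(knot, p_acc):
    """Misclassification probabilities under crossing-order errors."""
    diag = knotting.minimal_diagram(knot)
    table = knotting.classification_probability(diag, p_acc)
    for label, prob in sorted(table.items(), key=lambda kv: -kv[1]):
        click.echo(f"  {label:16s} {prob:8.4f}")


@cli.command("geometry")
@click.argument("curves", nargs=-1, required=True,
                type=click.Path(exists=True))
def cli_geometry(curves):
    """Writhe / linking / twist of closed 3D curves (CSV or whitespace
    x y z files; two curves give the linking number)."""
    data = [np.loadtxt(c, delimiter=None) for c in curves]
    for path, arr in zip(curves, data):
        click.echo(f"{path}: Wr = {knotting.writhe_gauss(arr):.4f}")
    if len(data) == 2:
        lk = knotting.linking_number(data[0], data[1])
        tw = knotting.twist_ribbon(data[0], data[1])
        click.echo(f"Lk = {lk:.4f}  Tw(ribbon) = {tw:.4f}")


if __name__ == "__main__":  # pragma: no cover
    cli()
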