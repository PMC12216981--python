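"""Lengths, replication-intermediate analysis, conformations, cleanup."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_skeleton, trace_image
from topotrace import crossings as cr
from topotrace import morphometrics as mm
from topotrace.errors import ConfigError, DegenerateError
from topotrace.synthfix import SynthSpec, generate, make_curve
from topotrace.tracing import Molecule


def square_loop(side=100):
    """Closed ring on a (side+1) x (side+1) grid: 4 x side axial steps."""
    pixels = (
        [(0, c) for c in range(side + 1)]
        + [(r, side) for r in range(1, side + 1)]
        + [(side, c) for c in range(side - 1, -1, -1)]
        + [(r, 0) for r in range(side - 1, 0, -1)]
    )
    return Molecule(pixels, [0] * len(pixels), closed=True)


class TestLengths:
    def test_square_loop_digital_closed_form(self):
        mol = square_loop(100)
        # 4 sides of 100 px at 1 nm/px, axial steps only
        assert mm.contour_length(mol, 1.0, smooth_px=0) == pytest.approx(400.0)

    def test_square_loop_smoothed_within_tolerance(self):
        mol = square_loop(100)
        got = mm.contour_length(mol, 1.0)  # corner rounding only
        assert got == pytest.approx(400.0, rel=0.02)

    def test_rendered_circle_close_to_circumference(self):
        spec = SynthSpec(topology="circle", contour_length_nm=628.3,
                         noise_sd_nm=0.0, seed=41)
        hm, gt = generate(spec)
        _, _, sk, nodes, trace = trace_image(hm)
        got = mm.contour_length(trace.molecules[0], sk.pixel_size_nm)
        assert got == pytest.approx(628.3, rel=0.05)

    def test_catenane_lengths_reported_separately(self, catenane_render):
        trace = catenane_render["trace"]
        gt = catenane_render["gt"]
        got = sorted(
            mm.contour_length(m, trace.pixel_size_nm)
            for m in trace.molecules
        )
        true = sorted(gt.contour_lengths_nm)
        for g, t in zip(got, true):
            assert g == pytest.approx(t, rel=0.07)

    def test_too_short_trace_rejected(self):
        with pytest.raises(DegenerateError):
            mm.contour_length(Molecule([(0, 0), (0, 1)], [0, 0], True), 1.0)

    @pytest.mark.parametrize(
        "bp,expected", [(2260, 768.0), (3574, 1215.0), (0, 0.0)]
    )
    def test_expected_length_from_base_pairs(self, bp, expected):
        assert mm.expected_length(bp) == expected

    def test_expected_length_negative_rejected(self):
        with pytest.raises(ValueError):
            mm.expected_length(-1)

    def test_percentage_error_worked_examples(self):
        assert mm.percentage_error(761, 768) == pytest.approx(0.91, abs=0.005)
        assert mm.percentage_error(1190, 1215) == pytest.approx(2.06, abs=0.01)
        assert mm.percentage_error(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            mm.percentage_error(10.0, 0.0)


def fork_skeleton(arm_a=150, arm_b=140, arm_c=60):
    """Two 3-way junctions joined by three arms of given pixel lengths."""
    # junctions at (0,0) and far right; three parallel-ish arms
    left = (50, 0)
    right = (50, 200)
    top = [(50 - min(k, 25, arm_a - k), int(round(200 * k / arm_a)))
           for k in range(1, arm_a)]
    mid = [(50, c) for c in range(1, 200)]
    bot = [(50 + min(k, 25, arm_b - k), int(round(200 * k / arm_b)))
           for k in range(1, arm_b)]
    # dedupe consecutive
    def clean(path):
        out = []
        for p in path:
            if not out or p != out[-1]:
                out.append(p)
        return out

    return build_skeleton([[left], [right], clean(top), mid, clean(bot)])


class TestTheta:
    def test_rendered_theta_unreplicated_is_most_dissimilar(self):
        spec = SynthSpec(topology="theta", contour_length_nm=900.0,
                         noise_sd_nm=0.0, seed=43)
        hm, gt = generate(spec)
        flat, mask, sk, nodes, _ = None, None, None, None, None
        from topotrace import imgproc, skeleton as sk_mod

        flat = imgproc.flatten(hm)
        mask = imgproc.mask_grains(flat)
        sk = sk_mod.prune_skeleton(
            sk_mod.skeletonize_height_biased(mask, flat, 1)
        )
        nodes = cr.merge_close_nodes(
            cr.detect_nodes(sk), sk, odd_connect_max_nm=0.0
        )
        theta = mm.analyze_theta(sk, nodes)
        assert theta.is_theta and theta.n_forks == 2
        # unreplicated arm = the long arc; the two replicated arms match
        assert theta.unreplicated_length_nm == max(theta.segment_lengths_nm)
        reps = sorted(theta.replicated_lengths_nm)
        assert reps[1] - reps[0] < 0.25 * reps[1]

    def test_circle_is_not_a_theta(self):
        spec = SynthSpec(topology="circle", noise_sd_nm=0.0, seed=44)
        hm, _ = generate(spec)
        _, _, sk, nodes, _ = trace_image(hm)
        assert not mm.analyze_theta(sk, nodes).is_theta

    def test_near_equal_segments_flagged_low_confidence(self):
        # synthetic skeleton: segments 400 / 390 / 380 px
        sk = fork_skeleton()
        nodes = cr.detect_nodes(sk)
        theta = mm.analyze_theta(sk, nodes)
        if theta.is_theta:
            spread = max(theta.segment_lengths_nm) - min(
                theta.segment_lengths_nm
            )
            if spread < 0.15 * np.mean(theta.segment_lengths_nm):
                assert theta.low_confidence


class TestReversedFork:
    def test_rendered_reversed_fork_detected(self):
        spec = SynthSpec(topology="theta_reversed", contour_length_nm=900.0,
                         noise_sd_nm=0.0, seed=45)
        hm, gt = generate(spec)
        from topotrace import imgproc, skeleton as sk_mod

        flat = imgproc.flatten(hm)
        mask = imgproc.mask_grains(flat)
        # replication-mode pruning: keep short genuine arms
        sk = sk_mod.prune_skeleton(
            sk_mod.skeletonize_height_biased(mask, flat, 1),
            length_fraction=0.02,
        )
        nodes = cr.merge_close_nodes(
            cr.detect_nodes(sk), sk, odd_connect_max_nm=0.0
        )
        flagged, length = mm.detect_reversed_fork(sk, nodes)
        assert flagged
        assert length < 50.0

    def test_long_stub_not_flagged(self):
        spine = [(50, c) for c in range(0, 120)]
        up = [(50 - k, 60) for k in range(1, 30)]
        down = [(50 + k, 60) for k in range(1, 80)]  # 80 nm arm
        sk = build_skeleton([spine, up, down])
        # central node is 4-way; the 30 nm arm makes it a reversed fork,
        # but an 80 nm arm alone must not
        sk80 = build_skeleton([spine, down])
        nodes80 = cr.detect_nodes(sk80)
        assert mm.detect_reversed_fork(sk80, nodes80) == (False, None)
        nodes = cr.detect_nodes(sk)
        flagged, length = mm.detect_reversed_fork(sk, nodes)
        assert flagged and length == pytest.approx(29, abs=3)

    def test_paired_crossing_not_flagged(self, clean_render):
        sk, nodes = clean_render["sk"], clean_render["nodes"]
        assert mm.detect_reversed_fork(sk, nodes) == (False, None)


class TestConformation:
    def test_open_catenane(self, catenane_render):
        got = mm.classify_conformation(
            catenane_render["sk"], catenane_render["nodes"]
        )
        assert got == "open"

    def test_pinched_catenane_merges_crossings_and_classifies_taut(self):
        spec = SynthSpec(topology="catenane_4node", contour_length_nm=500.0,
                         clustered=True, noise_sd_nm=0.0, seed=46)
        hm, gt = generate(spec)
        from topotrace import imgproc, skeleton as sk_mod

        flat = imgproc.flatten(hm)
        mask = imgproc.mask_grains(flat)
        sk = sk_mod.prune_skeleton(
            sk_mod.skeletonize_height_biased(mask, flat, 1)
        )
        nodes = cr.merge_close_nodes(cr.detect_nodes(sk), sk)
        # the four crossings collapse into fewer merged nodes
        assert 0 < len(nodes) < len(gt.crossings)
        got = mm.classify_conformation(sk, nodes)
        assert got == gt.conformation == "taut"

    def test_clustered_rule_fires_on_six_branch_node(self):
        sk = build_skeleton([[(5, c) for c in range(0, 30)]])
        node = cr.CrossingNode(0, {(5, 15)})
        node.branches = [[(5, 16)]] * 6
        assert mm.classify_conformation(sk, [node]) == "clustered"

    def test_no_nodes_unclassified(self, clean_render):
        sk = clean_render["sk"]
        assert mm.classify_conformation(sk, []) == "unclassified"

    def test_bowtie_single_node_two_lobes(self):
        # one 8-branch node bridging two separate loops
        def rect(r0, c0):
            return (
                [(r0, c) for c in range(c0, c0 + 10)]
                + [(r, c0 + 9) for r in range(r0 + 1, r0 + 10)]
                + [(r0 + 9, c) for c in range(c0 + 8, c0 - 1, -1)]
                + [(r, c0) for r in range(r0 + 8, r0, -1)]
            )

        lobe1 = rect(10, 5)
        lobe2 = rect(10, 25)
        bridge = [(15, c) for c in range(15, 25)]
        sk = build_skeleton([lobe1, lobe2, bridge])
        node = cr.CrossingNode(0, set(bridge))
        node.branches = [[p] for p in [(14, 14), (16, 14), (14, 25),
                                       (16, 25), (15, 14), (15, 26),
                                       (14, 15), (16, 15)]]
        got = mm.classify_conformation(sk, [node])
        assert got == "bow-tie"


class TestCleanup:
    def records(self):
        return pd.DataFrame(
            [
                # healthy knot
                dict(object_id=1, contour_length_nm=750.0, n_molecules=1,
                     n_linear_molecules=0, max_duplexes_per_crossing=2),
                # tracing failed
                dict(object_id=2, contour_length_nm=np.nan, n_molecules=0,
                     n_linear_molecules=0, max_duplexes_per_crossing=0),
                # broken mask -> linear fragment
                dict(object_id=3, contour_length_nm=500.0, n_molecules=2,
                     n_linear_molecules=1, max_duplexes_per_crossing=2),
                # clustered crossing
                dict(object_id=4, contour_length_nm=820.0, n_molecules=1,
                     n_linear_molecules=0, max_duplexes_per_crossing=3),
                # knot traced as two molecules
                dict(object_id=5, contour_length_nm=700.0, n_molecules=2,
                     n_linear_molecules=0, max_duplexes_per_crossing=2),
            ]
        )

    def test_empty_contour_removed_first(self):
        kept, removed = mm.cleanup_filter(self.records(), "topology")
        assert removed[1] == 1
        assert 2 not in kept["object_id"].values

    def test_step4_only_in_contour_and_distribution_modes(self):
        kept_topo, _ = mm.cleanup_filter(self.records(), "topology")
        assert 5 in kept_topo["object_id"].values
        kept_len, removed = mm.cleanup_filter(
            self.records(), "contour_length", expected_molecules=1
        )
        assert 5 not in kept_len["object_id"].values
        assert removed[4] == 1

    def test_clustered_retained_in_crossing_distribution_mode(self):
        kept, _ = mm.cleanup_filter(
            self.records(), "crossing_distributions", expected_molecules=1
        )
        assert 4 in kept["object_id"].values

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            mm.cleanup_filter(self.records(), "nonsense")

    def test_retention_monotone_in_steps(self):
        full, _ = mm.cleanup_filter(
            self.records(), "contour_length", expected_molecules=1
        )
        partial, _ = mm.cleanup_filter(self.records(), "topology")
        none, _ = mm.cleanup_filter(self.records(), "surface_compaction")
        assert len(full) <= len(partial) <= len(none)


class TestShapeFeatures:
    def test_rectangle_box_and_feret(self):
        pixels = np.array(
            [(r, c) for r in range(10) for c in range(40)]
        )
        feats = mm.grain_shape_features(pixels, 2.0)
        assert feats["smallest_bounding_width_nm"] == pytest.approx(18, abs=2)
        assert feats["smallest_bounding_length_nm"] == pytest.approx(78, abs=2)
        assert feats["max_feret_nm"] >= feats["smallest_bounding_width_nm"]
        assert feats["aspect_ratio"] > 3
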