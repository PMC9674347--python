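"""Segmentation, interface detection, and coarse-model construction."""

import numpy as np
import pytest

import xlweaver as xw
from xlweaver.io_formats import Chain, PAEMatrix, Residue, Structure
from xlweaver.representation import (InterfaceParams, SegmentationParams,
                                     bead_radius, build_coarse_model,
                                     detect_interfaces, segment_rigid_bodies)


def make_chain(confidences, start=1, spacing=3.8):
    residues = [
        Residue(start + i, "ALA", (i * spacing, 0.0, 0.0), float(c))
        for i, c in enumerate(confidences)
    ]
    return Structure(id="p", chains=[Chain("A", residues)])


class TestSegmentation:
    def test_uniform_confidence_single_range(self):
        s = make_chain([90.0] * 100)
        assert segment_rigid_bodies(s)["p"] == [(1, 100)]

    def test_low_confidence_dip_splits(self):
        """Brute-force threshold scan with smoothing disabled."""
        conf = [90.0] * 100
        for r in range(45, 56):
            conf[r - 1] = 40.0
        s = make_chain(conf)
        p = SegmentationParams(smoothing_window=1)
        got = segment_rigid_bodies(s, p)["p"]
        # oracle: direct threshold scan
        mask = [c > 70.0 for c in conf]
        runs, start = [], None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            if not m and start is not None:
                runs.append((start + 1, i))
                start = None
        if start is not None:
            runs.append((start + 1, len(mask)))
        runs = [r for r in runs if r[1] - r[0] + 1 >= p.min_segment]
        assert got == runs == [(1, 44), (56, 100)]

    def test_manual_break_forces_two_bodies(self):
        s = make_chain([90.0] * 120)
        p = SegmentationParams(manual_breaks=[("p", 61)])
        assert segment_rigid_bodies(s, p)["p"] == [(1, 60), (61, 120)]

    def test_short_chain_all_flexible(self, caplog):
        s = make_chain([95.0] * 5)
        assert segment_rigid_bodies(s)["p"] == []

    def test_smoothing_suppresses_single_residue_break(self):
        conf = [90.0] * 60
        conf[30] = 40.0
        s = make_chain(conf)
        assert segment_rigid_bodies(s)["p"] == [(1, 60)]

    def test_idempotent_and_chain_order_invariant(self, truth4):
        for st in truth4.structures:
            a = segment_rigid_bodies(st)
            b = segment_rigid_bodies(st)
            assert a == b


def pae_two_proteins(na, nb, fill=25.0):
    labels = [("A", i + 1) for i in range(na)] + [("B", i + 1) for i in range(nb)]
    return labels, np.full((na + nb, na + nb), fill)


class TestInterfaces:
    def test_all_above_threshold_no_patches(self):
        labels, values = pae_two_proteins(20, 20, fill=30.0)
        assert detect_interfaces(PAEMatrix(labels=labels, values=values)) == []

    def test_planted_block_recovered_exactly(self):
        labels, values = pae_two_proteins(30, 30, fill=25.0)
        values[5:15, 30 + 10:30 + 20] = 2.0
        values[30 + 10:30 + 20, 5:15] = 2.0
        patches = detect_interfaces(PAEMatrix(labels=labels, values=values))
        assert len(patches) == 1
        p = patches[0]
        # oracle: brute-force enumeration of qualifying pairs
        expected = {(i + 1, j + 1) for i in range(5, 15) for j in range(10, 20)}
        assert set(p.pairs) == expected
        assert p.range_a == (6, 15) and p.range_b == (11, 20)

    def test_threshold_is_strict(self):
        labels, values = pae_two_proteins(15, 15, fill=25.0)
        values[0:12, 15:27] = 3.5
        values[15:27, 0:12] = 3.5
        assert detect_interfaces(PAEMatrix(labels=labels, values=values)) == []

    def test_min_patch_discards_small(self):
        labels, values = pae_two_proteins(15, 15, fill=25.0)
        values[0:2, 15:17] = 1.0
        values[15:17, 0:2] = 1.0
        assert detect_interfaces(PAEMatrix(labels=labels, values=values)) == []

    def test_asymmetry_rule_min(self):
        labels, values = pae_two_proteins(12, 12, fill=25.0)
        # low only in one direction: min rule qualifies, max does not
        values[0:11, 12:23] = 2.0
        pmin = detect_interfaces(PAEMatrix(labels=labels, values=values),
                                 InterfaceParams(asymmetry_rule="min"))
        pmax = detect_interfaces(PAEMatrix(labels=labels, values=values),
                                 InterfaceParams(asymmetry_rule="max"))
        assert len(pmin) == 1 and pmax == []

    def test_single_protein_matrix_empty(self):
        labels = [("A", i + 1) for i in range(10)]
        out = detect_interfaces(PAEMatrix(labels=labels,
                                          values=np.full((10, 10), 1.0)))
        assert out == []


class TestCoarseModel:
    def test_bead_counts_100_residues(self):
        s = make_chain([90.0] * 100)
        m = build_coarse_model([s], {"p": [(1, 100)]})
        assert m.n_beads == 100
        assert m.n_ev_beads == 10
        assert len(m.rigid_bodies) == 1

    def test_bead_counts_9_residues(self):
        s = make_chain([90.0] * 9)
        m = build_coarse_model([s], {"p": []})
        assert m.n_ev_beads == 1
        assert m.ev_sizes[0] == 9

    def test_coverage_invariant(self, model4):
        assert model4.ev_sizes.sum() == model4.n_beads
        covered = np.concatenate([b for b in model4.rigid_bodies] +
                                 [model4.flexible_beads])
        assert sorted(covered) == list(range(model4.n_beads))

    def test_bead_radius_formula(self):
        assert bead_radius(1) == pytest.approx((3 * 130 / (4 * np.pi)) ** (1 / 3))
        assert bead_radius(10) == pytest.approx(10 ** (1 / 3) * bead_radius(1))

    def test_rigid_geometry_preserved_under_pose(self, model4, rng):
        from xlweaver.geometry import random_rotation

        B = len(model4.rigid_bodies)
        rots = np.stack([random_rotation(rng) for _ in range(B)])
        trans = rng.uniform(-50, 50, size=(B, 3))
        coords = model4.apply_poses(rots, trans)
        for body in model4.rigid_bodies:
            ref = model4.ref_coords[body]
            new = coords[body]
            dref = np.linalg.norm(ref[:, None] - ref[None], axis=2)
            dnew = np.linalg.norm(new[:, None] - new[None], axis=2)
            assert np.abs(dref - dnew).max() < 1e-6

    def test_six_subunit_default_yields_ten_bodies(self):
        """The default configuration (six subunits, four of them split in
        two) coarse-grains to ten rigid bodies."""
        truth = xw.generate_complex(seed=7)
        segments = {}
        for st in truth.structures:
            segments.update(xw.segment_rigid_bodies(st))
        m = build_coarse_model(truth.structures, segments)
        assert len(m.rigid_bodies) == 10

    def test_interface_merge_uses_pair_model_orientation(self, rng):
        """Two single-segment proteins merged through a pair model adopt the
        pair model's relative placement."""
        from xlweaver.geometry import random_rotation
        from xlweaver.representation import InterfacePatch

        # non-collinear (helical) shape so superpositions are unambiguous
        i = np.arange(30)
        shape = np.stack([1.5 * i, 5.0 * np.cos(i), 5.0 * np.sin(i)], axis=1)
        a = Structure(id="a", chains=[Chain("A", [
            Residue(k + 1, "ALA", tuple(shape[k]), 90.0) for k in range(30)])])
        Rb0 = random_rotation(rng)
        b_coords = shape @ Rb0.T + np.array([40.0, 8.0, -3.0])
        b = Structure(id="b", chains=[Chain("A", [
            Residue(k + 1, "ALA", tuple(b_coords[k]), 90.0) for k in range(30)])])
        # pair model: a in a rotated frame, b shifted +15 in z relative to a
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 7.0])
        pa = shape @ R.T + t
        pb = (shape + np.array([0.0, 0.0, 15.0])) @ R.T + t
        pair = Structure(id="ab", chains=[
            Chain("A", [Residue(i + 1, "ALA", tuple(p), 90.0)
                        for i, p in enumerate(pa)]),
            Chain("B", [Residue(i + 1, "ALA", tuple(p), 90.0)
                        for i, p in enumerate(pb)]),
        ])
        patch = InterfacePatch("a", "b", [(i, i) for i in range(1, 31)],
                               (1, 30), (1, 30))
        m = build_coarse_model(
            [a, b], {"a": [(1, 30)], "b": [(1, 30)]},
            interfaces=[patch], pair_models={("a", "b"): pair},
        )
        assert len(m.rigid_bodies) == 1
        beads_a = m.protein_beads("a")
        beads_b = m.protein_beads("b")
        delta = m.ref_coords[beads_b] - m.ref_coords[beads_a]
        assert np.allclose(delta, [0.0, 0.0, 15.0], atol=1e-6)
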