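"""Ensemble filtering, clustering, precision, densities, satisfaction."""

import numpy as np
import pytest

import xlweaver as xw
from xlweaver.ensemble_analysis import (AnalysisParams, Ensemble,
                                        cluster_models, cluster_precision,
                                        ensemble_xl_satisfaction,
                                        filter_models, localized_density,
                                        split_half_cc, static_xl_satisfaction)
from xlweaver.io_formats import Chain, CrosslinkSet, Residue, Structure
from xlweaver.sampling import Trajectory


def make_traj(run_id, scores, flex):
    """Trajectory of pure flexible-bead frames with given score arrays."""
    F = len(flex)
    return Trajectory(
        run_id=run_id,
        rotations=np.zeros((F, 0, 3, 3)),
        translations=np.zeros((F, 0, 3)),
        flex_coords=np.asarray(flex, dtype=float),
        scores={k: np.asarray(v, dtype=float) for k, v in scores.items()},
        acceptance_rate=1.0,
    )


def flex_model(n_beads):
    res = [Residue(i + 1, "ALA", (0.0, 0.0, 0.0), 50.0) for i in range(n_beads)]
    s = Structure(id="p", chains=[Chain("A", res)])
    return xw.build_coarse_model([s], {"p": []})


class TestFilter:
    def test_degenerate_identical_scores_one_cluster(self):
        m = flex_model(2)
        F = 50
        flex = np.zeros((F, 2, 3))
        scores = {k: np.ones(F) for k in
                  ("crosslink", "connectivity", "excluded_volume", "total")}
        ens = filter_models([make_traj(0, scores, flex)],
                            AnalysisParams(equilibration_fraction=0.0), model=m)
        assert ens.n_models == F

    def test_planted_bimodal_lower_mode_selected(self, rng):
        """Two score modes 10 sigma apart: the low-crosslink mode is
        retained; classification matches a 1-D midpoint oracle."""
        m = flex_model(2)
        F = 600
        xl = np.where(np.arange(F) % 2 == 0,
                      rng.normal(10.0, 1.0, F), rng.normal(110.0, 1.0, F))
        scores = {"crosslink": xl, "connectivity": np.zeros(F),
                  "excluded_volume": np.zeros(F), "total": xl}
        flex = np.zeros((F, 2, 3))
        ens = filter_models([make_traj(0, scores, flex)],
                            AnalysisParams(equilibration_fraction=0.0), model=m)
        oracle = np.nonzero(xl < 60.0)[0]
        assert set(ens.members[:, 1]) == set(oracle)

    def test_equilibration_fraction_discards_head(self):
        m = flex_model(1)
        F = 100
        scores = {k: np.zeros(F) for k in
                  ("crosslink", "connectivity", "excluded_volume", "total")}
        ens = filter_models([make_traj(0, scores, np.zeros((F, 1, 3)))],
                            AnalysisParams(equilibration_fraction=0.2), model=m)
        assert ens.members[:, 1].min() == 20


class TestStructuralClustering:
    def test_identical_frames_single_cluster_zero_precision(self):
        m = flex_model(5)
        F = 10
        flex = np.tile(np.arange(15).reshape(1, 5, 3).astype(float), (F, 1, 1))
        scores = {k: np.zeros(F) for k in
                  ("crosslink", "connectivity", "excluded_volume", "total")}
        ens = filter_models([make_traj(0, scores, flex)],
                            AnalysisParams(equilibration_fraction=0.0), model=m)
        rep = cluster_models(ens, AnalysisParams())
        assert rep.n_clusters == 1
        assert rep.precision == pytest.approx(0.0, abs=1e-9)

    def test_pairwise_rmsd_matches_hand_formula(self):
        """Two frames, one bead displaced by d: RMSD = d / sqrt(n)."""
        from xlweaver.ensemble_analysis import _pairwise_rmsd

        n, d = 5, 6.0
        a = np.arange(15).reshape(5, 3).astype(float) * 10
        b = a.copy()
        b[2, 0] += d
        out = _pairwise_rmsd(np.stack([a, b]), np.ones(n))
        assert out[0] == pytest.approx(d / np.sqrt(n))

    def test_two_separated_conformations_two_clusters(self):
        m = flex_model(4)
        base = np.arange(12).reshape(4, 3).astype(float) * 5
        frames = [base + np.random.default_rng(i).normal(0, 0.1, (4, 3))
                  for i in range(6)]
        shifted = base.copy()
        shifted[:2] += 200.0  # internal deformation far beyond threshold
        frames += [shifted + np.random.default_rng(10 + i).normal(0, 0.1, (4, 3))
                   for i in range(4)]
        F = len(frames)
        scores = {k: np.zeros(F) for k in
                  ("crosslink", "connectivity", "excluded_volume", "total")}
        ens = filter_models([make_traj(0, scores, np.stack(frames))],
                            AnalysisParams(equilibration_fraction=0.0), model=m)
        rep = cluster_models(ens, AnalysisParams())
        assert rep.n_clusters == 2
        assert (rep.labels == rep.top_cluster).sum() == 6


class TestPrecision:
    def test_two_frames_symmetric_displacement(self):
        n = 8
        base = np.zeros((n, 3))
        d = 7.0
        a = base.copy()
        a[:, 0] -= d / 2
        b = base.copy()
        b[:, 0] += d / 2
        assert cluster_precision(np.stack([a, b])) == pytest.approx(d / 2)

    def test_homogeneity(self, rng):
        stack = rng.normal(0, 2.0, size=(20, 10, 3))
        p1 = cluster_precision(stack)
        p2 = cluster_precision(stack.mean(0) + 2.0 * (stack - stack.mean(0)))
        assert p2 == pytest.approx(2.0 * p1)

    def test_single_frame_zero(self):
        assert cluster_precision(np.zeros((1, 4, 3))) == 0.0


class TestDensity:
    def test_single_bead_normalized_gaussian(self):
        g = localized_density(np.zeros((1, 1, 3)),
                              AnalysisParams(voxel=2.0, blur_sigma=4.0))
        assert g.values.sum() == pytest.approx(1.0, abs=1e-6)
        peak = np.unravel_index(np.argmax(g.values), g.values.shape)
        center = g.origin + g.voxel * np.array(peak)
        assert np.linalg.norm(center) < g.voxel

    def test_symmetric_beads_symmetric_density(self):
        # voxel chosen commensurate with the bead spacing so the symmetric
        # pair lands on voxel centers and the truncation windows mirror
        pts = np.array([[[-10.0, 0.0, 0.0]], [[10.0, 0.0, 0.0]]])
        g = localized_density(pts, AnalysisParams(voxel=2.5, blur_sigma=5.0))
        flipped = g.values[::-1]
        assert np.abs(g.values - flipped).max() < 1e-6

    def test_split_half_identical_halves_cc_one(self, rng):
        frames = np.tile(rng.normal(0, 10, (1, 6, 3)), (8, 1, 1))
        cc = split_half_cc(frames, AnalysisParams(split_rule="random"), rng=0)
        assert cc == pytest.approx(1.0, abs=1e-9)

    def test_split_half_independent_random_cc_near_zero(self, rng):
        frames = rng.uniform(-150, 150, size=(60, 40, 3))
        cc = split_half_cc(frames, AnalysisParams(voxel=10.0, blur_sigma=5.0,
                                                  split_rule="random"), rng=1)
        assert abs(cc) < 0.1

    def test_split_half_single_frame_raises(self):
        with pytest.raises(ValueError):
            split_half_cc(np.zeros((1, 3, 3)), AnalysisParams())


class TestSatisfaction:
    def test_adjacent_residues_satisfied(self, truth4):
        st = truth4.assembly_structure()
        xl = CrosslinkSet.from_pairs([("su1", 3, "su1", 4)])
        res = static_xl_satisfaction(st, xl)
        assert res.fraction == 1.0
        assert res.distances[0] < 5.0

    def test_matches_brute_force(self, truth4, links4):
        st = truth4.assembly_structure()
        res = static_xl_satisfaction(st, links4)
        # oracle: direct distance check on the assembly coordinates
        sat = set()
        for l in links4:
            a = truth4.assembly[l.protein1][l.residue1 - 1]
            b = truth4.assembly[l.protein2][l.residue2 - 1]
            if np.linalg.norm(a - b) <= 35.0:
                sat.add(l.key)
        got = {l.key for l, s in zip(res.links, res.satisfied) if s}
        assert got == sat
        assert res.fraction == 1.0  # noise-free links in truth

    def test_cutoff_inclusive(self):
        res_a = [Residue(1, "LYS", (0.0, 0.0, 0.0), 90.0)]
        res_b = [Residue(1, "LYS", (35.0, 0.0, 0.0), 90.0)]
        st = Structure(id="ab", chains=[Chain("A", res_a), Chain("B", res_b)])
        xl = CrosslinkSet.from_pairs([("A", 1, "B", 1)])
        assert static_xl_satisfaction(st, xl).fraction == 1.0

    def test_no_mappable_links_undefined(self, truth4):
        st = truth4.assembly_structure()
        xl = CrosslinkSet.from_pairs([("zz", 1, "qq", 2)])
        res = static_xl_satisfaction(st, xl)
        assert res.fraction is None
        assert len(res.unmapped) == 1

    def test_ensemble_min_over_models(self):
        """A link at 40 A in one model and 30 A in another is satisfied."""
        m = flex_model(2)
        flex = np.array([[[0, 0, 0], [40.0, 0, 0]],
                         [[0, 0, 0], [30.0, 0, 0]]], dtype=float)
        scores = {k: np.zeros(2) for k in
                  ("crosslink", "connectivity", "excluded_volume", "total")}
        ens = filter_models([make_traj(0, scores, flex)],
                            AnalysisParams(equilibration_fraction=0.0), model=m)
        xl = CrosslinkSet.from_pairs([("p", 1, "p", 2)])
        res = ensemble_xl_satisfaction(ens, xl)
        assert res.fraction == 1.0
        assert res.distances[0] == pytest.approx(30.0)

    def test_single_model_ensemble_equals_static(self, truth4, model4, links4):
        tc = truth4.coords_for_model(model4)
        static = static_xl_satisfaction((model4, tc), links4)
        from xlweaver.geometry import kabsch

        rots, trans = [], []
        for body in model4.rigid_bodies:
            R, t = kabsch(model4.ref_coords[body], tc[body])
            rots.append(R)
            trans.append(t)
        traj = Trajectory(
            run_id=0, rotations=np.array(rots)[None],
            translations=np.array(trans)[None],
            flex_coords=tc[model4.flexible_beads][None],
            scores={k: np.zeros(1) for k in
                    ("crosslink", "connectivity", "excluded_volume", "total")},
            acceptance_rate=1.0)
        ens = Ensemble(model=model4, trajectories=[traj],
                       members=np.array([[0, 0]]),
                       scores={k: np.zeros(1) for k in
                               ("crosslink", "connectivity",
                                "excluded_volume", "total")})
        dyn = ensemble_xl_satisfaction(ens, links4)
        assert dyn.fraction == static.fraction
        assert np.allclose(np.sort(dyn.distances), np.sort(static.distances),
                           atol=1e-3)

    def test_ensemble_geq_static_every_member(self, rng):
        """min over models can only help: ensemble satisfaction >= static
        satisfaction of each member, on random ensembles (brute force)."""
        m = flex_model(6)
        F = 5
        flex = rng.uniform(-40, 40, size=(F, 6, 3))
        scores = {k: np.zeros(F) for k in
                  ("crosslink", "connectivity", "excluded_volume", "total")}
        ens = filter_models([make_traj(0, scores, flex)],
                            AnalysisParams(equilibration_fraction=0.0), model=m)
        xl = CrosslinkSet.from_pairs(
            [("p", i + 1, "p", j + 1) for i in range(6) for j in range(i + 1, 6)])
        dyn = ensemble_xl_satisfaction(ens, xl)
        # brute-force min over models
        mins = []
        for l in dyn.links:
            ds = [np.linalg.norm(flex[f, l.residue1 - 1] - flex[f, l.residue2 - 1])
                  for f in range(F)]
            mins.append(min(ds))
        assert np.allclose(np.sort(dyn.distances), np.sort(mins), atol=1e-9)
        for f in range(F):
            static = static_xl_satisfaction((m, flex[f]), xl)
            assert dyn.fraction >= static.fraction

    def test_satisfaction_rigid_motion_invariant(self, truth4, links4, rng):
        from xlweaver.geometry import random_rotation

        st = truth4.assembly_structure()
        base = static_xl_satisfaction(st, links4)
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        moved = Structure(id="truth", chains=[
            Chain(c.chain_id, [
                Residue(r.index, r.name, tuple(np.asarray(r.ca_xyz) @ R.T + t),
                        r.confidence) for r in c.residues])
            for c in st.chains])
        out = static_xl_satisfaction(moved, links4)
        assert out.fraction == base.fraction
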