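"""Monte Carlo sampling: determinism, initialization, minimizer, Metropolis."""

import numpy as np
import pytest

import xlweaver as xw
from xlweaver.geometry import rotation_angle
from xlweaver.io_formats import Chain, Residue, Structure
from xlweaver.restraints import ScoreBreakdown, Scorer
from xlweaver.sampling import (Configuration, SamplingParams,
                               initialize_random, minimize_connectivity,
                               run_mc, run_replicates)


class TestInitialization:
    def test_same_seed_identical(self, model4):
        p = SamplingParams(box_edge=160)
        a = initialize_random(model4, 42, p)
        b = initialize_random(model4, 42, p)
        assert np.array_equal(a.coords(model4), b.coords(model4))

    def test_distinct_seeds_distinct_configurations(self, model4):
        p = SamplingParams(box_edge=160)
        coords = [initialize_random(model4, s, p).coords(model4)
                  for s in range(1, 21)]
        for i in range(20):
            for j in range(i + 1, 20):
                assert not np.allclose(coords[i], coords[j])

    def test_rotations_uniform_mean_angle(self, rng):
        """Uniform random rotations have mean angle pi/2 + 2/pi."""
        from xlweaver.geometry import random_rotation

        angles = [rotation_angle(random_rotation(rng)) for _ in range(10_000)]
        expected = np.pi / 2 + 2 / np.pi
        assert np.mean(angles) == pytest.approx(expected, rel=0.02)

    def test_box_too_small_raises(self, model4):
        with pytest.raises(ValueError):
            initialize_random(model4, 0, SamplingParams(box_edge=20))


class TestMinimizer:
    def test_connected_configuration_fixed_point(self, model4, truth4):
        tc = truth4.coords_for_model(model4)
        from xlweaver.geometry import kabsch

        rots, trans = [], []
        for body in model4.rigid_bodies:
            R, t = kabsch(model4.ref_coords[body], tc[body])
            rots.append(R)
            trans.append(t)
        cfg = Configuration(np.array(rots), np.array(trans),
                            tc[model4.flexible_beads].copy())
        sc = Scorer(model4)
        out, trace = minimize_connectivity(cfg, model4, sc)
        assert trace[0] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(out.coords(model4), cfg.coords(model4), atol=1e-9)

    def test_two_beads_converge_to_contact(self):
        res = [Residue(1, "ALA", (0.0, 0.0, 0.0), 50.0),
               Residue(2, "ALA", (0.0, 0.0, 0.0), 50.0)]
        s = Structure(id="p", chains=[Chain("A", res)])
        m = xw.build_coarse_model([s], {"p": []})
        c = m.radii1[0] + m.radii1[1]
        cfg = Configuration(np.zeros((0, 3, 3)), np.zeros((0, 3)),
                            np.array([[0.0, 0.0, 0.0], [c + 50.0, 0.0, 0.0]]))
        sc = Scorer(m)
        out, trace = minimize_connectivity(
            cfg, m, sc, SamplingParams(minimizer_steps=2000, minimizer_rate=0.2))
        d = np.linalg.norm(out.flex_coords[1] - out.flex_coords[0])
        assert d <= c + 1e-2

    def test_trace_monotone_non_increasing(self, model4, links4):
        sc = Scorer(model4, links4)
        cfg = initialize_random(model4, 3, SamplingParams(box_edge=160))
        _, trace = minimize_connectivity(cfg, model4, sc)
        assert np.all(np.diff(trace) <= 1e-12)


class _ZeroScorer:
    def score(self, coords):
        return ScoreBreakdown(0.0, 0.0, 0.0, 0.0)


class TestMC:
    def test_zero_restraints_full_acceptance(self, model4):
        cfg = initialize_random(model4, 1, SamplingParams(box_edge=160))
        traj = run_mc(cfg, model4, _ZeroScorer(),
                      SamplingParams(n_frames=500, box_edge=160), run_seed=2)
        assert traj.acceptance_rate == 1.0

    def test_trajectory_length_default_frames(self, model4):
        cfg = initialize_random(model4, 1, SamplingParams(box_edge=160))
        traj = run_mc(cfg, model4, _ZeroScorer(),
                      SamplingParams(n_frames=100, box_edge=160), run_seed=2)
        assert traj.n_frames == 100
        assert traj.rotations.shape[0] == 100

    def test_harmonic_well_variance(self):
        """One bead in a 1-D harmonic well samples var = T/k (Boltzmann)."""
        st = Structure(id="p", chains=[
            Chain("A", [Residue(1, "ALA", (0.0, 0.0, 0.0), 50.0)])])
        m = xw.build_coarse_model([st], {"p": []})

        class Well:
            def score(self, coords):
                return ScoreBreakdown(0.0, 0.0, 0.0,
                                      0.5 * coords[0, 0] ** 2)

        cfg = Configuration(np.zeros((0, 3, 3)), np.zeros((0, 3)),
                            np.zeros((1, 3)))
        traj = run_mc(cfg, m, Well(),
                      SamplingParams(n_frames=30_000, bead_sigma=3.0,
                                     temperature=1.0), run_seed=42)
        x = traj.flex_coords[5000:, 0, 0]
        assert x.var() == pytest.approx(1.0, rel=0.08)

    def test_determinism(self, model4, links4):
        sc = Scorer(model4, links4)
        p = SamplingParams(n_frames=300, box_edge=160)
        cfg = initialize_random(model4, 5, p)
        a = run_mc(cfg, model4, sc, p, run_seed=9)
        b = run_mc(cfg, model4, sc, p, run_seed=9)
        assert np.array_equal(a.flex_coords, b.flex_coords)
        assert np.array_equal(a.scores["total"], b.scores["total"])

    def test_detailed_balance_two_state(self):
        """Metropolis on a double-well 1-D landscape reproduces Boltzmann
        occupancy of the two half-spaces."""
        st = Structure(id="p", chains=[
            Chain("A", [Residue(1, "ALA", (0.0, 0.0, 0.0), 50.0)])])
        m = xw.build_coarse_model([st], {"p": []})
        delta = 1.5  # energy offset of the x>0 well

        class TwoState:
            def score(self, coords):
                base = 0.5 * (abs(coords[0, 0]) - 3.0) ** 2
                off = delta if coords[0, 0] > 0 else 0.0
                return ScoreBreakdown(0.0, 0.0, 0.0, base + off)

        cfg = Configuration(np.zeros((0, 3, 3)), np.zeros((0, 3)),
                            np.array([[-3.0, 0.0, 0.0]]))
        traj = run_mc(cfg, m, TwoState(),
                      SamplingParams(n_frames=60_000, bead_sigma=3.0),
                      run_seed=11)
        x = traj.flex_coords[10_000:, 0, 0]
        frac_high = np.mean(x > 0)
        expected = np.exp(-delta) / (1 + np.exp(-delta))
        assert frac_high == pytest.approx(expected, abs=0.05)


class TestReplicates:
    def test_counts(self, model4, links4):
        sc = Scorer(model4, links4)
        p = SamplingParams(n_runs=3, n_frames=50, seed=7, box_edge=160)
        trajs = run_replicates(model4, sc, p)
        assert len(trajs) == 3
        assert sum(t.n_frames for t in trajs) == 150

    def test_single_run(self, model4, links4):
        sc = Scorer(model4, links4)
        trajs = run_replicates(model4, sc,
                               SamplingParams(n_runs=1, n_frames=20, seed=7,
                                              box_edge=160))
        assert len(trajs) == 1

    def test_order_independent_seed_derivation(self, model4, links4):
        """Run i's trajectory is identical whether computed alone or as part
        of the full replicate set."""
        sc = Scorer(model4, links4)
        p = SamplingParams(n_runs=3, n_frames=40, seed=99, box_edge=160)
        full = run_replicates(model4, sc, p)
        children = np.random.SeedSequence(99).spawn(3)
        rng = np.random.default_rng(children[2])
        cfg = xw.initialize_random(model4, rng, p)
        cfg, _ = minimize_connectivity(cfg, model4, sc, p)
        alone = run_mc(cfg, model4, sc, p, run_seed=rng, run_id=2)
        assert np.array_equal(alone.flex_coords, full[2].flex_coords)
        assert np.array_equal(alone.translations, full[2].translations)
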