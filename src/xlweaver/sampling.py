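"""Replicated Metropolis Monte Carlo over rigid-body poses and flexible beads.

A sampling campaign is: randomized initialization of every rigid body in a
cubic box, a connectivity-only steepest-descent pre-minimization so chains
start connected, then ``n_runs`` independent Monte Carlo runs of
``n_frames`` steps each (one mover chosen uniformly per step, Gaussian
proposal, Metropolis acceptance at fixed temperature with an optional
linear annealing schedule). Every step records one frame with its full
score breakdown, so the default campaign of 20 x 10,000 samples 200,000
configurations.

Everything is deterministic given (master seed, params): per-run seeds are
spawned from the master seed by index, so runs can execute in any order and
still produce identical trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import random_rotation
from .representation import CoarseModel
from .restraints import ScoreBreakdown, Scorer

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingParams",
    "Configuration",
    "Trajectory",
    "initialize_random",
    "minimize_connectivity",
    "run_mc",
    "run_replicates",
]


@dataclass
class SamplingParams:
    """Monte Carlo campaign parameters.

    ``trans_sigma``/``rot_sigma``/``bead_sigma`` are the Gaussian proposal
    scales (Å, radians, Å); defaults are tuned for 30-50% acceptance on the
    bundled synthetic benchmark. ``anneal_from`` enables a linear temperature
    ramp from that value down to ``temperature`` over a run.
    """

    n_runs: int = 20
    n_frames: int = 10_000
    seed: int = 0
    box_edge: float = 300.0
    trans_sigma: float = 3.0
    rot_sigma: float = 0.05
    bead_sigma: float = 3.0
    temperature: float = 1.0
    anneal_from: float | None = None
    minimizer_steps: int = 500
    minimizer_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_frames < 1:
            raise ValueError("n_runs and n_frames must be >= 1")
        if min(self.trans_sigma, self.rot_sigma, self.bead_sigma) <= 0:
            raise ValueError("proposal sigmas must be > 0")


@dataclass
class Configuration:
    """A single model configuration: per-body poses plus flexible beads."""

    rotations: np.ndarray     # (B, 3, 3), x = R @ x_ref + t
    translations: np.ndarray  # (B, 3)
    flex_coords: np.ndarray   # (n_flex, 3)

    def coords(self, model: CoarseModel) -> np.ndarray:
        return model.apply_poses(self.rotations, self.translations,
                                 self.flex_coords)

    def copy(self) -> "Configuration":
        return Configuration(self.rotations.copy(), self.translations.copy(),
                             self.flex_coords.copy())


@dataclass
class Trajectory:
    """All frames of one Monte Carlo run (poses, not materialized coords)."""

    run_id: int
    rotations: np.ndarray     # (F, B, 3, 3)
    translations: np.ndarray  # (F, B, 3)
    flex_coords: np.ndarray   # (F, n_flex, 3)
    scores: dict[str, np.ndarray]
    acceptance_rate: float
    n_rejected_nonfinite: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.translations)

    def configuration(self, frame: int) -> Configuration:
        return Configuration(self.rotations[frame], self.translations[frame],
                             self.flex_coords[frame])

    def coords(self, model: CoarseModel, frame: int) -> np.ndarray:
        return self.configuration(frame).coords(model)

    def bead_positions(self, model: CoarseModel, bead: int) -> np.ndarray:
        """Positions of one 1-res bead across all frames, (F, 3)."""
        b = model.bead_body[bead]
        if b >= 0:
            ref = model.ref_coords[bead]
            return np.einsum("fij,j->fi", self.rotations[:, b], ref) + \
                self.translations[:, b]
        k = int(np.nonzero(model.flexible_beads == bead)[0][0])
        return self.flex_coords[:, k]


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def initialize_random(
    model: CoarseModel, seed, params: SamplingParams | None = None
) -> Configuration:
    """Random initial configuration: each rigid body gets a uniform random
    rotation and a centroid uniform in the box; flexible beads are placed by
    a contact-distance random walk from their nearest placed chain anchor."""
    params = params or SamplingParams()
    rng = _as_rng(seed)
    half = params.box_edge / 2.0
    B = len(model.rigid_bodies)
    rotations = np.zeros((B, 3, 3))
    translations = np.zeros((B, 3))
    for b, body in enumerate(model.rigid_bodies):
        ref = model.ref_coords[body]
        diameter = 0.0
        if len(ref) > 1:
            ext = ref.max(axis=0) - ref.min(axis=0)
            diameter = float(np.linalg.norm(ext))
        if diameter > params.box_edge:
            raise ValueError(
                f"rigid body {b} (diameter {diameter:.0f} Å) does not fit in a "
                f"{params.box_edge:.0f} Å box"
            )
        R = random_rotation(rng)
        target = rng.uniform(-half, half, size=3)
        centroid = ref.mean(axis=0)
        rotations[b] = R
        translations[b] = target - R @ centroid
    coords = model.apply_poses(rotations, translations)
    placed = np.zeros(model.n_beads, dtype=bool)
    for body in model.rigid_bodies:
        placed[body] = True
    _walk_flexible(model, coords, placed, rng, half)
    return Configuration(rotations, translations,
                         coords[model.flexible_beads].copy())


def _walk_flexible(model, coords, placed, rng, half) -> None:
    """Place unplaced beads by random walk from adjacent placed beads."""
    order = np.arange(model.n_beads)
    for p in range(len(model.proteins)):
        beads = order[model.bead_protein == p]
        if not len(beads):
            continue
        if not placed[beads].any():
            coords[beads[0]] = rng.uniform(-half, half, size=3)
            placed[beads[0]] = True
        # forward then backward sweeps from placed anchors
        for sweep in (beads, beads[::-1]):
            prev = None
            for i in sweep:
                if placed[i]:
                    prev = i
                elif prev is not None:
                    step = model.radii1[i] + model.radii1[prev]
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    coords[i] = coords[prev] + step * u
                    placed[i] = True
                    prev = i


# ---------------------------------------------------------------------------
# Connectivity pre-minimization
# ---------------------------------------------------------------------------

def minimize_connectivity(
    config: Configuration,
    model: CoarseModel,
    scorer: Scorer,
    params: SamplingParams | None = None,
) -> tuple[Configuration, np.ndarray]:
    """Steepest-descent on the connectivity term only.

    Rigid bodies translate along their net connectivity force; flexible
    beads move individually. Backtracking halves the step until the score
    does not increase, so the returned trace is non-increasing; stops after
    ``minimizer_steps`` iterations or when the improvement drops below 1e-6.

    Returns the minimized configuration and the score trace.
    """
    params = params or SamplingParams()
    cfg = config.copy()
    coords = cfg.coords(model)
    start_coords = coords.copy()
    trace = [scorer.connectivity(coords)]
    for _ in range(params.minimizer_steps):
        grad = scorer.connectivity_gradient(coords)
        step_coords = np.zeros_like(coords)
        for b, body in enumerate(model.rigid_bodies):
            step_coords[body] = -grad[body].sum(axis=0) / max(len(body), 1)
        if len(model.flexible_beads):
            step_coords[model.flexible_beads] = -grad[model.flexible_beads]
        rate = params.minimizer_rate
        current = trace[-1]
        improved = False
        for _ in range(20):
            trial = coords + rate * step_coords
            s = scorer.connectivity(trial)
            if s <= current:
                coords = trial
                trace.append(s)
                improved = True
                break
            rate *= 0.5
        if not improved or (len(trace) > 1 and trace[-2] - trace[-1] < 1e-6):
            break
    # fold the coordinate updates back into poses (bodies only translated)
    for b, body in enumerate(model.rigid_bodies):
        cfg.translations[b] += coords[body[0]] - start_coords[body[0]]
    if len(model.flexible_beads):
        cfg.flex_coords = coords[model.flexible_beads].copy()
    return cfg, np.asarray(trace)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def run_mc(
    config: Configuration,
    model: CoarseModel,
    scorer,
    params: SamplingParams | None = None,
    run_seed=0,
    run_id: int = 0,
) -> Trajectory:
    """One Monte Carlo run of ``n_frames`` steps from ``config``.

    Per step one mover is chosen uniformly among the rigid bodies
    (translate + rotate about the body centroid) and the flexible beads
    (displace); the perturbation is Gaussian and accepted with probability
    ``min(1, exp(-dS/T))``. Every step records a frame. A proposal with a
    non-finite score is rejected and counted.
    """
    params = params or SamplingParams()
    rng = _as_rng(run_seed)
    B = len(model.rigid_bodies)
    nflex = len(model.flexible_beads)
    n_movers = B + nflex
    if n_movers == 0:
        raise ValueError("model has no movable parts")
    F = params.n_frames

    cur = config.copy()
    coords = cur.coords(model)
    cur_score = scorer.score(coords)

    rot_out = np.empty((F, B, 3, 3))
    trans_out = np.empty((F, B, 3))
    flex_out = np.empty((F, nflex, 3))
    score_out = {k: np.empty(F) for k in
                 ("crosslink", "excluded_volume", "connectivity", "total")}
    accepted = 0
    nonfinite = 0

    for step in range(F):
        if params.anneal_from is not None and F > 1:
            frac = step / (F - 1)
            temperature = params.anneal_from + \
                (params.temperature - params.anneal_from) * frac
        else:
            temperature = params.temperature
        mover = int(rng.integers(n_movers))
        if mover < B:
            body = model.rigid_bodies[mover]
            old_rows = coords[body].copy()
            old_R = cur.rotations[mover].copy()
            old_t = cur.translations[mover].copy()
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(0.0, params.rot_sigma)
            dt = rng.normal(0.0, params.trans_sigma, size=3)
            Rot = _axis_angle(axis, angle)
            c = old_rows.mean(axis=0)
            coords[body] = (old_rows - c) @ Rot.T + c + dt
            cur.rotations[mover] = Rot @ old_R
            cur.translations[mover] = Rot @ (old_t - c) + c + dt
        else:
            k = mover - B
            bead = model.flexible_beads[k]
            old_rows = coords[bead].copy()
            dt = rng.normal(0.0, params.bead_sigma, size=3)
            coords[bead] = old_rows + dt
            cur.flex_coords[k] = coords[bead]

        new_score = scorer.score(coords)
        delta = new_score.total - cur_score.total
        u = rng.random()
        if not np.isfinite(new_score.total):
            nonfinite += 1
            accept = False
        elif delta <= 0:
            accept = True
        else:
            accept = u < np.exp(-delta / temperature)

        if accept:
            cur_score = new_score
            accepted += 1
        else:  # revert
            if mover < B:
                coords[body] = old_rows
                cur.rotations[mover] = old_R
                cur.translations[mover] = old_t
            else:
                coords[bead] = old_rows
                cur.flex_coords[k] = old_rows

        rot_out[step] = cur.rotations
        trans_out[step] = cur.translations
        flex_out[step] = cur.flex_coords
        for key, val in cur_score.as_dict().items():
            score_out[key][step] = val

    return Trajectory(
        run_id=run_id,
        rotations=rot_out,
        translations=trans_out,
        flex_coords=flex_out,
        scores=score_out,
        acceptance_rate=accepted / F,
        n_rejected_nonfinite=nonfinite,
    )


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix from axis (unit) and angle via Rodrigues' formula."""
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def run_seed_for(master_seed: int, run_index: int) -> np.random.SeedSequence:
    """Counter-based per-run seed derivation: run i gets child i of the
    master SeedSequence, independent of execution order."""
    return np.random.SeedSequence(master_seed).spawn(run_index + 1)[run_index]


def run_replicates(
    model: CoarseModel,
    scorer,
    params: SamplingParams | None = None,
    minimize: bool = True,
) -> list[Trajectory]:
    """``n_runs`` independent runs from unique random initializations.

    Per-run seeds are spawned from ``params.seed`` by run index, so the set
    of trajectories is identical regardless of execution order; total frames
    = n_runs x n_frames.
    """
    params = params or SamplingParams()
    children = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    trajs = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cfg = initialize_random(model, rng, params)
        if minimize:
            cfg, _ = minimize_connectivity(cfg, model, scorer, params)
        trajs.append(run_mc(cfg, model, scorer, params, run_seed=rng, run_id=i))
    return trajs
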