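"""Ensemble filtering, clustering, precision, convergence and crosslink
satisfaction.

The analysis mirrors standard integrative-modeling practice: sampled frames
are first clustered in restraint-score space and the cluster that best
satisfies the crosslink data is retained; retained frames are superposed and
clustered structurally by bead RMSD; the top structural cluster yields a
centroid model, a residue-weighted RMSF cluster precision, per-subunit
localized probability densities, and a split-half density cross-correlation
as a sampling-exhaustiveness diagnostic. Crosslink satisfaction uses the
35 Å Cα-Cα convention for lysine-reactive crosslinkers (30 Å reach + 5 Å
dynamics margin), either statically for one model or as a min-over-models
ensemble statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN, KMeans

from .geometry import kabsch, rmsd as _rmsd
from .io_formats import Crosslink, CrosslinkSet, Structure
from .representation import CoarseModel
from .sampling import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "Ensemble",
    "ClusterReport",
    "SatisfactionResult",
    "filter_models",
    "cluster_models",
    "cluster_precision",
    "localized_density",
    "split_half_cc",
    "static_xl_satisfaction",
    "ensemble_xl_satisfaction",
    "analyze",
]


@dataclass
class AnalysisParams:
    """Knobs of the ensemble analysis.

    ``equilibration_fraction`` of each run is discarded before score-space
    filtering; ``max_frames`` caps the frames materialized for structural
    clustering and densities (deterministic even stride), keeping the
    analysis tractable at any campaign size.
    """

    score_cluster_method: str = "density_based"
    rmsd_threshold: float = 20.0
    voxel: float = 5.0
    blur_sigma: float = 10.0
    satisfaction_cutoff: float = 35.0
    equilibration_fraction: float = 0.2
    max_frames: int = 200
    split_rule: str = "run_parity"
    dbscan_eps: float = 0.8
    dbscan_min_samples: int = 10

    def __post_init__(self) -> None:
        if self.voxel <= 0 or self.satisfaction_cutoff <= 0:
            raise ValueError("voxel and satisfaction_cutoff must be > 0")
        if not (0 <= self.equilibration_fraction < 1):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.score_cluster_method not in ("density_based", "kmeans"):
            raise ValueError("score_cluster_method must be density_based or kmeans")
        if self.split_rule not in ("run_parity", "random"):
            raise ValueError("split_rule must be run_parity or random")


@dataclass
class Ensemble:
    """A retained set of sampled frames referencing their trajectories."""

    model: CoarseModel
    trajectories: list[Trajectory]
    members: np.ndarray              # (M, 2) of (trajectory index, frame index)
    scores: dict[str, np.ndarray]    # per-member score arrays

    @property
    def n_models(self) -> int:
        return len(self.members)

    @property
    def run_ids(self) -> np.ndarray:
        return np.array([self.trajectories[t].run_id for t, _ in self.members])

    def subsample(self, max_frames: int) -> np.ndarray:
        """Indices of an even-stride subsample of the members."""
        m = self.n_models
        if m <= max_frames:
            return np.arange(m)
        return np.unique(np.linspace(0, m - 1, max_frames).astype(int))

    def coords(self, sel: np.ndarray | None = None) -> np.ndarray:
        """Materialized bead coordinates, (len(sel), n_beads, 3)."""
        if sel is None:
            sel = np.arange(self.n_models)
        out = np.empty((len(sel), self.model.n_beads, 3))
        for k, idx in enumerate(sel):
            t, f = self.members[idx]
            out[k] = self.trajectories[t].coords(self.model, f)
        return out

    def link_min_distances(self, link_beads: np.ndarray) -> np.ndarray:
        """Per link, the minimum bead-bead distance over all members."""
        mins = np.full(len(link_beads), np.inf)
        for t, traj in enumerate(self.trajectories):
            frames = self.members[self.members[:, 0] == t, 1]
            if not len(frames):
                continue
            for li, (i, j) in enumerate(link_beads):
                pi = traj.bead_positions(self.model, i)[frames]
                pj = traj.bead_positions(self.model, j)[frames]
                d = np.sqrt(np.sum((pi - pj) ** 2, axis=1))
                mins[li] = min(mins[li], float(d.min()))
        return mins


# ---------------------------------------------------------------------------
# Score-space filtering
# ---------------------------------------------------------------------------

_FEATURES = ("crosslink", "connectivity", "excluded_volume", "total")


def filter_models(
    trajectories: list[Trajectory],
    params: AnalysisParams | None = None,
    model: CoarseModel | None = None,
) -> Ensemble:
    """Cluster post-equilibration frames in restraint-score space and retain
    the cluster with the best (lowest) mean crosslink score, ties broken by
    total score.

    Frames are embedded in the 4-D space (crosslink, connectivity, excluded
    volume, total); clustering is density-based (DBSCAN on a subsample with
    nearest-neighbour assignment of the rest) or k-means.
    """
    params = params or AnalysisParams()
    members, feats = [], []
    for t, traj in enumerate(trajectories):
        start = int(np.floor(params.equilibration_fraction * traj.n_frames))
        frames = np.arange(start, traj.n_frames)
        members.append(np.stack([np.full(len(frames), t), frames], axis=1))
        feats.append(np.stack([traj.scores[k][start:] for k in _FEATURES], axis=1))
    members = np.concatenate(members)
    X = np.concatenate(feats)
    labels = _score_cluster_labels(X, params)

    valid = labels >= 0
    if not valid.any():
        logger.warning("score clustering found no cluster; retaining all frames")
        labels = np.zeros(len(X), dtype=int)
        valid = labels >= 0
    best_label, best_key = None, None
    for lab in np.unique(labels[valid]):
        sel = labels == lab
        key = (X[sel, 0].mean(), X[sel, 3].mean())
        if best_key is None or key < best_key:
            best_label, best_key = lab, key
    keep = labels == best_label
    if model is None:
        raise ValueError("filter_models requires the coarse model")
    return Ensemble(
        model=model,
        trajectories=list(trajectories),
        members=members[keep],
        scores={k: X[keep, i] for i, k in enumerate(_FEATURES)},
    )


def _score_cluster_labels(X: np.ndarray, params: AnalysisParams) -> np.ndarray:
    std = X.std(axis=0)
    informative = std > 1e-12
    if not informative.any():
        logger.warning("degenerate score features (all identical); one cluster")
        return np.zeros(len(X), dtype=int)
    Z = (X[:, informative] - X[:, informative].mean(axis=0)) / std[informative]
    if params.score_cluster_method == "kmeans":
        return KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(Z)
    # density-based: DBSCAN on an even-stride subsample, then nearest-
    # neighbour label assignment for the remaining frames
    n_fit = min(len(Z), 4000)
    fit_idx = np.unique(np.linspace(0, len(Z) - 1, n_fit).astype(int))
    # density threshold scales with the sample so thin fringes of the score
    # distribution register as noise, not as spurious "best" clusters
    min_samples = max(params.dbscan_min_samples, len(fit_idx) // 50)
    db = DBSCAN(eps=params.dbscan_eps, min_samples=min_samples)
    fit_labels = db.fit_predict(Z[fit_idx])
    clustered = fit_idx[fit_labels >= 0]
    if not len(clustered):
        return np.zeros(len(X), dtype=int)
    tree = cKDTree(Z[clustered])
    _, nearest = tree.query(Z, k=1)
    return fit_labels[fit_labels >= 0][nearest]


# ---------------------------------------------------------------------------
# Structural clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    """Structural-cluster summary of a retained ensemble."""

    members: np.ndarray                  # (m, 2) analyzed (traj, frame) pairs
    labels: np.ndarray                   # structural cluster label per member
    top_cluster: int
    centroid_member: tuple[int, int]     # (traj index, frame index)
    centroid_coords: np.ndarray          # (n_beads, 3)
    aligned_coords: np.ndarray           # (m_top, n_beads, 3) top cluster only
    precision: float
    split_half_cc: float | None = None
    ensemble_satisfaction: float | None = None
    per_link_min_distance: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _superpose_stack(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Superpose every frame onto the first by weighted least squares."""
    out = np.empty_like(coords)
    ref = coords[0]
    for i, frame in enumerate(coords):
        R, t = kabsch(frame, ref, weights=weights)
        out[i] = frame @ R.T + t
    return out


def _pairwise_rmsd(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Condensed pairwise weighted RMSD over superposed frames."""
    m = len(coords)
    w = weights / weights.sum()
    flat = coords.reshape(m, -1)
    out = np.empty(m * (m - 1) // 2)
    k = 0
    for i in range(m - 1):
        diff = flat[i + 1:] - flat[i]
        d2 = (diff.reshape(m - i - 1, -1, 3) ** 2).sum(axis=2)
        out[k:k + m - i - 1] = np.sqrt(d2 @ w)
        k += m - i - 1
    return out


def cluster_models(
    ensemble: Ensemble, params: AnalysisParams | None = None
) -> ClusterReport:
    """Superpose an (even-stride subsample of the) ensemble, group frames by
    single-linkage pairwise bead RMSD at ``rmsd_threshold``, and summarize
    the largest cluster: centroid frame (minimum summed RMSD to members) and
    residue-weighted RMSF precision.
    """
    params = params or AnalysisParams()
    if ensemble.n_models < 1:
        raise ValueError("empty ensemble")
    weights = ensemble.model.residue_weights()
    sel = ensemble.subsample(params.max_frames)
    coords = ensemble.coords(sel)
    aligned = _superpose_stack(coords, weights)
    m = len(aligned)
    if m == 1:
        return ClusterReport(
            members=ensemble.members[sel], labels=np.zeros(1, dtype=int),
            top_cluster=0, centroid_member=tuple(ensemble.members[sel][0]),
            centroid_coords=aligned[0], aligned_coords=aligned, precision=0.0,
        )
    condensed = _pairwise_rmsd(aligned, weights)
    if np.all(condensed <= params.rmsd_threshold):
        labels = np.zeros(m, dtype=int)
    else:
        labels = fcluster(linkage(condensed, method="single"),
                          t=params.rmsd_threshold, criterion="distance") - 1
    uniq, counts = np.unique(labels, return_counts=True)
    top = int(uniq[np.argmax(counts)])
    in_top = np.nonzero(labels == top)[0]
    # centroid: member of the top cluster minimizing summed RMSD to the rest
    from scipy.spatial.distance import squareform
    D = squareform(condensed)
    centroid_local = in_top[np.argmin(D[np.ix_(in_top, in_top)].sum(axis=1))]
    top_aligned = _superpose_stack(aligned[in_top], weights)
    return ClusterReport(
        members=ensemble.members[sel],
        labels=labels,
        top_cluster=top,
        centroid_member=tuple(ensemble.members[sel][centroid_local]),
        centroid_coords=aligned[centroid_local],
        aligned_coords=top_aligned,
        precision=cluster_precision(top_aligned, weights),
    )


def cluster_precision(
    aligned_coords: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Residue-weighted root-mean-square fluctuation (Å) of bead positions
    about their cluster-mean positions, over a superposed frame stack."""
    aligned = np.asarray(aligned_coords)
    if aligned.ndim != 3:
        raise ValueError("expected a (frames, beads, 3) stack")
    if len(aligned) < 2:
        return 0.0
    if weights is None:
        weights = np.ones(aligned.shape[1])
    mean = aligned.mean(axis=0)
    msf = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # per-bead MSF
    return float(np.sqrt((weights * msf).sum() / weights.sum()))


# ---------------------------------------------------------------------------
# Localized densities and split-half convergence
# ---------------------------------------------------------------------------

def _make_grid(points: np.ndarray, voxel: float, pad: float):
    """Grid centered on the points' bounding box, padded by ``pad``."""
    lo = points.reshape(-1, 3).min(axis=0) - pad
    hi = points.reshape(-1, 3).max(axis=0) + pad
    center = 0.5 * (lo + hi)
    n = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 1)
    origin = center - (n - 1) / 2.0 * voxel
    return origin, n


def _deposit(
    points: np.ndarray, masses: np.ndarray, origin: np.ndarray,
    shape: np.ndarray, voxel: float, sigma: float,
) -> np.ndarray:
    """Sum of truncated (3σ) Gaussians on the grid."""
    values = np.zeros(tuple(shape))
    r = max(int(np.ceil(3.0 * sigma / voxel)), 1)
    offsets = np.arange(-r, r + 1)
    for p, mass in zip(points, masses):
        nearest = np.round((p - origin) / voxel).astype(int)
        idx = [nearest[a] + offsets for a in range(3)]
        keep = [(ix >= 0) & (ix < shape[a]) for a, ix in enumerate(idx)]
        if not all(k.any() for k in keep):
            continue
        axes = []
        for a in range(3):
            x = origin[a] + idx[a][keep[a]] * voxel
            axes.append(np.exp(-((x - p[a]) ** 2) / (2 * sigma * sigma)))
        kern = mass * axes[0][:, None, None] * axes[1][None, :, None] * \
            axes[2][None, None, :]
        values[np.ix_(idx[0][keep[0]], idx[1][keep[1]], idx[2][keep[2]])] += kern
    return values


def localized_density(
    aligned_coords: np.ndarray,
    params: AnalysisParams | None = None,
    bead_sel: np.ndarray | None = None,
    masses: np.ndarray | None = None,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Occupancy density of (a subunit's) beads across a superposed ensemble.

    Each bead deposits a Gaussian of width ``blur_sigma`` and mass equal to
    its residue count, per frame; the grid is normalized to unit sum.
    Returns a :class:`~xlweaver.map_fit.DensityGrid`.
    """
    from .map_fit import DensityGrid

    params = params or AnalysisParams()
    aligned = np.asarray(aligned_coords)
    if aligned.ndim == 2:
        aligned = aligned[None]
    if bead_sel is not None:
        aligned = aligned[:, bead_sel]
        if masses is not None:
            masses = masses[bead_sel]
    pts = aligned.reshape(-1, 3)
    if masses is None:
        mass_flat = np.ones(len(pts))
    else:
        mass_flat = np.tile(np.asarray(masses, dtype=float), len(aligned))
    if grid is None:
        origin, shape = _make_grid(pts, params.voxel, 3.0 * params.blur_sigma)
    else:
        origin, shape = grid
    values = _deposit(pts, mass_flat, origin, shape, params.voxel,
                      params.blur_sigma)
    total = values.sum()
    if total > 0:
        values /= total
    return DensityGrid(origin=np.asarray(origin, dtype=float),
                       voxel=params.voxel, values=values)


def split_half_cc(
    report_or_coords,
    params: AnalysisParams | None = None,
    run_ids: np.ndarray | None = None,
    rng=None,
) -> float:
    """Sampling-exhaustiveness diagnostic: split the top cluster in half,
    compute the whole-complex density of each half on a shared grid, and
    return the Pearson correlation over voxels supported by either half.

    The split is by run parity (default) or random halves; accepts either a
    :class:`ClusterReport` or a raw aligned coordinate stack.
    """
    params = params or AnalysisParams()
    if isinstance(report_or_coords, ClusterReport):
        coords = report_or_coords.aligned_coords
        if run_ids is None:
            members = report_or_coords.members[
                report_or_coords.labels == report_or_coords.top_cluster]
            run_ids = members[:, 0]
    else:
        coords = np.asarray(report_or_coords)
    m = len(coords)
    if m < 2:
        raise ValueError("need at least 2 frames to split")
    if params.split_rule == "run_parity" and run_ids is not None:
        mask = (np.asarray(run_ids) % 2) == 0
        if not mask.any() or mask.all():
            logger.warning("run-parity split degenerate; falling back to "
                           "alternating frames")
            mask = (np.arange(m) % 2) == 0
    elif params.split_rule == "random":
        rng = np.random.default_rng(rng)
        mask = np.zeros(m, dtype=bool)
        mask[rng.permutation(m)[: m // 2]] = True
    else:
        mask = (np.arange(m) % 2) == 0
    half_a, half_b = coords[mask], coords[~mask]
    if not len(half_a) or not len(half_b):
        raise ValueError("one half of the split is empty")
    grid = _make_grid(coords.reshape(-1, 3), params.voxel,
                      3.0 * params.blur_sigma)
    da = localized_density(half_a, params, grid=grid)
    db = localized_density(half_b, params, grid=grid)
    a, b = da.values.ravel(), db.values.ravel()
    support = (a > 0) | (b > 0)
    a, b = a[support], b[support]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Crosslink satisfaction
# ---------------------------------------------------------------------------

@dataclass
class SatisfactionResult:
    """Crosslink satisfaction against one model or an ensemble.

    ``fraction`` is None (undefined, not zero) when no link is mappable.
    Distances are Cα-Cα (static) or min-over-models (ensemble)."""

    fraction: float | None
    distances: np.ndarray
    satisfied: np.ndarray
    links: list[Crosslink]
    unmapped: list[Crosslink] = field(default_factory=list)
    per_protein: dict[str, list[float]] = field(default_factory=dict)
    cutoff: float = 35.0

    @property
    def violated_links(self) -> list[Crosslink]:
        return [l for l, s in zip(self.links, self.satisfied) if not s]


def _residue_lookup(target) -> dict[tuple[str, int], np.ndarray]:
    """(protein, residue) -> coordinate for a Structure or (model, coords)."""
    if isinstance(target, Structure):
        from .representation import protein_names

        table = {}
        for name, chain in zip(protein_names(target), target.chains):
            for res, xyz in zip(chain.indices, chain.ca_array):
                table[(name, int(res))] = xyz
        return table
    model, coords = target
    return {
        (model.proteins[p], int(r)): coords[i]
        for i, (p, r) in enumerate(zip(model.bead_protein, model.bead_resindex))
    }


def static_xl_satisfaction(
    target, crosslinks: CrosslinkSet, cutoff: float | None = None
) -> SatisfactionResult:
    """Fraction of mappable crosslinks with Cα-Cα distance <= cutoff
    (inclusive; default the set's 35 Å satisfaction convention) in a single
    structure or (model, coords) pair. Per-protein distance lists support
    violin-style summaries."""
    cutoff = crosslinks.cutoff_satisfaction if cutoff is None else cutoff
    table = _residue_lookup(target)
    links, dists, unmapped = [], [], []
    per_protein: dict[str, list[float]] = {}
    for link in crosslinks:
        a = table.get((link.protein1, link.residue1))
        b = table.get((link.protein2, link.residue2))
        if a is None or b is None:
            unmapped.append(link)
            continue
        d = float(np.linalg.norm(a - b))
        links.append(link)
        dists.append(d)
        per_protein.setdefault(link.protein1, []).append(d)
        if link.protein2 != link.protein1:
            per_protein.setdefault(link.protein2, []).append(d)
    dists = np.asarray(dists)
    satisfied = dists <= cutoff if len(dists) else np.zeros(0, dtype=bool)
    fraction = float(satisfied.mean()) if len(dists) else None
    if fraction is None:
        logger.warning("no mappable crosslinks; satisfaction undefined")
    return SatisfactionResult(
        fraction=fraction, distances=dists, satisfied=satisfied, links=links,
        unmapped=unmapped, per_protein=per_protein, cutoff=cutoff,
    )


def ensemble_xl_satisfaction(
    ensemble: Ensemble, crosslinks: CrosslinkSet, cutoff: float | None = None
) -> SatisfactionResult:
    """Ensemble crosslink satisfaction: a link is satisfied if its bead-bead
    distance is within the cutoff in at least one model of the ensemble."""
    cutoff = crosslinks.cutoff_satisfaction if cutoff is None else cutoff
    model = ensemble.model
    links, pairs, unmapped = [], [], []
    for link in crosslinks:
        try:
            i = model.bead_index(link.protein1, link.residue1)
            j = model.bead_index(link.protein2, link.residue2)
        except KeyError:
            unmapped.append(link)
            continue
        links.append(link)
        pairs.append((i, j))
    if not pairs:
        logger.warning("no mappable crosslinks; satisfaction undefined")
        return SatisfactionResult(
            fraction=None, distances=np.zeros(0),
            satisfied=np.zeros(0, dtype=bool), links=[], unmapped=unmapped,
            cutoff=cutoff,
        )
    mins = ensemble.link_min_distances(np.asarray(pairs, dtype=int))
    satisfied = mins <= cutoff
    per_protein: dict[str, list[float]] = {}
    for link, d in zip(links, mins):
        per_protein.setdefault(link.protein1, []).append(float(d))
        if link.protein2 != link.protein1:
            per_protein.setdefault(link.protein2, []).append(float(d))
    return SatisfactionResult(
        fraction=float(satisfied.mean()), distances=mins, satisfied=satisfied,
        links=links, unmapped=unmapped, per_protein=per_protein, cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------

def analyze(
    trajectories: list[Trajectory],
    model: CoarseModel,
    crosslinks: CrosslinkSet | None = None,
    params: AnalysisParams | None = None,
) -> ClusterReport:
    """Filter, cluster, and validate a sampling campaign in one call."""
    params = params or AnalysisParams()
    ensemble = filter_models(trajectories, params, model=model)
    report = cluster_models(ensemble, params)
    report.split_half_cc = split_half_cc(report, params)
    if crosslinks is not None:
        sat = ensemble_xl_satisfaction(ensemble, crosslinks,
                                       params.satisfaction_cutoff)
        report.ensemble_satisfaction = sat.fraction
        report.per_link_min_distance = sat.distances
    return report
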