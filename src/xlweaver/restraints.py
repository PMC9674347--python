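"""Restraint scoring for coarse-model configurations.

Three terms, each a one-sided (upper-bound) harmonic so a "perfect"
configuration scores exactly zero:

* crosslink — per link, the distance d between the two 1-residue beads
  contributes ``0.5 * xl_k * max(0, d - xl_length)**2`` with the 21 Å
  restraint length convention for lysine-reactive MS-cleavable crosslinkers;
* excluded volume — over all 10-residue bead pairs not in the same rigid
  body, the overlap ``o = max(0, r_i + r_j - d)`` contributes
  ``0.5 * ev_k * o**2``;
* connectivity — consecutive beads of one protein that do not share a rigid
  body are held within contact distance ``conn_slack * (r_i + r_j)`` by the
  same one-sided harmonic.

The total is a weighted sum and is invariant under a global rigid motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CrosslinkSet
from .representation import CoarseModel

logger = logging.getLogger(__name__)

__all__ = [
    "RestraintParams",
    "ScoreBreakdown",
    "Scorer",
    "crosslink_score",
    "excluded_volume_score",
    "connectivity_score",
    "total_score",
]


@dataclass
class RestraintParams:
    """Force constants (per Å²) and length conventions of the three terms."""

    xl_length: float = 21.0
    xl_k: float = 1.0
    ev_k: float = 1.0
    ev_min_seq_sep: int = 20
    conn_k: float = 1.0
    conn_slack: float = 1.0
    weights: dict[str, float] = field(
        default_factory=lambda: {"crosslink": 1.0, "excluded_volume": 1.0,
                                 "connectivity": 1.0}
    )

    def __post_init__(self) -> None:
        for name, v in (("xl_length", self.xl_length), ("xl_k", self.xl_k),
                        ("ev_k", self.ev_k), ("conn_k", self.conn_k),
                        ("conn_slack", self.conn_slack)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ScoreBreakdown:
    """Weighted restraint terms for one configuration; total is their sum."""

    crosslink: float
    excluded_volume: float
    connectivity: float
    total: float
    per_link_distance: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "crosslink": self.crosslink,
            "excluded_volume": self.excluded_volume,
            "connectivity": self.connectivity,
            "total": self.total,
        }


def _upper_harmonic(d: np.ndarray, bound: np.ndarray | float, k: float) -> float:
    excess = np.maximum(0.0, d - bound)
    return float(0.5 * k * np.sum(excess * excess))


class Scorer:
    """Composite restraint score bound to a coarse model and a crosslink set.

    Link endpoints that cannot be mapped to model beads are excluded from
    scoring and listed in :attr:`excluded_links` (never silently dropped).
    """

    def __init__(
        self,
        model: CoarseModel,
        crosslinks: CrosslinkSet | None = None,
        params: RestraintParams | None = None,
    ):
        self.model = model
        self.params = params or RestraintParams()
        self.crosslinks = crosslinks
        self.excluded_links: list = []
        pairs = []
        if crosslinks is not None:
            for link in crosslinks:
                try:
                    i = model.bead_index(link.protein1, link.residue1)
                    j = model.bead_index(link.protein2, link.residue2)
                except KeyError:
                    self.excluded_links.append(link)
                    continue
                pairs.append((i, j))
            if self.excluded_links:
                logger.warning(
                    "%d crosslinks could not be mapped to model beads and are "
                    "excluded from scoring", len(self.excluded_links),
                )
        self.link_beads = (np.array(pairs, dtype=int) if pairs
                           else np.zeros((0, 2), dtype=int))
        # excluded-volume pair list: all 10-res bead pairs not sharing a
        # rigid body; bead pairs close in sequence on the same chain are
        # also excluded (their proximity is forced by the covalent chain at
        # segment boundaries, not a clash — the usual polymer convention)
        K = model.n_ev_beads
        ii, jj = np.triu_indices(K, k=1)
        body = model.ev_body
        keep = ~((body[ii] >= 0) & (body[ii] == body[jj]))
        same_chain = model.ev_protein[ii] == model.ev_protein[jj]
        seq_gap = np.maximum(model.ev_res_lo[jj] - model.ev_res_hi[ii],
                             model.ev_res_lo[ii] - model.ev_res_hi[jj])
        keep &= ~(same_chain & (seq_gap <= self.params.ev_min_seq_sep))
        self.ev_pairs = np.stack([ii[keep], jj[keep]], axis=1)
        self.ev_bounds = model.ev_radii[self.ev_pairs[:, 0]] + \
            model.ev_radii[self.ev_pairs[:, 1]]
        # connectivity pair list: consecutive beads not sharing a rigid body
        cp = model.chain_pairs
        if len(cp):
            bb = model.bead_body
            keep = ~((bb[cp[:, 0]] >= 0) & (bb[cp[:, 0]] == bb[cp[:, 1]]))
            self.conn_pairs = cp[keep]
        else:
            self.conn_pairs = cp
        self.conn_bounds = self.params.conn_slack * (
            model.radii1[self.conn_pairs[:, 0]] + model.radii1[self.conn_pairs[:, 1]]
        ) if len(self.conn_pairs) else np.zeros(0)

    # -- individual terms ---------------------------------------------------

    def link_distances(self, coords: np.ndarray) -> np.ndarray:
        if not len(self.link_beads):
            return np.zeros(0)
        delta = coords[self.link_beads[:, 0]] - coords[self.link_beads[:, 1]]
        return np.sqrt(np.sum(delta * delta, axis=1))

    def crosslink(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.link_distances(coords)
        return _upper_harmonic(d, self.params.xl_length, self.params.xl_k), d

    def excluded_volume(self, coords: np.ndarray) -> float:
        if not len(self.ev_pairs):
            return 0.0
        centers = self.model.ev_centers(coords)
        delta = centers[self.ev_pairs[:, 0]] - centers[self.ev_pairs[:, 1]]
        d = np.sqrt(np.sum(delta * delta, axis=1))
        overlap = np.maximum(0.0, self.ev_bounds - d)
        return float(0.5 * self.params.ev_k * np.sum(overlap * overlap))

    def connectivity(self, coords: np.ndarray) -> float:
        if not len(self.conn_pairs):
            return 0.0
        delta = coords[self.conn_pairs[:, 0]] - coords[self.conn_pairs[:, 1]]
        d = np.sqrt(np.sum(delta * delta, axis=1))
        return _upper_harmonic(d, self.conn_bounds, self.params.conn_k)

    def connectivity_gradient(self, coords: np.ndarray) -> np.ndarray:
        """dS_conn/dx per bead (used by the pre-sampling minimizer)."""
        grad = np.zeros_like(coords)
        if not len(self.conn_pairs):
            return grad
        i, j = self.conn_pairs[:, 0], self.conn_pairs[:, 1]
        delta = coords[i] - coords[j]
        d = np.sqrt(np.sum(delta * delta, axis=1))
        excess = np.maximum(0.0, d - self.conn_bounds)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(d[:, None] > 0, delta / np.maximum(d, 1e-12)[:, None], 0.0)
        f = (self.params.conn_k * excess)[:, None] * unit
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)
        return grad

    # -- composite ----------------------------------------------------------

    def score(self, coords: np.ndarray) -> ScoreBreakdown:
        w = self.params.weights
        xl_raw, d = self.crosslink(coords)
        xl = w.get("crosslink", 1.0) * xl_raw
        ev = w.get("excluded_volume", 1.0) * self.excluded_volume(coords)
        conn = w.get("connectivity", 1.0) * self.connectivity(coords)
        return ScoreBreakdown(
            crosslink=xl, excluded_volume=ev, connectivity=conn,
            total=xl + ev + conn, per_link_distance=d,
        )


# -- thin functional wrappers ------------------------------------------------

def crosslink_score(
    model: CoarseModel, coords: np.ndarray, crosslinks: CrosslinkSet,
    params: RestraintParams | None = None,
) -> tuple[float, np.ndarray]:
    """Crosslink restraint score and per-link distances (unweighted)."""
    return Scorer(model, crosslinks, params).crosslink(coords)


def excluded_volume_score(
    model: CoarseModel, coords: np.ndarray, params: RestraintParams | None = None
) -> float:
    return Scorer(model, None, params).excluded_volume(coords)


def connectivity_score(
    model: CoarseModel, coords: np.ndarray, params: RestraintParams | None = None
) -> float:
    return Scorer(model, None, params).connectivity(coords)


def total_score(
    model: CoarseModel, coords: np.ndarray, crosslinks: CrosslinkSet,
    params: RestraintParams | None = None,
) -> ScoreBreakdown:
    return Scorer(model, crosslinks, params).score(coords)
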