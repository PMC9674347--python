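"""Multi-resolution coarse-grained representation of predicted structures.

Converts Cα traces with per-residue confidence (pLDDT) and predicted-
aligned-error (PAE) matrices into the bead model that sampling operates on:

* a 1-residue bead layer (bead center = Cα) used for crosslink distances
  and chain connectivity,
* a 10-residue bead layer (bead center = centroid of its residues) used for
  soft excluded volume,
* rigid bodies (confident segments, optionally merged across an interface
  using a pairwise-prediction model) and flexible beads (everything else).

Bead radii come from a single average residue volume of 130 Å³ via
r = (3 V / 4 π)^(1/3); the radii only feed soft excluded volume, so a
per-residue-type volume table is deliberately not used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import kabsch
from .io_formats import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "RESIDUE_VOLUME",
    "SegmentationParams",
    "InterfaceParams",
    "InterfacePatch",
    "CoarseModel",
    "protein_names",
    "segment_rigid_bodies",
    "detect_interfaces",
    "build_coarse_model",
]

#: Average residue volume (Å³) used for all bead radii.
RESIDUE_VOLUME = 130.0


def bead_radius(n_residues: int | np.ndarray) -> np.ndarray:
    """Radius of a sphere holding ``n_residues`` x 130 Å³."""
    return (3.0 * np.asarray(n_residues) * RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class SegmentationParams:
    """Controls splitting a confidence trace into rigid segments.

    The pLDDT trace is smoothed by a centered moving average before
    thresholding so single-residue dips do not break a body; a window of 1
    disables smoothing. ``manual_breaks`` force a boundary immediately before
    the named residue regardless of confidence.
    """

    plddt_threshold: float = 70.0
    smoothing_window: int = 5
    min_segment: int = 10
    manual_breaks: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


@dataclass
class InterfaceParams:
    """Controls PAE-based interface detection.

    A residue pair qualifies when its combined PAE (asymmetry resolved by
    ``asymmetry_rule`` over PAE(i,j) and PAE(j,i)) is strictly below
    ``pae_threshold`` Å; connected patches smaller than ``min_patch`` pairs
    are discarded.
    """

    pae_threshold: float = 3.5
    min_patch: int = 10
    asymmetry_rule: str = "min"

    def __post_init__(self) -> None:
        if self.pae_threshold <= 0:
            raise ValueError("pae_threshold must be > 0")
        if self.asymmetry_rule not in ("min", "mean", "max"):
            raise ValueError("asymmetry_rule must be one of min/mean/max")


@dataclass
class InterfacePatch:
    """A contiguous block of low-PAE residue pairs between two proteins."""

    protein_a: str
    protein_b: str
    pairs: list[tuple[int, int]]          # (residue index on a, on b)
    range_a: tuple[int, int]
    range_b: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.pairs)


def protein_names(structure: Structure) -> list[str]:
    """Protein name for each chain of a structure.

    Single-chain files are named after the file (structure id); chains of a
    multi-chain file (e.g. an assembled complex) are named by their chain id.
    """
    if len(structure.chains) == 1:
        return [structure.id]
    return [c.chain_id for c in structure.chains]


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _smooth(conf: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return conf
    return ndimage.uniform_filter1d(conf, size=window, mode="nearest")


def segment_rigid_bodies(
    structure: Structure, params: SegmentationParams | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Split each chain into rigid residue ranges of high confidence.

    Returns, per protein, ordered disjoint (first, last) residue-index
    ranges, each at least ``min_segment`` residues long; residues in no range
    are flexible. A chain shorter than ``min_segment`` yields no ranges (all
    flexible) with a warning.
    """
    params = params or SegmentationParams()
    out: dict[str, list[tuple[int, int]]] = {}
    names = protein_names(structure)
    breaks = set(params.manual_breaks)
    for name, chain in zip(names, structure.chains):
        idx = chain.indices
        if len(idx) < params.min_segment:
            logger.warning(
                "chain %s has %d residues (< min_segment=%d); all flexible",
                name, len(idx), params.min_segment,
            )
            out[name] = []
            continue
        conf = _smooth(chain.confidence_array, params.smoothing_window)
        confident = conf > params.plddt_threshold
        ranges: list[tuple[int, int]] = []
        start: int | None = None
        for pos in range(len(idx)):
            forced = (name, int(idx[pos])) in breaks
            if confident[pos] and start is None:
                start = pos
            elif start is not None and (not confident[pos] or forced):
                ranges.append((int(idx[start]), int(idx[pos - 1])))
                start = pos if (confident[pos] and forced) else None
        if start is not None:
            ranges.append((int(idx[start]), int(idx[-1])))
        ranges = [
            r for r in ranges if r[1] - r[0] + 1 >= params.min_segment
        ]
        out[name] = ranges
    return out


# ---------------------------------------------------------------------------
# Interface detection
# ---------------------------------------------------------------------------

_COMBINE = {
    "min": np.minimum,
    "max": np.maximum,
    "mean": lambda a, b: 0.5 * (a + b),
}


def detect_interfaces(pae, params: InterfaceParams | None = None) -> list[InterfacePatch]:
    """Find inter-protein interface patches in a PAE matrix.

    For every residue pair (i on protein A, j on protein B) the two
    asymmetric entries PAE(i,j) and PAE(j,i) are combined per
    ``asymmetry_rule``; pairs strictly below ``pae_threshold`` are grouped
    into 8-connected patches, and patches with fewer than ``min_patch`` pairs
    are discarded. Patches are returned largest first.
    """
    params = params or InterfaceParams()
    prots = pae.proteins
    if len(prots) < 2:
        logger.warning("PAE matrix covers a single protein; no inter-protein block")
        return []
    combine = _COMBINE[params.asymmetry_rule]
    patches: list[InterfacePatch] = []
    for ia in range(len(prots)):
        for ib in range(ia + 1, len(prots)):
            pa, pb = prots[ia], prots[ib]
            rows = pae.block_indices(pa)
            cols = pae.block_indices(pb)
            block = combine(pae.values[np.ix_(rows, cols)],
                            pae.values[np.ix_(cols, rows)].T)
            mask = block < params.pae_threshold
            if not mask.any():
                continue
            labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
            res_a = np.array([pae.labels[i][1] for i in rows])
            res_b = np.array([pae.labels[j][1] for j in cols])
            for k in range(1, n + 1):
                ii, jj = np.nonzero(labels == k)
                if len(ii) < params.min_patch:
                    continue
                ra = res_a[ii]
                rb = res_b[jj]
                patches.append(
                    InterfacePatch(
                        protein_a=pa,
                        protein_b=pb,
                        pairs=[(int(a), int(b)) for a, b in zip(ra, rb)],
                        range_a=(int(ra.min()), int(ra.max())),
                        range_b=(int(rb.min()), int(rb.max())),
                    )
                )
    patches.sort(key=lambda p: p.size, reverse=True)
    return patches


# ---------------------------------------------------------------------------
# Coarse model
# ---------------------------------------------------------------------------

@dataclass
class CoarseModel:
    """The two-layer bead model sampling operates on.

    Beads are stored protein by protein in residue order. ``ref_coords`` are
    the reference 1-residue bead centers; a configuration is produced by
    applying a pose (proper rotation + translation) to each rigid body and
    independent coordinates to each flexible bead. 10-residue excluded-volume
    bead centers are always derived from the current 1-residue coordinates,
    so rigid-body internal geometry is preserved exactly under any pose.
    """

    proteins: list[str]
    bead_protein: np.ndarray      # (N,) protein index per 1-res bead
    bead_resindex: np.ndarray     # (N,) residue index per 1-res bead
    ref_coords: np.ndarray        # (N, 3)
    confidence: np.ndarray        # (N,)
    radii1: np.ndarray            # (N,) 1-res bead radii
    rigid_bodies: list[np.ndarray]
    flexible_beads: np.ndarray
    bead_body: np.ndarray         # (N,) body index, -1 for flexible
    ev_starts: np.ndarray         # (K,) start offsets of 10-res beads
    ev_sizes: np.ndarray          # (K,) residue counts
    ev_radii: np.ndarray          # (K,)
    ev_body: np.ndarray           # (K,) body index, -1 if flexible
    ev_protein: np.ndarray        # (K,)
    ev_res_lo: np.ndarray         # (K,) first residue index covered
    ev_res_hi: np.ndarray         # (K,) last residue index covered
    chain_pairs: np.ndarray       # (P, 2) consecutive 1-res bead pairs
    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    _index: dict | None = None

    @property
    def n_beads(self) -> int:
        return len(self.ref_coords)

    @property
    def n_ev_beads(self) -> int:
        return len(self.ev_starts)

    def bead_index(self, protein: str, resindex: int) -> int:
        """1-res bead index for (protein, residue); KeyError if absent."""
        if self._index is None:
            self._index = {
                (self.proteins[p], int(r)): i
                for i, (p, r) in enumerate(zip(self.bead_protein, self.bead_resindex))
            }
        return self._index[(protein, int(resindex))]

    def apply_poses(
        self,
        rotations: np.ndarray,
        translations: np.ndarray,
        flex_coords: np.ndarray | None = None,
    ) -> np.ndarray:
        """Coordinates for given per-body poses (x = R @ x_ref + t) and
        flexible-bead positions (reference positions if omitted)."""
        coords = self.ref_coords.copy()
        for b, body in enumerate(self.rigid_bodies):
            coords[body] = self.ref_coords[body] @ rotations[b].T + translations[b]
        if flex_coords is not None and len(self.flexible_beads):
            coords[self.flexible_beads] = flex_coords
        return coords

    def ev_centers(self, coords: np.ndarray) -> np.ndarray:
        """Centers of the 10-residue beads for the given 1-res coordinates."""
        sums = np.add.reduceat(coords, self.ev_starts, axis=0)
        return sums / self.ev_sizes[:, None]

    def protein_beads(self, protein: str) -> np.ndarray:
        p = self.proteins.index(protein)
        return np.nonzero(self.bead_protein == p)[0]

    def residue_weights(self) -> np.ndarray:
        """Per-1-res-bead residue counts (all ones; kept explicit because
        precision and superposition are defined residue-weighted)."""
        return np.ones(self.n_beads)


def _find_segment(
    segments: list[tuple[int, int]], residues: np.ndarray
) -> int | None:
    """Segment index containing the majority of the given residues."""
    best, best_n = None, 0
    for si, (lo, hi) in enumerate(segments):
        n = int(np.sum((residues >= lo) & (residues <= hi)))
        if n > best_n:
            best, best_n = si, n
    return best


def build_coarse_model(
    structures: list[Structure],
    segments: dict[str, list[tuple[int, int]]],
    interfaces: list[InterfacePatch] | None = None,
    pair_models: dict[tuple[str, str], Structure] | None = None,
    ev_bead_size: int = 10,
) -> CoarseModel:
    """Assemble the coarse model from per-protein structures and segments.

    Each segment becomes a rigid body; segments of two proteins joined by an
    interface patch (largest patch first) are merged into one rigid body
    using the pairwise model's relative orientation; remaining residues
    become flexible beads. Conflicting placements of the same segment by two
    incompatible pair models raise a ValueError naming the conflict.
    """
    # --- 1-residue bead layer ------------------------------------------------
    prot_names: list[str] = []
    prot_chain: list = []
    for s in structures:
        for name, chain in zip(protein_names(s), s.chains):
            if name in prot_names:
                raise ValueError(f"duplicate protein name {name!r}")
            prot_names.append(name)
            prot_chain.append(chain)

    bead_protein, bead_resindex, coords, confs = [], [], [], []
    for p, chain in enumerate(prot_chain):
        bead_protein.append(np.full(len(chain), p))
        bead_resindex.append(chain.indices)
        coords.append(chain.ca_array)
        confs.append(chain.confidence_array)
    bead_protein = np.concatenate(bead_protein)
    bead_resindex = np.concatenate(bead_resindex)
    ref_coords = np.concatenate(coords).astype(float)
    confidence = np.concatenate(confs)
    n = len(ref_coords)
    radii1 = np.full(n, float(bead_radius(1)))

    # --- rigid bodies from segments -----------------------------------------
    bead_body = np.full(n, -1, dtype=int)
    bodies: list[list[int]] = []
    seg_of_body: list[tuple[str, tuple[int, int]]] = []
    for p, name in enumerate(prot_names):
        sel = bead_protein == p
        resi = bead_resindex[sel]
        offsets = np.nonzero(sel)[0]
        for lo, hi in segments.get(name, []):
            members = offsets[(resi >= lo) & (resi <= hi)]
            if len(members) == 0:
                continue
            bead_body[members] = len(bodies)
            bodies.append(list(members))
            seg_of_body.append((name, (lo, hi)))

    # --- interface merging ---------------------------------------------------
    if interfaces:
        _merge_interfaces(
            interfaces, pair_models or {}, prot_names, prot_chain,
            segments, bead_body, bodies, ref_coords, bead_protein, bead_resindex,
        )

    # compact body numbering (merging empties some body slots)
    rigid_bodies = [np.array(b, dtype=int) for b in bodies if len(b)]
    bead_body = np.full(n, -1, dtype=int)
    for bi, body in enumerate(rigid_bodies):
        bead_body[body] = bi
    flexible_beads = np.nonzero(bead_body < 0)[0]

    # --- 10-residue excluded-volume layer ------------------------------------
    # chunked within maximal runs of constant body assignment, so every
    # excluded-volume bead is purely rigid (one body) or purely flexible
    ev_starts, ev_sizes, ev_body_l, ev_prot = [], [], [], []
    for p in range(len(prot_names)):
        offsets = np.nonzero(bead_protein == p)[0]
        run_start = 0
        for k in range(1, len(offsets) + 1):
            if k == len(offsets) or \
                    bead_body[offsets[k]] != bead_body[offsets[run_start]]:
                run = offsets[run_start:k]
                for s in range(0, len(run), ev_bead_size):
                    members = run[s:s + ev_bead_size]
                    ev_starts.append(members[0])
                    ev_sizes.append(len(members))
                    ev_body_l.append(int(bead_body[members[0]]))
                    ev_prot.append(p)
                run_start = k
    ev_starts = np.array(ev_starts, dtype=int)
    ev_sizes = np.array(ev_sizes, dtype=int)
    ev_radii = bead_radius(ev_sizes)

    # --- chain topology -------------------------------------------------------
    pairs = []
    for p in range(len(prot_names)):
        offsets = np.nonzero(bead_protein == p)[0]
        for a, b in zip(offsets[:-1], offsets[1:]):
            pairs.append((a, b))
    chain_pairs = np.array(pairs, dtype=int) if pairs else np.zeros((0, 2), dtype=int)

    return CoarseModel(
        proteins=prot_names,
        bead_protein=bead_protein,
        bead_resindex=bead_resindex,
        ref_coords=ref_coords,
        confidence=confidence,
        radii1=radii1,
        rigid_bodies=rigid_bodies,
        flexible_beads=flexible_beads,
        bead_body=bead_body,
        ev_starts=ev_starts,
        ev_sizes=ev_sizes,
        ev_radii=ev_radii,
        ev_body=np.array(ev_body_l, dtype=int),
        ev_protein=np.array(ev_prot, dtype=int),
        ev_res_lo=np.array([bead_resindex[s] for s in ev_starts], dtype=int),
        ev_res_hi=np.array([bead_resindex[s + n - 1] for s, n in
                            zip(ev_starts, ev_sizes)], dtype=int),
        chain_pairs=chain_pairs,
        segments=dict(segments),
    )


def _chain_coords_for(chain, residues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the chain's residues restricted to ``residues``."""
    idx = chain.indices
    mask = np.isin(idx, residues)
    return idx[mask], chain.ca_array[mask]


def _merge_interfaces(
    interfaces, pair_models, prot_names, prot_chain, segments,
    bead_body, bodies, ref_coords, bead_protein, bead_resindex,
) -> None:
    """Merge rigid bodies joined by interface patches, in place.

    The anchor protein's body keeps its frame; the partner's whole body is
    re-posed so the two segments adopt the pair model's relative orientation.
    """
    placed: dict[int, tuple[str, str]] = {}  # body id -> patch that placed it
    for patch in sorted(interfaces, key=lambda p: p.size, reverse=True):
        key = (patch.protein_a, patch.protein_b)
        pm = pair_models.get(key) or pair_models.get(key[::-1])
        if pm is None:
            logger.warning("no pair model for interface %s-%s; not merged", *key)
            continue
        try:
            pa = prot_names.index(patch.protein_a)
            pb = prot_names.index(patch.protein_b)
        except ValueError as exc:
            raise ValueError(f"interface references unknown protein: {exc}")
        res_a = np.array(sorted({a for a, _ in patch.pairs}))
        res_b = np.array(sorted({b for _, b in patch.pairs}))
        sa = _find_segment(segments.get(patch.protein_a, []), res_a)
        sb = _find_segment(segments.get(patch.protein_b, []), res_b)
        if sa is None or sb is None:
            logger.warning("interface %s-%s falls in flexible region; not merged", *key)
            continue
        body_a = _body_of_segment(bodies, bead_body, bead_protein, bead_resindex,
                                  pa, segments[patch.protein_a][sa])
        body_b = _body_of_segment(bodies, bead_body, bead_protein, bead_resindex,
                                  pb, segments[patch.protein_b][sb])
        if body_a is None or body_b is None:
            continue

        # pair-model chains are matched to (protein_a, protein_b) by order
        swap = key not in pair_models
        ch_a = pm.chains[1] if swap else pm.chains[0]
        ch_b = pm.chains[0] if swap else pm.chains[1]

        def seg_beads(p, seg):
            lo, hi = seg
            return np.nonzero((bead_protein == p) & (bead_resindex >= lo)
                              & (bead_resindex <= hi))[0]

        new_ref_b = _pair_model_placement(
            seg_beads(pa, segments[patch.protein_a][sa]),
            seg_beads(pb, segments[patch.protein_b][sb]),
            ch_a, ch_b, ref_coords, bodies[body_b], bead_resindex,
        )
        if body_a == body_b:
            drift = np.sqrt(np.mean(np.sum(
                (ref_coords[bodies[body_b]] - new_ref_b) ** 2, axis=1)))
            if drift > 5.0:
                raise ValueError(
                    f"conflicting interface orientations for segment of "
                    f"{patch.protein_b} ({segments[patch.protein_b][sb]}): patch "
                    f"{patch.protein_a}-{patch.protein_b} disagrees with placement "
                    f"by {placed.get(body_b)} (RMSD {drift:.1f} Å)"
                )
            continue
        ref_coords[bodies[body_b]] = new_ref_b
        bodies[body_a].extend(bodies[body_b])
        for i in bodies[body_b]:
            bead_body[i] = body_a
        bodies[body_b] = []
        placed[body_a] = (patch.protein_a, patch.protein_b)


def _body_of_segment(bodies, bead_body, bead_protein, bead_resindex, p, seg):
    lo, hi = seg
    sel = (bead_protein == p) & (bead_resindex >= lo) & (bead_resindex <= hi)
    owners = np.unique(bead_body[sel])
    owners = owners[owners >= 0]
    return int(owners[0]) if len(owners) else None


def _pair_model_placement(
    seg_a_beads, seg_b_beads, pm_chain_a, pm_chain_b,
    ref_coords, body_b_members, bead_resindex,
) -> np.ndarray:
    """Reference coordinates for protein-b's whole body expressed in
    protein-a's current reference frame, adopting the pair model's relative
    orientation of the two interface segments."""
    ia = bead_resindex[seg_a_beads]
    ib = bead_resindex[seg_b_beads]
    ja, pair_a = _chain_coords_for(pm_chain_a, ia)
    jb, pair_b = _chain_coords_for(pm_chain_b, ib)
    _, keep_a, _ = np.intersect1d(ia, ja, return_indices=True)
    _, keep_b, _ = np.intersect1d(ib, jb, return_indices=True)
    if len(keep_a) < 3 or len(keep_b) < 3:
        raise ValueError("pair model lacks residues covering the interface segments")
    # current reference -> pair frame, for each side
    Ra, ta = kabsch(ref_coords[seg_a_beads][keep_a], pair_a)
    Rb, tb = kabsch(ref_coords[seg_b_beads][keep_b], pair_b)
    # body-b beads -> pair frame -> a's current frame
    in_pair = ref_coords[body_b_members] @ Rb.T + tb
    return (in_pair - ta) @ Ra
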