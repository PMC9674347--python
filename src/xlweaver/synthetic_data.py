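"""Ground-truth toy assemblies and every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes
without pretending to real protein geometry: each subunit is a chain of
bent helical rigid segments joined by extended flexible linkers; subunits
are packed side by side into a connected assembly with defined interface
contacts. From the ground truth it emits

* per-subunit structures (PDB, Cα trace, pLDDT-style confidence in the
  B-factor column: 85-95 inside rigid segments, 40-60 in linkers, so the
  trace straddles the pLDDT-70 threshold exactly at segment boundaries),
* lysine-lysine crosslink tables sampled under a 30 Å true-distance cap
  with a tunable false-positive fraction (decoys drawn beyond 50 Å so they
  are unambiguously unsatisfiable),
* predicted-aligned-error matrices, low within rigid bodies and across true
  interfaces (~N(2, 0.5)) and high elsewhere (~N(20, 3)),
* a low-resolution density map of the true assembly, and
* variant/domain tables with a planted domain-class enrichment.

Everything is reproducible byte-for-byte from the seed (coordinates are
rounded to PDB precision at generation time).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import kabsch, random_rotation
from .io_formats import (Chain, CrosslinkSet, PAEMatrix, Residue, Structure,
                         write_crosslinks, write_pae, write_structure)
from .representation import (CoarseModel, SegmentationParams,
                             build_coarse_model, segment_rigid_bodies)
from .restraints import Scorer

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "generate_complex",
    "simulate_crosslinks",
    "simulate_confidence",
    "simulate_density_map",
    "simulate_variants",
    "benchmark_recovery",
]


@dataclass
class GroundTruth:
    """True assembly plus everything needed to grade a pipeline run."""

    proteins: list[str]
    structures: list[Structure]               # monomer frames (randomized)
    assembly: dict[str, np.ndarray]           # protein -> true Cα coords
    segments: dict[str, list[tuple[int, int]]]
    lysines: dict[str, np.ndarray]
    interfaces: list[tuple[str, str, tuple[int, int], tuple[int, int]]]
    seed: int
    params: dict = field(default_factory=dict)

    def assembly_structure(self) -> Structure:
        """The true assembly as a multi-chain structure (one chain/subunit)."""
        chains = []
        for prot, st in zip(self.proteins, self.structures):
            src = st.chains[0]
            chains.append(Chain(
                chain_id=prot,
                residues=[
                    Residue(r.index, r.name, tuple(xyz), r.confidence)
                    for r, xyz in zip(src.residues, self.assembly[prot])
                ],
            ))
        return Structure(id="truth", chains=chains)

    def coords_for_model(self, model: CoarseModel) -> np.ndarray:
        """True coordinates in the bead order of a coarse model."""
        out = np.empty((model.n_beads, 3))
        for prot, st in zip(self.proteins, self.structures):
            idx = st.chains[0].indices
            lookup = {int(r): i for i, r in enumerate(idx)}
            beads = model.protein_beads(prot)
            rows = [lookup[int(r)] for r in model.bead_resindex[beads]]
            out[beads] = self.assembly[prot][rows]
        return out

    def lysine_table(self) -> list[tuple[str, int]]:
        return [(p, int(r)) for p in self.proteins for r in self.lysines[p]]


# ---------------------------------------------------------------------------
# Geometry of one subunit
# ---------------------------------------------------------------------------

_CA_STEP = 3.8          # Å between consecutive Cα
_EV_CLEARANCE = 14.0    # Å between 10-res bead centers of different bodies


def _segment_blob(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """A compact self-avoiding chain: a boustrophedon path over a near-cubic
    lattice (3.8 Å spacing), jittered and randomly oriented. Consecutive
    residues are adjacent, so connectivity is satisfied by construction."""
    nx = int(np.ceil(n_res ** (1 / 3)))
    ny = int(np.ceil(np.sqrt(n_res / nx)))
    nz = int(np.ceil(n_res / (nx * ny)))
    pts = []
    for iz in range(nz):
        ys = range(ny) if iz % 2 == 0 else range(ny - 1, -1, -1)
        for iy in ys:
            xs = range(nx) if (iy + iz) % 2 == 0 else range(nx - 1, -1, -1)
            for ix in xs:
                pts.append((ix, iy, iz))
    coords = np.asarray(pts[:n_res], dtype=float) * _CA_STEP
    coords += rng.uniform(-0.3, 0.3, size=coords.shape)
    coords -= coords.mean(axis=0)
    coords = coords @ random_rotation(rng).T
    # orient so the chain runs along +y: entry corner faces -y, exit +y,
    # which lets inter-segment linkers leave through facing corners
    from scipy.spatial.transform import Rotation
    v = coords[-1] - coords[0]
    R, _ = Rotation.align_vectors([[0.0, 1.0, 0.0]], [v])
    coords = coords @ R.as_matrix().T
    twist = rng.uniform(0, 2 * np.pi)
    ct, st = np.cos(twist), np.sin(twist)
    Ry = np.array([[ct, 0, st], [0, 1.0, 0], [-st, 0, ct]])
    return coords @ Ry.T


def _build_subunit(
    size: int, n_rigid: int, linker_len: int, rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Local segment blobs and rigid ranges for one subunit (blobs are not
    yet placed; linkers are interpolated at assembly time)."""
    n_linkers = n_rigid - 1
    seg_total = size - n_linkers * linker_len
    base = seg_total // n_rigid
    seg_lens = [base + (1 if s < seg_total % n_rigid else 0)
                for s in range(n_rigid)]
    blobs, ranges = [], []
    i = 0
    for s, seg_len in enumerate(seg_lens):
        blobs.append(_segment_blob(seg_len, rng))
        ranges.append((i + 1, i + seg_len))
        i += seg_len + (linker_len if s < n_rigid - 1 else 0)
    return blobs, ranges


# ---------------------------------------------------------------------------
# Assembly generation
# ---------------------------------------------------------------------------

def generate_complex(
    n_subunits: int = 6,
    sizes: list[int] | None = None,
    n_rigid_per_subunit: list[int] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    linker_len: int = 12,
    clearance: float = 10.0,
    lysine_period: int = 5,
    max_tries: int = 50,
) -> GroundTruth:
    """Generate a connected multi-subunit ground-truth assembly.

    Each rigid segment is a compact self-avoiding blob; blobs are packed
    against the growing assembly until every residue pair between bodies
    clears ``clearance`` Å — close enough for interface crosslinks, far
    enough that the true assembly has zero excluded-volume score — with a
    z-stagger so the assembly is not planar. Crosslinkable "lysines" are
    drawn at rate 1/``lysine_period`` among rigid-segment residues
    (irregularly spaced, as in real sequences). The layout is re-jittered up
    to ``max_tries`` times until the truth scores zero on connectivity and
    excluded volume and every adjacent subunit pair shares at least four
    crosslinkable contacts; otherwise an error is raised.

    With ``out_dir`` set, one PDB per subunit is written (confidence in the
    B-factor column).
    """
    if sizes is None:
        sizes = [100] * n_subunits
    if len(sizes) != n_subunits:
        raise ValueError("len(sizes) must equal n_subunits")
    if any(s < 30 for s in sizes):
        raise ValueError("every subunit must have >= 30 residues")
    if n_rigid_per_subunit is None:
        n_rigid_per_subunit = [2 if i < (10 - n_subunits) else 1
                               for i in range(n_subunits)]
    proteins = [f"su{i + 1}" for i in range(n_subunits)]
    children = np.random.SeedSequence(seed).spawn(max_tries)

    for attempt in range(max_tries):
        rng = np.random.default_rng(children[attempt])
        truth = _layout_attempt(
            proteins, sizes, n_rigid_per_subunit, linker_len, clearance,
            lysine_period, rng, seed,
        )
        if truth is not None:
            break
    else:
        raise RuntimeError(
            f"could not pack a clash-free connected assembly in {max_tries} tries"
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for st in truth.structures:
            write_structure(st, out_dir / f"{st.id}.pdb")
    return truth


def _scan_placement(
    blob: np.ndarray, base: np.ndarray, direction: np.ndarray,
    constraints: list[tuple[np.ndarray, float]], start: float = 0.0,
) -> np.ndarray:
    """Slide ``blob`` from ``base`` along ``direction`` (1 Å steps) until,
    for every (points, clearance) constraint, all residue pairs clear;
    returns the blob center."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    offset = start
    while True:
        center = base + offset * d
        ok = True
        for pts, clearance in constraints:
            if pts is None or not len(pts):
                continue
            dmin = np.sqrt(((pts[:, None] - (blob + center)[None]) ** 2)
                           .sum(axis=2)).min()
            if dmin < clearance:
                ok = False
                break
        if ok:
            return center
        offset += 1.0


def _layout_attempt(
    proteins, sizes, n_rigid, linker_len, clearance, lysine_period,
    rng, seed,
) -> GroundTruth | None:
    assembly: dict[str, np.ndarray] = {}
    segments: dict[str, list[tuple[int, int]]] = {}
    lysines: dict[str, np.ndarray] = {}
    structures: list[Structure] = []

    n_sub = len(proteins)
    built = [_build_subunit(size, n_rigid[i], linker_len, rng)
             for i, size in enumerate(sizes)]

    # first-segment blobs sit on a ring in the x-z plane (every subunit
    # touches its two neighbours, closing the assembly); the ring radius is
    # the smallest at which all pairs clear, with z-jitter off the plane
    z_jit = np.array([0.0] + [rng.uniform(-3, 3) for _ in range(n_sub - 1)])
    thetas = 2.0 * np.pi * np.arange(n_sub) / n_sub
    radial = np.stack([np.cos(thetas), np.zeros(n_sub), np.sin(thetas)], axis=1)
    R = 5.0
    while True:
        base_centers = R * radial + np.stack(
            [np.zeros(n_sub), np.zeros(n_sub), z_jit], axis=1)
        pts = [built[i][0][0] + base_centers[i] for i in range(n_sub)]
        dmin = min(
            np.sqrt(((pts[i][:, None] - pts[j][None]) ** 2).sum(axis=2)).min()
            for i in range(n_sub) for j in range(i + 1, n_sub)
        )
        if dmin >= clearance:
            break
        R += 1.0

    placed_pts: list[np.ndarray] = []
    for i, (prot, size) in enumerate(zip(proteins, sizes)):
        blobs, ranges = built[i]
        other = [built[j][0][0] + base_centers[j] for j in range(n_sub)
                 if j != i] + placed_pts
        all_pts = np.concatenate(other) if other else None
        centers = [base_centers[i]]
        for k in range(1, len(blobs)):
            own = np.concatenate([blobs[j] + centers[j] for j in range(k)])
            # the linker crosses the gap to the subunit's own previous
            # segments, so that gap is wide enough for its beads to clear
            # both blobs' excluded volume; against other subunits the
            # ordinary contact clearance applies, keeping later segments
            # crosslinkable to their neighbours
            centers.append(_scan_placement(
                blobs[k], centers[0], [0.0, 1.0, 0.0],
                [(own, clearance + 14.0), (all_pts, clearance)], start=10.0))

        # assemble the chain: blobs in place, linkers interpolated
        coords = np.zeros((size, 3))
        for k, ((lo, hi), blob, center) in enumerate(zip(ranges, blobs, centers)):
            coords[lo - 1:hi] = blob + center
            if k < len(blobs) - 1:
                a = coords[hi - 1]
                b = (blobs[k + 1] + centers[k + 1])[0]
                for j in range(1, linker_len + 1):
                    coords[hi - 1 + j] = a + (b - a) * j / (linker_len + 1)
        placed_pts.append(coords)
        assembly[prot] = np.round(coords, 3)
        segments[prot] = ranges
        in_rigid = np.zeros(size + 1, dtype=bool)
        for lo, hi in ranges:
            in_rigid[lo:hi + 1] = True
        # irregular lysine spacing (as in real sequences): a periodic lattice
        # would give the rod an artificial shift/flip symmetry that makes the
        # link data less informative than real crosslinks are
        lys_mask = rng.random(size + 1) < (1.0 / lysine_period)
        lys = np.array([r for r in range(1, size + 1)
                        if lys_mask[r] and in_rigid[r]], dtype=int)
        lysines[prot] = lys

        # emitted monomer: randomized frame, confidence straddling pLDDT 70
        conf = np.round(rng.uniform(40.0, 60.0, size=size), 2)
        for lo, hi in ranges:
            conf[lo - 1:hi] = np.round(rng.uniform(85.0, 95.0, size=hi - lo + 1), 2)
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, size=3)
        mono = np.round(assembly[prot] @ R.T + t, 3)
        residues = [
            Residue(r, "LYS" if r in lys else "ALA", tuple(mono[r - 1]),
                    float(conf[r - 1]))
            for r in range(1, size + 1)
        ]
        structures.append(Structure(id=prot, chains=[Chain("A", residues)]))

    truth = GroundTruth(
        proteins=list(proteins), structures=structures, assembly=assembly,
        segments=dict(segments), lysines=lysines, interfaces=[], seed=seed,
        params={"sizes": list(sizes), "n_rigid": list(n_rigid),
                "linker_len": linker_len, "clearance": clearance,
                "lysine_period": lysine_period},
    )

    # interfaces: contact ranges between every touching subunit pair
    linked_partners = {p: 0 for p in proteins}
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            xa, xb = assembly[a], assembly[b]
            d = np.sqrt(((xa[:, None] - xb[None]) ** 2).sum(axis=2))
            ia, ib = np.nonzero(d <= 18.0)
            if not len(ia):
                continue
            truth.interfaces.append(
                (a, b, (int(ia.min()) + 1, int(ia.max()) + 1),
                 (int(ib.min()) + 1, int(ib.max()) + 1))
            )
            la = assembly[a][lysines[a] - 1]
            lb = assembly[b][lysines[b] - 1]
            dl = np.sqrt(((la[:, None] - lb[None]) ** 2).sum(axis=2))
            if np.sum(dl <= 30.0) >= 4:
                linked_partners[a] += 1
                linked_partners[b] += 1

    # validity: confidence-based segmentation must recover the generated
    # segments exactly; the truth must score zero on connectivity and
    # excluded volume; every subunit must have two crosslinkable neighbours
    # (the ring is closed) so no subunit dangles off a single interface
    need = 2 if len(proteins) >= 3 else 1
    if any(v < need for v in linked_partners.values()):
        return None
    recovered: dict[str, list[tuple[int, int]]] = {}
    for st in structures:
        recovered.update(segment_rigid_bodies(st, SegmentationParams()))
    if recovered != segments:
        return None
    model = _truth_model(truth)
    coords = truth.coords_for_model(model)
    scorer = Scorer(model)
    if scorer.connectivity(coords) > 1e-9 or scorer.excluded_volume(coords) > 1e-9:
        return None
    return truth


def _truth_model(truth: GroundTruth) -> CoarseModel:
    """Coarse model built from the emitted structures and true segments."""
    return build_coarse_model(truth.structures, truth.segments)


# ---------------------------------------------------------------------------
# Crosslinks
# ---------------------------------------------------------------------------

def simulate_crosslinks(
    truth: GroundTruth,
    n_links: int = 98,
    fp_rate: float = 0.0,
    max_true_dist: float = 30.0,
    seed: int = 0,
    inter_fraction: float = 0.3,
    min_seq_sep: int = 5,
    decoy_floor: float = 50.0,
    stratify_inter: bool = False,
    out_path: str | Path | None = None,
) -> tuple[CrosslinkSet, list]:
    """Sample lysine-lysine crosslinks from the ground truth.

    ``round(fp_rate * n_links)`` decoys come from lysine pairs farther than
    ``decoy_floor`` (50 Å) in truth, so decoys can never satisfy the 35 Å
    validation cutoff; the rest are true links with true distance <=
    ``max_true_dist`` (30 Å), of which a fraction ``inter_fraction`` is
    intermolecular (the census of a typical crosslinking study: 98 links,
    ~30% intermolecular). Intramolecular candidates require a sequence
    separation of at least ``min_seq_sep``. With ``stratify_inter`` the
    intermolecular links are allocated round-robin over the contacting
    rigid-segment pairs instead of uniformly, emulating a curated modeling
    set that covers every interface.

    Returns the link set and the list of decoy links.
    """
    rng = np.random.default_rng(seed)
    lys = truth.lysine_table()
    pos = np.array([truth.assembly[p][r - 1] for p, r in lys])
    n = len(lys)
    ii, jj = np.triu_indices(n, k=1)
    d = np.sqrt(((pos[ii] - pos[jj]) ** 2).sum(axis=1))
    same = np.array([lys[a][0] == lys[b][0] for a, b in zip(ii, jj)])
    seqsep = np.array([abs(lys[a][1] - lys[b][1]) for a, b in zip(ii, jj)])

    n_decoy = int(round(fp_rate * n_links))
    n_true = n_links - n_decoy
    n_inter = int(round(inter_fraction * n_true))
    n_intra = n_true - n_inter

    pools = {
        "inter": np.nonzero(~same & (d <= max_true_dist))[0],
        "intra": np.nonzero(same & (d <= max_true_dist) &
                            (seqsep >= min_seq_sep))[0],
        "decoy": np.nonzero(d > decoy_floor)[0],
    }
    need = {"inter": n_inter, "intra": n_intra, "decoy": n_decoy}
    chosen: dict[str, np.ndarray] = {}
    for kind, k in need.items():
        pool = pools[kind]
        if len(pool) < k:
            raise ValueError(
                f"cannot sample {k} {kind} links: only {len(pool)} qualifying "
                f"lysine pairs in the ground truth"
            )
        if kind == "inter" and stratify_inter and k > 0:
            chosen[kind] = _stratified_inter(truth, lys, ii, jj, pool, k, rng)
        else:
            chosen[kind] = rng.choice(pool, size=k, replace=False)

    def to_pairs(idx):
        return [(lys[ii[q]][0], lys[ii[q]][1], lys[jj[q]][0], lys[jj[q]][1])
                for q in idx]

    true_pairs = to_pairs(chosen["inter"]) + to_pairs(chosen["intra"])
    decoy_pairs = to_pairs(chosen["decoy"])
    xl = CrosslinkSet.from_pairs(true_pairs + decoy_pairs)
    decoy_keys = {l.key for l in CrosslinkSet.from_pairs(decoy_pairs)}
    decoys = [l for l in xl if l.key in decoy_keys]
    if out_path is not None:
        write_crosslinks(xl, out_path)
    return xl, decoys


def _stratified_inter(truth, lys, ii, jj, pool, k, rng) -> np.ndarray:
    """Allocate k intermolecular links round-robin over contacting
    rigid-segment pairs, uniformly within each pair's candidates."""
    def segment_of(prot, res):
        for s, (lo, hi) in enumerate(truth.segments[prot]):
            if lo <= res <= hi:
                return s
        return -1

    groups: dict[tuple, list[int]] = {}
    for q in pool:
        (pa, ra), (pb, rb) = lys[ii[q]], lys[jj[q]]
        key = tuple(sorted([(pa, segment_of(pa, ra)), (pb, segment_of(pb, rb))]))
        groups.setdefault(key, []).append(q)
    order = sorted(groups)
    shuffled = {g: rng.permutation(groups[g]) for g in order}
    taken: list[int] = []
    depth = 0
    while len(taken) < k:
        advanced = False
        for g in order:
            if len(taken) >= k:
                break
            if depth < len(shuffled[g]):
                taken.append(int(shuffled[g][depth]))
                advanced = True
        if not advanced:
            break
        depth += 1
    return np.asarray(taken[:k], dtype=int)


# ---------------------------------------------------------------------------
# Confidence (PAE) matrices
# ---------------------------------------------------------------------------

def simulate_confidence(
    truth: GroundTruth,
    seed: int = 0,
    low_mean: float = 2.0,
    low_sd: float = 0.5,
    high_mean: float = 20.0,
    high_sd: float = 3.0,
    out_dir: str | Path | None = None,
) -> dict[tuple[str, str], PAEMatrix]:
    """One PAE matrix per adjacent subunit pair: low (~N(2, 0.5), clipped at
    zero) within each rigid segment and across the true interface block,
    high (~N(20, 3)) everywhere else."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], PAEMatrix] = {}
    size = {p: s.chains[0].indices.max() for p, s in
            zip(truth.proteins, truth.structures)}
    for (a, b, range_a, range_b) in truth.interfaces:
        labels = [(a, r) for r in range(1, size[a] + 1)] + \
                 [(b, r) for r in range(1, size[b] + 1)]
        n = len(labels)
        values = np.clip(rng.normal(high_mean, high_sd, size=(n, n)), 0, None)
        offs = {a: 0, b: size[a]}
        for prot in (a, b):
            for lo, hi in truth.segments[prot]:
                sl = slice(offs[prot] + lo - 1, offs[prot] + hi)
                values[sl, sl] = np.clip(
                    rng.normal(low_mean, low_sd, size=(hi - lo + 1, hi - lo + 1)),
                    0, None)
        sa = slice(range_a[0] - 1, range_a[1])
        sb = slice(offs[b] + range_b[0] - 1, offs[b] + range_b[1])
        block = np.clip(rng.normal(
            low_mean, low_sd,
            size=(range_a[1] - range_a[0] + 1, range_b[1] - range_b[0] + 1)),
            0, None)
        values[sa, sb] = block
        values[sb, sa] = block.T + np.clip(
            rng.normal(0, 0.1, size=block.T.shape), -0.3, 0.3)
        pae = PAEMatrix(labels=labels, values=np.abs(values))
        out[(a, b)] = pae
        if out_dir is not None:
            write_pae(pae, Path(out_dir) / f"pae_{a}_{b}.json")
    return out


# ---------------------------------------------------------------------------
# Density, variants, recovery
# ---------------------------------------------------------------------------

def simulate_density_map(
    truth: GroundTruth, resolution: float = 23.0, voxel: float = 6.0,
    out_path: str | Path | None = None,
):
    """Low-resolution density of the true assembly (one unit mass per Cα)."""
    from .io_formats import write_density
    from .map_fit import simulate_density

    coords = np.concatenate([truth.assembly[p] for p in truth.proteins])
    grid = simulate_density(coords, resolution=resolution, voxel=voxel)
    if out_path is not None:
        write_density(grid, out_path)
    return grid


_DISEASES = ["CED", "JATD", "NPHP", "MSS", "RP", "SRTD"]
_AA = list("ACDEFGHIKLMNPQRSTVWY")


def simulate_variants(
    truth: GroundTruth,
    n_variants: int = 100,
    head_fraction: float = 0.79,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant and domain tables with a planted domain-class enrichment.

    The first rigid segment of each subunit is annotated as a WD40 "head",
    any later segments as TPR "tail"; ``head_fraction`` of the variants are
    placed uniformly in WD40 ranges and the rest in TPR ranges.
    """
    rng = np.random.default_rng(seed)
    dom_rows = []
    ranges: dict[str, list[tuple[int, int, str]]] = {}
    for prot in truth.proteins:
        segs = truth.segments[prot]
        anns = []
        for k, (lo, hi) in enumerate(segs):
            cls = "WD40" if k == 0 else "TPR"
            dom_rows.append({"protein": prot, "start": lo, "end": hi,
                             "domain_class": cls})
            anns.append((lo, hi, cls))
        ranges[prot] = anns
    domains = pd.DataFrame(dom_rows)

    def draw(cls):
        cand = [(p, lo, hi) for p, anns in ranges.items()
                for lo, hi, c in anns if c == cls]
        p, lo, hi = cand[rng.integers(len(cand))]
        return p, int(rng.integers(lo, hi + 1))

    n_head = int(round(head_fraction * n_variants))
    rows = []
    for k in range(n_variants):
        cls = "WD40" if k < n_head else "TPR"
        prot, resi = draw(cls)
        ref, alt = rng.choice(_AA, size=2, replace=False)
        rows.append({"protein": prot, "residue": resi, "ref_aa": ref,
                     "alt_aa": alt,
                     "disease": _DISEASES[rng.integers(len(_DISEASES))]})
    variants = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        variants.to_csv(out_dir / "variants.csv", index=False)
        domains.to_csv(out_dir / "domains.csv", index=False)
    return variants, domains


def benchmark_recovery(
    centroid_coords: np.ndarray,
    truth: GroundTruth,
    model: CoarseModel,
    crosslinks: CrosslinkSet | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Grade a pipeline result against the ground truth.

    Reports the bead RMSD of the centroid to the truth after least-squares
    superposition, the per-subunit placement error (subunit-centroid
    distance after the same global superposition), and, if links are given,
    the static satisfaction of the true links in the centroid. Subunits
    missing from the model are reported, not fatal.
    """
    from .ensemble_analysis import static_xl_satisfaction
    from .geometry import rmsd as _rmsd, superpose

    true_coords = truth.coords_for_model(model)
    aligned = superpose(true_coords, centroid_coords)
    report: dict = {
        "centroid_rmsd": float(_rmsd(aligned, true_coords)),
        "per_subunit_error": {},
        "missing_subunits": [p for p in truth.proteins
                             if p not in model.proteins],
    }
    for prot in truth.proteins:
        if prot in model.proteins:
            beads = model.protein_beads(prot)
            report["per_subunit_error"][prot] = float(np.linalg.norm(
                aligned[beads].mean(axis=0) - true_coords[beads].mean(axis=0)))
    if crosslinks is not None:
        sat = static_xl_satisfaction((model, centroid_coords), crosslinks)
        report["centroid_link_satisfaction"] = sat.fraction
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
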