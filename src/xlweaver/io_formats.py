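"""Readers and writers for every external representation the pipeline touches.

Structures (PDB/mmCIF, Cα + per-residue confidence in the B-factor column),
predicted-aligned-error (PAE) matrices (JSON), crosslink tables (CSV),
sampled ensembles (multi-model PDB + score sidecar) and density maps
(CCP4/MRC via gemmi).

Conventions: residue numbering is 1-based, chain/protein names are
case-sensitive exact strings, and ensemble coordinates are serialized at
PDB precision (3 decimal places).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Chain",
    "Structure",
    "Crosslink",
    "CrosslinkSet",
    "PAEMatrix",
    "EnsembleRecord",
    "FormatError",
    "read_structure",
    "write_structure",
    "read_crosslinks",
    "write_crosslinks",
    "read_pae",
    "write_pae",
    "write_ensemble",
    "read_ensemble",
    "read_density",
    "write_density",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue: 1-based index, 3-letter name, Cα position (Å), pLDDT-style
    confidence in [0, 100] (stored in the B-factor column on disk)."""

    index: int
    name: str
    ca_xyz: tuple[float, float, float]
    confidence: float


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    @property
    def ca_array(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    @property
    def confidence_array(self) -> np.ndarray:
        return np.array([r.confidence for r in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A (possibly multi-chain) structure reduced to its Cα trace.

    Invariants: residue indices strictly increasing per chain, finite
    coordinates, confidence in [0, 100].
    """

    id: str
    chains: list[Chain]

    def validate(self) -> None:
        for ch in self.chains:
            idx = ch.indices
            if len(idx) and not np.all(np.diff(idx) > 0):
                raise ValueError(
                    f"residue indices not strictly increasing in chain {ch.chain_id}"
                )
            xyz = ch.ca_array
            if len(xyz) and not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite Cα coordinate in chain {ch.chain_id}")
            conf = ch.confidence_array
            if len(conf) and (conf.min() < 0 or conf.max() > 100):
                raise ValueError(f"confidence outside [0, 100] in chain {ch.chain_id}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


_COOR_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
}


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a Cα-trace :class:`Structure`.

    The B-factor column populates per-residue confidence. Residues lacking a
    Cα atom are dropped with a logged warning.
    """
    path = Path(path)
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=_COOR_FORMATS[format])
    except KeyError:
        raise FormatError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            ca = gres.find_atom("CA", "*")
            if ca is None:
                logger.warning(
                    "residue %s %d in chain %s of %s has no CA atom; dropped",
                    gres.name, gres.seqid.num, gch.name, path.name,
                )
                continue
            residues.append(
                Residue(
                    index=gres.seqid.num,
                    name=gres.name,
                    ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                    # B-factor column carries 2 decimals; round away the
                    # float32 representation gemmi stores internally
                    confidence=round(float(ca.b_iso), 2),
                )
            )
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))
    out = Structure(id=path.stem, chains=chains)
    out.validate()
    return out


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Cα-trace structure as PDB, confidence in the B-factor column."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*res.ca_xyz)
            atom.b_iso = res.confidence
            atom.occ = 1.0
            gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Crosslinks
# ---------------------------------------------------------------------------

def _canonical_pair(p1: str, r1: int, p2: str, r2: int):
    a, b = (p1, int(r1)), (p2, int(r2))
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Crosslink:
    """An unordered residue-pair restraint between two proteins (stored in
    canonical sorted order)."""

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    score: float | None = None

    @property
    def is_intra(self) -> bool:
        return self.protein1 == self.protein2

    @property
    def key(self):
        return ((self.protein1, self.residue1), (self.protein2, self.residue2))


@dataclass
class CrosslinkSet:
    """A deduplicated set of unordered crosslinks plus the distance
    conventions used to restrain (21 Å) and to validate (35 Å) them."""

    links: list[Crosslink] = field(default_factory=list)
    cutoff_satisfaction: float = 35.0
    cutoff_restraint: float = 21.0
    n_rows_read: int = 0  # raw row count before deduplication

    def __post_init__(self) -> None:
        if self.cutoff_satisfaction < self.cutoff_restraint:
            raise ValueError("cutoff_satisfaction must be >= cutoff_restraint")

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    @property
    def n_inter(self) -> int:
        return sum(not l.is_intra for l in self.links)

    @property
    def n_intra(self) -> int:
        return sum(l.is_intra for l in self.links)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, int, str, int]],
        scores: Iterable[float] | None = None,
        **kwargs,
    ) -> "CrosslinkSet":
        rows = list(pairs)
        sc = list(scores) if scores is not None else [None] * len(rows)
        seen: dict = {}
        n_raw = 0
        for (p1, r1, p2, r2), s in zip(rows, sc):
            r1, r2 = int(r1), int(r2)
            if r1 <= 0 or r2 <= 0:
                logger.warning("rejecting crosslink with non-positive residue index: "
                               "%s %s %s %s", p1, r1, p2, r2)
                continue
            n_raw += 1
            if (p1, r1) == (p2, r2):
                logger.warning("rejecting self-link %s %d", p1, r1)
                continue
            (a, b) = _canonical_pair(p1, r1, p2, r2)
            if (a, b) not in seen:
                seen[(a, b)] = s
        links = [
            Crosslink(a[0], a[1], b[0], b[1], score=s)
            for (a, b), s in seen.items()
        ]
        return cls(links=links, n_rows_read=n_raw, **kwargs)


def read_crosslinks(path: str | Path, **kwargs) -> CrosslinkSet:
    """Read a crosslink CSV (columns protein1, residue1, protein2, residue2
    and optionally score) into a deduplicated :class:`CrosslinkSet`.

    Rows with residue index <= 0 are rejected with a warning; unknown protein
    names are permitted here and validated later against structures. Several
    files (e.g. from alternative enrichment preparations) may be passed to
    :func:`read_crosslink_tables` to be pooled into one set.
    """
    df = pd.read_csv(path)
    return _crosslinks_from_frame(df, **kwargs)


def _crosslinks_from_frame(df: pd.DataFrame, **kwargs) -> CrosslinkSet:
    required = ["protein1", "residue1", "protein2", "residue2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"crosslink table missing columns: {missing}")
    pairs = list(
        zip(df["protein1"].astype(str), df["residue1"].astype(int),
            df["protein2"].astype(str), df["residue2"].astype(int))
    )
    scores = df["score"].tolist() if "score" in df.columns else None
    return CrosslinkSet.from_pairs(pairs, scores=scores, **kwargs)


def read_crosslink_tables(paths: Sequence[str | Path], **kwargs) -> CrosslinkSet:
    """Concatenate several crosslink CSVs and deduplicate them as one set."""
    frames = [pd.read_csv(p) for p in paths]
    return _crosslinks_from_frame(pd.concat(frames, ignore_index=True), **kwargs)


def write_crosslinks(xl: CrosslinkSet, path: str | Path) -> None:
    rows = [
        {"protein1": l.protein1, "residue1": l.residue1,
         "protein2": l.protein2, "residue2": l.residue2,
         "score": l.score}
        for l in xl.links
    ]
    pd.DataFrame(rows, columns=["protein1", "residue1", "protein2",
                                "residue2", "score"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PAE matrices
# ---------------------------------------------------------------------------

@dataclass
class PAEMatrix:
    """Predicted-aligned-error matrix over the pooled residues of one or two
    proteins. ``labels[i]`` is the (protein, residue-index) of row/column i;
    values are Å, non-negative and generally asymmetric."""

    labels: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(
                f"PAE matrix shape {self.values.shape} does not match "
                f"{n} labels (must be square)"
            )
        if np.any(self.values < 0):
            raise FormatError("PAE matrix contains negative entries")

    @property
    def proteins(self) -> list[str]:
        seen: list[str] = []
        for p, _ in self.labels:
            if p not in seen:
                seen.append(p)
        return seen

    def block_indices(self, protein: str) -> np.ndarray:
        return np.array([i for i, (p, _) in enumerate(self.labels) if p == protein],
                        dtype=int)


def read_pae(path: str | Path) -> PAEMatrix:
    """Read a PAE matrix from JSON (keys ``labels`` and ``values``)."""
    with open(path) as fh:
        obj = json.load(fh)
    try:
        labels = [(str(p), int(r)) for p, r in obj["labels"]]
        values = np.asarray(obj["values"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed PAE JSON {path}: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"PAE matrix in {path} is not square: {values.shape}")
    return PAEMatrix(labels=labels, values=values)


def write_pae(pae: PAEMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"labels": [[p, r] for p, r in pae.labels],
             "values": pae.values.tolist()},
            fh,
        )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleRecord:
    """One sampled frame: per-rigid-body pose (x -> R @ x_ref + t), flexible
    bead coordinates, and the score breakdown for the frame."""

    frame_id: int
    run_id: int
    rotations: np.ndarray      # (n_bodies, 3, 3)
    translations: np.ndarray   # (n_bodies, 3)
    flex_coords: np.ndarray    # (n_flex, 3)
    scores: dict[str, float] = field(default_factory=dict)

    def validate(self, atol: float = 1e-6) -> None:
        for R in self.rotations:
            if abs(np.linalg.det(R) - 1.0) > 1e-4:
                raise ValueError("pose rotation is not a proper rotation")
        comps = [v for k, v in self.scores.items() if k != "total"]
        if "total" in self.scores and comps:
            if abs(sum(comps) - self.scores["total"]) > max(1e-6, 1e-9 * abs(self.scores["total"])):
                raise ValueError("score breakdown components do not sum to total")


_SCORE_COLS = ["run_id", "frame_id", "crosslink", "excluded_volume",
               "connectivity", "total"]


def write_ensemble(records: Sequence[EnsembleRecord], model, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB of bead pseudo-atoms plus a
    sidecar CSV score table (``<path>.scores.csv``).

    ``model`` is a :class:`~xlweaver.representation.CoarseModel`; each record's
    poses are applied to the model's reference coordinates to produce one
    MODEL block per frame.
    """
    path = Path(path)
    lines: list[str] = []
    score_rows = []
    for imod, rec in enumerate(records, start=1):
        if rec.rotations.shape[0] != len(model.rigid_bodies):
            raise ValueError(
                f"record {rec.frame_id}: {rec.rotations.shape[0]} poses for "
                f"{len(model.rigid_bodies)} rigid bodies"
            )
        coords = model.apply_poses(rec.rotations, rec.translations, rec.flex_coords)
        lines.append(f"MODEL     {imod:4d}")
        serial = 1
        for ip, prot in enumerate(model.proteins):
            sel = model.bead_protein == ip
            cid = _short_chain_id(ip)
            for resi, (x, y, z) in zip(model.bead_resindex[sel], coords[sel]):
                lines.append(
                    f"ATOM  {serial % 100000:5d}  CA  BEA {cid}{int(resi):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
                serial += 1
        lines.append("ENDMDL")
        score_rows.append(
            {"run_id": rec.run_id, "frame_id": rec.frame_id,
             **{k: rec.scores.get(k, np.nan)
                for k in ("crosslink", "excluded_volume", "connectivity", "total")}}
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    pd.DataFrame(score_rows, columns=_SCORE_COLS).to_csv(
        _sidecar_path(path), index=False
    )
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".scores.csv")


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _short_chain_id(i: int) -> str:
    return _CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)]


def read_ensemble(path: str | Path, model) -> list[EnsembleRecord]:
    """Read an ensemble written by :func:`write_ensemble`.

    Per-rigid-body poses are re-derived from the bead coordinates by
    least-squares superposition against the model's reference coordinates, so
    a round trip reproduces poses to coordinate (3-decimal) precision.
    """
    from .geometry import kabsch  # local import to avoid a cycle

    path = Path(path)
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            frames.append(np.asarray(current, dtype=float))
            current = None
        elif line.startswith("ATOM") and current is not None:
            current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    scores = pd.read_csv(_sidecar_path(path))
    if len(scores) != len(frames):
        raise FormatError(
            f"{len(frames)} MODEL blocks but {len(scores)} score rows in sidecar"
        )
    records = []
    for coords, (_, row) in zip(frames, scores.iterrows()):
        if coords.shape[0] != model.n_beads:
            raise FormatError(
                f"frame has {coords.shape[0]} beads, model defines {model.n_beads}"
            )
        rots, trans = [], []
        for body in model.rigid_bodies:
            R, t = kabsch(model.ref_coords[body], coords[body])
            rots.append(R)
            trans.append(t)
        rec = EnsembleRecord(
            frame_id=int(row["frame_id"]),
            run_id=int(row["run_id"]),
            rotations=np.asarray(rots) if rots else np.zeros((0, 3, 3)),
            translations=np.asarray(trans) if trans else np.zeros((0, 3)),
            flex_coords=coords[model.flexible_beads],
            scores={k: float(row[k]) for k in
                    ("crosslink", "excluded_volume", "connectivity", "total")
                    if k in row and np.isfinite(row[k])},
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Density maps (CCP4/MRC)
# ---------------------------------------------------------------------------

def write_density(grid, path: str | Path) -> None:
    """Write a :class:`~xlweaver.map_fit.DensityGrid` as a CCP4/MRC map
    (mode 2, float32), origin stored in the header."""
    values = np.ascontiguousarray(grid.values, dtype=np.float32)
    g = gemmi.FloatGrid(*values.shape)
    arr = np.array(g, copy=False)
    arr[...] = values
    edge = np.array(values.shape) * grid.voxel
    g.set_unit_cell(gemmi.UnitCell(edge[0], edge[1], edge[2], 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ox, oy, oz = grid.origin
    ccp4.set_header_float(50, float(ox))
    ccp4.set_header_float(51, float(oy))
    ccp4.set_header_float(52, float(oz))
    ccp4.write_ccp4_map(str(path))


def read_density(path: str | Path):
    """Read a CCP4/MRC map into a :class:`~xlweaver.map_fit.DensityGrid`."""
    from .map_fit import DensityGrid

    ccp4 = gemmi.read_ccp4_map(str(path))
    values = np.array(ccp4.grid, copy=True).astype(float)
    nu = ccp4.grid.nu
    voxel = ccp4.grid.unit_cell.a / nu
    origin = np.array([ccp4.header_float(50), ccp4.header_float(51),
                       ccp4.header_float(52)], dtype=float)
    return DensityGrid(origin=origin, voxel=float(voxel), values=values)
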