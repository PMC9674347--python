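"""Mapping disease-associated missense variants onto domain annotations and
onto an assembled model.

Two analyses: (1) per-domain-class variant counts/fractions (e.g. how many
missense variants of the β-propeller "head" WD40 domains versus the
α-solenoid TPR "tail" of a subunit family), and (2) variant-to-interface
proximity — the nearest other-subunit distance of each variant residue in
an assembled model, flagging variants that sit at subunit interfaces.

Domain ranges are user-supplied annotation (CSV/DataFrame), not detected;
variant tables are inputs, never scraped from clinical databases.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ensemble_analysis import _residue_lookup

logger = logging.getLogger(__name__)

__all__ = [
    "read_variants",
    "read_domains",
    "variant_domain_enrichment",
    "interface_proximity",
]

VARIANT_COLUMNS = ["protein", "residue", "ref_aa", "alt_aa", "disease"]
DOMAIN_COLUMNS = ["protein", "start", "end", "domain_class"]


def read_variants(path) -> pd.DataFrame:
    """Read a variant CSV (protein, residue, ref_aa, alt_aa, disease)."""
    df = pd.read_csv(path)
    missing = [c for c in ("protein", "residue") if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    df["residue"] = df["residue"].astype(int)
    if (df["residue"] < 1).any():
        raise ValueError("variant residue indices must be >= 1")
    return df


def read_domains(path) -> pd.DataFrame:
    """Read a domain-annotation CSV (protein, start, end, domain_class)."""
    df = pd.read_csv(path)
    missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table missing columns: {missing}")
    for prot, grp in df.groupby("protein"):
        spans = sorted(zip(grp["start"], grp["end"]))
        for (s1, e1), (s2, _) in zip(spans[:-1], spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping domain ranges for {prot}")
    return df


def variant_domain_enrichment(
    variants: pd.DataFrame,
    domains: pd.DataFrame,
    subset: list[str] | None = None,
    protein_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each variant the domain class of its containing range and
    tabulate counts and fractions per class.

    Variants in no annotated range are classed "other"; ``subset`` limits
    the tabulation to the listed proteins (e.g. the structural core of a
    complex). Variants beyond a protein's known length are rejected with a
    warning. Returns (per-variant assignments, per-class summary).
    """
    v = variants.copy()
    if subset is not None:
        v = v[v["protein"].isin(subset)].copy()
    if protein_lengths:
        bad = v.apply(
            lambda r: r["residue"] > protein_lengths.get(r["protein"], np.inf),
            axis=1,
        )
        if bad.any():
            logger.warning("%d variants beyond protein length rejected",
                           int(bad.sum()))
            v = v[~bad].copy()

    def classify(row):
        d = domains[domains["protein"] == row["protein"]]
        hit = d[(d["start"] <= row["residue"]) & (row["residue"] <= d["end"])]
        return hit.iloc[0]["domain_class"] if len(hit) else "other"

    v["domain_class"] = v.apply(classify, axis=1) if len(v) else \
        pd.Series(dtype=object)
    counts = v["domain_class"].value_counts()
    summary = pd.DataFrame({
        "count": counts,
        "fraction": counts / counts.sum() if counts.sum() else counts,
    })
    summary.index.name = "domain_class"
    return v, summary.reset_index()


def interface_proximity(
    variants: pd.DataFrame,
    target,
    cutoff: float = 10.0,
) -> pd.DataFrame:
    """Distance of each variant residue to the nearest residue of any other
    subunit in an assembled model.

    ``target`` is a Structure or a (CoarseModel, coords) pair. A variant is
    ``proximal`` when that distance is <= cutoff (default 10 Å); the nearest
    partner subunit is reported. Variant residues absent from the model
    (disordered regions) are reported with ``mapped = False``.
    """
    table = _residue_lookup(target)
    by_protein: dict[str, np.ndarray] = {}
    for (prot, _), xyz in table.items():
        by_protein.setdefault(prot, []).append(xyz)
    by_protein = {p: np.asarray(x) for p, x in by_protein.items()}

    rows = []
    for _, var in variants.iterrows():
        key = (var["protein"], int(var["residue"]))
        pos = table.get(key)
        if pos is None:
            rows.append({**var.to_dict(), "mapped": False, "nearest_distance":
                         np.nan, "nearest_partner": None, "proximal": False})
            continue
        best_d, best_p = np.inf, None
        for prot, xyz in by_protein.items():
            if prot == var["protein"]:
                continue
            d = float(np.sqrt(((xyz - pos) ** 2).sum(axis=1)).min())
            if d < best_d:
                best_d, best_p = d, prot
        rows.append({
            **var.to_dict(), "mapped": True,
            "nearest_distance": best_d if np.isfinite(best_d) else np.nan,
            "nearest_partner": best_p,
            "proximal": bool(best_d <= cutoff),
        })
    return pd.DataFrame(rows)
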