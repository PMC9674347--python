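"""Small rigid-geometry helpers: weighted Kabsch superposition, RMSD,
uniform random rotations."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["kabsch", "superpose", "rmsd", "random_rotation", "rotation_angle"]


def kabsch(
    ref: np.ndarray, mobile: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (R, t) with mobile ≈ R @ ref + t.

    Proper rotation only (det +1); ``weights`` are per-point and default to
    uniform.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if weights is None:
        w = np.ones(len(ref))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu_r = w @ ref
    mu_m = w @ mobile
    H = (ref - mu_r).T @ ((mobile - mu_m) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_m - R @ mu_r
    return R, t


def superpose(
    ref: np.ndarray, mobile: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Return ``mobile`` superposed onto ``ref`` by weighted least squares."""
    R, t = kabsch(mobile, ref, weights=weights)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted root-mean-square deviation between matched point sets."""
    d2 = np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn from the uniform (Haar) distribution on SO(3)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle (radians) of a rotation matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))
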