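"""Low-level 3D geometry helpers (internal).

All functions operate on numpy float arrays of shape (3,) or (n, 3) in
Angstrom / degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle",
    "dihedral",
    "kabsch_rmsd",
    "kabsch_rotation",
    "place_atom",
    "rmsd",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float))
    w = _unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(u @ w, -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(-y, x)))


def place_atom(a, b, c, bond: float, theta: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C with |CD| = bond, angle(B,C,D) = theta and
    torsion(A,B,C,D) = torsion (degrees).  Standard NeRF construction.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    th = np.radians(theta)
    ph = np.radians(torsion)
    # local displacement in the frame of the B->C bond
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(ph),
            bond * np.sin(th) * np.sin(ph),
        ]
    )
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Plain (unsuperposed) RMSD between matched coordinate sets."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError(f"coordinate shape mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation matrix R and centroids (cp, cq) such that
    ``(p - cp) @ R.T + cq`` superposes p onto q in the least-squares sense.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"need matched (n, 3) arrays, got {p.shape} and {q.shape}")
    cp = p.mean(axis=0)
    cq = q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    r = vt.T @ d @ u.T
    return r, cp, cq


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between p and q over all rigid superpositions."""
    r, cp, cq = kabsch_rotation(p, q)
    p2 = (np.asarray(p, float) - cp) @ r.T + cq
    return rmsd(p2, q)
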