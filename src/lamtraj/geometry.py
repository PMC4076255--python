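"""Periodic-boundary geometry primitives.

Orthorhombic boxes only.  All displacement-based analyses in the package go
through :func:`minimum_image_displacement`, so wrapped coordinates are safe
inputs everywhere; intramolecular geometry (dihedrals, bond vectors) is
computed on coordinates unwrapped with :func:`unwrap_group`.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image_displacement",
    "minimum_image_distance",
    "unwrap_group",
    "dihedral_angles",
    "rotation_aligning",
]


def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement ``b - a`` in an orthorhombic box.

    Broadcasts over leading axes.  Each component of the result lies in
    ``[-L/2, L/2)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ValueError("box lengths must be strictly positive")
    d = b - a
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Euclidean norm of the minimum-image displacement."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def unwrap_group(coords: np.ndarray, box) -> np.ndarray:
    """Unwrap a connected group of atoms relative to its first atom.

    ``coords`` has shape ``(..., n_atoms, 3)``; successive atoms are assumed
    bonded (or at least closer than half a box length), as is the case for
    the atom ordering within one lipid.  Returns coordinates in which
    consecutive displacements are minimum-image, anchored at atom 0.
    """
    coords = np.asarray(coords, dtype=np.float64)
    steps = minimum_image_displacement(coords[..., :-1, :], coords[..., 1:, :], box)
    out = np.empty_like(coords)
    out[..., 0, :] = coords[..., 0, :]
    out[..., 1:, :] = coords[..., 0:1, :] + np.cumsum(steps, axis=-2)
    return out


def dihedral_angles(p1, p2, p3, p4, degrees: bool = True) -> np.ndarray:
    """Signed torsion angle of four points, in ``(-180, 180]`` degrees.

    Uses the atan2 construction; broadcasts over leading axes.  The trans
    conformation of a straight alkane fragment maps to +180.  Raises if any
    consecutive triple is collinear (the torsion is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    scale = np.linalg.norm(b2, axis=-1) * np.maximum(
        np.linalg.norm(b1, axis=-1), np.linalg.norm(b3, axis=-1)
    )
    if np.any(norm1 <= 1e-10 * scale) or np.any(norm2 <= 1e-10 * scale):
        raise ValueError("collinear atoms: dihedral undefined")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2u)
    ang = np.arctan2(y, x)
    if degrees:
        ang = np.degrees(ang)
        # map -180 to +180 so the range is (-180, 180]
        ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def rotation_aligning(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation matrices mapping unit vectors ``v_from`` onto ``v_to``.

    Batched over the leading axis: inputs ``(n, 3)``, output ``(n, 3, 3)``.
    The rotation axis is ``v_from x v_to`` (minimal-angle rotation); the
    antiparallel case rotates by pi about an arbitrary perpendicular axis.
    """
    v_from = np.asarray(v_from, dtype=np.float64)
    v_to = np.asarray(v_to, dtype=np.float64)
    single = v_from.ndim == 1
    if single:
        v_from = v_from[None]
        v_to = v_to[None]
    a = v_from / np.linalg.norm(v_from, axis=-1, keepdims=True)
    b = v_to / np.linalg.norm(v_to, axis=-1, keepdims=True)
    axis = np.cross(a, b)
    s2 = np.einsum("ni,ni->n", axis, axis)
    c = np.einsum("ni,ni->n", a, b)
    n = a.shape[0]
    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    K = np.zeros((n, 3, 3))
    K[:, 0, 1] = -axis[:, 2]
    K[:, 0, 2] = axis[:, 1]
    K[:, 1, 0] = axis[:, 2]
    K[:, 1, 2] = -axis[:, 0]
    K[:, 2, 0] = -axis[:, 1]
    K[:, 2, 1] = axis[:, 0]
    ok = s2 > 1e-24
    factor = np.zeros(n)
    factor[ok] = (1.0 - c[ok]) / s2[ok]
    R = eye + K + factor[:, None, None] * (K @ K)
    # degenerate: parallel (identity already) or antiparallel (rotate by pi)
    anti = (~ok) & (c < 0)
    if np.any(anti):
        for i in np.nonzero(anti)[0]:
            # any unit vector perpendicular to a[i]
            p = np.cross(a[i], [1.0, 0.0, 0.0])
            if np.dot(p, p) < 1e-12:
                p = np.cross(a[i], [0.0, 1.0, 0.0])
            p /= np.linalg.norm(p)
            R[i] = 2.0 * np.outer(p, p) - np.eye(3)
    return R[0] if single else R
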