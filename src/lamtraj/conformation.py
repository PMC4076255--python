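"""Chain conformation: gauche/trans rotamers, tilt distributions, protrusion.

The rotamer state of a C-C-C-C torsion uses the standard three-fold alkane
split: trans for |theta| >= 120 deg, gauche+ for 0 < theta < 120, gauche-
otherwise (the boundary 120 deg counts as trans).  Gauche+ and gauche- are
pooled into a single P(gauche) per dihedral and leaflet, but both are kept
in the output.

Chain tilt uses the vector between the midpoints of the first and last
carbon pairs of a chain (C71-C72 to C81-C82 for a 12-carbon sn-1 chain;
C83-C84 to C91-C92 for a 10-carbon sn-2 chain) against the fixed +z layer
normal.  A tilt of 0 deg means the chain vector is aligned with the normal;
180 deg means it has flipped over.  A lipid-frame is classified as
*protruding* when its chain angle falls in a configurable window (default
[70, 180] deg for leaflets whose chains point along +z, mirrored for the
others) -- i.e. the chain points sideways or back into the headgroup region.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import dihedral_angles, unwrap_group
from .model import AnalysisWindow, LeafletAssignment, TopologyRoleMap, Trajectory

__all__ = [
    "compute_dihedral",
    "classify_conformer",
    "chain_dihedral_labels",
    "compute_chain_dihedrals",
    "GaucheProfile",
    "compute_gauche_profile",
    "compute_chain_vectors",
    "TiltDistribution",
    "compute_tilt_distribution",
    "classify_protruding",
]

GAUCHE_BOUNDARY_DEG = 120.0


def compute_dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Signed torsion angle in (-180, 180] degrees (atan2 construction)."""
    return dihedral_angles(p1, p2, p3, p4)


def classify_conformer(theta) -> np.ndarray:
    """Rotamer state(s) of torsion angle(s): 'trans', 'gauche_plus', 'gauche_minus'."""
    theta = np.asarray(theta, dtype=np.float64)
    out = np.where(
        np.abs(theta) >= GAUCHE_BOUNDARY_DEG,
        "trans",
        np.where(theta > 0, "gauche_plus", "gauche_minus"),
    )
    return out if out.ndim else out[()]


def chain_dihedral_labels(role_map: TopologyRoleMap, chain: str = "sn1") -> list[str]:
    """Labels like 'C71-C74', naming the first and fourth carbon of each torsion."""
    names = role_map.chain_carbon_names(chain)
    return [f"{names[k]}-{names[k + 3]}" for k in range(len(names) - 3)]


def compute_chain_dihedrals(
    traj: Trajectory,
    role_map: TopologyRoleMap,
    chain: str = "sn1",
    window: AnalysisWindow | None = None,
) -> tuple[np.ndarray, list[str]]:
    """All chain torsions; returns (angles (F, L, n_dihedral) deg, labels)."""
    sub = traj.window(window)
    carbons = role_map.chain_carbon_matrix(chain)  # (L, nC)
    if carbons.shape[1] < 4:
        raise ValueError(f"chain {chain} declares fewer than 4 carbons")
    coords = sub.coords[:, carbons, :]  # (F, L, nC, 3)
    coords = np.stack(
        [unwrap_group(coords[f], sub.box[f]) for f in range(sub.n_frames)]
    )
    ang = dihedral_angles(
        coords[:, :, :-3], coords[:, :, 1:-2], coords[:, :, 2:-1], coords[:, :, 3:]
    )
    return ang, chain_dihedral_labels(role_map, chain)


@dataclass
class GaucheProfile:
    """Per-dihedral, per-leaflet gauche populations with binomial errors."""

    labels: list[str]
    leaflets: list[int]
    p_gauche: np.ndarray  # (n_dihedral, n_leaflets)
    p_gauche_plus: np.ndarray
    p_gauche_minus: np.ndarray
    counts: np.ndarray  # (n_dihedral, n_leaflets) sample sizes
    chain: str = "sn1"

    @property
    def se(self) -> np.ndarray:
        p = self.p_gauche
        return np.sqrt(np.maximum(p * (1 - p), 0.0) / np.maximum(self.counts, 1))

    @property
    def p_trans(self) -> np.ndarray:
        return 1.0 - self.p_gauche

    def chain_average(self, leaflet: int | None = None) -> float:
        """Mean P(gauche) over dihedrals, in one leaflet or overall."""
        if leaflet is None:
            tot = (self.p_gauche * self.counts).sum(axis=1) / self.counts.sum(axis=1)
            return float(tot.mean())
        j = self.leaflets.index(leaflet)
        return float(self.p_gauche[:, j].mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.labels):
            for j, leaf in enumerate(self.leaflets):
                rows.append(
                    {
                        "chain": self.chain,
                        "dihedral_label": lab,
                        "leaflet": leaf,
                        "p_gauche": self.p_gauche[i, j],
                        "p_gauche_plus": self.p_gauche_plus[i, j],
                        "p_gauche_minus": self.p_gauche_minus[i, j],
                        "se": self.se[i, j],
                        "n": int(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def compute_gauche_profile(
    traj: Trajectory,
    role_map: TopologyRoleMap,
    leaflets: LeafletAssignment,
    window: AnalysisWindow | None = None,
    chain: str = "sn1",
) -> GaucheProfile:
    """Fraction of gauche conformers per dihedral and leaflet.

    The fraction counts lipid-frames classified gauche (pooling gauche+ and
    gauche-) over the analysis window.
    """
    angles, labels = compute_chain_dihedrals(traj, role_map, chain, window)
    if angles.shape[0] == 0:
        raise ValueError("empty analysis window")
    states = classify_conformer(angles)  # (F, L, nd)
    leaf_ids = sorted(set(int(l) for l in leaflets.labels))
    nd = len(labels)
    p = np.zeros((nd, len(leaf_ids)))
    pp = np.zeros_like(p)
    pm = np.zeros_like(p)
    counts = np.zeros_like(p)
    for j, leaf in enumerate(leaf_ids):
        lipids = leaflets.lipids_in(leaf)
        s = states[:, lipids, :]  # (F, nl, nd)
        n = s.shape[0] * s.shape[1]
        pp[:, j] = (s == "gauche_plus").sum(axis=(0, 1)) / n
        pm[:, j] = (s == "gauche_minus").sum(axis=(0, 1)) / n
        p[:, j] = pp[:, j] + pm[:, j]
        counts[:, j] = n
    return GaucheProfile(
        labels=labels,
        leaflets=leaf_ids,
        p_gauche=p,
        p_gauche_plus=pp,
        p_gauche_minus=pm,
        counts=counts,
        chain=chain,
    )


def compute_chain_vectors(
    traj: Trajectory,
    role_map: TopologyRoleMap,
    chain: str = "sn1",
    window: AnalysisWindow | None = None,
) -> np.ndarray:
    """Unit chain vectors, shape (F, L, 3).

    The vector runs from the midpoint of the first two chain carbons to the
    midpoint of the last two (C71-C72 -> C81-C82 for sn-1).
    """
    sub = traj.window(window)
    carbons = role_map.chain_carbon_matrix(chain)
    coords = sub.coords[:, carbons, :]  # (F, L, nC, 3)
    # unwrap along the bonded chain so wrapped lipids give correct midpoints
    coords = np.stack(
        [unwrap_group(coords[f], sub.box[f]) for f in range(sub.n_frames)]
    )
    v = 0.5 * (coords[:, :, -2] + coords[:, :, -1]) - 0.5 * (
        coords[:, :, 0] + coords[:, :, 1]
    )
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise ValueError("coincident chain midpoints: chain vector undefined")
    return v / norm


@dataclass
class TiltDistribution:
    """Per-leaflet histograms of the chain-vector angle to +z, [0, 180] deg."""

    bin_centers: np.ndarray
    bin_width: float
    counts: dict[int, np.ndarray]  # leaflet -> (n_bins,)
    peaks: dict[int, list[float]] = field(default_factory=dict)

    @property
    def total_counts(self) -> np.ndarray:
        return np.sum(list(self.counts.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for leaf, c in self.counts.items():
            for center, n in zip(self.bin_centers, c):
                rows.append(
                    {"leaflet": leaf, "bin_center_deg": center, "count": int(n)}
                )
        return pd.DataFrame(rows)


def _smoothed_peaks(
    counts: np.ndarray, centers: np.ndarray, rel_height: float = 0.05
) -> list[float]:
    """Local maxima of the 3-bin moving average, descending by height."""
    if counts.sum() == 0:
        return []
    padded = np.pad(counts.astype(float), 1, mode="edge")
    smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    thresh = rel_height * smooth.max()
    found = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        if smooth[i] > left and smooth[i] >= right and smooth[i] > thresh:
            found.append((smooth[i], centers[i]))
    found.sort(key=lambda t: -t[0])
    return [angle for _, angle in found]


def compute_tilt_distribution(
    vectors: np.ndarray,
    leaflets: LeafletAssignment,
    bin_width: float = 2.0,
) -> TiltDistribution:
    """Histogram chain-vector angles to +z per leaflet and detect peaks.

    ``vectors`` has shape (F, L, 3) (or (L, 3) for one frame).  Peaks are
    local maxima of the 3-bin moving average, reported in descending height.
    """
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim == 2:
        v = v[None]
    if v.size == 0:
        raise ValueError("no vectors")
    if bin_width <= 0 or bin_width > 180:
        raise ValueError("bin width must be in (0, 180]")
    theta = np.degrees(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))  # (F, L)
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts: dict[int, np.ndarray] = {}
    peaks: dict[int, list[float]] = {}
    for leaf in sorted(set(int(l) for l in leaflets.labels)):
        lipids = leaflets.lipids_in(leaf)
        th = np.minimum(theta[:, lipids].ravel(), 180.0 - 1e-12)
        h, _ = np.histogram(th, bins=edges)
        counts[leaf] = h
        peaks[leaf] = _smoothed_peaks(h, centers)
    return TiltDistribution(
        bin_centers=centers, bin_width=bin_width, counts=counts, peaks=peaks
    )


def classify_protruding(
    vectors: np.ndarray,
    leaflets: LeafletAssignment,
    theta_lo: float = 70.0,
    theta_hi: float = 180.0,
) -> dict[int, float]:
    """Fraction of protruding lipid-frames per leaflet.

    A lipid-frame protrudes when its chain angle to +z lies in
    ``[theta_lo, theta_hi]`` for leaflets whose chains point along +z, or in
    the mirrored window ``[180 - theta_hi, 180 - theta_lo]`` otherwise.
    Leaflet orientation comes from ``leaflets.normals`` (+z assumed when
    absent).
    """
    if not 0.0 < theta_lo < theta_hi <= 180.0:
        raise ValueError("need 0 < theta_lo < theta_hi <= 180")
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim == 2:
        v = v[None]
    theta = np.degrees(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))
    out: dict[int, float] = {}
    for leaf in sorted(set(int(l) for l in leaflets.labels)):
        lipids = leaflets.lipids_in(leaf)
        th = theta[:, lipids]
        normal = 1.0
        if leaflets.normals is not None:
            normal = float(leaflets.normals[leaf - 1])
        if normal >= 0:
            mask = (th >= theta_lo) & (th <= theta_hi)
        else:
            mask = (th >= 180.0 - theta_hi) & (th <= 180.0 - theta_lo)
        out[leaf] = float(mask.mean())
    return out
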