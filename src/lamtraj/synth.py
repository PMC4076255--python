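"""Synthetic trajectories with known statistical structure.

The study system -- an anhydrous double bilayer of sugar-headgroup lipids,
four leaflets of 64 lipids on an 8x8 in-plane lattice, chains pre-tilted
~15 deg to the layer normal -- is emulated by :func:`make_lamellar_trajectory`
with controllable per-dihedral gauche probability, tilt-mode mixture,
lattice packing and lamellar repeat spacing.  Every sampled quantity
(dihedral rotamer states, tilt angles, leaflet membership) is recorded in a
:class:`GroundTruth` object, so the expected value of each downstream
estimator is known without re-simulation.

Separate, narrower generators provide analytic oracles for individual
stages: isotropic rotational Brownian motion of unit vectors (closed form
``C2(t) = exp(-6 D_r t)``), a jittered hexagonal slab (RDF first maximum at
the lattice constant), a periodic density stack (known d-spacing), and a
chain whose C-H vectors diffuse with per-carbon rates (closed form
``tau = 1/(6 D_r)`` per carbon).

Chains are built with ideal geometry -- 1.53 Å C-C bonds, 111 deg angles,
dihedrals exactly 180/+60/-60 deg plus optional jitter -- because the
analyses consume only angles and distances.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import rotation_aligning
from .model import AtomRecord, TopologyRoleMap, Trajectory

__all__ = [
    "LamellarSpec",
    "RotDiffSpec",
    "GroundTruth",
    "make_lamellar_trajectory",
    "simulate_rotational_diffusion",
    "make_hex_lattice_slab",
    "make_density_trajectory",
    "make_ch_diffusion_trajectory",
]

BOND_CC = 1.53
BOND_CH = 1.09
BOND_OC = 1.43
ANGLE_CCC = 111.0
#: axial (z) and lateral offsets of the rigid pseudo-disaccharide headgroup,
#: in the lipid frame with the chain extending toward +axial.  The ordering
#: is O1 (glycosidic oxygen, nearest the chain), C1, C4, C1', C4'.
HEAD_ATOMS = (
    ("O1", "headgroup_atom", None, (0.0, 0.0, 2.4)),
    ("C1", "ring_anchor", "C1", (0.8, 0.0, 1.2)),
    ("C4", "ring_anchor", "C4", (-0.5, 0.9, 0.0)),
    ("C1'", "ring_anchor", "C1p", (0.6, -0.7, -1.2)),
    ("C4'", "ring_anchor", "C4p", (-0.3, 0.5, -2.4)),
)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class LamellarSpec:
    """Parameters of the synthetic double-bilayer lamellar system.

    Defaults reproduce the study conditions: 4 leaflets of 64 lipids (8x8),
    a 12-carbon sn-1 chain, ~15 deg chain pre-tilt, per-dihedral gauche
    probability 0.16 (the maltoside chain average), lattice constant
    6.28 Å (area per lipid 39.4 Ų) and repeat spacing 32.2 Å.
    """

    lipids_per_leaflet: int = 64
    n_leaflets: int = 4
    sn1_carbons: int = 12
    sn2_carbons: int | None = None
    tilt_modes: tuple[tuple[float, float, float], ...] = ((15.0, 2.0, 1.0),)
    gauche_p: float | tuple[float, ...] = 0.16
    gauche_p_sn2: float | tuple[float, ...] | None = None
    dihedral_jitter_sd: float = 0.0
    headgroup_width: float = 0.6  # slab width; Gaussian sd = width / 2
    headgroup_atom_jitter_sd: float = 0.8
    headgroup_pair_gap: float = 5.0
    d_spacing: float = 32.2
    lattice_a: float = 6.28
    xy_jitter_sd: float = 0.3
    n_frames: int = 50
    dt_ps: float = 5.0
    exact_tilt_fractions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet < 1 or self.n_leaflets < 1:
            raise ValueError("lipid and leaflet counts must be positive")
        if self.n_leaflets % 2:
            raise ValueError("leaflet count must be even (stacked bilayers)")
        if self.sn1_carbons < 4:
            raise ValueError("sn-1 chain needs at least 4 carbons")
        if self.sn2_carbons is not None and self.sn2_carbons < 4:
            raise ValueError("sn-2 chain needs at least 4 carbons")
        w = [m[2] for m in self.tilt_modes]
        if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValueError("tilt mode weights must be nonnegative and sum to 1")
        for p in np.atleast_1d(self.gauche_probabilities("sn1")):
            if not 0.0 <= p <= 1.0:
                raise ValueError("gauche probabilities must lie in [0, 1]")
        if self.d_spacing <= 0 or self.lattice_a <= 0:
            raise ValueError("spacing and lattice constant must be positive")
        if self.n_frames < 1 or self.dt_ps <= 0:
            raise ValueError("need n_frames >= 1 and dt_ps > 0")

    @property
    def n_side(self) -> int:
        n = int(round(np.sqrt(self.lipids_per_leaflet)))
        return n if n * n == self.lipids_per_leaflet else -1

    def n_dihedrals(self, chain: str) -> int:
        n = self.sn1_carbons if chain == "sn1" else (self.sn2_carbons or 0)
        return max(n - 3, 0)

    def gauche_probabilities(self, chain: str) -> np.ndarray:
        nd = self.n_dihedrals(chain)
        p = self.gauche_p if chain == "sn1" else (
            self.gauche_p_sn2 if self.gauche_p_sn2 is not None else self.gauche_p
        )
        arr = np.atleast_1d(np.asarray(p, dtype=float))
        if arr.size == 1:
            return np.full(nd, float(arr[0]))
        if arr.size != nd:
            raise ValueError(
                f"{chain}: expected {nd} per-dihedral probabilities, got {arr.size}"
            )
        return arr.astype(float)


@dataclass
class RotDiffSpec:
    """Isotropic rotational Brownian motion of independent unit vectors."""

    d_r: float  # rotational diffusion coefficient, 1/ps
    dt_ps: float
    n_frames: int
    n_vectors: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_r < 0:
            raise ValueError("D_r must be >= 0")
        if self.dt_ps <= 0:
            raise ValueError("frame interval must be positive")
        if self.n_frames < 1 or self.n_vectors < 1:
            raise ValueError("need at least one frame and one vector")
        if self.d_r * self.dt_ps > 0.1:
            raise ValueError(
                "D_r * dt > 0.1: small-step rotational update is invalid"
            )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the lamellar generator sampled, frame by frame.

    ``tilt_deg[chain]`` is the chain-vector angle to the global +z axis;
    ``tilt_relative_deg[chain]`` is the angle to the leaflet's own chain
    axis (what the tilt modes parameterise).  ``dihedral_states[chain]``
    codes 0 = trans, 1 = gauche+, 2 = gauche-.
    """

    leaflet_labels: np.ndarray  # (n_lipids,) 1..k
    leaflet_normals: np.ndarray  # (k,) +1/-1 chain direction along z
    tilt_deg: dict = field(default_factory=dict)  # chain -> (F, L)
    tilt_relative_deg: dict = field(default_factory=dict)
    dihedral_states: dict = field(default_factory=dict)  # chain -> (F, L, nd)
    gauche_p: dict = field(default_factory=dict)  # chain -> (nd,)

    def gauche_fraction(self, chain: str = "sn1") -> np.ndarray:
        """Realised per-dihedral gauche fraction over all frames and lipids."""
        s = self.dihedral_states[chain]
        return (s != 0).mean(axis=(0, 1))

    def protruding_fraction(
        self, chain: str = "sn1", theta_lo: float = 70.0, theta_hi: float = 180.0
    ) -> float:
        """Fraction of lipid-frames whose relative tilt lies in the window."""
        rel = self.tilt_relative_deg[chain]
        return float(((rel >= theta_lo) & (rel <= theta_hi)).mean())

    def to_json(self, path) -> None:
        data = {
            "leaflet_labels": self.leaflet_labels.tolist(),
            "leaflet_normals": self.leaflet_normals.tolist(),
            "gauche_p": {k: v.tolist() for k, v in self.gauche_p.items()},
            "tilt_deg": {k: v.tolist() for k, v in self.tilt_deg.items()},
            "tilt_relative_deg": {
                k: v.tolist() for k, v in self.tilt_relative_deg.items()
            },
            "dihedral_states": {
                k: v.tolist() for k, v in self.dihedral_states.items()
            },
        }
        Path(path).write_text(json.dumps(data))


# ---------------------------------------------------------------------------
# Ideal-geometry chain construction (batched NeRF)
# ---------------------------------------------------------------------------

def build_chains(dihedrals_deg: np.ndarray, bond: float = BOND_CC,
                 angle_deg: float = ANGLE_CCC) -> np.ndarray:
    """Build alkane backbones from torsions; shape (L, nd) -> (L, nd+3, 3).

    Atom 0 sits at the origin, atom 1 along +z; torsion k places atom k+3.
    """
    dih = np.radians(np.asarray(dihedrals_deg, dtype=np.float64))
    L, nd = dih.shape
    n = nd + 3
    theta = np.radians(angle_deg)
    pos = np.zeros((L, n, 3))
    pos[:, 1, 2] = bond
    # atom 2: bond angle at atom 1 between (p0 - p1) and (p2 - p1)
    pos[:, 2] = pos[:, 1] + bond * np.array(
        [np.sin(np.pi - theta), 0.0, np.cos(np.pi - theta)]
    )
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    for k in range(nd):
        A, B, C = pos[:, k], pos[:, k + 1], pos[:, k + 2]
        bc = C - B
        bc /= np.linalg.norm(bc, axis=1, keepdims=True)
        ab = B - A
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        m = np.cross(nrm, bc)
        phi = dih[:, k]
        d = (
            -cos_t * bc
            + sin_t * np.cos(phi)[:, None] * m
            + sin_t * np.sin(phi)[:, None] * nrm
        )
        pos[:, k + 3] = C + bond * d
    return pos


def methylene_hydrogens(chain: np.ndarray, bond: float = BOND_CH) -> np.ndarray:
    """Two hydrogens per carbon, perpendicular to the local C-C-C plane.

    ``chain`` has shape (L, nC, 3); the result has shape (L, nC, 2, 3).
    Terminal carbons use the plane of the three nearest backbone atoms.
    """
    L, nc, _ = chain.shape
    prev = np.empty_like(chain)
    nxt = np.empty_like(chain)
    prev[:, 1:] = chain[:, :-1]
    prev[:, 0] = chain[:, 2]  # C0 uses plane of (C2, C0, C1)
    nxt[:, :-1] = chain[:, 1:]
    nxt[:, -1] = chain[:, -3]  # last uses plane of (Cn-3, Cn-1, Cn-2)
    u = prev - chain
    v = nxt - chain
    nrm = np.cross(u, v)
    nrm /= np.linalg.norm(nrm, axis=2, keepdims=True)
    h = np.empty((L, nc, 2, 3))
    h[:, :, 0] = chain + bond * nrm
    h[:, :, 1] = chain - bond * nrm
    return h


# ---------------------------------------------------------------------------
# Lamellar generator
# ---------------------------------------------------------------------------

def _role_template(spec: LamellarSpec) -> list[AtomRecord]:
    recs = [
        AtomRecord(0, name, role, anchor=anchor)
        for name, role, anchor, _ in HEAD_ATOMS
    ]
    for chain, n, first in (
        ("sn1", spec.sn1_carbons, 71),
        ("sn2", spec.sn2_carbons or 0, 83),
    ):
        for k in range(n):
            cname = f"C{first + k}"
            recs.append(AtomRecord(0, cname, "chain_carbon", chain=chain))
            recs.append(
                AtomRecord(0, f"H{first + k}A", "chain_hydrogen", parent=cname)
            )
            recs.append(
                AtomRecord(0, f"H{first + k}B", "chain_hydrogen", parent=cname)
            )
    return recs


def _sample_dihedral_angles(
    rng: np.random.Generator, p: np.ndarray, L: int, jitter_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample rotamer states and angles for L chains; states (L, nd)."""
    nd = p.size
    u = rng.random((L, nd))
    gauche = u < p[None, :]
    sign = rng.random((L, nd)) < 0.5
    states = np.zeros((L, nd), dtype=np.int8)
    states[gauche & sign] = 1
    states[gauche & ~sign] = 2
    angles = np.where(states == 0, 180.0, np.where(states == 1, 60.0, -60.0))
    if jitter_sd > 0:
        angles = angles + rng.normal(0.0, jitter_sd, (L, nd))
    return states, angles


def _sample_tilts(
    rng: np.random.Generator, spec: LamellarSpec, L: int
) -> np.ndarray:
    """Sample per-lipid tilt angles (deg, relative to the leaflet axis)."""
    modes = spec.tilt_modes
    w = np.array([m[2] for m in modes])
    if spec.exact_tilt_fractions:
        counts = np.floor(w * L).astype(int)
        # distribute remainder to the heaviest modes deterministically
        for i in np.argsort(-w)[: L - counts.sum()]:
            counts[i] += 1
        which = np.repeat(np.arange(len(modes)), counts)
        rng.shuffle(which)
    else:
        which = rng.choice(len(modes), size=L, p=w / w.sum())
    means = np.array([m[0] for m in modes])[which]
    sds = np.array([m[1] for m in modes])[which]
    return np.clip(rng.normal(means, sds), 0.0, 180.0)


def _angles_between_z(v: np.ndarray) -> np.ndarray:
    return np.degrees(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))


def _chain_vector(chain: np.ndarray) -> np.ndarray:
    """Unit vector mid(C_0-C_1) -> mid(C_{n-2}-C_{n-1}); (L, nC, 3) -> (L, 3)."""
    v = 0.5 * (chain[:, -2] + chain[:, -1]) - 0.5 * (chain[:, 0] + chain[:, 1])
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_lamellar_trajectory(
    spec: LamellarSpec,
) -> tuple[Trajectory, TopologyRoleMap, GroundTruth]:
    """Generate the double-bilayer system plus its ground-truth record.

    Per frame, each lipid's chain torsions are resampled independently from
    the per-dihedral gauche probabilities (gauche fraction is a marginal
    statistic; temporal correlation is exercised by the rotational-diffusion
    generator), the whole chain is rotated to a freshly sampled tilt angle
    about a uniform azimuth, and the lipid is planted on its lattice site
    with small in-plane and slab jitters.  Deterministic for a fixed seed.
    """
    n_side = spec.n_side
    if n_side < 0:
        raise ValueError("lipids_per_leaflet must be a perfect square (n x n grid)")
    rng = np.random.default_rng(spec.seed)
    L_leaf = spec.lipids_per_leaflet
    n_lip = L_leaf * spec.n_leaflets
    d = spec.d_spacing
    lx = ly = n_side * spec.lattice_a
    lz = (spec.n_leaflets // 2) * d
    box = np.array([lx, ly, lz])

    chains = [("sn1", spec.sn1_carbons)]
    if spec.sn2_carbons:
        chains.append(("sn2", spec.sn2_carbons))
    max_extent = max(
        (n - 1) * BOND_CC * np.sin(np.radians(ANGLE_CCC) / 2) for _, n in chains
    )
    if max_extent > lz / 2:
        raise ValueError(
            f"chain extent {max_extent:.1f} Å exceeds half the box height;"
            " enlarge the repeat spacing"
        )

    template = _role_template(spec)
    role_map = TopologyRoleMap.from_template(n_lip, template)
    per_lipid = len(template)
    n_atoms = per_lipid * n_lip

    # leaflet bookkeeping: headgroup planes sit g/2 either side of each
    # lamellar interface (z = 0, d, ...); chains point into the bilayer.
    g = spec.headgroup_pair_gap
    leaf_z = np.empty(spec.n_leaflets)
    leaf_dir = np.empty(spec.n_leaflets)
    for b in range(spec.n_leaflets // 2):
        leaf_z[2 * b] = b * d + g / 2.0
        leaf_dir[2 * b] = +1.0
        leaf_z[2 * b + 1] = (b + 1) * d - g / 2.0
        leaf_dir[2 * b + 1] = -1.0
    labels = np.repeat(np.arange(1, spec.n_leaflets + 1), L_leaf)
    lipid_dir = leaf_dir[labels - 1]
    lipid_z = leaf_z[labels - 1]

    # lattice sites (shared by all leaflets)
    ii, jj = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    site = np.stack(
        [(ii.ravel() + 0.5) * spec.lattice_a, (jj.ravel() + 0.5) * spec.lattice_a],
        axis=1,
    )
    sites = np.tile(site, (spec.n_leaflets, 1))

    head_local = np.array([a[3] for a in HEAD_ATOMS])  # lipid frame, chain at +z
    head_center = head_local.mean(axis=0)
    head_local = head_local - head_center  # centre at origin
    o1_local = head_local[0]

    coords = np.empty((spec.n_frames, n_atoms, 3))
    gt = GroundTruth(
        leaflet_labels=labels,
        leaflet_normals=leaf_dir.copy(),
    )
    for cname, _ in chains:
        nd = spec.n_dihedrals(cname)
        gt.dihedral_states[cname] = np.empty(
            (spec.n_frames, n_lip, nd), dtype=np.int8
        )
        gt.tilt_deg[cname] = np.empty((spec.n_frames, n_lip))
        gt.tilt_relative_deg[cname] = np.empty((spec.n_frames, n_lip))
        gt.gauche_p[cname] = spec.gauche_probabilities(cname)

    # atom index layout inside one lipid
    head_slice = slice(0, len(HEAD_ATOMS))
    offs = len(HEAD_ATOMS)
    chain_layout = {}
    for cname, nC in chains:
        c_idx = offs + 3 * np.arange(nC)
        h_idx = np.stack([c_idx + 1, c_idx + 2], axis=1)
        chain_layout[cname] = (c_idx, h_idx)
        offs += 3 * nC

    for f in range(spec.n_frames):
        frame = np.empty((n_atoms, 3))
        # whole-lipid placement
        xy = sites + rng.normal(0.0, spec.xy_jitter_sd, sites.shape)
        zc = lipid_z + rng.normal(0.0, spec.headgroup_width / 2.0, n_lip)
        origin = np.column_stack([xy, zc])  # headgroup centre per lipid

        # headgroup atoms: mirrored along z for down-pointing leaflets
        hl = head_local[None, :, :] * np.array([1.0, 1.0, 1.0])
        head = np.repeat(hl, n_lip, axis=0)
        head[:, :, 2] *= lipid_dir[:, None]
        head = head + origin[:, None, :]
        if spec.headgroup_atom_jitter_sd > 0:
            head = head + rng.normal(
                0.0, spec.headgroup_atom_jitter_sd, head.shape
            )

        # chain anchor: ideal O1 position extended along the chain direction
        o1 = origin + np.outer(lipid_dir, [0, 0, 1]) * o1_local[2] + np.array(
            [o1_local[0], o1_local[1], 0.0]
        )
        anchor = o1 + np.outer(lipid_dir * BOND_OC, [0.0, 0.0, 1.0])

        for cname, nC in chains:
            nd = spec.n_dihedrals(cname)
            p = gt.gauche_p[cname]
            states, angles = _sample_dihedral_angles(
                rng, p, n_lip, spec.dihedral_jitter_sd
            )
            chain = build_chains(angles)
            v0 = _chain_vector(chain)
            theta_rel = _sample_tilts(rng, spec, n_lip)
            phi = rng.uniform(0.0, 2 * np.pi, n_lip)
            st = np.sin(np.radians(theta_rel))
            ct = np.cos(np.radians(theta_rel))
            target = np.column_stack(
                [st * np.cos(phi), st * np.sin(phi), ct * lipid_dir]
            )
            R = rotation_aligning(v0, target)
            chain = np.einsum("lij,lkj->lki", R, chain)
            hyd = methylene_hydrogens(chain)
            # sn-2 branches sideways near the chain start
            shift = anchor if cname == "sn1" else anchor + np.array([2.5, 0.0, 0.0])
            chain = chain + shift[:, None, :]
            hyd = hyd + shift[:, None, None, :]

            c_idx, h_idx = chain_layout[cname]
            base = np.arange(n_lip)[:, None] * per_lipid
            frame[(base + c_idx[None, :]).ravel()] = chain.reshape(-1, 3)
            frame[(base[:, :, None] + h_idx[None, :, :]).ravel()] = hyd.reshape(
                -1, 3
            )
            gt.dihedral_states[cname][f] = states
            gt.tilt_relative_deg[cname][f] = theta_rel
            gt.tilt_deg[cname][f] = _angles_between_z(target)

        base = np.arange(n_lip)[:, None] * per_lipid
        head_rows = (base + np.arange(len(HEAD_ATOMS))[None, :]).ravel()
        frame[head_rows] = head.reshape(-1, 3)
        coords[f] = np.mod(frame, box)

    times = np.arange(spec.n_frames) * spec.dt_ps
    names = [template[i % per_lipid].name for i in range(n_atoms)]
    traj = Trajectory(coords, np.tile(box, (spec.n_frames, 1)), times, names)
    return traj, role_map, gt


# ---------------------------------------------------------------------------
# Rotational diffusion of unit vectors
# ---------------------------------------------------------------------------

def simulate_rotational_diffusion(spec: RotDiffSpec) -> np.ndarray:
    """Isotropic rotational Brownian motion; returns (n_frames, n_vectors, 3).

    Each step applies a small rotation drawn as a 3-D Gaussian rotation
    vector with per-component variance ``2 D_r dt`` (uniform random axis,
    chi-distributed angle), which reproduces the closed form
    ``C2(t) = exp(-6 D_r t)`` in the small-step regime.  Vectors stay unit
    length to 1e-9 by construction (renormalised every step).
    """
    rng = np.random.default_rng(spec.seed)
    V, F = spec.n_vectors, spec.n_frames
    u = rng.normal(size=(V, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = np.empty((F, V, 3))
    out[0] = u
    sd = np.sqrt(2.0 * spec.d_r * spec.dt_ps)
    for f in range(1, F):
        if sd > 0:
            omega = rng.normal(0.0, sd, (V, 3))
            theta = np.linalg.norm(omega, axis=1, keepdims=True)
            safe = np.where(theta > 0, theta, 1.0)
            k = omega / safe
            ct = np.cos(theta)
            st = np.sin(theta)
            u = (
                u * ct
                + np.cross(k, u) * st
                + k * np.einsum("vi,vi->v", k, u)[:, None] * (1.0 - ct)
            )
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[f] = u
    return out


# ---------------------------------------------------------------------------
# Hexagonal slab (RDF oracle)
# ---------------------------------------------------------------------------

def make_hex_lattice_slab(
    a: float, n_side: int, jitter_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """2-D hexagonal lattice at fixed z; returns (points (N, 3), box (3,)).

    The box is commensurate with the lattice for even ``n_side`` (periodic
    continuation seamless); every point then has six neighbours at exactly
    ``a`` under minimum image when ``jitter_sd`` is 0.
    """
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    rows = cols = n_side
    row_h = a * np.sqrt(3.0) / 2.0
    pts = []
    for j in range(rows):
        for i in range(cols):
            pts.append([(i + 0.5 * (j % 2)) * a, j * row_h, 0.0])
    pts_arr = np.array(pts)
    box = np.array([cols * a, max(rows, 1) * row_h, max(cols * a, rows * row_h)])
    pts_arr[:, 2] = box[2] / 2.0
    if jitter_sd > 0:
        pts_arr[:, :2] += rng.normal(0.0, jitter_sd, (len(pts_arr), 2))
    return pts_arr, box


# ---------------------------------------------------------------------------
# Periodic density stack (LDP / d-spacing oracle)
# ---------------------------------------------------------------------------

def make_density_trajectory(
    d: float,
    headgroup_width: float,
    n_frames: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    repeats: int = 2,
    heads_per_plane: int = 400,
    fillers_per_slab: int = 400,
    lxy: float = 30.0,
) -> tuple[Trajectory, TopologyRoleMap]:
    """Lamellar density stack with known repeat spacing ``d``.

    Headgroup atoms are Gaussian-distributed (sd ``headgroup_width``) about
    planes separated by ``d``; filler atoms occupy the interleaved slabs.
    Per-frame Gaussian noise (sd ``noise_sd``) resamples the positions.
    """
    if d <= 2 * headgroup_width:
        raise ValueError("repeat spacing must exceed twice the headgroup width")
    rng = np.random.default_rng(seed)
    lz = repeats * d
    box = np.array([lxy, lxy, lz])
    heads = []
    fillers = []
    for r in range(repeats):
        z0 = (r + 0.5) * d
        z = rng.normal(z0, headgroup_width, heads_per_plane)
        xy = rng.uniform(0, lxy, (heads_per_plane, 2))
        heads.append(np.column_stack([xy, z]))
        zf = rng.uniform(z0 + 2 * headgroup_width, z0 + d - 2 * headgroup_width,
                         fillers_per_slab)
        xyf = rng.uniform(0, lxy, (fillers_per_slab, 2))
        fillers.append(np.column_stack([xyf, zf]))
    base = np.vstack(heads + fillers)
    n_heads = repeats * heads_per_plane
    coords = np.empty((n_frames, len(base), 3))
    for f in range(n_frames):
        frame = base.copy()
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        coords[f] = np.mod(frame, box)
    atoms = [
        AtomRecord(0, "O1", "headgroup_atom") for _ in range(n_heads)
    ] + [AtomRecord(0, "C99", "other") for _ in range(len(base) - n_heads)]
    role_map = TopologyRoleMap(1, atoms)
    times = np.arange(n_frames, dtype=float)
    names = [a.name for a in atoms]
    return (
        Trajectory(coords, np.tile(box, (n_frames, 1)), times, names),
        role_map,
    )


# ---------------------------------------------------------------------------
# Chain with per-carbon C-H rotational diffusion (correlation-time oracle)
# ---------------------------------------------------------------------------

def make_ch_diffusion_trajectory(
    d_r_per_carbon,
    n_lipids: int = 4,
    n_frames: int = 2000,
    dt_ps: float = 1.0,
    seed: int = 0,
    d_r_rings: tuple[float, float, float] | None = None,
) -> tuple[Trajectory, TopologyRoleMap]:
    """Static chains whose C-H unit vectors diffuse with per-carbon rates.

    Carbon positions are frozen (all-trans backbone); each carbon's two
    hydrogens ride independent rotational-diffusion unit vectors with that
    carbon's ``D_r``, so each C-H correlation time has the closed form
    ``1/(6 D_r)``.  Optional ``d_r_rings = (D_ring1, D_ring2, D_ring12)``
    drives the three sugar ring vectors the same way.
    """
    d_r = np.asarray(d_r_per_carbon, dtype=float)
    nC = d_r.size
    if nC < 4 or nC > 12:
        raise ValueError("need between 4 and 12 chain carbons")
    template = [
        AtomRecord(0, "O1", "headgroup_atom"),
        AtomRecord(0, "C1", "ring_anchor", anchor="C1"),
        AtomRecord(0, "C4", "ring_anchor", anchor="C4"),
        AtomRecord(0, "C1'", "ring_anchor", anchor="C1p"),
        AtomRecord(0, "C4'", "ring_anchor", anchor="C4p"),
    ]
    for k in range(nC):
        cname = f"C{71 + k}"
        template.append(AtomRecord(0, cname, "chain_carbon", chain="sn1"))
        template.append(AtomRecord(0, f"H{71 + k}A", "chain_hydrogen", parent=cname))
        template.append(AtomRecord(0, f"H{71 + k}B", "chain_hydrogen", parent=cname))
    role_map = TopologyRoleMap.from_template(n_lipids, template)
    per_lipid = len(template)

    backbone = build_chains(np.full((1, nC - 3), 180.0))[0]  # (nC, 3)
    spacing = 10.0
    box = np.array(
        [max(n_lipids * spacing, 40.0), 40.0, 60.0]
    )
    rng = np.random.default_rng(seed)
    carbon_seeds = rng.integers(0, 2**31 - 1, size=nC)
    ring_seeds = rng.integers(0, 2**31 - 1, size=3)

    origins = np.array(
        [[5.0 + lip * spacing, 20.0, 20.0] for lip in range(n_lipids)]
    )
    bases = np.arange(n_lipids) * per_lipid
    coords = np.empty((n_frames, per_lipid * n_lipids, 3))
    heads = origins + np.array([0.0, 0.0, -2.0])
    coords[:, bases + 0] = heads[None]  # O1, static
    if d_r_rings is not None:
        # each ring vector rides its own diffusion series (one per lipid)
        u1, u2, u12 = (
            simulate_rotational_diffusion(
                RotDiffSpec(d_r_rings[m], dt_ps, n_frames, n_lipids,
                            int(ring_seeds[m]))
            )
            for m in range(3)
        )
        c1p = heads[None] + np.array([0.0, 0.0, -1.0])
        c4 = c1p + 2.8 * u12  # ring12: C1' -> C4
        c1 = c4 - 2.8 * u1  # ring1: C1 -> C4
        c4p = c1p + 2.8 * u2  # ring2: C1' -> C4'
        coords[:, bases + 1] = c1
        coords[:, bases + 2] = c4
        coords[:, bases + 3] = c1p
        coords[:, bases + 4] = c4p
    else:
        for off, shift in (
            (1, [0.5, 0.0, -1.0]),
            (2, [-0.5, 0.5, -2.0]),
            (3, [0.3, -0.5, -3.0]),
            (4, [-0.3, 0.2, -4.0]),
        ):
            coords[:, bases + off] = (heads + np.array(shift))[None]
    for k in range(nC):
        c_at = bases + 5 + 3 * k
        c_pos = origins + backbone[k]
        coords[:, c_at] = c_pos[None]
        u = simulate_rotational_diffusion(
            RotDiffSpec(float(d_r[k]), dt_ps, n_frames, 2 * n_lipids,
                        int(carbon_seeds[k]))
        )
        for h in range(2):
            coords[:, c_at + 1 + h] = c_pos[None] + BOND_CH * u[:, h::2]
    times = np.arange(n_frames) * dt_ps
    names = [template[i % per_lipid].name for i in range(per_lipid * n_lipids)]
    traj = Trajectory(coords, np.tile(box, (n_frames, 1)), times, names)
    return traj, role_map
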