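"""Core data model shared by every analysis stage.

The package works on three kinds of objects:

* :class:`Trajectory` -- ordered frames of Cartesian coordinates (Å) with
  orthorhombic box lengths (Å) and timestamps (ps).
* :class:`TopologyRoleMap` -- a name-driven description of what each atom of
  each lipid *is* (chain carbon C71..C82 / C83..C92, chain hydrogen, sugar
  ring anchor C1/C4/C1'/C4', other headgroup atom), so that analyses are
  independent of the file format the coordinates came from.
* :class:`AnalysisWindow` -- a half-open frame range plus a block count for
  block averaging (the usual convention for discarding the equilibration
  part of a run, e.g. keeping the last 80% of frames).

Units are Å, ps and degrees throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "AtomRecord",
    "TopologyRoleMap",
    "AnalysisWindow",
    "LeafletAssignment",
    "ELEMENT_MASSES",
    "element_of",
    "ROLES",
]

#: Atomic masses (amu) for the elements that occur in glycolipid systems.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

#: Recognised atom roles.
ROLES = frozenset(
    {"chain_carbon", "chain_hydrogen", "ring_anchor", "headgroup_atom", "other"}
)

RING_ANCHORS = ("C1", "C4", "C1p", "C4p")

SN1_RANGE = (71, 82)
SN2_RANGE = (83, 92)


def element_of(name: str) -> str:
    """Guess the element from an atom name (first alphabetic character)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass
class Trajectory:
    """Ordered coordinate frames with orthorhombic boxes and timestamps.

    Parameters
    ----------
    coords :
        Array of shape ``(n_frames, n_atoms, 3)``, Å.
    box :
        Array of shape ``(n_frames, 3)`` with ``(Lx, Ly, Lz)`` per frame, Å.
    times :
        Strictly increasing timestamps, ps, shape ``(n_frames,)``.
    atom_names :
        One name per atom, shared by all frames.
    """

    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray
    atom_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        f, n, _ = self.coords.shape
        if self.box.shape != (f, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if self.times.shape != (f,):
            raise ValueError("times must have shape (n_frames,)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be strictly positive")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.atom_names and len(self.atom_names) != n:
            raise ValueError("atom_names length must equal the atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt_ps(self) -> float:
        """Frame interval in ps (median of successive time differences)."""
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a frame interval")
        return float(np.median(np.diff(self.times)))

    def window(self, window: "AnalysisWindow | None") -> "Trajectory":
        """Return the sub-trajectory selected by ``window`` (a view)."""
        if window is None:
            return self
        window.check(self.n_frames)
        sl = slice(window.first, window.last)
        return Trajectory(
            self.coords[sl], self.box[sl], self.times[sl], self.atom_names
        )


@dataclass
class AnalysisWindow:
    """Half-open frame range ``[first, last)`` with a block count.

    The block count partitions the window into equal contiguous blocks for
    block-average error estimation; a final partial block is dropped.
    """

    first: int
    last: int
    blocks: int = 1

    def __post_init__(self) -> None:
        if self.first < 0 or self.last <= self.first:
            raise ValueError("require 0 <= first < last")
        if self.blocks < 1:
            raise ValueError("block count must be >= 1")

    @classmethod
    def from_fraction(
        cls, n_frames: int, discard: float = 0.2, blocks: int = 1
    ) -> "AnalysisWindow":
        """Window discarding the leading ``discard`` fraction of frames.

        The default (discard the first 20%) mirrors the convention of keeping
        the last 160 ns of a 200 ns run for production analysis.
        """
        if not 0.0 <= discard < 1.0:
            raise ValueError("discard fraction must be in [0, 1)")
        first = int(round(n_frames * discard))
        if first >= n_frames:
            raise ValueError("discard fraction leaves no frames")
        return cls(first=first, last=n_frames, blocks=blocks)

    def check(self, n_frames: int) -> None:
        if self.last > n_frames:
            raise ValueError(
                f"window [{self.first}, {self.last}) exceeds frame count {n_frames}"
            )

    @property
    def n_frames(self) -> int:
        return self.last - self.first

    def block_bounds(self) -> list[tuple[int, int]]:
        """Equal-sized block ranges (absolute frame indices); partial dropped."""
        size = self.n_frames // self.blocks
        if size < 1:
            raise ValueError("more blocks than frames in window")
        return [
            (self.first + b * size, self.first + (b + 1) * size)
            for b in range(self.blocks)
        ]


@dataclass
class AtomRecord:
    """Role of a single atom within one lipid."""

    lipid: int
    name: str
    role: str
    chain: str | None = None  # 'sn1' | 'sn2' for chain atoms
    parent: str | None = None  # parent carbon name for chain hydrogens
    anchor: str | None = None  # C1 | C4 | C1p | C4p for ring anchors

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for atom {self.name!r}")
        if self.role == "chain_carbon" and self.chain not in ("sn1", "sn2"):
            raise ValueError(f"chain carbon {self.name!r} needs chain sn1/sn2")
        if self.role == "chain_hydrogen" and not self.parent:
            raise ValueError(f"chain hydrogen {self.name!r} needs a parent carbon")
        if self.role == "ring_anchor" and self.anchor not in RING_ANCHORS:
            raise ValueError(
                f"ring anchor {self.name!r} must declare one of {RING_ANCHORS}"
            )


def _carbon_number(name: str) -> int:
    digits = "".join(ch for ch in name if ch.isdigit())
    if not digits:
        raise ValueError(f"chain carbon name {name!r} carries no index")
    return int(digits)


class TopologyRoleMap:
    """Per-lipid atom-name -> role table driving all analyses.

    Atom records are listed in trajectory atom order.  Indexing helpers
    (chain carbons in order, hydrogens per carbon, ring anchors, headgroup
    atoms, per-atom masses and lipid ids) are precomputed on construction.
    """

    def __init__(
        self,
        lipid_count: int,
        atoms: Sequence[AtomRecord],
        leaflet_hint: Sequence[int] | None = None,
    ) -> None:
        if lipid_count < 1:
            raise ValueError("lipid_count must be >= 1")
        self.lipid_count = int(lipid_count)
        self.atoms = list(atoms)
        self.leaflet_hint = list(leaflet_hint) if leaflet_hint is not None else None
        if self.leaflet_hint is not None and len(self.leaflet_hint) != lipid_count:
            raise ValueError("leaflet_hint must have one label per lipid")
        self._index()
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_template(
        cls,
        lipid_count: int,
        template: Sequence[AtomRecord],
        leaflet_hint: Sequence[int] | None = None,
    ) -> "TopologyRoleMap":
        """Replicate a single-lipid template ``lipid_count`` times."""
        atoms = [
            AtomRecord(lipid, rec.name, rec.role, rec.chain, rec.parent, rec.anchor)
            for lipid in range(lipid_count)
            for rec in template
        ]
        return cls(lipid_count, atoms, leaflet_hint)

    # -- indexing -------------------------------------------------------------

    def _index(self) -> None:
        n = len(self.atoms)
        self.n_atoms = n
        self.lipid_ids = np.array([a.lipid for a in self.atoms], dtype=np.int64)
        self.masses = np.array(
            [ELEMENT_MASSES[element_of(a.name)] for a in self.atoms]
        )
        self._carbons: dict[int, dict[str, int]] = {
            l: {} for l in range(self.lipid_count)
        }
        self._chain_names: dict[str, list[str]] = {"sn1": [], "sn2": []}
        self._hydrogens: dict[tuple[int, str], list[int]] = {}
        self._anchors: dict[int, dict[str, int]] = {
            l: {} for l in range(self.lipid_count)
        }
        self._head: dict[int, list[int]] = {l: [] for l in range(self.lipid_count)}
        chain_nums: dict[str, set[int]] = {"sn1": set(), "sn2": set()}
        for i, a in enumerate(self.atoms):
            if not 0 <= a.lipid < self.lipid_count:
                raise ValueError(f"atom {i} references lipid {a.lipid} out of range")
            if a.role == "chain_carbon":
                if a.name in self._carbons[a.lipid]:
                    raise ValueError(
                        f"duplicate chain carbon {a.name!r} in lipid {a.lipid}"
                    )
                self._carbons[a.lipid][a.name] = i
                chain_nums[a.chain].add(_carbon_number(a.name))
            elif a.role == "chain_hydrogen":
                self._hydrogens.setdefault((a.lipid, a.parent), []).append(i)
            elif a.role == "ring_anchor":
                if a.anchor in self._anchors[a.lipid]:
                    raise ValueError(
                        f"ring anchor {a.anchor!r} declared twice in lipid {a.lipid}"
                    )
                self._anchors[a.lipid][a.anchor] = i
                self._head[a.lipid].append(i)
            elif a.role == "headgroup_atom":
                self._head[a.lipid].append(i)
        for chain, lo in (("sn1", SN1_RANGE[0]), ("sn2", SN2_RANGE[0])):
            nums = sorted(chain_nums[chain])
            self._chain_names[chain] = [f"C{k}" for k in nums]

    def _validate(self) -> None:
        for chain, (lo, hi) in (("sn1", SN1_RANGE), ("sn2", SN2_RANGE)):
            names = self._chain_names[chain]
            if not names:
                continue
            nums = [_carbon_number(n) for n in names]
            if nums[0] != lo:
                raise ValueError(f"{chain} chain must start at C{lo}")
            if nums != list(range(lo, lo + len(nums))):
                raise ValueError(f"{chain} chain carbons must be contiguous from C{lo}")
            if nums[-1] > hi:
                raise ValueError(f"{chain} chain carbons must not exceed C{hi}")
        for (lipid, parent), idxs in self._hydrogens.items():
            if parent not in self._carbons[lipid]:
                raise ValueError(
                    f"hydrogens {idxs} reference undeclared carbon {parent!r}"
                    f" in lipid {lipid}"
                )

    # -- queries --------------------------------------------------------------

    def chain_carbon_names(self, chain: str = "sn1") -> list[str]:
        return list(self._chain_names[chain])

    def has_chain(self, chain: str) -> bool:
        return bool(self._chain_names[chain])

    def chain_carbon_indices(self, lipid: int, chain: str = "sn1") -> list[int]:
        return [self._carbons[lipid][n] for n in self._chain_names[chain]]

    def chain_carbon_matrix(self, chain: str = "sn1") -> np.ndarray:
        """Array ``(lipid_count, n_carbons)`` of atom indices."""
        return np.array(
            [self.chain_carbon_indices(l, chain) for l in range(self.lipid_count)],
            dtype=np.int64,
        )

    def carbon_index(self, lipid: int, name: str) -> int:
        return self._carbons[lipid][name]

    def carbon_selection(self, name: str) -> np.ndarray:
        """Atom indices of carbon ``name`` across all lipids that declare it."""
        idx = [
            self._carbons[l][name]
            for l in range(self.lipid_count)
            if name in self._carbons[l]
        ]
        if not idx:
            raise ValueError(f"no lipid declares chain carbon {name!r}")
        return np.array(idx, dtype=np.int64)

    def hydrogens_of(self, lipid: int, carbon: str) -> list[int]:
        return list(self._hydrogens.get((lipid, carbon), []))

    def ring_anchor(self, lipid: int, label: str) -> int:
        try:
            return self._anchors[lipid][label]
        except KeyError:
            raise ValueError(
                f"lipid {lipid} declares no ring anchor {label!r}"
            ) from None

    def headgroup_indices(self, lipid: int) -> list[int]:
        idx = self._head[lipid]
        if not idx:
            raise ValueError(f"lipid {lipid} declares no headgroup atoms")
        return list(idx)

    def component_of_atoms(self) -> np.ndarray:
        """Per-atom component label: 'sugar', 'chain' or 'other'."""
        comp = np.empty(self.n_atoms, dtype=object)
        for i, a in enumerate(self.atoms):
            if a.role in ("ring_anchor", "headgroup_atom"):
                comp[i] = "sugar"
            elif a.role in ("chain_carbon", "chain_hydrogen"):
                comp[i] = "chain"
            else:
                comp[i] = "other"
        return comp

    def iter_lipids(self) -> Iterator[int]:
        return iter(range(self.lipid_count))


@dataclass
class LeafletAssignment:
    """Partition of lipids into leaflets, labelled 1..k by ascending mean z.

    ``normals`` holds, per leaflet, the sign (+1/-1) of the direction the
    chains point along z -- the reference axis used for tilt semantics and
    protrusion windows.
    """

    labels: np.ndarray  # (n_lipids,) ints in 1..k
    normals: np.ndarray | None = None  # (k,) +1/-1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if uniq.min() < 1:
            raise ValueError("leaflet labels start at 1")
        self.n_leaflets = int(uniq.max())
        if self.normals is not None:
            self.normals = np.asarray(self.normals)
            if self.normals.shape != (self.n_leaflets,):
                raise ValueError("normals must have one entry per leaflet")

    @property
    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}

    def lipids_in(self, leaflet: int) -> np.ndarray:
        return np.nonzero(self.labels == leaflet)[0]
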