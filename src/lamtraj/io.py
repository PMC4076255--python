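"""Trajectory and role-map I/O.

Two plain-text trajectory dialects are supported natively:

* **Multi-model PDB** -- standard ``MODEL``/``ATOM``/``ENDMDL`` records.  A
  ``CRYST1`` record before each model carries the (possibly per-frame) box;
  a ``REMARK   6 TIME_PS`` record carries the timestamp.  Files written by
  other tools that carry a single leading ``CRYST1`` and no time remark are
  accepted (the box is reused; times fall back to the frame index in ps).
* **Extended XYZ** -- per frame: atom count line, then a comment line
  ``Lx Ly Lz time_ps``, then ``name x y z`` lines.  Standard XYZ lacks box
  metadata, hence the comment-line convention.

Binary MD formats can be brought in through the ``adapter`` route
(:func:`from_mdanalysis`), which converts any MDAnalysis Universe.

Role maps are stored as human-editable YAML (see :func:`load_role_map`).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .model import AtomRecord, TopologyRoleMap, Trajectory

__all__ = [
    "load_trajectory",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "from_mdanalysis",
    "load_role_map",
    "save_role_map",
]

FORMATS = ("pdb_multimodel", "xyz")


def load_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a trajectory, auto-detecting the dialect from the suffix.

    ``fmt`` may be ``"pdb_multimodel"`` or ``"xyz"``; when omitted it is
    inferred from the file extension (.pdb / .xyz).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".pdb": "pdb_multimodel", ".xyz": "xyz"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer trajectory format from {path.name!r}")
    if fmt == "pdb_multimodel":
        return read_pdb(path)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# XYZ dialect
# ---------------------------------------------------------------------------

def read_xyz(path) -> Trajectory:
    frames = []
    boxes = []
    times = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ValueError(f"frame {frame_no}: expected atom count, got {lines[i]!r}")
        comment = lines[i + 1].split()
        if len(comment) < 3:
            raise ValueError(
                f"frame {frame_no}: comment line must carry 'Lx Ly Lz [time_ps]'"
            )
        box = [float(v) for v in comment[:3]]
        t = float(comment[3]) if len(comment) > 3 else float(frame_no)
        coords = np.empty((n, 3))
        frame_names = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            frame_names.append(parts[0])
            coords[j] = [float(v) for v in parts[1:4]]
        if not names:
            names = frame_names
        elif frame_names != names:
            raise ValueError(f"frame {frame_no}: atom names/order differ from frame 0")
        frames.append(coords)
        boxes.append(box)
        times.append(t)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    if any(f.shape != frames[0].shape for f in frames):
        raise ValueError("inconsistent atom count across frames")
    return Trajectory(np.array(frames), np.array(boxes), np.array(times), names)


def write_xyz(traj: Trajectory, path) -> None:
    names = traj.atom_names or [f"X{i}" for i in range(traj.n_atoms)]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            lx, ly, lz = traj.box[f]
            fh.write(f"{lx:.6f} {ly:.6f} {lz:.6f} {traj.times[f]:.6f}\n")
            for name, (x, y, z) in zip(names, traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Multi-model PDB dialect
# ---------------------------------------------------------------------------

def read_pdb(path, lipid_ids: np.ndarray | None = None) -> Trajectory:
    frames: list[np.ndarray] = []
    boxes: list[list[float] | None] = []
    times: list[float | None] = []
    names: list[str] = []
    cur: list[list[float]] = []
    cur_names: list[str] = []
    cur_box: list[float] | None = None
    cur_time: float | None = None
    last_box: list[float] | None = None
    in_model = False
    seen_model_record = False

    def flush(frame_no: int) -> None:
        nonlocal cur, cur_names, cur_box, cur_time
        if not cur:
            return
        if not names:
            names.extend(cur_names)
        elif len(cur_names) != len(names):
            raise ValueError(
                f"frame {frame_no}: atom count {len(cur_names)} differs from"
                f" frame 0 ({len(names)})"
            )
        frames.append(np.array(cur))
        boxes.append(cur_box)
        times.append(cur_time)
        cur, cur_names, cur_box, cur_time = [], [], None, None

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                last_box = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                if in_model or not seen_model_record:
                    cur_box = last_box
            elif rec == "REMARK" and "TIME_PS" in line:
                cur_time = float(line.split()[-1])
            elif rec == "MODEL ":
                in_model = True
                seen_model_record = True
                if cur_box is None:
                    cur_box = last_box
            elif rec in ("ATOM  ", "HETATM"):
                cur_names.append(line[12:16].strip())
                cur.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            elif rec == "ENDMDL":
                flush(len(frames))
                in_model = False
    flush(len(frames))
    if not frames:
        raise ValueError(f"{path}: no coordinate frames found")
    for i, b in enumerate(boxes):
        if b is None:
            if last_box is None:
                raise ValueError(f"{path}: frame {i} has no CRYST1 box record")
            boxes[i] = last_box
    if any(t is None for t in times):
        times = [float(i) for i in range(len(frames))]
    return Trajectory(
        np.array(frames), np.array(boxes, dtype=float), np.array(times), names
    )


def write_pdb(
    traj: Trajectory, path, role_map: TopologyRoleMap | None = None
) -> None:
    """Write a multi-model PDB; coordinates keep 1e-3 Å precision.

    When a role map is given, lipid indices go into the residue number
    column (mod 10000) so third-party viewers group atoms sensibly.
    """
    names = traj.atom_names or [f"X{i}" for i in range(traj.n_atoms)]
    resids = (
        role_map.lipid_ids % 10000 + 1
        if role_map is not None
        else np.ones(traj.n_atoms, dtype=int)
    )
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            lx, ly, lz = traj.box[f]
            fh.write(
                f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            fh.write(f"REMARK   6 TIME_PS {traj.times[f]:.6f}\n")
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, (name, (x, y, z)) in enumerate(zip(names, traj.coords[f])):
                pdb_name = name if len(name) == 4 else f" {name:<3s}"
                elem = name[0].upper()
                fh.write(
                    f"ATOM  {(i % 99999) + 1:5d} {pdb_name:<4s} LIP A"
                    f"{int(resids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def from_mdanalysis(universe) -> Trajectory:
    """Adapter: convert an MDAnalysis Universe (any backing format)."""
    coords = []
    boxes = []
    times = []
    for ts in universe.trajectory:
        if ts.dimensions is None or np.any(np.asarray(ts.dimensions[:3]) <= 0):
            raise ValueError(f"frame {ts.frame}: missing or invalid box dimensions")
        coords.append(universe.atoms.positions.astype(np.float64).copy())
        boxes.append(np.asarray(ts.dimensions[:3], dtype=np.float64))
        times.append(float(ts.time))
    times_arr = np.array(times)
    if len(times_arr) > 1 and np.any(np.diff(times_arr) <= 0):
        times_arr = np.arange(len(times_arr), dtype=float)
    return Trajectory(
        np.array(coords),
        np.array(boxes),
        times_arr,
        [str(n) for n in universe.atoms.names],
    )


# ---------------------------------------------------------------------------
# Role-map YAML
# ---------------------------------------------------------------------------

_ATOM_KEYS = {"lipid", "name", "role", "chain", "parent", "anchor"}


def _record_from_dict(d: dict, lipid: int | None = None) -> AtomRecord:
    unknown = set(d) - _ATOM_KEYS
    if unknown:
        raise ValueError(f"unknown atom keys {sorted(unknown)} in role map")
    return AtomRecord(
        lipid=int(d["lipid"]) if lipid is None else lipid,
        name=str(d["name"]),
        role=str(d["role"]),
        chain=d.get("chain"),
        parent=d.get("parent"),
        anchor=d.get("anchor"),
    )


def load_role_map(path) -> TopologyRoleMap:
    """Load a role map from YAML.

    Two layouts are accepted: ``template`` (one lipid's atoms, replicated
    ``lipid_count`` times -- the compact form) or ``atoms`` (explicit
    per-atom records with a ``lipid`` field).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "lipid_count" not in data:
        raise ValueError("role map must be a mapping with a 'lipid_count' key")
    lipid_count = int(data["lipid_count"])
    hint = data.get("leaflet_hint")
    if "template" in data:
        template = [_record_from_dict(d, lipid=0) for d in data["template"]]
        return TopologyRoleMap.from_template(lipid_count, template, hint)
    if "atoms" in data:
        atoms = [_record_from_dict(d) for d in data["atoms"]]
        return TopologyRoleMap(lipid_count, atoms, hint)
    raise ValueError("role map needs either a 'template' or an 'atoms' section")


def save_role_map(role_map: TopologyRoleMap, path) -> None:
    """Write a role map as YAML (template form when lipids are identical)."""
    per_lipid = len(role_map.atoms) // role_map.lipid_count
    template = role_map.atoms[:per_lipid]
    uniform = len(role_map.atoms) == per_lipid * role_map.lipid_count and all(
        (a.name, a.role, a.chain, a.parent, a.anchor)
        == (t.name, t.role, t.chain, t.parent, t.anchor)
        for l in range(role_map.lipid_count)
        for a, t in zip(role_map.atoms[l * per_lipid : (l + 1) * per_lipid], template)
    )

    def rec_dict(a: AtomRecord, with_lipid: bool) -> dict:
        d: dict = {}
        if with_lipid:
            d["lipid"] = a.lipid
        d["name"] = a.name
        d["role"] = a.role
        for k in ("chain", "parent", "anchor"):
            v = getattr(a, k)
            if v is not None:
                d[k] = v
        return d

    data: dict = {"lipid_count": role_map.lipid_count}
    if role_map.leaflet_hint is not None:
        data["leaflet_hint"] = list(map(int, role_map.leaflet_hint))
    if uniform:
        data["template"] = [rec_dict(a, False) for a in template]
    else:
        data["atoms"] = [rec_dict(a, True) for a in role_map.atoms]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
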