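"""Readers and writers for PDB, DCD, multi-frame XYZ and the JSON topology.

PDB structure interchange goes through biotite; DCD (CHARMM-style binary,
little-endian, no fixed atoms) through MDAnalysis' low-level DCD layer.
The JSON topology dialect carries the per-atom nonbonded parameters that a
structure file cannot::

    {"atoms": [{"index": 0, "charge": -0.52, "lj_rmin_half": 1.908,
                "lj_epsilon": 0.086, "gb_radius": 1.7, "gb_screen": 0.72,
                "donor_heavy": false, "acceptor": true, "polar_h": false,
                "mass": 12.011}],
     "segments": {"ligand": [8, 9, 10]},
     "rings": [[9, 10, 11, 12, 13, 14]]}

Atoms may be addressed by ``index`` or by ``("residue_id", "name")``.
``mass`` is optional (element-derived default); the force-field fields are
required for every listed atom. The ``segments`` map re-tags atoms (the
ligand is whatever the JSON says it is — never inferred from HETATM), and
``rings`` lists planar-ring atom index groups for π-stacking detection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
from MDAnalysis.lib.formats.libdcd import DCDFile

from .errors import (
    DimensionError,
    EmptyInputError,
    ParseError,
    ValidationError,
)
from .topology import AtomRecord, Topology
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_xyz",
    "write_xyz",
    "read_dcd",
    "write_dcd",
    "read_topology_json",
    "write_topology_json",
]

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}


def _element_mass(element: str) -> float:
    return _ELEMENT_MASS.get(element.upper(), 12.011)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> int:
    """Validate fixed-column ATOM/HETATM records; returns the record count."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n += 1
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: line {lineno}: record shorter than 54 columns")
            if line[26] not in (" ", ""):
                raise ParseError(
                    f"{path}: line {lineno}: insertion codes are unsupported "
                    f"(found '{line[26]}')"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: unparseable {what} coordinate "
                        f"field '{line[lo:hi].strip()}'"
                    ) from None
            try:
                int(line[22:26])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: unparseable residue number "
                    f"'{line[22:26].strip()}'"
                ) from None
    return n


def read_pdb(path: Union[str, Path]) -> tuple[Topology, np.ndarray]:
    """Read a single-model PDB into a partial topology plus one coordinate frame.

    Force-field fields are left at defaults; :func:`read_topology_json`
    fills them. The chain identifier becomes the segment tag.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if _prescan_pdb(path) == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    arr = PDBFile.read(str(path)).get_structure(model=1)
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]) or str(arr.atom_name[i])[:1]
        atoms.append(
            AtomRecord(
                index=i,
                name=str(arr.atom_name[i]),
                residue_id=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                segment=str(arr.chain_id[i]),
                mass=_element_mass(element),
            )
        )
    topology = Topology(atoms=atoms)
    coords = np.asarray(arr.coord, dtype=float)
    logger.info("read_pdb: %s -> %d atoms, %d residues", path, topology.n_atoms,
                topology.n_residues)
    return topology, coords


def write_pdb(path: Union[str, Path], topology: Topology, coords: np.ndarray) -> None:
    """Write one frame as PDB; serial numbers are 1-based in the file only."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise DimensionError(
            f"coords shape {coords.shape} != ({topology.n_atoms}, 3)"
        )
    arr = struc.AtomArray(topology.n_atoms)
    arr.coord = coords
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.res_id = np.array([a.residue_id for a in topology.atoms])
    arr.res_name = np.array([a.residue_name[:3] for a in topology.atoms])
    arr.chain_id = np.array([(a.segment[:1] or "A").upper() for a in topology.atoms])
    arr.element = np.array([a.name[:1].upper() for a in topology.atoms])
    arr.hetero = np.array([a.segment == "ligand" for a in topology.atoms])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    logger.info("write_pdb: %s <- %d atoms", path, topology.n_atoms)


# ---------------------------------------------------------------------------
# XYZ (multi-frame plain text)
# ---------------------------------------------------------------------------

def read_xyz(path: Union[str, Path]) -> tuple[np.ndarray, list[str]]:
    """Read a multi-frame XYZ file; returns (frames x atoms x 3, atom names)."""
    path = Path(path)
    frames: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {pos + 1}: expected atom count, got "
                f"'{lines[pos].strip()}'"
            ) from None
        body = lines[pos + 2: pos + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(
                f"{path}: truncated frame {frame_idx}: expected {natoms} atom "
                f"lines, found {len(body)}"
            )
        frame = np.empty((natoms, 3))
        for i, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {pos + 3 + i}: expected 'name x y z'"
                )
            if frame_idx == 0:
                names.append(parts[0])
            try:
                frame[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(
                    f"{path}: line {pos + 3 + i}: unparseable coordinates"
                ) from None
        frames.append(frame)
        pos += 2 + natoms
        frame_idx += 1
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    logger.info("read_xyz: %s -> %d frames x %d atoms", path, len(frames),
                frames[0].shape[0])
    return np.stack(frames), names


def write_xyz(path: Union[str, Path], trajectory: Trajectory,
              topology: Optional[Topology] = None) -> None:
    names = ([a.name for a in topology.atoms] if topology is not None
             else ["X"] * trajectory.n_atoms)
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f"frame {f} t={trajectory.times_ps[f]:.6f} ps\n")
            for name, (x, y, z) in zip(names, trajectory.coordinates[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
    logger.info("write_xyz: %s <- %d frames", path, trajectory.n_frames)


# ---------------------------------------------------------------------------
# DCD (CHARMM binary)
# ---------------------------------------------------------------------------

def read_dcd(path: Union[str, Path]) -> tuple[np.ndarray, Optional[float]]:
    """Read all DCD frames; returns (coords, frame spacing from header or None)."""
    with DCDFile(str(path)) as f:
        header = f.header
        arr = f.readframes()
    coords = np.asarray(arr.xyz, dtype=float)
    spacing = None
    delta = float(header.get("delta", 0.0))
    nsavc = int(header.get("nsavc", 0))
    if delta > 0 and nsavc > 0:
        spacing = delta * nsavc
    logger.info("read_dcd: %s -> %d frames x %d atoms", path, coords.shape[0],
                coords.shape[1])
    return coords, spacing


def write_dcd(path: Union[str, Path], trajectory: Trajectory) -> None:
    """Write a CHARMM-dialect DCD. Coordinates are stored in float32."""
    coords32 = trajectory.coordinates.astype(np.float32)
    with DCDFile(str(path), "w") as f:
        f.write_header(
            remarks="bindscape trajectory",
            natoms=trajectory.n_atoms,
            istart=0,
            nsavc=1,
            delta=float(trajectory.frame_spacing_ps),
            is_periodic=0,
        )
        for frame in coords32:
            f.write(xyz=frame.astype(np.float64))
    logger.info("write_dcd: %s <- %d frames", path, trajectory.n_frames)


def read_trajectory(path: Union[str, Path], topology: Topology,
                    frame_spacing_ps: Optional[float] = None) -> Trajectory:
    """Load a DCD or XYZ trajectory and bind it to ``topology``.

    ``frame_spacing_ps`` is taken from the DCD header when present there,
    otherwise it must be supplied by the caller.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        coords, header_spacing = read_dcd(path)
        spacing = header_spacing if header_spacing is not None else frame_spacing_ps
    elif path.suffix.lower() == ".xyz":
        coords, _ = read_xyz(path)
        spacing = frame_spacing_ps
    else:
        raise ParseError(f"unsupported trajectory format: {path.suffix}")
    if spacing is None:
        raise ValidationError(
            "frame_spacing_ps not in file header and not supplied by caller"
        )
    if coords.shape[1] != topology.n_atoms:
        raise DimensionError(
            f"{path}: {coords.shape[1]} atoms per frame but topology has "
            f"{topology.n_atoms}"
        )
    return Trajectory(coordinates=coords, frame_spacing_ps=spacing)


def write_trajectory(path: Union[str, Path], trajectory: Trajectory,
                     topology: Optional[Topology] = None) -> None:
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        write_dcd(path, trajectory)
    elif path.suffix.lower() == ".xyz":
        write_xyz(path, trajectory, topology)
    else:
        raise ParseError(f"unsupported trajectory format: {path.suffix}")


# ---------------------------------------------------------------------------
# JSON topology dialect
# ---------------------------------------------------------------------------

_REQUIRED_FF_FIELDS = ("charge", "lj_rmin_half", "lj_epsilon", "gb_radius",
                       "gb_screen")


def read_topology_json(path: Union[str, Path], topology: Topology) -> Topology:
    """Populate force-field fields of ``topology`` from the JSON dialect.

    Returns a new :class:`Topology`; the input is unchanged. Every listed
    atom must carry the full nonbonded parameter set (it participates in
    GB); missing fields raise a single validation error listing all
    offending atoms.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    atoms = [dataclasses.replace(a) for a in topology.atoms]
    by_key = {(a.residue_id, a.name): a.index for a in topology.atoms}

    missing: list[str] = []
    unresolved: list[str] = []
    seen: set[int] = set()
    for entry in doc.get("atoms", []):
        if "index" in entry:
            idx = int(entry["index"])
            if not (0 <= idx < topology.n_atoms):
                raise ValidationError(f"{path}: atom index {idx} out of range")
        else:
            key = (int(entry["residue_id"]), str(entry["name"]))
            if key not in by_key:
                unresolved.append(f"residue {key[0]} atom {key[1]}")
                continue
            idx = by_key[key]
        absent = [f for f in _REQUIRED_FF_FIELDS if f not in entry]
        if absent:
            missing.append(
                f"atom {idx} ({atoms[idx].name}): missing {', '.join(absent)}"
            )
            continue
        seen.add(idx)
        atoms[idx] = dataclasses.replace(
            atoms[idx],
            charge=float(entry["charge"]),
            lj_rmin_half=float(entry["lj_rmin_half"]),
            lj_epsilon=float(entry["lj_epsilon"]),
            gb_radius=float(entry["gb_radius"]),
            gb_screen=float(entry["gb_screen"]),
            is_donor_heavy=bool(entry.get("donor_heavy", False)),
            is_acceptor=bool(entry.get("acceptor", False)),
            is_polar_h=bool(entry.get("polar_h", False)),
            mass=float(entry.get("mass", atoms[idx].mass)),
        )
    if missing:
        raise ValidationError(
            f"{path}: incomplete GB/nonbonded parameters:\n  " + "\n  ".join(missing)
        )
    if unresolved:
        logger.warning("%s: %d unresolved atom entries: %s", path,
                       len(unresolved), "; ".join(unresolved))
    not_listed = sorted(set(range(topology.n_atoms)) - seen)
    if not_listed:
        logger.warning("%s: %d topology atoms not listed in JSON", path,
                       len(not_listed))

    for seg_name, indices in doc.get("segments", {}).items():
        for idx in indices:
            atoms[idx] = dataclasses.replace(atoms[idx], segment=str(seg_name))

    for ring_id, members in enumerate(doc.get("rings", [])):
        if len(members) < 3:
            raise ValidationError(f"{path}: ring {ring_id} has < 3 atoms")
        for idx in members:
            atoms[idx] = dataclasses.replace(atoms[idx], ring_id=ring_id)

    new_top = Topology(atoms=atoms)
    logger.info("read_topology_json: %s -> %d parameterized atoms", path, len(seen))
    return new_top


def write_topology_json(path: Union[str, Path], topology: Topology) -> None:
    segments: dict[str, list[int]] = {}
    for a in topology.atoms:
        if a.segment:
            segments.setdefault(a.segment, []).append(a.index)
    doc = {
        "atoms": [
            {
                "index": a.index,
                "charge": a.charge,
                "lj_rmin_half": a.lj_rmin_half,
                "lj_epsilon": a.lj_epsilon,
                "gb_radius": a.gb_radius,
                "gb_screen": a.gb_screen,
                "donor_heavy": a.is_donor_heavy,
                "acceptor": a.is_acceptor,
                "polar_h": a.is_polar_h,
                "mass": a.mass,
            }
            for a in topology.atoms
        ],
        "segments": segments,
        "rings": [members for _, members in sorted(topology.rings.items())],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    logger.info("write_topology_json: %s <- %d atoms", path, topology.n_atoms)
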