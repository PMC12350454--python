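"""Geometric interaction typing per frame and fingerprint differencing.

Detectors evaluate ligand–receptor geometric criteria frame by frame
over a window and aggregate per partner into occupancy (fraction of
frames present) and mean geometry. The criteria are purely geometric and
invariant under any rigid motion of a frame:

* hydrogen bond — donor-heavy to acceptor distance ≤ ``d_max`` (3.5 Å)
  AND donor–H–acceptor angle ≥ ``angle_min`` (135°);
* van der Waals contact — minimum interatomic distance ≤
  ``rmin_half_i + rmin_half_j + pad`` (pad 0.5 Å);
* π-stacking — ring centroid distance ≤ ``d_max`` (5.5 Å) AND
  interplanar angle ≤ ``tilt_max`` (30°), normals from the best-fit
  plane of each ring.

The thresholds are configurable; the defaults are conventional geometric
criteria. :func:`fingerprint_diff` compares two systems (e.g. mutant vs
wild type): interactions present above an occupancy floor in exactly one
system, plus type switches for shared partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .topology import Topology
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "detect_hbonds",
    "detect_contacts",
    "detect_pi_stacking",
    "fingerprint_diff",
]

DEFAULT_HBOND_DMAX = 3.5      # Å, donor-acceptor
DEFAULT_HBOND_ANGLE_MIN = 135.0  # degrees, D-H...A
DEFAULT_CONTACT_PAD = 0.5     # Å on top of summed Rmin/2
DEFAULT_PI_DMAX = 5.5         # Å centroid-centroid
DEFAULT_PI_TILT_MAX = 30.0    # degrees interplanar
DEFAULT_OCCUPANCY_MIN = 0.5


@dataclass
class InteractionRecord:
    """One ligand-residue interaction aggregated over a frame window."""

    kind: str                     # "hbond" | "contact" | "pi_stack"
    partner_residue_id: int
    ligand_atoms: tuple[int, ...]
    occupancy: float
    mean_distance: float          # Å over frames where present
    mean_angle: float = float("nan")  # degrees, where defined

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError("occupancy must lie in [0, 1]")


def _window(trajectory: Trajectory, frame_window) -> range:
    if frame_window is None:
        return range(trajectory.n_frames)
    start, stop = frame_window
    if not (0 <= start < stop <= trajectory.n_frames):
        raise ValidationError(f"bad frame window [{start}, {stop})")
    return range(start, stop)


def _split_groups(topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    lig = np.array([a.index for a in topology.atoms if a.segment == "ligand"])
    rec = np.array([a.index for a in topology.atoms if a.segment != "ligand"])
    return rec, lig


def _donor_h_pairs(topology: Topology, coords: np.ndarray,
                   heavy_idx: np.ndarray) -> list[tuple[int, int]]:
    """Pair each polar H with the nearest donor-heavy atom in its residue."""
    pairs = []
    by_res: dict[tuple[str, int], list[int]] = {}
    for i in heavy_idx:
        a = topology.atoms[i]
        if a.is_donor_heavy:
            by_res.setdefault((a.segment, a.residue_id), []).append(i)
    for a in topology.atoms:
        if not a.is_polar_h:
            continue
        cands = by_res.get((a.segment, a.residue_id), [])
        if not cands:
            continue
        d = [np.linalg.norm(coords[c] - coords[a.index]) for c in cands]
        pairs.append((cands[int(np.argmin(d))], a.index))
    return pairs


def _hbond_frame(topology: Topology, coords: np.ndarray,
                 d_max: float, angle_min: float) -> list[tuple[int, int, int, float, float]]:
    """All (donor, H, acceptor, distance, angle) hits in one frame,
    between the ligand and the rest of the system (both directions)."""
    hits = []
    all_idx = np.arange(topology.n_atoms)
    donors = _donor_h_pairs(topology, coords, all_idx)
    acceptors = [a.index for a in topology.atoms if a.is_acceptor]
    for d_atom, h_atom in donors:
        d_seg = topology.atoms[d_atom].segment
        for acc in acceptors:
            if topology.atoms[acc].segment == d_seg:
                continue  # intra-molecular pairs are not fingerprint material
            r_da = np.linalg.norm(coords[acc] - coords[d_atom])
            if r_da > d_max:
                continue
            v1 = coords[d_atom] - coords[h_atom]
            v2 = coords[acc] - coords[h_atom]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= angle_min:
                hits.append((d_atom, h_atom, acc, r_da, angle))
    return hits


def detect_hbonds(
    trajectory: Trajectory,
    topology: Topology,
    frame_window: Optional[tuple[int, int]] = None,
    d_max: float = DEFAULT_HBOND_DMAX,
    angle_min: float = DEFAULT_HBOND_ANGLE_MIN,
) -> list[InteractionRecord]:
    """Ligand-receptor hydrogen bonds with occupancy over the window."""
    trajectory.check_topology(topology)
    if not any(a.is_donor_heavy or a.is_acceptor for a in topology.atoms):
        logger.warning("detect_hbonds: no donor/acceptor flags in topology")
        return []
    frames = _window(trajectory, frame_window)
    agg: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for f in frames:
        for d_atom, h_atom, acc, r, ang in _hbond_frame(
                topology, trajectory.coordinates[f], d_max, angle_min):
            agg.setdefault((d_atom, acc), []).append((r, ang))
    records = []
    nf = len(frames)
    for (d_atom, acc), geom in sorted(agg.items()):
        lig_atom = acc if topology.atoms[acc].segment == "ligand" else d_atom
        partner_atom = d_atom if lig_atom == acc else acc
        partner = topology.atoms[partner_atom].residue_id
        rs, angs = zip(*geom)
        records.append(InteractionRecord(
            kind="hbond", partner_residue_id=partner,
            ligand_atoms=(lig_atom,), occupancy=len(geom) / nf,
            mean_distance=float(np.mean(rs)), mean_angle=float(np.mean(angs)),
        ))
    return records


def detect_contacts(
    trajectory: Trajectory,
    topology: Topology,
    frame_window: Optional[tuple[int, int]] = None,
    pad: float = DEFAULT_CONTACT_PAD,
) -> list[InteractionRecord]:
    """Residue-level van der Waals contacts between ligand and receptor."""
    trajectory.check_topology(topology)
    rec, lig = _split_groups(topology)
    if rec.size == 0 or lig.size == 0:
        return []
    frames = _window(trajectory, frame_window)
    rmin = topology.lj_rmin_half
    cut = rmin[rec][:, None] + rmin[lig][None, :] + pad
    agg: dict[int, list[float]] = {}
    rec_res = np.array([topology.atoms[i].residue_id for i in rec])
    for f in frames:
        coords = trajectory.coordinates[f]
        d = np.sqrt(np.sum(
            (coords[rec][:, None, :] - coords[lig][None, :, :]) ** 2, axis=2))
        touching = d <= cut
        for rid in np.unique(rec_res):
            rows = rec_res == rid
            if touching[rows].any():
                agg.setdefault(int(rid), []).append(float(d[rows].min()))
    records = []
    nf = len(frames)
    for rid, dists in sorted(agg.items()):
        records.append(InteractionRecord(
            kind="contact", partner_residue_id=rid,
            ligand_atoms=tuple(int(i) for i in lig),
            occupancy=len(dists) / nf, mean_distance=float(np.mean(dists)),
        ))
    return records


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane through ring atoms."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def detect_pi_stacking(
    trajectory: Trajectory,
    topology: Topology,
    frame_window: Optional[tuple[int, int]] = None,
    d_max: float = DEFAULT_PI_DMAX,
    tilt_max: float = DEFAULT_PI_TILT_MAX,
) -> list[InteractionRecord]:
    """π-stacking between ligand rings and receptor rings."""
    trajectory.check_topology(topology)
    for ring_id, members in topology.rings.items():
        if len(members) < 3:
            raise ValidationError(f"ring {ring_id} has fewer than 3 atoms")
    lig_rings = {rid: m for rid, m in topology.rings.items()
                 if topology.atoms[m[0]].segment == "ligand"}
    rec_rings = {rid: m for rid, m in topology.rings.items()
                 if topology.atoms[m[0]].segment != "ligand"}
    if not lig_rings or not rec_rings:
        return []
    frames = _window(trajectory, frame_window)
    agg: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for f in frames:
        coords = trajectory.coordinates[f]
        for lid, lmem in lig_rings.items():
            lc, ln = _ring_plane(coords[np.array(lmem)])
            for rid_ring, rmem in rec_rings.items():
                rc, rn = _ring_plane(coords[np.array(rmem)])
                dist = float(np.linalg.norm(lc - rc))
                if dist > d_max:
                    continue
                cosang = abs(float(np.dot(ln, rn)))
                tilt = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
                if tilt <= tilt_max:
                    agg.setdefault((lid, rid_ring), []).append((dist, tilt))
    records = []
    nf = len(frames)
    for (lid, rid_ring), geom in sorted(agg.items()):
        partner_atom = topology.rings[rid_ring][0]
        rs, tilts = zip(*geom)
        records.append(InteractionRecord(
            kind="pi_stack",
            partner_residue_id=topology.atoms[partner_atom].residue_id,
            ligand_atoms=tuple(topology.rings[lid]),
            occupancy=len(geom) / nf,
            mean_distance=float(np.mean(rs)), mean_angle=float(np.mean(tilts)),
        ))
    return records


def fingerprint_diff(
    records_a: Sequence[InteractionRecord],
    records_b: Sequence[InteractionRecord],
    occupancy_min: float = DEFAULT_OCCUPANCY_MIN,
) -> list[dict]:
    """Compare two systems' interaction fingerprints.

    Returns rows for interactions present (occupancy >= floor) in exactly
    one system and for partners whose interaction type differs between
    systems (e.g. a hydrogen bond degrading to a bare contact).
    """
    def keyed(records):
        out = {}
        for r in records:
            if r.occupancy >= occupancy_min:
                out[(r.kind, r.partner_residue_id)] = r
        return out

    ka, kb = keyed(records_a), keyed(records_b)
    diff: list[dict] = []
    for key in sorted(set(ka) - set(kb)):
        diff.append({"change": "only_in_a", "kind": key[0],
                     "partner_residue_id": key[1],
                     "occupancy_a": ka[key].occupancy, "occupancy_b": 0.0})
    for key in sorted(set(kb) - set(ka)):
        diff.append({"change": "only_in_b", "kind": key[0],
                     "partner_residue_id": key[1],
                     "occupancy_a": 0.0, "occupancy_b": kb[key].occupancy})
    # type switches: same partner, disjoint specific kinds
    specific = ("hbond", "pi_stack")
    partners_a = {k[1]: k[0] for k in ka if k[0] in specific}
    partners_b = {k[1]: k[0] for k in kb if k[0] in specific}
    contacts_a = {k[1] for k in ka if k[0] == "contact"}
    contacts_b = {k[1] for k in kb if k[0] == "contact"}
    for rid in sorted(set(partners_a) | set(partners_b)):
        kind_a = partners_a.get(rid)
        kind_b = partners_b.get(rid)
        if kind_a == kind_b or (kind_a is not None and kind_b is not None):
            continue
        if kind_a is not None and rid in contacts_b:
            diff.append({
                "change": "type_switch", "partner_residue_id": rid,
                "kind": f"{kind_a}->contact",
                "occupancy_a": ka[(kind_a, rid)].occupancy,
                "occupancy_b": kb[("contact", rid)].occupancy,
            })
        elif kind_b is not None and rid in contacts_a:
            diff.append({
                "change": "type_switch", "partner_residue_id": rid,
                "kind": f"contact->{kind_b}",
                "occupancy_a": ka[("contact", rid)].occupancy,
                "occupancy_b": kb[(kind_b, rid)].occupancy,
            })
    return diff
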