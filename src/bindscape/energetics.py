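"""Single-trajectory MM/GBSA over a frame window, with per-residue
decomposition.

The binding estimate is the end-state average

    dG_bind = dE_vdw + dE_eel + dG_GB + dG_surf

with receptor and ligand conformations extracted from the complex frames
(single-trajectory protocol: intramolecular bonded terms cancel exactly,
so only intermolecular MM terms and the solvation change survive).
Electrostatics is screened Coulomb; dispersion/repulsion is 12-6
Lennard-Jones in the Rmin/epsilon convention with Lorentz-Berthelot
combination; polar solvation is generalized Born with Still's f_GB over
HCT pairwise-descreening effective radii; nonpolar solvation is linear
in the Shrake-Rupley solvent-accessible surface area. No nonbonded
cutoff is applied — the systems this package analyses are small.

Per-frame identities hold exactly by construction:
``gas = vdw + eel``, ``solv = gb + surf``, ``total = gas + solv``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import (
    COULOMB_KCAL,
    DEFAULT_EPS_IN,
    DEFAULT_EPS_OUT,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SURF_BETA,
    DEFAULT_SURF_GAMMA,
    GB_KCAL,
    GB_OFFSET,
)
from .errors import (
    ClashError,
    EmptyInputError,
    ParameterError,
    ValidationError,
)
from .topology import Selection, Topology
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GBSAParams",
    "EnergyComponents",
    "ResidueDecomposition",
    "coulomb_inter",
    "lj_inter",
    "hct_radii",
    "gb_energy",
    "sasa",
    "mmgbsa",
    "per_residue_decomposition",
    "aggregate_components",
]

_CLASH_DISTANCE = 0.1  # Å


@dataclass
class GBSAParams:
    """Tunable MM/GBSA parameters (conventional implicit-solvent defaults)."""

    eps_in: float = DEFAULT_EPS_IN
    eps_out: float = DEFAULT_EPS_OUT
    surf_gamma: float = DEFAULT_SURF_GAMMA   # kcal/(mol Å^2)
    surf_beta: float = DEFAULT_SURF_BETA     # kcal/mol
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = 960
    #: effective Born radii = intrinsic radii (no descreening); closed-form
    #: checks use this mode
    fixed_radii: bool = False


@dataclass
class EnergyComponents:
    """Per-frame MM/GBSA components (kcal/mol) and their mean ± sd."""

    vdw: np.ndarray
    eel: np.ndarray
    gb: np.ndarray
    surf: np.ndarray
    gas: np.ndarray
    solv: np.ndarray
    total: np.ndarray

    _FIELDS = ("vdw", "eel", "gb", "surf", "gas", "solv", "total")

    def mean(self) -> dict[str, float]:
        return {f: float(np.mean(getattr(self, f))) for f in self._FIELDS}

    def sd(self) -> dict[str, float]:
        return {f: float(np.std(getattr(self, f))) for f in self._FIELDS}

    def summary(self) -> dict[str, tuple[float, float]]:
        m, s = self.mean(), self.sd()
        return {f: (m[f], s[f]) for f in self._FIELDS}


@dataclass
class ResidueDecomposition:
    """Per-residue contributions (mean over frames) split by component.

    Pairwise intermolecular terms are split 50/50 between the partners;
    each residue additionally carries its own GB self-polarization change
    and its share of the surface-area change. The contributions of all
    receptor residues plus the ligand term sum to the total binding free
    energy frame by frame.
    """

    #: (segment, residue_id, residue_name) -> component name -> per-frame array
    residues: dict[tuple[str, int, str], dict[str, np.ndarray]]
    ligand_term: dict[str, np.ndarray]

    def totals_per_frame(self) -> np.ndarray:
        acc = sum(sum(parts.values()) for parts in self.residues.values())
        acc = acc + sum(self.ligand_term.values())
        return acc

    def residue_means(self) -> dict[tuple[str, int, str], dict[str, float]]:
        out = {}
        for key, parts in self.residues.items():
            d = {c: float(np.mean(v)) for c, v in parts.items()}
            d["total"] = float(np.mean(sum(parts.values())))
            d["total_sd"] = float(np.std(sum(parts.values())))
            out[key] = d
        return out


# ---------------------------------------------------------------------------
# pairwise molecular-mechanics terms
# ---------------------------------------------------------------------------

def _check_clashes(r: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> None:
    bad = np.argwhere(r < _CLASH_DISTANCE)
    if bad.size:
        i, j = bad[0]
        raise ClashError(
            f"atoms {int(idx_a[i])} and {int(idx_b[j])} are "
            f"{r[i, j]:.3f} Å apart (< {_CLASH_DISTANCE} Å)"
        )


def _pair_distances(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    diff = coords[ia][:, None, :] - coords[ib][None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def coulomb_inter(
    coords: np.ndarray,
    topology: Topology,
    group_a: Selection,
    group_b: Selection,
    eps_in: float = DEFAULT_EPS_IN,
) -> float:
    """Intermolecular screened Coulomb energy between two disjoint groups."""
    ia, ib = group_a.as_array(), group_b.as_array()
    if np.intersect1d(ia, ib).size:
        raise ValidationError("groups must be disjoint")
    r = _pair_distances(coords, ia, ib)
    _check_clashes(r, ia, ib)
    q = topology.charges
    return float(COULOMB_KCAL * np.sum(np.outer(q[ia], q[ib]) / r) / eps_in)


def coulomb_pair_matrix(
    coords: np.ndarray,
    topology: Topology,
    group_a: Selection,
    group_b: Selection,
    eps_in: float = DEFAULT_EPS_IN,
) -> np.ndarray:
    """Pairwise Coulomb terms (|A| x |B|); sums to :func:`coulomb_inter`."""
    ia, ib = group_a.as_array(), group_b.as_array()
    r = _pair_distances(coords, ia, ib)
    _check_clashes(r, ia, ib)
    q = topology.charges
    return COULOMB_KCAL * np.outer(q[ia], q[ib]) / r / eps_in


def lj_pair_matrix(
    coords: np.ndarray,
    topology: Topology,
    group_a: Selection,
    group_b: Selection,
) -> np.ndarray:
    """Pairwise 12-6 LJ terms with Lorentz-Berthelot combination.

    ``Rmin_ij = rmin_half_i + rmin_half_j``, ``eps_ij = sqrt(eps_i eps_j)``;
    the pair term is ``eps_ij ((Rmin/r)^12 - 2 (Rmin/r)^6)``, equal to
    ``-eps_ij`` at ``r = Rmin_ij``.
    """
    ia, ib = group_a.as_array(), group_b.as_array()
    r = _pair_distances(coords, ia, ib)
    _check_clashes(r, ia, ib)
    rmin = topology.lj_rmin_half
    eps = topology.lj_epsilon
    rmin_ij = rmin[ia][:, None] + rmin[ib][None, :]
    eps_ij = np.sqrt(np.outer(eps[ia], eps[ib]))
    sr6 = (rmin_ij / r) ** 6
    return eps_ij * (sr6**2 - 2.0 * sr6)


def lj_inter(
    coords: np.ndarray,
    topology: Topology,
    group_a: Selection,
    group_b: Selection,
) -> float:
    """Intermolecular Lennard-Jones energy between two groups (no cutoff)."""
    return float(np.sum(lj_pair_matrix(coords, topology, group_a, group_b)))


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def _hct_integral(r: float | np.ndarray, rho: float | np.ndarray,
                  s: float | np.ndarray) -> np.ndarray:
    """HCT pairwise-descreening integral H(r, rho, s).

    The 1/|x|^4 volume integral (divided by 4 pi) over the scaled
    neighbor sphere of radius ``s`` at distance ``r``, excluding the
    self sphere of radius ``rho``. Closed form via the spherical-cap
    antiderivative F(u) = (1/4r)(-(s^2 - r^2)/(2 u^2) - 2 r/u - ln u);
    equivalent to the standard HCT formula.
    """
    r = np.asarray(r, dtype=float)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), r.shape)
    s = np.broadcast_to(np.asarray(s, dtype=float), r.shape)

    out = np.zeros_like(r)
    active = (s > 0) & (r + s > rho)
    if not np.any(active):
        return out
    rr, pp, ss = r[active], rho[active], s[active]
    U = rr + ss
    L = np.maximum(pp, np.abs(rr - ss))

    def F(u):
        return (-(ss**2 - rr**2) / (2.0 * u**2) - 2.0 * rr / u - np.log(u)) / (4.0 * rr)

    h = F(U) - F(L)
    engulfed = ss - rr > pp  # self sphere fully inside the neighbor sphere
    if np.any(engulfed):
        h = np.where(engulfed, h + 1.0 / pp - 1.0 / (ss - rr), h)
    out[active] = h
    return out


def hct_radii(
    coords: np.ndarray,
    topology: Topology,
    group: Selection,
    offset: float = GB_OFFSET,
) -> np.ndarray:
    """Effective Born radii for ``group`` by HCT pairwise descreening.

    ``1/R_i = 1/rho_i - sum_j H(r_ij, rho_i, S_j rho_j)`` with reduced
    radii ``rho = gb_radius - offset``. Radii are floored at half the
    reduced radius (logged); an isolated atom recovers ``rho_i``.
    """
    idx = group.as_array()
    if idx.size == 0:
        raise EmptyInputError("group is empty")
    intrinsic = topology.gb_radii[idx]
    if np.any(intrinsic <= 0):
        bad = idx[intrinsic <= 0]
        raise ParameterError(f"non-positive intrinsic GB radius for atoms {bad.tolist()}")
    rho = intrinsic - offset
    if np.any(rho <= 0):
        raise ParameterError("reduced GB radius non-positive; offset too large")
    screen = topology.gb_screens[idx]
    xyz = coords[idx]
    n = idx.size
    inv_R = 1.0 / rho
    if n > 1:
        d = np.sqrt(np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=2))
        s_j = screen * rho  # scaled neighbor radii
        H = _hct_integral(d, rho[:, None], s_j[None, :])
        np.fill_diagonal(H, 0.0)
        inv_R = inv_R - H.sum(axis=1)
    R = 1.0 / inv_R
    floor = 0.5 * rho
    bad = (inv_R <= 0) | (R < floor)
    if np.any(bad):
        logger.warning("hct_radii: %d effective radii floored at rho/2",
                       int(bad.sum()))
        R = np.where(bad, floor, R)
    return R


def gb_energy(
    coords: np.ndarray,
    topology: Topology,
    group: Selection,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
    radii: Optional[np.ndarray] = None,
) -> float:
    """Generalized-Born polar solvation free energy of ``group`` (kcal/mol).

    Still's interpolation ``f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j)))``
    with self terms ``f = R_i``; for one ion this is the Born equation.
    """
    return float(np.sum(gb_atom_shares(coords, topology, group, eps_in,
                                       eps_out, radii)))


def gb_atom_shares(
    coords: np.ndarray,
    topology: Topology,
    group: Selection,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
    radii: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-atom halves of the GB energy (cross terms split 50/50 + self).

    Summing the shares gives :func:`gb_energy` exactly.
    """
    idx = group.as_array()
    if idx.size == 0:
        raise EmptyInputError("group is empty")
    if radii is None:
        radii = hct_radii(coords, topology, group)
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (idx.size,):
        raise ValidationError("radii must be per-atom for the group")
    q = topology.charges[idx]
    xyz = coords[idx]
    pref = -GB_KCAL * (1.0 / eps_in - 1.0 / eps_out)
    r2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=2)
    RR = np.outer(radii, radii)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    # diagonal: r = 0 -> f = R_i exactly
    qq = np.outer(q, q)
    pair = pref * qq / f
    # the energy is the full double sum over (i, j) including the self
    # terms; atom i's share is its row, which splits every unordered
    # cross pair 50/50 between the partners
    return pair.sum(axis=1)


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    rxy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rxy * np.cos(theta), rxy * np.sin(theta), z])


def sasa(
    coords: np.ndarray,
    topology: Topology,
    group: Selection,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = 960,
    radii: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2), Shrake-Rupley style.

    Atom radii default to ``lj_rmin_half`` as a van-der-Waals proxy. The
    point lattice is a fixed Fibonacci spiral, so results are
    deterministic for a given ``n_sphere_points``.
    """
    if n_sphere_points < 24:
        raise ParameterError("n_sphere_points must be >= 24 for usable accuracy")
    idx = group.as_array()
    if idx.size == 0:
        raise EmptyInputError("group is empty")
    if radii is None:
        radii = topology.lj_rmin_half[idx]
    radii = np.asarray(radii, dtype=float)
    ext = radii + probe_radius
    xyz = coords[idx]
    lattice = _sphere_lattice(n_sphere_points)
    areas = np.empty(idx.size)
    for a in range(idx.size):
        pts = xyz[a] + ext[a] * lattice
        # neighbors whose expanded sphere can bury points of atom a
        d = np.sqrt(np.sum((xyz - xyz[a]) ** 2, axis=1))
        neigh = np.where((d < ext + ext[a]) & (np.arange(idx.size) != a))[0]
        if neigh.size:
            dp = np.sum((pts[:, None, :] - xyz[neigh][None, :, :]) ** 2, axis=2)
            lim = ext[neigh][None, :] ** 2
            inside = dp < lim - 1e-9
            # points exactly on a neighbor's surface (coincident spheres):
            # assign the shared surface to the lower atom index
            boundary = (np.abs(dp - lim) <= 1e-9) & (neigh[None, :] < a)
            buried = np.any(inside | boundary, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[a] = frac * 4.0 * np.pi * ext[a] ** 2
    return areas


# ---------------------------------------------------------------------------
# MM/GBSA composition
# ---------------------------------------------------------------------------

def _effective_radii(coords, topology, group, params: GBSAParams) -> np.ndarray:
    if params.fixed_radii:
        return topology.gb_radii[group.as_array()]
    return hct_radii(coords, topology, group)


def _union_selection(a: Selection, b: Selection) -> Selection:
    return Selection(indices=tuple(sorted(set(a.indices) | set(b.indices))))


def mmgbsa(
    trajectory: Trajectory,
    topology: Topology,
    receptor: Selection,
    ligand: Selection,
    frame_window: Optional[tuple[int, int]] = None,
    params: Optional[GBSAParams] = None,
) -> EnergyComponents:
    """Single-trajectory MM/GBSA binding components over a frame window.

    Receptor and ligand conformations are extracted from the complex
    frames. Effective Born radii and SASA are recomputed per end state
    (complex / receptor / ligand), so the solvation terms capture
    desolvation of the interface.
    """
    trajectory.check_topology(topology)
    if params is None:
        params = GBSAParams()
    start, stop = frame_window if frame_window is not None else (0, trajectory.n_frames)
    if not (0 <= start < stop <= trajectory.n_frames):
        raise EmptyInputError(f"empty or invalid frame window [{start}, {stop})")
    cx = _union_selection(receptor, ligand)
    nf = stop - start
    comp = {f: np.empty(nf) for f in ("vdw", "eel", "gb", "surf")}
    for k, f in enumerate(range(start, stop)):
        coords = trajectory.coordinates[f]
        comp["vdw"][k] = lj_inter(coords, topology, receptor, ligand)
        comp["eel"][k] = coulomb_inter(coords, topology, receptor, ligand,
                                       params.eps_in)
        gb_parts = {}
        sa_parts = {}
        for name, grp in (("complex", cx), ("receptor", receptor), ("ligand", ligand)):
            radii = _effective_radii(coords, topology, grp, params)
            gb_parts[name] = gb_energy(coords, topology, grp, params.eps_in,
                                       params.eps_out, radii)
            sa_parts[name] = float(np.sum(sasa(
                coords, topology, grp, params.probe_radius,
                params.n_sphere_points)))
        comp["gb"][k] = gb_parts["complex"] - gb_parts["receptor"] - gb_parts["ligand"]
        dsasa = sa_parts["complex"] - sa_parts["receptor"] - sa_parts["ligand"]
        comp["surf"][k] = params.surf_gamma * dsasa + params.surf_beta
    return aggregate_components(comp["vdw"], comp["eel"], comp["gb"], comp["surf"])


def per_residue_decomposition(
    trajectory: Trajectory,
    topology: Topology,
    receptor: Selection,
    ligand: Selection,
    frame_window: Optional[tuple[int, int]] = None,
    params: Optional[GBSAParams] = None,
) -> ResidueDecomposition:
    """Split the MM/GBSA total into per-residue contributions.

    Intermolecular Coulomb and LJ pair terms are split 50/50 between the
    receptor residue and the ligand; GB is decomposed through per-atom
    shares of each end state; the surface term through per-atom SASA
    changes. The residue contributions plus the ligand term reproduce the
    total binding free energy exactly, frame by frame.
    """
    trajectory.check_topology(topology)
    if params is None:
        params = GBSAParams()
    start, stop = frame_window if frame_window is not None else (0, trajectory.n_frames)
    if not (0 <= start < stop <= trajectory.n_frames):
        raise EmptyInputError(f"empty or invalid frame window [{start}, {stop})")
    nf = stop - start
    rec_idx = receptor.as_array()
    lig_idx = ligand.as_array()
    cx = _union_selection(receptor, ligand)
    cx_idx = cx.as_array()
    pos_in_cx = {int(a): i for i, a in enumerate(cx_idx)}

    rec_residues = []
    seen = set()
    for a in rec_idx:
        res = topology.residue_of(int(a))
        key = (res[0], res[1], res[2])
        if key not in seen:
            seen.add(key)
            rec_residues.append((key, [int(i) for i in rec_idx
                                       if res[3] <= i < res[4]]))

    zero = lambda: {c: np.zeros(nf) for c in ("eel", "vdw", "gb", "surf")}
    residues = {key: zero() for key, _ in rec_residues}
    ligand_term = zero()

    rec_row = {int(a): i for i, a in enumerate(rec_idx)}
    for k, f in enumerate(range(start, stop)):
        coords = trajectory.coordinates[f]
        eel_pairs = coulomb_pair_matrix(coords, topology, receptor, ligand,
                                        params.eps_in)
        vdw_pairs = lj_pair_matrix(coords, topology, receptor, ligand)

        shares = {}
        sa = {}
        for name, grp in (("complex", cx), ("receptor", receptor), ("ligand", ligand)):
            radii = _effective_radii(coords, topology, grp, params)
            shares[name] = gb_atom_shares(coords, topology, grp, params.eps_in,
                                          params.eps_out, radii)
            sa[name] = sasa(coords, topology, grp, params.probe_radius,
                            params.n_sphere_points)
        rec_pos = {int(a): i for i, a in enumerate(rec_idx)}
        lig_pos = {int(a): i for i, a in enumerate(lig_idx)}

        for key, atoms in rec_residues:
            rows = [rec_row[a] for a in atoms]
            residues[key]["eel"][k] = 0.5 * eel_pairs[rows, :].sum()
            residues[key]["vdw"][k] = 0.5 * vdw_pairs[rows, :].sum()
            dgb = sum(shares["complex"][pos_in_cx[a]] - shares["receptor"][rec_pos[a]]
                      for a in atoms)
            residues[key]["gb"][k] = dgb
            dsa = sum(sa["complex"][pos_in_cx[a]] - sa["receptor"][rec_pos[a]]
                      for a in atoms)
            residues[key]["surf"][k] = params.surf_gamma * dsa
        ligand_term["eel"][k] = 0.5 * eel_pairs.sum()
        ligand_term["vdw"][k] = 0.5 * vdw_pairs.sum()
        ligand_term["gb"][k] = sum(
            shares["complex"][pos_in_cx[a]] - shares["ligand"][lig_pos[a]]
            for a in lig_idx
        )
        ligand_term["surf"][k] = params.surf_gamma * sum(
            sa["complex"][pos_in_cx[a]] - sa["ligand"][lig_pos[a]]
            for a in lig_idx
        ) + params.surf_beta
    return ResidueDecomposition(residues=residues, ligand_term=ligand_term)


def aggregate_components(vdw, eel, gb, surf) -> EnergyComponents:
    """Assemble the seven reported quantities from the four raw components.

    Accepts scalars or per-frame arrays; ``gas = vdw + eel``,
    ``solv = gb + surf``, ``total = gas + solv`` hold element-wise.
    """
    vdw = np.atleast_1d(np.asarray(vdw, dtype=float))
    eel = np.atleast_1d(np.asarray(eel, dtype=float))
    gb = np.atleast_1d(np.asarray(gb, dtype=float))
    surf = np.atleast_1d(np.asarray(surf, dtype=float))
    if not (vdw.shape == eel.shape == gb.shape == surf.shape):
        raise ValidationError("component arrays must share a shape")
    gas = vdw + eel
    solv = gb + surf
    total = gas + solv
    return EnergyComponents(vdw=vdw, eel=eel, gb=gb, surf=surf, gas=gas,
                            solv=solv, total=total)
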