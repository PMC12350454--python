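"""Toy complexes and trajectories with known ground truth.

Three generators make every pipeline stage testable without any real MD
output:

* :func:`build_toy_complex` — a bead "kinase": a curved Cα-like chain
  (3.8 Å spacing) whose concavity forms a pocket, plus a small ligand
  with a six-bead planar ring, full nonbonded parameters (zero net charge
  per molecule), and designated donor/H/acceptor atoms.
* :func:`simulate_two_basin` — an overdamped Langevin walk on a tilted
  quartic double well in a 1-D binding collective variable (the
  ligand–anchor mass-center distance), embedded deterministically into
  the 2-D CV pair (ligand RMSD-like, COM distance) the landscape stage
  consumes. The long-run CV histogram is Boltzmann-distributed in the
  returned exact potential, which is handed back for oracle checks.
* :func:`simulate_block_correlated` — frames whose bead displacements are
  drawn from a zero-mean block-covariance Gaussian (intra-block rho_in,
  inter-block rho_out, isotropic per axis), so the sample DCCM converges
  to the prescribed correlations.

All generators are pure functions of (spec, seed): one integer seed, one
`numpy` Generator, no global RNG state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad

from .constants import KB_KCAL
from .errors import ParameterError, StabilityError, ValidationError
from .topology import AtomRecord, Topology
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ToySpec",
    "TwoBasinTruth",
    "build_toy_complex",
    "simulate_two_basin",
    "simulate_block_correlated",
    "write_fixture_set",
]

_CA_SPACING = 3.8  # Å, consecutive bead distance
_GAMMA = 1.0       # ps^-1 amu-equivalent friction; only the stationary
                   # distribution matters downstream


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one toy complex + trajectory.

    The double well lives in the 1-D CV ``x`` = ligand–anchor mass-center
    distance: minima near ``cv_center_1`` / ``cv_center_2`` (Å), free-
    energy offset ``delta_u_kcal`` between them and barrier
    ``barrier_kcal`` above the lower well. ``coupling`` scales down all
    off-diagonal bead correlations by ``(1 - coupling)`` while the ligand
    occupies basin 2 (state-dependent decorrelation).
    """

    n_residues: int = 20
    n_ligand_atoms: int = 8
    temperature_K: float = 310.0
    frame_spacing_ps: float = 10.0
    integration_dt_ps: float = 0.025
    n_frames: int = 5000
    seed: int = 0
    # basin parameters
    cv_center_1: float = 6.0
    cv_center_2: float = 10.0
    delta_u_kcal: float = 1.0
    barrier_kcal: float = 3.0
    # correlation parameters
    n_blocks: int = 2
    rho_intra: float = 0.9
    rho_inter: float = 0.0
    sigma: float = 0.5  # Å per-atom displacement scale
    coupling: float = 0.0

    def validate(self) -> None:
        if self.n_residues < 4:
            raise ParameterError("n_residues < 4: pocket undefinable")
        if self.n_ligand_atoms < 1:
            raise ParameterError("need at least one ligand atom")
        if not (0.0 <= self.rho_intra <= 1.0 and 0.0 <= self.rho_inter <= 1.0):
            raise ParameterError("correlations must lie in [0, 1]")
        if not (0.0 <= self.coupling <= 1.0):
            raise ParameterError("coupling must lie in [0, 1]")
        if self.barrier_kcal < 0:
            raise ParameterError("barrier must be non-negative")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.cv_center_2 <= self.cv_center_1:
            raise ParameterError("cv_center_2 must exceed cv_center_1")
        if self.frame_spacing_ps <= 0:
            raise ParameterError("frame_spacing_ps must be positive")
        if not (0 < self.integration_dt_ps <= self.frame_spacing_ps):
            raise ParameterError(
                "integration_dt_ps must be positive and at most the frame spacing"
            )

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature_K


@dataclass
class TwoBasinTruth:
    """Exact generator internals handed back for oracle checks."""

    potential: Callable[[np.ndarray], np.ndarray]  # U(x), kcal/mol
    gradient: Callable[[np.ndarray], np.ndarray]
    cv_center_1: float
    cv_center_2: float
    barrier_kcal: float
    delta_u_kcal: float
    kT: float
    embed_slope: float
    embed_intercept: float
    embed_wobble_amp: float
    embed_wobble_period: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.cv_center_1 + self.cv_center_2)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Deterministic 1-D -> 2nd CV embedding (ligand-RMSD-like axis).

        A linear trend plus a sinusoidal modulation: the resulting curve
        in the 2-D CV plane bends through flat and steep stretches like a
        real (ligand RMSD, COM distance) landscape, so its binned image
        stays 4-connected instead of degenerating to a bare diagonal.
        """
        u = np.asarray(x, dtype=float) - self.cv_center_1
        return (self.embed_intercept + self.embed_slope * u
                + self.embed_wobble_amp
                * np.sin(2.0 * np.pi * u / self.embed_wobble_period))

    def boltzmann_weight(self, lo: float, hi: float) -> float:
        """Unnormalized Boltzmann weight of the CV interval [lo, hi]."""
        val, _ = quad(lambda x: np.exp(-self.potential(x) / self.kT), lo, hi,
                      limit=200)
        return val

    def expected_occupancy_ratio(self) -> float:
        """Boltzmann basin-2 : basin-1 population ratio from the exact U."""
        width = self.cv_center_2 - self.cv_center_1
        lo = self.cv_center_1 - 3.0 * width
        hi = self.cv_center_2 + 3.0 * width
        w1 = self.boltzmann_weight(lo, self.midpoint)
        w2 = self.boltzmann_weight(self.midpoint, hi)
        return w2 / w1

    def expected_bin_weights(self, fel, n_grid: int = 400_000) -> np.ndarray:
        """Exact (quadrature) Boltzmann weight of every 2-D bin.

        The second CV is a deterministic function of the first, so the
        weight of bin (i, j) is the integral of ``exp(-U/kT)`` over the
        x-values that land in that bin. Computed by midpoint quadrature
        on a fine x grid pushed through the embedding.
        """
        lo, hi = float(fel.x_edges[0]), float(fel.x_edges[-1])
        dx = (hi - lo) / n_grid
        xs = lo + (np.arange(n_grid) + 0.5) * dx
        w = np.exp(-self.potential(xs) / self.kT) * dx
        ys = self.embed(xs)
        grid, _, _ = np.histogram2d(xs, ys, bins=[fel.x_edges, fel.y_edges],
                                    weights=w)
        return grid

    def fel_rms_error(self, fel, min_count: int = 25) -> tuple[float, int]:
        """RMS deviation of an empirical landscape from the exact potential.

        Both surfaces are referenced to their own maximum-weight bin and
        compared over well-sampled bins (``count >= min_count``), where
        the histogram estimate of G is not shot-noise dominated. Returns
        ``(rms kcal/mol, n bins used)``.
        """
        pops = np.argwhere(fel.counts >= min_count)
        if pops.size == 0:
            raise ValidationError("no well-sampled bins")
        weights = self.expected_bin_weights(fel)[tuple(pops.T)]
        counts = fel.counts[tuple(pops.T)].astype(float)
        usable = weights > 0
        emp = -self.kT * np.log(counts[usable] / counts.max())
        model = -self.kT * np.log(weights[usable] / weights.max())
        rms = float(np.sqrt(np.mean((emp - model) ** 2)))
        return rms, int(usable.sum())


_SINGLE_WELL_K = 2.0  # kcal/(mol Å^2) harmonic constant for barrier = 0


def _double_well(spec: ToySpec) -> tuple[Callable, Callable]:
    c1, c2 = spec.cv_center_1, spec.cv_center_2
    if spec.barrier_kcal == 0.0:
        # degenerate case: a single harmonic well at c1 (a tilted quartic
        # with zero barrier would be unconfined)
        def U0(x):
            x = np.asarray(x, dtype=float)
            return 0.5 * _SINGLE_WELL_K * (x - c1) ** 2

        def dU0(x):
            x = np.asarray(x, dtype=float)
            return _SINGLE_WELL_K * (x - c1)

        return U0, dU0
    m = 0.5 * (c1 + c2)
    a = 0.5 * (c2 - c1)
    h = spec.barrier_kcal
    tilt = spec.delta_u_kcal / (c2 - c1)

    def U(x):
        x = np.asarray(x, dtype=float)
        return h * ((x - m) ** 2 - a**2) ** 2 / a**4 + tilt * (x - c1)

    def dU(x):
        x = np.asarray(x, dtype=float)
        return 4.0 * h * (x - m) * ((x - m) ** 2 - a**2) / a**4 + tilt

    return U, dU


def _protein_reference(spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Bead chain on a circular arc (concave pocket) with a gentle z-wave.

    Returns (bead coordinates, pocket center). The z modulation keeps the
    chain non-planar so superpositions are well-conditioned.
    """
    n = spec.n_residues
    arc_radius = max(6.0, n * _CA_SPACING / np.pi * 0.55)
    dtheta = 2.0 * np.arcsin(_CA_SPACING / (2.0 * arc_radius))
    theta = (np.arange(n) - (n - 1) / 2.0) * dtheta
    beads = np.column_stack([
        arc_radius * np.cos(theta),
        arc_radius * np.sin(theta),
        0.8 * np.sin(np.arange(n) * 0.9),
    ])
    pocket_center = np.zeros(3)  # arc center: the concave side
    return beads, pocket_center


def build_toy_complex(spec: ToySpec) -> tuple[Topology, np.ndarray, dict]:
    """Deterministic bead complex with full nonbonded parameters.

    Returns ``(topology, reference coordinates, topology-JSON document)``.
    Charges are drawn and recentred to sum to zero per molecule; LJ and GB
    parameters are drawn in physically plausible ranges (intrinsic Born
    radii 1.2–2.0 Å). One pocket-adjacent residue carries a donor-heavy /
    polar-H pair, the ligand an acceptor and a six-bead planar ring.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed % (2**31), 11])
    beads, pocket = _protein_reference(spec)
    n = spec.n_residues
    anchor_res = n // 2  # 0-based residue index used as the CV anchor
    donor_res = max(0, anchor_res - 2)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    q_prot = rng.normal(0.0, 0.15, n)
    q_prot -= q_prot.mean()
    for i in range(n):
        atoms.append(AtomRecord(
            index=len(atoms), name="CA", residue_id=i + 1, residue_name="ALA",
            segment="protein", mass=110.0, charge=float(q_prot[i]),
            lj_rmin_half=float(rng.uniform(1.6, 2.0)),
            lj_epsilon=float(rng.uniform(0.05, 0.2)),
            gb_radius=float(rng.uniform(1.5, 2.0)),
            gb_screen=float(rng.uniform(0.7, 0.85)),
            is_donor_heavy=(i == donor_res),
            is_acceptor=(i == donor_res + 1),
        ))
        coords.append(beads[i])
        if i == donor_res:
            # polar hydrogen 1.0 Å from its donor bead, toward the pocket
            towards = pocket - beads[i]
            towards /= np.linalg.norm(towards)
            h_charge = 0.25
            atoms.append(AtomRecord(
                index=len(atoms), name="HD", residue_id=i + 1,
                residue_name="ALA", segment="protein", mass=1.008,
                charge=h_charge, lj_rmin_half=0.6, lj_epsilon=0.0157,
                gb_radius=1.2, gb_screen=0.85, is_polar_h=True,
            ))
            coords.append(beads[i] + 1.0 * towards)
            # re-balance so the protein still sums to zero
            atoms[-2] = dataclasses.replace(atoms[-2],
                                            charge=atoms[-2].charge - h_charge)

    # ligand: hexagonal ring (6 beads) plus a short tail, near the pocket
    nl = spec.n_ligand_atoms
    ring_size = min(6, nl)
    lig_local = []
    for k in range(ring_size):
        ang = 2.0 * np.pi * k / ring_size
        lig_local.append([1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.0])
    for k in range(ring_size, nl):
        lig_local.append([0.0, 0.0, 1.4 * (k - ring_size + 1)])
    lig_local = np.array(lig_local)
    lig_local -= lig_local.mean(axis=0)

    anchor_xyz = beads[anchor_res]
    direction = pocket - anchor_xyz
    direction /= np.linalg.norm(direction)
    lig_center = anchor_xyz + spec.cv_center_1 * direction
    q_lig = rng.normal(0.0, 0.2, nl)
    q_lig -= q_lig.mean()
    for k in range(nl):
        atoms.append(AtomRecord(
            index=len(atoms), name=f"L{k}", residue_id=1, residue_name="LIG",
            segment="ligand", mass=float(rng.uniform(12.0, 16.0)),
            charge=float(q_lig[k]),
            lj_rmin_half=float(rng.uniform(1.5, 1.9)),
            lj_epsilon=float(rng.uniform(0.05, 0.15)),
            gb_radius=float(rng.uniform(1.2, 1.8)),
            gb_screen=float(rng.uniform(0.7, 0.85)),
            is_acceptor=(k == 0),
            ring_id=0 if (k < ring_size and ring_size >= 3) else None,
        ))
        coords.append(lig_center + lig_local[k])

    topology = Topology(atoms=atoms)
    reference = np.array(coords)
    doc = _topology_json_doc(topology)
    return topology, reference, doc


def _topology_json_doc(topology: Topology) -> dict:
    segments: dict[str, list[int]] = {}
    for a in topology.atoms:
        segments.setdefault(a.segment, []).append(a.index)
    return {
        "atoms": [
            {
                "index": a.index, "charge": a.charge,
                "lj_rmin_half": a.lj_rmin_half, "lj_epsilon": a.lj_epsilon,
                "gb_radius": a.gb_radius, "gb_screen": a.gb_screen,
                "donor_heavy": a.is_donor_heavy, "acceptor": a.is_acceptor,
                "polar_h": a.is_polar_h, "mass": a.mass,
            }
            for a in topology.atoms
        ],
        "segments": segments,
        "rings": [m for _, m in sorted(topology.rings.items())],
    }


def _block_correlation(spec: ToySpec, n_sites: int, damp: float = 0.0) -> np.ndarray:
    """Site correlation matrix: rho_intra inside contiguous blocks,
    rho_inter across, all off-diagonals scaled by (1 - damp)."""
    block = np.repeat(np.arange(spec.n_blocks),
                      np.diff(np.linspace(0, n_sites, spec.n_blocks + 1).astype(int)))
    same = block[:, None] == block[None, :]
    C = np.where(same, spec.rho_intra, spec.rho_inter) * (1.0 - damp)
    np.fill_diagonal(C, 1.0)
    return C


def _correlation_cholesky(C: np.ndarray) -> np.ndarray:
    evals = np.linalg.eigvalsh(C)
    if evals.min() < -1e-10:
        raise ParameterError(
            f"correlation matrix not positive semi-definite "
            f"(min eigenvalue {evals.min():.3e})"
        )
    # eigen-based square root tolerates the semi-definite boundary
    w, V = np.linalg.eigh(C)
    return V * np.sqrt(np.clip(w, 0.0, None))


def _residue_displacements(rng: np.random.Generator, L: np.ndarray,
                           sigma: float) -> np.ndarray:
    """One frame of correlated (n_sites, 3) displacements."""
    z = rng.standard_normal((L.shape[0], 3))
    return sigma * (L @ z)


def _spread_to_atoms(topology: Topology, disp_per_residue: np.ndarray,
                     segment: str = "protein") -> np.ndarray:
    """Apply per-residue displacements to every atom of that residue."""
    out = np.zeros((topology.n_atoms, 3))
    r = 0
    for seg, rid, rname, start, stop in topology.residues:
        if seg != segment:
            continue
        out[start:stop] = disp_per_residue[r]
        r += 1
    return out


def _protein_residue_count(topology: Topology) -> int:
    return sum(1 for seg, *_ in topology.residues if seg == "protein")


def simulate_two_basin(
    spec: ToySpec,
) -> tuple[Trajectory, dict[str, np.ndarray], TwoBasinTruth]:
    """Langevin walk on the tilted double well, mapped onto the complex.

    The overdamped Euler-Maruyama update
    ``x <- x - U'(x) dt/gamma + sqrt(2 kT dt/gamma) eta`` runs at
    ``integration_dt_ps``; frames are saved every ``frame_spacing_ps``
    (the intervening substeps decorrelate successive frames and keep the
    discretization bias of the stationary law negligible). The long-run
    CV histogram converges to ``exp(-U/kT)``. The ligand translates
    rigidly along the pocket axis so the CV is the ligand-anchor
    mass-center distance; protein beads fluctuate with the
    block-correlated noise (scaled down by ``coupling`` while in basin 2).

    Returns ``(trajectory, {"cv_x": ..., "cv_y": ...}, truth)`` where
    ``cv_x`` is the exact CV series, ``cv_y`` its deterministic embedding
    and ``truth`` carries the exact potential for oracle checks.
    """
    spec.validate()
    U, dU = _double_well(spec)
    dt = spec.integration_dt_ps
    substeps = max(1, int(round(spec.frame_spacing_ps / dt)))
    kT = spec.kT

    # stability pre-check over the thermally accessible region (the walker
    # cannot climb far beyond barrier + ~10 kT up the outer quartic walls)
    width = spec.cv_center_2 - spec.cv_center_1
    grid = np.linspace(spec.cv_center_1 - width, spec.cv_center_2 + width, 2048)
    accessible = grid[U(grid) <= spec.barrier_kcal + 10.0 * kT]
    max_step = np.max(np.abs(dU(accessible))) * dt / _GAMMA
    if max_step > width:
        raise StabilityError(
            f"integration dt = {dt} ps too large: max |U'| dt/gamma = "
            f"{max_step:.2f} Å exceeds the well separation {width:.2f} Å"
        )

    rng = np.random.default_rng([spec.seed % (2**31), 23])
    x = np.empty(spec.n_frames)
    xt = float(spec.cv_center_1)
    amp = float(np.sqrt(2.0 * kT * dt / _GAMMA))
    # scalar-inlined dU for the hot loop (identical to _double_well's)
    m = 0.5 * (spec.cv_center_1 + spec.cv_center_2)
    a2 = (0.5 * width) ** 2
    a4 = a2 * a2
    h4 = 4.0 * spec.barrier_kcal
    tilt = spec.delta_u_kcal / width
    dt_g = dt / _GAMMA
    harmonic = spec.barrier_kcal == 0.0
    c1 = float(spec.cv_center_1)
    for t in range(spec.n_frames):
        noise = rng.standard_normal(substeps)
        if harmonic:
            for s in range(substeps):
                xt = xt - _SINGLE_WELL_K * (xt - c1) * dt_g + amp * noise[s]
        else:
            for s in range(substeps):
                d = xt - m
                xt = xt - (h4 * d * (d * d - a2) / a4 + tilt) * dt_g + amp * noise[s]
        x[t] = xt

    topology, reference, _ = build_toy_complex(spec)
    n_prot_res = _protein_residue_count(topology)
    lig_idx = np.array([a.index for a in topology.atoms if a.segment == "ligand"])
    anchor_res = spec.n_residues // 2
    anchor_atom = next(a.index for a in topology.atoms
                       if a.segment == "protein" and a.residue_id == anchor_res + 1)
    direction = reference[lig_idx].mean(axis=0) - reference[anchor_atom]
    direction /= np.linalg.norm(direction)

    L_free = _correlation_cholesky(_block_correlation(spec, n_prot_res))
    L_bound = _correlation_cholesky(
        _block_correlation(spec, n_prot_res, damp=spec.coupling))
    midpoint = 0.5 * (spec.cv_center_1 + spec.cv_center_2)

    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    for t in range(spec.n_frames):
        L = L_bound if x[t] > midpoint else L_free
        disp = _spread_to_atoms(
            topology, _residue_displacements(rng, L, spec.sigma))
        frame = reference + disp
        frame[lig_idx] = reference[lig_idx] + (x[t] - spec.cv_center_1) * direction
        coords[t] = frame

    truth = TwoBasinTruth(
        potential=U, gradient=dU,
        cv_center_1=spec.cv_center_1, cv_center_2=spec.cv_center_2,
        barrier_kcal=spec.barrier_kcal, delta_u_kcal=spec.delta_u_kcal,
        kT=kT, embed_slope=0.6, embed_intercept=1.0,
        embed_wobble_amp=0.35, embed_wobble_period=2.0,
    )
    cv = {"cv_x": x, "cv_y": truth.embed(x)}
    trajectory = Trajectory(coordinates=coords, frame_spacing_ps=dt)
    return trajectory, cv, truth


def simulate_block_correlated(spec: ToySpec) -> Trajectory:
    """Frames of block-correlated Gaussian bead displacements.

    Each frame's per-residue displacement (applied to all atoms of the
    residue, same across x/y/z independently) is drawn from a zero-mean
    Gaussian whose site correlation is ``rho_intra`` within contiguous
    residue blocks and ``rho_inter`` across, scaled by ``sigma`` Å. The
    ligand stays at its reference position.
    """
    spec.validate()
    topology, reference, _ = build_toy_complex(spec)
    n_prot_res = _protein_residue_count(topology)
    L = _correlation_cholesky(_block_correlation(spec, n_prot_res))
    rng = np.random.default_rng([spec.seed % (2**31), 37])
    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    for t in range(spec.n_frames):
        disp = _spread_to_atoms(
            topology, _residue_displacements(rng, L, spec.sigma))
        coords[t] = reference + disp
    return Trajectory(coordinates=coords, frame_spacing_ps=spec.frame_spacing_ps)


# ---------------------------------------------------------------------------
# fixture sets on disk
# ---------------------------------------------------------------------------

_DEFAULT_FIXTURES: tuple[tuple[str, str, ToySpec], ...] = (
    ("two_basin", "two_basin", ToySpec(seed=101, n_frames=2000)),
    ("block_corr", "block_correlated", ToySpec(seed=202, n_frames=2000)),
    ("static_complex", "static", ToySpec(seed=303, n_frames=1)),
)


def write_fixture_set(
    out_dir,
    fixtures: Optional[Sequence[tuple[str, str, ToySpec]]] = None,
) -> dict:
    """Write PDB + DCD + topology JSON (+ manifest) for each fixture.

    ``fixtures`` is a sequence of ``(name, kind, spec)`` with kind one of
    ``two_basin | block_correlated | static``; the default set covers all
    three. The manifest records seeds, parameters and the true barrier so
    regeneration is reproducible; identical specs yield identical files.
    """
    from .io import write_dcd, write_pdb, write_topology_json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fixtures is None:
        fixtures = _DEFAULT_FIXTURES
    manifest = {"fixtures": []}
    for name, kind, spec in fixtures:
        topology, reference, _ = build_toy_complex(spec)
        if kind == "two_basin":
            trajectory, cv, truth = simulate_two_basin(spec)
        elif kind == "block_correlated":
            trajectory = simulate_block_correlated(spec)
        elif kind == "static":
            trajectory = Trajectory(
                coordinates=reference[None, :, :].repeat(spec.n_frames, axis=0),
                frame_spacing_ps=spec.frame_spacing_ps,
            )
        else:
            raise ValidationError(f"unknown fixture kind '{kind}'")
        pdb = out_dir / f"{name}.pdb"
        dcd = out_dir / f"{name}.dcd"
        tjson = out_dir / f"{name}.topology.json"
        write_pdb(pdb, topology, reference)
        write_dcd(dcd, trajectory)
        write_topology_json(tjson, topology)
        entry = {
            "name": name,
            "kind": kind,
            "seed": spec.seed,
            "spec": dataclasses.asdict(spec),
            "true_barrier_kcal": spec.barrier_kcal,
            "files": {"pdb": pdb.name, "dcd": dcd.name, "topology": tjson.name},
            "sha256": {p.name: _sha256(p) for p in (pdb, dcd, tjson)},
        }
        manifest["fixtures"].append(entry)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("write_fixture_set: %s <- %d fixtures", out_dir, len(manifest["fixtures"]))
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
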