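"""Superposition and stability metrics: RMSD, RMSF, RoG, COM distances.

All superpositions are weighted least-squares rigid fits (Kabsch). The
ligand RMSD convention is deliberate: fit on the protein selection, then
measure the ligand without re-fitting, so the series reflects pose change
inside the pocket — the quantity used as a binding-mode collective
variable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    DimensionError,
    EmptyInputError,
    ValidationError,
)
from .topology import Selection, Topology
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SeriesResult",
    "kabsch_fit",
    "rmsd_series",
    "average_replicas",
    "rmsf",
    "radius_of_gyration",
    "com_distance_series",
    "select_stable_replica",
]


@dataclass
class SeriesResult:
    """A per-frame (or per-residue) scalar series with its time spacing."""

    values: np.ndarray
    frame_spacing_ps: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"series '{self.label}' has non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMS
    deviation from ``reference``. The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DimensionError(
            f"mobile {mobile.shape} vs reference {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for a rigid fit, got {n}")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    com_mob = weights @ mobile / wsum
    com_ref = weights @ reference / wsum
    mob_c = mobile - com_mob
    ref_c = reference - com_ref
    # collinear point sets leave the rotation about the axis undetermined
    if np.linalg.matrix_rank(ref_c * weights[:, None], tol=1e-10) < 2:
        raise DegenerateGeometryError("reference points are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=weights)
    rotation = rot.as_matrix()
    translation = com_ref - rotation @ com_mob
    # recompute the residual directly: scipy's rssd loses precision near 0
    moved = mobile @ rotation.T + translation
    rmsd = _weighted_rmsd(moved, reference, weights)
    return rotation, translation, float(rmsd)


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(weights @ d2 / weights.sum()))


def rmsd_series(
    trajectory: Trajectory,
    topology: Topology,
    measure_selection: Selection,
    fit_selection: Optional[Selection] = None,
    reference: Optional[np.ndarray] = None,
    label: str = "rmsd",
) -> SeriesResult:
    """Per-frame RMSD after superposition on ``fit_selection`` only.

    ``reference`` defaults to frame 0. With ``fit_selection=None`` no
    superposition is applied (raw deviation from the reference). The fit
    is mass-weighted; the measured RMSD is mass-weighted over
    ``measure_selection``, which is *not* re-fit — passing the protein as
    fit and the ligand as measure yields the pocket-frame ligand RMSD.
    """
    trajectory.check_topology(topology)
    if len(measure_selection) == 0:
        raise EmptyInputError("measure_selection is empty")
    ref = trajectory.coordinates[0] if reference is None else np.asarray(reference, float)
    if ref.shape != (topology.n_atoms, 3):
        raise DimensionError(f"reference shape {ref.shape}")
    masses = topology.masses
    meas_idx = measure_selection.as_array()
    values = np.empty(trajectory.n_frames)
    if fit_selection is not None and len(fit_selection) == 0:
        raise EmptyInputError("fit_selection is empty")
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        if fit_selection is not None:
            fit_idx = fit_selection.as_array()
            rot, trans, _ = kabsch_fit(
                frame[fit_idx], ref[fit_idx], weights=masses[fit_idx]
            )
            moved = frame[meas_idx] @ rot.T + trans
        else:
            moved = frame[meas_idx]
        values[f] = _weighted_rmsd(moved, ref[meas_idx], masses[meas_idx])
    return SeriesResult(values=values, frame_spacing_ps=trajectory.frame_spacing_ps,
                        label=label)


def average_replicas(*series: SeriesResult, label: str = "mean") -> SeriesResult:
    """Element-wise mean of replica series (equal lengths and spacings)."""
    if not series:
        raise EmptyInputError("no series given")
    n = len(series[0])
    spacing = series[0].frame_spacing_ps
    for s in series[1:]:
        if len(s) != n:
            raise DimensionError(
                f"series lengths differ: {n} vs {len(s)} ('{s.label}')"
            )
        if s.frame_spacing_ps != spacing:
            raise ValidationError("series frame spacings differ")
    stacked = np.stack([s.values for s in series])
    return SeriesResult(values=stacked.mean(axis=0), frame_spacing_ps=spacing,
                        label=label)


def align_to_mean(
    trajectory: Trajectory,
    topology: Topology,
    fit_selection: Selection,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all frames onto their mean structure.

    Fits on ``fit_selection`` (mass-weighted), recomputes the mean, and
    repeats until the mean shifts by < ``tol`` Å or ``max_iter`` rounds.
    Returns ``(aligned coordinates, converged mean structure)``; the
    transform from each fit is applied to *all* atoms.
    """
    trajectory.check_topology(topology)
    if len(fit_selection) == 0:
        raise EmptyInputError("fit_selection is empty")
    fit_idx = fit_selection.as_array()
    masses = topology.masses[fit_idx]
    coords = trajectory.coordinates.copy()
    mean = coords[0].copy()
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            rot, trans, _ = kabsch_fit(coords[f][fit_idx], mean[fit_idx], masses)
            coords[f] = coords[f] @ rot.T + trans
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(np.max(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return coords, mean


def rmsf(
    trajectory: Trajectory,
    topology: Topology,
    selection: Selection,
    fit_selection: Optional[Selection] = None,
    label: str = "rmsf",
) -> SeriesResult:
    """Per-residue RMSF after iterative superposition onto the mean structure.

    Per atom: sqrt(<|r_i - <r_i>|^2>) over frames; atoms are then averaged
    within each residue, so the result has one value per residue touched by
    ``selection``.
    """
    if trajectory.n_frames < 2:
        raise ValidationError("RMSF undefined for a single frame")
    if len(selection) == 0:
        raise EmptyInputError("selection is empty")
    fit_sel = fit_selection if fit_selection is not None else selection
    coords, mean = align_to_mean(trajectory, topology, fit_sel)
    idx = selection.as_array()
    fluct = coords[:, idx, :] - mean[idx]
    per_atom = np.sqrt(np.mean(np.sum(fluct**2, axis=2), axis=0))
    # group by residue, in residue-table order
    res_values = []
    for seg, rid, rname, start, stop in topology.residues:
        members = [k for k, i in enumerate(idx) if start <= i < stop]
        if members:
            res_values.append(per_atom[members].mean())
    return SeriesResult(values=np.array(res_values),
                        frame_spacing_ps=trajectory.frame_spacing_ps, label=label)


def radius_of_gyration(
    trajectory: Trajectory,
    topology: Topology,
    selection: Selection,
    label: str = "rog",
) -> SeriesResult:
    """Per-frame mass-weighted radius of gyration of ``selection``."""
    trajectory.check_topology(topology)
    if len(selection) == 0:
        raise EmptyInputError("selection is empty")
    idx = selection.as_array()
    m = topology.masses[idx]
    if m.sum() <= 0:
        raise ValidationError("selection has zero total mass")
    xyz = trajectory.coordinates[:, idx, :]
    com = np.einsum("fij,i->fj", xyz, m) / m.sum()
    d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    values = np.sqrt(np.einsum("fi,i->f", d2, m) / m.sum())
    return SeriesResult(values=values, frame_spacing_ps=trajectory.frame_spacing_ps,
                        label=label)


def com_distance_series(
    trajectory: Trajectory,
    topology: Topology,
    selection_a: Selection,
    selection_b: Selection,
    label: str = "com_distance",
) -> SeriesResult:
    """Per-frame distance between the mass centers of two selections."""
    trajectory.check_topology(topology)
    if len(selection_a) == 0 or len(selection_b) == 0:
        raise EmptyInputError("both selections must be non-empty")
    values = np.empty(trajectory.n_frames)
    ia, ib = selection_a.as_array(), selection_b.as_array()
    ma, mb = topology.masses[ia], topology.masses[ib]
    coma = np.einsum("fij,i->fj", trajectory.coordinates[:, ia, :], ma) / ma.sum()
    comb = np.einsum("fij,i->fj", trajectory.coordinates[:, ib, :], mb) / mb.sum()
    values = np.sqrt(np.sum((coma - comb) ** 2, axis=1))
    return SeriesResult(values=values, frame_spacing_ps=trajectory.frame_spacing_ps,
                        label=label)


def select_stable_replica(
    replica_series: Sequence[SeriesResult],
    window_frames: int,
) -> int:
    """Index of the replica with the smallest RMSD variance over the final window.

    Stability is about fluctuation, not offset, so the criterion is the
    variance (not the mean) of the protein RMSD in the last
    ``window_frames`` frames. Ties go to the lowest index.
    """
    if not replica_series:
        raise EmptyInputError("no replicas given")
    variances = []
    for s in replica_series:
        if window_frames > len(s):
            raise ValidationError(
                f"window {window_frames} exceeds series length {len(s)}"
            )
        variances.append(np.var(s.values[-window_frames:]))
    best = int(np.argmin(variances))  # argmin takes the first minimum
    logger.info("select_stable_replica: variances=%s -> replica %d",
                np.round(variances, 6).tolist(), best)
    return best
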