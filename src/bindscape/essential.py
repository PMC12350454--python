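"""Essential dynamics: PCA of coordinate fluctuations and the
dynamic cross-correlation matrix (DCCM), optionally reconstructed from a
principal-component subset.

PCA diagonalizes the 3N x 3N covariance of the fluctuations of the
selected sites after iterative superposition onto the mean structure.
The DCCM is the residue-level normalized cross-correlation

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

over a frame window, with one site per residue (its first selected
atom). Positive entries mean residues move in the same direction,
negative entries anti-correlated motion. Sites with zero variance get a
NaN sentinel row/column — "undefined" is a different statement from
"uncorrelated", which zero would assert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DimensionError,
    EmptyInputError,
    ParameterError,
    ValidationError,
)
from .geometry import align_to_mean
from .topology import Selection, Topology
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "DCCMatrix",
    "fit_pca",
    "variance_explained",
    "project",
    "dccm",
    "region_correlation_summary",
]


@dataclass
class PCAModel:
    """Eigendecomposition of the fluctuation covariance of a selection."""

    mean_structure: np.ndarray        # (n_sites, 3), aligned frame of reference
    eigenvectors: np.ndarray          # (n_modes, 3 * n_sites), orthonormal rows
    eigenvalues: np.ndarray           # Å^2, descending
    n_frames_fit: int
    selection: Selection
    aligned: bool = True

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class DCCMatrix:
    """Residue-residue correlation matrix in [-1, 1] with NaN sentinels."""

    matrix: np.ndarray
    residue_ids: list[int]
    selection: Selection
    pc_subset: Optional[int] = None


def fit_pca(
    trajectory: Trajectory,
    topology: Topology,
    selection: Selection,
    align: bool = True,
) -> PCAModel:
    """PCA of the selection's fluctuations over the whole trajectory.

    Frames are first superposed onto their converged mean (same iterative
    scheme RMSF uses) unless ``align=False`` (useful for selections too
    small to superpose, or data without rigid drift). With fewer frames
    than 3N the covariance is rank-deficient; that is allowed and logged,
    and the eigenbasis is still complete (trailing eigenvalues are ~0).
    """
    if trajectory.n_frames <= 1:
        raise ValidationError("PCA needs more than one frame")
    if len(selection) == 0:
        raise EmptyInputError("selection is empty")
    if align:
        aligned, mean = align_to_mean(trajectory, topology, selection)
    else:
        aligned = trajectory.coordinates
        mean = aligned.mean(axis=0)
    idx = selection.as_array()
    X = (aligned[:, idx, :] - mean[idx]).reshape(trajectory.n_frames, -1)
    ndof = X.shape[1]
    if ndof > trajectory.n_frames:
        logger.info("fit_pca: 3N = %d > n_frames = %d; covariance is "
                    "rank-deficient", ndof, trajectory.n_frames)
    cov = (X.T @ X) / (trajectory.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes
    return PCAModel(
        mean_structure=mean[idx].copy(),
        eigenvectors=evecs,
        eigenvalues=evals,
        n_frames_fit=trajectory.n_frames,
        selection=selection,
        aligned=align,
    )


def variance_explained(model: PCAModel, k: int) -> float:
    """Fraction of total fluctuation variance carried by the top-k modes."""
    if not (1 <= k <= model.n_modes):
        raise ParameterError(f"k must be in [1, {model.n_modes}], got {k}")
    total = model.eigenvalues.sum()
    if total == 0:
        return 0.0
    return float(model.eigenvalues[:k].sum() / total)


def smallest_k_for_variance(model: PCAModel, threshold: float = 0.5) -> int:
    """Smallest number of modes whose cumulative variance reaches ``threshold``."""
    total = model.eigenvalues.sum()
    if total == 0:
        return model.n_modes
    cum = np.cumsum(model.eigenvalues) / total
    return int(np.searchsorted(cum, threshold) + 1)


def project(
    trajectory: Trajectory,
    topology: Topology,
    model: PCAModel,
    k: Optional[int] = None,
) -> np.ndarray:
    """Frame scores along the top-k modes (frames x k).

    Frames are aligned with the same scheme used for fitting before their
    fluctuations are projected. Projecting onto all modes and
    reconstructing reproduces the fluctuations exactly (complete basis).
    """
    if k is None:
        k = model.n_modes
    if not (1 <= k <= model.n_modes):
        raise ParameterError(f"k out of range: {k}")
    if model.aligned:
        aligned, _ = align_to_mean(trajectory, topology, model.selection)
    else:
        aligned = trajectory.coordinates
    idx = model.selection.as_array()
    if 3 * len(idx) != model.eigenvectors.shape[1]:
        raise DimensionError("selection does not match the fitted model")
    X = (aligned[:, idx, :] - model.mean_structure).reshape(trajectory.n_frames, -1)
    return X @ model.eigenvectors[:k].T


def _site_indices(topology: Topology, selection: Selection) -> tuple[list[int], list[int]]:
    """One site per residue: the first selected atom of each residue."""
    sites: list[int] = []
    res_ids: list[int] = []
    sel = set(selection.indices)
    for seg, rid, rname, start, stop in topology.residues:
        for i in range(start, stop):
            if i in sel:
                sites.append(i)
                res_ids.append(rid)
                break
    return sites, res_ids


def dccm(
    trajectory: Trajectory,
    topology: Topology,
    selection: Selection,
    frame_window: Optional[tuple[int, int]] = None,
    pc_subset: Optional[int] = None,
    model: Optional[PCAModel] = None,
    align: bool = False,
) -> DCCMatrix:
    """Residue-level DCCM over a frame window, optionally PC-filtered.

    With ``pc_subset`` the window fluctuations are reconstructed from the
    top-k modes of ``model`` (fit on the whole trajectory when not given)
    before correlating — the matrix then shows only the motion the
    essential subspace carries. ``pc_subset`` equal to all modes
    reproduces the unfiltered matrix.

    Fluctuations are taken about the window mean of the coordinates as
    given; pass ``align=True`` (or superpose upstream) for trajectories
    with global rigid drift — note that removing the rigid-body motion
    redistributes correlation between regions, as it must.
    """
    trajectory.check_topology(topology)
    if trajectory.n_frames < 2:
        raise ValidationError("DCCM needs at least two frames")
    sites, res_ids = _site_indices(topology, selection)
    if not sites:
        raise EmptyInputError("selection touches no residues")
    site_sel = Selection(indices=tuple(sites))

    if pc_subset is not None:
        if model is None:
            model = fit_pca(trajectory, topology, site_sel, align=align)
        elif model.eigenvectors.shape[1] != 3 * len(sites):
            raise DimensionError(
                "PCA model selection does not match the DCCM site set "
                "(one site per residue); fit the model on the same sites"
            )

    if align:
        aligned, mean = align_to_mean(trajectory, topology, site_sel)
    else:
        aligned = trajectory.coordinates
        mean = aligned.mean(axis=0)

    start, stop = frame_window if frame_window is not None else (0, trajectory.n_frames)
    if not (0 <= start < stop <= trajectory.n_frames):
        raise ValidationError(f"bad frame window [{start}, {stop})")
    if stop - start < 2:
        raise ValidationError("DCCM window needs at least two frames")

    idx = np.array(sites)
    window = aligned[start:stop, idx, :]
    fluct = window - window.mean(axis=0)

    if pc_subset is not None:
        if not (1 <= pc_subset <= model.n_modes):
            raise ParameterError(f"pc_subset out of range: {pc_subset}")
        # reconstruct window fluctuations from the top-k global modes;
        # fluctuations are taken about the window mean in mode space too
        flat = (aligned[start:stop, idx, :] - model.mean_structure).reshape(stop - start, -1)
        scores = flat @ model.eigenvectors[:pc_subset].T
        recon = scores @ model.eigenvectors[:pc_subset]
        recon -= recon.mean(axis=0)
        fluct = recon.reshape(stop - start, len(sites), 3)

    dots = np.einsum("fik,fjk->ij", fluct, fluct) / fluct.shape[0]
    var = np.diag(dots).copy()
    zero = var <= 0
    if zero.any():
        logger.warning("dccm: %d zero-variance residues set to NaN sentinel",
                       int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        C = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), np.nan)
    C[zero, :] = np.nan
    C[:, zero] = np.nan
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0, out=C, where=~np.isnan(C))
    return DCCMatrix(matrix=C, residue_ids=res_ids, selection=site_sel,
                     pc_subset=pc_subset)


def region_correlation_summary(
    dccm_result: DCCMatrix,
    region_a: Sequence[int],
    region_b: Sequence[int],
) -> tuple[float, float]:
    """Mean off-diagonal correlation between two residue regions and the
    fraction of positive entries.

    Regions are residue-id lists; ``region_a == region_b`` summarizes the
    internal coherence of one region (e.g. pocket-pocket or
    C-terminal-C-terminal). Symmetric in its arguments.
    """
    pos = {rid: i for i, rid in enumerate(dccm_result.residue_ids)}
    try:
        ia = [pos[r] for r in region_a]
        ib = [pos[r] for r in region_b]
    except KeyError as exc:
        raise ValidationError(f"residue {exc.args[0]} not in the DCCM") from None
    if not ia or not ib:
        raise EmptyInputError("regions must be non-empty")
    entries = []
    for i in ia:
        for j in ib:
            if i != j:
                entries.append(dccm_result.matrix[i, j])
    if not entries:
        raise ValidationError(
            "regions of size 1 with A == B have no off-diagonal entries"
        )
    arr = np.array(entries)
    if np.isnan(arr).any():
        logger.warning("region_correlation_summary: ignoring %d undefined entries",
                       int(np.isnan(arr).sum()))
        arr = arr[~np.isnan(arr)]
    return float(arr.mean()), float(np.mean(arr > 0))
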