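"""Free-energy landscape over two collective variables, and the chain
ground basin → crucial interval → representative frame.

The landscape is a 2D histogram of the CV pair converted with
``G = -kT ln(P / P_max)``, so the most populated bin sits at G = 0.
Unsampled bins carry an infinite-G sentinel — ``-kT ln 0`` is undefined
and an unsampled bin must never masquerade as a minimum. The ground
basin is the 4-connected flood fill from the global-minimum bin over bins
with ``G <= cutoff``; the crucial interval is the fixed-length frame
window holding the most ground-basin frames, and the representative frame
is the in-basin frame nearest that window's center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL
from .errors import EmptyInputError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FELGrid",
    "Basin",
    "CrucialInterval",
    "compute_fel",
    "find_ground_basin",
    "frame_basin_membership",
    "crucial_interval",
    "representative_frame",
]


@dataclass
class FELGrid:
    """Binned 2D free-energy surface with its temperature and bin edges."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) integers
    G: np.ndarray       # kcal/mol; np.inf marks unsampled bins
    kT: float
    n_frames_total: int


@dataclass
class Basin:
    """Connected set of bins around the global free-energy minimum."""

    member_bins: set[tuple[int, int]]
    cutoff_kcal: float


@dataclass
class CrucialInterval:
    """Half-open frame window maximizing ground-basin occupancy."""

    start_frame: int
    end_frame: int
    in_basin_count: int
    representative_frame: int = -1


def compute_fel(
    cv_x: np.ndarray,
    cv_y: np.ndarray,
    n_bins: int = 50,
    temperature_K: float = 310.0,
) -> FELGrid:
    """Histogram the CV pair and convert to relative free energy.

    ``G(x, y) = -k_B T ln(P(x, y) / P_max)``; the histogram spans
    ``[min, max]`` on each axis with ``n_bins`` equal bins.
    """
    cv_x = np.asarray(cv_x, dtype=float)
    cv_y = np.asarray(cv_y, dtype=float)
    if cv_x.shape != cv_y.shape or cv_x.ndim != 1:
        raise ValidationError("cv_x and cv_y must be equal-length 1D series")
    if not (np.all(np.isfinite(cv_x)) and np.all(np.isfinite(cv_y))):
        raise ValidationError("CV series contain non-finite values")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2 per axis")
    if np.ptp(cv_x) == 0 or np.ptp(cv_y) == 0:
        raise ParameterError(
            "a CV is constant (zero range); a 2D landscape is undefined — "
            "consider a 1-D histogram of the varying CV instead"
        )
    counts, x_edges, y_edges = np.histogram2d(cv_x, cv_y, bins=n_bins)
    counts = counts.astype(int)
    kT = KB_KCAL * temperature_K
    G = np.full_like(counts, np.inf, dtype=float)
    populated = counts > 0
    cmax = counts.max()
    G[populated] = -kT * np.log(counts[populated] / cmax)
    return FELGrid(x_edges=x_edges, y_edges=y_edges, counts=counts, G=G,
                   kT=kT, n_frames_total=int(counts.sum()))


def find_ground_basin(fel: FELGrid, cutoff_kcal: float | None = None) -> Basin:
    """Flood-fill the ground basin from the global-minimum bin.

    Expansion uses 4-neighborhood over populated bins with
    ``G <= cutoff_kcal`` (default ``1 * kT`` above the minimum, which is 0
    by construction). An exact tie between disjoint global minima is
    broken toward the lexicographically lowest bin and logged.
    """
    if cutoff_kcal is None:
        cutoff_kcal = fel.kT
    if not np.any(np.isfinite(fel.G)):
        raise EmptyInputError("landscape has no populated bins")
    minima = np.argwhere(fel.G == 0.0)
    if len(minima) > 1:
        logger.info(
            "find_ground_basin: %d tied global minima; starting from "
            "lexicographically lowest %s", len(minima), tuple(minima[0]),
        )
    start = tuple(int(v) for v in min(map(tuple, minima)))
    nx, ny = fel.G.shape
    eligible = np.isfinite(fel.G) & (fel.G <= cutoff_kcal)
    members: set[tuple[int, int]] = set()
    stack = [start]
    while stack:
        i, j = stack.pop()
        if (i, j) in members:
            continue
        members.add((i, j))
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and (ni, nj) not in members \
                    and eligible[ni, nj]:
                stack.append((ni, nj))
    return Basin(member_bins=members, cutoff_kcal=float(cutoff_kcal))


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram-consistent bin index per value; -1 for out-of-range."""
    idx = np.searchsorted(edges, values, side="right") - 1
    # np.histogram puts values equal to the last edge in the last bin
    idx[values == edges[-1]] = len(edges) - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def frame_basin_membership(
    cv_x: np.ndarray,
    cv_y: np.ndarray,
    fel: FELGrid,
    basin: Basin,
) -> np.ndarray:
    """Boolean per-frame series: does the frame's CV bin belong to the basin?

    Frames falling outside the histogram range are never members.
    """
    cv_x = np.asarray(cv_x, dtype=float)
    cv_y = np.asarray(cv_y, dtype=float)
    ix = _bin_indices(cv_x, fel.x_edges)
    iy = _bin_indices(cv_y, fel.y_edges)
    member = np.zeros(cv_x.shape[0], dtype=bool)
    in_range = (ix >= 0) & (iy >= 0)
    pairs = set(basin.member_bins)
    member[in_range] = [
        (i, j) in pairs for i, j in zip(ix[in_range], iy[in_range])
    ]
    return member


def crucial_interval(membership: np.ndarray, window_frames: int = 100) -> CrucialInterval:
    """Contiguous window of ``window_frames`` maximizing in-basin frames.

    Ties go to the earliest start. Raises if no frame is in the basin at
    all — a landscape without ground-state sampling has no crucial
    interval.
    """
    membership = np.asarray(membership, dtype=bool)
    n = membership.shape[0]
    if window_frames > n:
        raise ValidationError(
            f"window {window_frames} exceeds series length {n}"
        )
    if not membership.any():
        raise EmptyInputError("no frames in the ground basin")
    csum = np.concatenate([[0], np.cumsum(membership)])
    window_counts = csum[window_frames:] - csum[:-window_frames]
    start = int(np.argmax(window_counts))  # argmax takes the first maximum
    return CrucialInterval(
        start_frame=start,
        end_frame=start + window_frames,
        in_basin_count=int(window_counts[start]),
    )


def representative_frame(
    interval: CrucialInterval,
    membership: np.ndarray,
) -> int:
    """In-basin frame inside the interval nearest its center; ties → lower index.

    The center of the half-open window [start, end) is
    ``(start + end - 1) / 2``.
    """
    membership = np.asarray(membership, dtype=bool)
    frames = np.arange(interval.start_frame, interval.end_frame)
    inside = frames[membership[interval.start_frame: interval.end_frame]]
    if inside.size == 0:
        raise ValidationError(
            "no in-basin frame inside the crucial interval — membership "
            "series inconsistent with interval construction"
        )
    center = (interval.start_frame + interval.end_frame - 1) / 2.0
    dist = np.abs(inside - center)
    best = int(inside[np.argmin(dist)])  # argmin → lowest index on ties
    interval.representative_frame = best
    return best
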