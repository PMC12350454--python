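"""The in-memory trajectory container: frames x atoms x 3 Cartesian Å."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ValidationError
from .topology import Topology

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Coordinates in Å with a fixed saved-frame spacing in ps.

    The frame spacing is always an explicit input — upstream engines save
    at arbitrary strides and no default could be trusted.
    """

    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_spacing_ps: float
    origin_time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise DimensionError(
                f"coordinates must be (frames, atoms, 3); got {self.coordinates.shape}"
            )
        if self.frame_spacing_ps <= 0:
            raise ValidationError("frame_spacing_ps must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return self.origin_time_ps + self.frame_spacing_ps * np.arange(self.n_frames)

    def check_topology(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise DimensionError(
                f"trajectory has {self.n_atoms} atoms but topology has "
                f"{topology.n_atoms}"
            )

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        """Half-open frame window as a new Trajectory (view, not copy)."""
        return Trajectory(
            coordinates=self.coordinates[start:stop],
            frame_spacing_ps=self.frame_spacing_ps,
            origin_time_ps=self.origin_time_ps + start * self.frame_spacing_ps,
        )
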