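"""Domain types shared by every stage: atoms, topologies, selections.

A :class:`Topology` is an ordered list of :class:`AtomRecord` plus the
residue partition and planar-ring definitions derived from it. Residue
identity is the pair ``(segment, residue_id)``; atoms of one residue must
be contiguous so that residue ranges partition the atom list.

Selections are produced by :func:`select` from a small query language::

    segment:<tag> | resid:<a>[-<b>] | name:<atom-name>

joined by ``AND`` / ``OR`` (``AND`` binds tighter). Queries are
case-sensitive for tags and atom names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyInputError, SelectionSyntaxError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["AtomRecord", "Topology", "Selection", "select"]


@dataclass(frozen=True)
class AtomRecord:
    """One atom with identity, mass and nonbonded force-field parameters.

    ``lj_rmin_half`` / ``lj_epsilon`` follow the Rmin/2-epsilon convention
    (Å, kcal/mol); ``gb_radius`` is the intrinsic Born radius (Å) and
    ``gb_screen`` the dimensionless HCT screening factor. Donor/acceptor/
    polar-hydrogen flags and ``ring_id`` feed the interaction detectors.
    """

    index: int
    name: str
    residue_id: int
    residue_name: str
    segment: str = ""
    mass: float = 12.011
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    gb_radius: float = 0.0
    gb_screen: float = 0.0
    is_donor_heavy: bool = False
    is_acceptor: bool = False
    is_polar_h: bool = False
    ring_id: Optional[int] = None


@dataclass
class Topology:
    """Ordered atom list plus the residue partition and ring definitions."""

    atoms: list[AtomRecord]
    #: ordered (segment, residue_id, residue_name, start, stop) with
    #: half-open atom index ranges partitioning the atom list
    residues: list[tuple[str, int, str, int, int]] = field(default_factory=list)
    #: ring_id -> ordered atom index list
    rings: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            self.residues = _build_residue_table(self.atoms)
        if not self.rings:
            self.rings = _build_ring_table(self.atoms)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyInputError("topology has zero atoms")
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValidationError(
                    f"atom indices must be dense and 0-based; atom {i} has index {a.index}"
                )
            if a.mass <= 0:
                raise ValidationError(f"atom {i} ({a.name}) has non-positive mass")
        stops = 0
        for seg, rid, rname, start, stop in self.residues:
            if start != stops:
                raise ValidationError(
                    f"residue ({seg},{rid}) range [{start},{stop}) does not "
                    f"continue the partition at atom {stops}"
                )
            stops = stop
        if stops != len(self.atoms):
            raise ValidationError("residue ranges do not cover the atom list")
        for ring_id, members in self.rings.items():
            if len(members) < 3:
                raise ValidationError(f"ring {ring_id} has fewer than 3 atoms")

    # -- convenience array views -----------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms], dtype=float)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    @property
    def gb_radii(self) -> np.ndarray:
        return np.array([a.gb_radius for a in self.atoms], dtype=float)

    @property
    def gb_screens(self) -> np.ndarray:
        return np.array([a.gb_screen for a in self.atoms], dtype=float)

    def residue_of(self, atom_index: int) -> tuple[str, int, str, int, int]:
        """Residue tuple owning ``atom_index``."""
        for res in self.residues:
            if res[3] <= atom_index < res[4]:
                return res
        raise ValidationError(f"atom index {atom_index} outside residue table")

    def with_atoms(self, atoms: Sequence[AtomRecord]) -> "Topology":
        """New topology with the same length but replaced atom records."""
        if len(atoms) != self.n_atoms:
            raise ValidationError("with_atoms must preserve the atom count")
        return Topology(atoms=list(atoms))


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free 0-based atom indices bound to a topology size."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValidationError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    def validate_against(self, topology: Topology) -> None:
        n = topology.n_atoms
        bad = [i for i in self.indices if not (0 <= i < n)]
        if bad:
            raise ValidationError(f"selection indices out of range: {bad[:5]}")


def _build_residue_table(atoms: Sequence[AtomRecord]):
    residues = []
    start = 0
    for i, a in enumerate(atoms):
        key = (a.segment, a.residue_id)
        if i == 0:
            continue
        prev = atoms[i - 1]
        if (prev.segment, prev.residue_id) != key:
            residues.append((prev.segment, prev.residue_id, prev.residue_name, start, i))
            start = i
    last = atoms[-1]
    residues.append((last.segment, last.residue_id, last.residue_name, start, len(atoms)))
    # non-contiguous residues would produce duplicate keys
    keys = [(seg, rid) for seg, rid, *_ in residues]
    if len(set(keys)) != len(keys):
        raise ValidationError("atoms of one residue must be contiguous")
    return residues


def _build_ring_table(atoms: Sequence[AtomRecord]) -> dict[int, list[int]]:
    rings: dict[int, list[int]] = {}
    for a in atoms:
        if a.ring_id is not None:
            rings.setdefault(a.ring_id, []).append(a.index)
    return rings


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

def _match_term(term: str, topology: Topology) -> set[int]:
    if ":" not in term:
        raise SelectionSyntaxError(f"expected '<kind>:<value>' term, got '{term}'")
    kind, _, value = term.partition(":")
    if kind == "segment":
        return {a.index for a in topology.atoms if a.segment == value}
    if kind == "name":
        return {a.index for a in topology.atoms if a.name == value}
    if kind == "resid":
        try:
            if "-" in value:
                lo_s, _, hi_s = value.partition("-")
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(value)
        except ValueError as exc:
            raise SelectionSyntaxError(f"bad resid value '{value}'") from exc
        return {a.index for a in topology.atoms if lo <= a.residue_id <= hi}
    raise SelectionSyntaxError(f"unknown selection kind '{kind}' in '{term}'")


def select(topology: Topology, query: str) -> Selection:
    """Evaluate a selection query against a topology.

    ``AND`` binds tighter than ``OR``; there is no grouping. The result is
    ordered by atom index and duplicate-free, so repeated evaluation of the
    same query is bit-stable. An empty result is legal but logged.
    """
    tokens = query.split()
    if not tokens:
        raise SelectionSyntaxError("empty query")
    # split on OR, evaluate AND-conjunctions
    or_groups: list[list[str]] = [[]]
    expect_term = True
    for tok in tokens:
        if tok in ("AND", "OR"):
            if expect_term:
                raise SelectionSyntaxError(f"operator '{tok}' in term position")
            if tok == "OR":
                or_groups.append([])
            expect_term = True
        else:
            if not expect_term:
                raise SelectionSyntaxError(
                    f"expected AND/OR before '{tok}'"
                )
            or_groups[-1].append(tok)
            expect_term = False
    if expect_term:
        raise SelectionSyntaxError("query ends with a dangling operator")

    result: set[int] = set()
    for group in or_groups:
        acc = _match_term(group[0], topology)
        for term in group[1:]:
            acc &= _match_term(term, topology)
        result |= acc
    if not result:
        logger.warning("selection %r matched no atoms", query)
    return Selection(indices=tuple(sorted(result)))
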