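"""Rigid units, poses and assembly configurations.

Two protein subunits assembling across an interface are modelled as rigid
bodies: one is held fixed, the other moves by a proper rigid motion (a pose).
All coordinates are in Angstroms in a right-handed frame.  Atom order is the
order of appearance in the source file and is the canonical vectorization used
by the configuration similarity metric, so that epsilon-deduplication of
sampled configurations is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    EmptySelectionError,
    MissingChainError,
    StericClashError,
    UnitMismatchError,
)

DEFAULT_VDW_RADIUS = 1.2  # Angstrom, single hard-sphere radius for every atom


@dataclass(frozen=True)
class Atom:
    """A point atom with a hard-sphere radius.

    Parameters
    ----------
    atom_id : str
        Opaque label, unique within its rigid unit.
    residue_id : int
        Residue sequence number the atom belongs to.
    chain_id : str
        Chain label from the source structure.
    position : np.ndarray
        Cartesian position, shape (3,), Angstrom.
    vdw_radius : float
        Hard-sphere radius, Angstrom.
    """

    atom_id: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.atom_id}: vdw_radius must be positive")


@dataclass(frozen=True)
class RigidUnit:
    """An ordered collection of atoms treated as a single rigid motif."""

    atoms: tuple[Atom, ...]
    unit_label: str = "unit"
    composition: str = "monomer"  # "monomer" | "dimer"

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"rigid unit {self.unit_label!r} must contain atoms")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom positions stacked in file order, shape (n, 3)."""
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def atom_ids(self) -> tuple[str, ...]:
        return tuple(a.atom_id for a in self.atoms)

    def index_of(self, atom_id: str) -> int:
        try:
            return self.atom_ids.index(atom_id)
        except ValueError:
            raise KeyError(f"atom {atom_id!r} not in unit {self.unit_label!r}") from None


@dataclass(frozen=True)
class Pose:
    """A proper rigid motion x -> R x + t of the mobile unit."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """self after other: x -> R_s (R_o x + t_o) + t_s."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class AssemblyConfiguration:
    """A relative placement of the mobile unit against the fixed unit.

    The fixed unit is never transformed; ``mobile_coords`` are the mobile
    unit's atom positions after applying the pose.
    """

    fixed_unit: RigidUnit
    mobile_unit: RigidUnit
    pose: Pose
    mobile_coords: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mobile_coords", self.pose.apply(self.mobile_unit.coords)
        )


def _same_units(x: AssemblyConfiguration, y: AssemblyConfiguration) -> bool:
    return (
        x.fixed_unit.atom_ids == y.fixed_unit.atom_ids
        and x.mobile_unit.atom_ids == y.mobile_unit.atom_ids
    )


def similarity_distance(x: AssemblyConfiguration, y: AssemblyConfiguration) -> float:
    """2-norm between the mobile coordinate vectors of two configurations.

    Symmetric, zero iff the mobile placements coincide, and satisfies the
    triangle inequality (it is the Euclidean metric on the 3n-vector of
    mobile atom positions).
    """
    if not _same_units(x, y):
        raise UnitMismatchError("configurations do not share units / atom ordering")
    return float(np.linalg.norm(x.mobile_coords - y.mobile_coords))


def make_dimer_unit(unit_a: RigidUnit, unit_b: RigidUnit, pose: Pose,
                    unit_label: Optional[str] = None) -> RigidUnit:
    """Merge two rigid units into one rigid dimer motif.

    Atoms of ``unit_a`` keep their coordinates; atoms of ``unit_b`` are placed
    by ``pose``.  Raises :class:`StericClashError` when any cross pair sits
    closer than the sum of the hard-sphere radii.
    """
    posed_b = pose.apply(unit_b.coords)
    diff = unit_a.coords[:, None, :] - posed_b[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    limit = unit_a.radii[:, None] + unit_b.radii[None, :]
    if np.any(dist < limit):
        i, j = np.unravel_index(np.argmin(dist - limit), dist.shape)
        raise StericClashError(
            f"atoms {unit_a.atoms[i].atom_id}/{unit_b.atoms[j].atom_id} clash at "
            f"{dist[i, j]:.3f} A (< {limit[i, j]:.3f} A)"
        )
    atoms = list(unit_a.atoms)
    for atom, xyz in zip(unit_b.atoms, posed_b):
        atoms.append(Atom(atom.atom_id, atom.residue_id, atom.chain_id,
                          xyz, atom.vdw_radius))
    label = unit_label or f"{unit_a.unit_label}+{unit_b.unit_label}"
    return RigidUnit(tuple(atoms), unit_label=label, composition="dimer")


def load_monomer(structure_file: str | Path, chain_selector: str,
                 atom_subset: Optional[Sequence[int]] = None,
                 unit_label: Optional[str] = None) -> RigidUnit:
    """Read one chain of a PDB file as a rigid unit.

    Parameters
    ----------
    structure_file : path
        PDB file with standard ATOM/HETATM records.
    chain_selector : str
        Chain identifier to extract.
    atom_subset : sequence of int, optional
        If given, keep only atoms whose residue id is in this collection.

    Returns
    -------
    RigidUnit with the selected atoms in file order.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(structure_file))
    structure = pdb_file.get_structure(model=1)
    chains = set(structure.chain_id)
    if chain_selector not in chains:
        raise MissingChainError(
            f"chain {chain_selector!r} not in {sorted(chains)} of {structure_file}"
        )
    sel = structure.chain_id == chain_selector
    if atom_subset is not None:
        wanted = set(int(r) for r in atom_subset)
        sel = sel & np.isin(structure.res_id, sorted(wanted))
    picked = structure[sel]
    if picked.array_length() == 0:
        raise EmptySelectionError(
            f"selection (chain {chain_selector!r}, residues {atom_subset}) is empty"
        )
    atoms = []
    for i in range(picked.array_length()):
        atoms.append(
            Atom(
                atom_id=f"{picked.chain_id[i]}:{picked.res_id[i]}:{picked.atom_name[i]}:{i}",
                residue_id=int(picked.res_id[i]),
                chain_id=str(picked.chain_id[i]),
                position=np.array(picked.coord[i], dtype=float),
            )
        )
    label = unit_label or f"{Path(structure_file).stem}:{chain_selector}"
    return RigidUnit(tuple(atoms), unit_label=label, composition="monomer")
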