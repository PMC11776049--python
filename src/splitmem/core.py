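"""Domain types and geometric conventions shared by all modules.

Conventions
-----------
* coordinates in nm, times in ns, masses in amu, charges in e,
  energies in kJ/mol, force constants in kJ mol^-1 nm^-2;
* z is the bilayer normal; the membrane centre of mass is the reference
  origin for restraints and profiles;
* boxes are orthorhombic -- triclinic input is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "AtomTable",
    "BondedTerm",
    "ConfigurationError",
    "LeafletAssignment",
    "MembraneComposition",
    "MoleculeTopology",
    "SystemFrame",
    "Trajectory",
    "VirtualSiteDef",
    "assign_leaflets",
    "guess_mass",
    "membrane_com",
]

#: arity of each bonded-term kind
BONDED_ARITY = {"bond": 2, "pair": 2, "angle": 3, "dihedral": 4, "exclusion": 2}

#: default species treated as non-lipids (never split, excluded from membrane COM)
NON_LIPID_SPECIES = frozenset({"SOL", "WAT", "TIP3", "NA", "CL", "K", "ION", "BRW"})

# masses in amu, keyed by leading element symbol of the atom name
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "V": 0.0,  # virtual sites
    "M": 0.0,  # dummy/virtual (MW etc.)
}


class ConfigurationError(ValueError):
    """Raised when a request is inconsistent with the system description."""


def guess_mass(atom_name: str) -> float:
    """Guess an atomic mass (amu) from a GRO/PDB atom name.

    Two-letter ion symbols are tried before single-letter elements so that
    ``NA`` resolves to sodium, not nitrogen.
    """
    name = atom_name.strip().upper()
    if not name:
        return 0.0
    if name[:2] in ("NA", "CL", "MG") and len(name) <= 3:
        return _ELEMENT_MASSES[name[:2]]
    head = name.lstrip("0123456789")
    if head and head[0] in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[head[0]]
    return 0.0


@dataclass
class AtomRecord:
    """One atom: identity, mass/charge, and (optionally) coordinates.

    ``index`` is 1-based, following the GRO/TOP convention.  Topology-only
    atoms leave ``position`` as ``None``.
    """

    index: int
    name: str
    residue_name: str
    residue_id: int
    mass: float = 0.0
    charge: float = 0.0
    type: str = ""
    position: np.ndarray | None = None
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"atom {self.name}: mass must be >= 0, got {self.mass}")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if not np.all(np.isfinite(self.position)):
                raise ValueError(f"atom {self.name}: non-finite position")


@dataclass
class BondedTerm:
    """A bonded interaction referencing 1-based atom indices within a molecule."""

    kind: str
    atom_indices: tuple[int, ...]
    function_type: int = 1
    parameters: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in BONDED_ARITY:
            raise ValueError(f"unknown bonded kind {self.kind!r}")
        self.atom_indices = tuple(int(i) for i in self.atom_indices)
        if len(self.atom_indices) != BONDED_ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} needs {BONDED_ARITY[self.kind]} atoms, "
                f"got {len(self.atom_indices)}"
            )
        self.parameters = tuple(float(p) for p in self.parameters)


@dataclass
class VirtualSiteDef:
    """Construction rule for a massless, non-interacting site.

    ``vsite2`` places the site on the line through two atoms
    (``r = r_i + a (r_j - r_i)``); ``vsite3`` uses an out-of-plane
    construction from three atoms
    (``r = r_i + a r_ij + b r_ik + c (r_ij x r_ik)``), which can reproduce
    any target position as long as the constructing atoms are not collinear.
    """

    site_index: int
    constructing_atoms: tuple[int, ...]
    construction_type: str  # "vsite2" | "vsite3"
    geometric_parameters: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.constructing_atoms = tuple(int(i) for i in self.constructing_atoms)
        if self.construction_type not in ("vsite2", "vsite3"):
            raise ValueError(f"unknown construction {self.construction_type!r}")
        n_expected = 2 if self.construction_type == "vsite2" else 3
        if len(self.constructing_atoms) != n_expected:
            raise ValueError(
                f"{self.construction_type} needs {n_expected} constructing atoms"
            )
        self.geometric_parameters = tuple(float(p) for p in self.geometric_parameters)


@dataclass
class MoleculeTopology:
    """Topology of one molecule species: atoms, bonded terms, virtual sites."""

    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    bonded: list[BondedTerm] = field(default_factory=list)
    virtual_sites: list[VirtualSiteDef] = field(default_factory=list)
    #: unknown ITP sections carried through verbatim on write
    extra_sections: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    @property
    def total_mass(self) -> float:
        return float(sum(a.mass for a in self.atoms))

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def atom_index(self, name: str) -> int:
        """1-based index of the uniquely named atom ``name``."""
        hits = [a.index for a in self.atoms if a.name == name]
        if not hits:
            raise KeyError(f"{self.name}: no atom named {name!r}")
        if len(hits) > 1:
            raise KeyError(f"{self.name}: atom name {name!r} is not unique")
        return hits[0]

    def validate(self) -> None:
        n = self.n_atoms
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise ValueError(f"{self.name}: duplicate atom index {a.index}")
            seen.add(a.index)
        for term in self.bonded:
            for i in term.atom_indices:
                if not (1 <= i <= n):
                    raise ValueError(
                        f"{self.name}: bonded index {i} out of range 1..{n}"
                    )

    def bonds(self) -> list[BondedTerm]:
        return [t for t in self.bonded if t.kind == "bond"]


class AtomTable:
    """Column store of per-atom metadata shared by every frame of a trajectory.

    Molecules are contiguous runs of atoms with the same ``(residue_id,
    residue_name)``; ``mol_slices`` exposes them as index ranges.
    """

    def __init__(
        self,
        names: Sequence[str],
        resnames: Sequence[str],
        resids: Sequence[int],
        masses: Sequence[float] | None = None,
        charges: Sequence[float] | None = None,
    ) -> None:
        self.names = np.asarray(names, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        n = len(self.names)
        if masses is None:
            masses = [guess_mass(str(nm)) for nm in self.names]
        self.masses = np.asarray(masses, dtype=float)
        if charges is None:
            charges = np.zeros(n)
        self.charges = np.asarray(charges, dtype=float)
        if not (len(self.resnames) == len(self.resids) == len(self.masses) == n):
            raise ValueError("AtomTable columns must have equal length")
        self._mol_slices: list[slice] | None = None

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_records(cls, records: Iterable[AtomRecord]) -> "AtomTable":
        recs = list(records)
        return cls(
            names=[r.name for r in recs],
            resnames=[r.residue_name for r in recs],
            resids=[r.residue_id for r in recs],
            masses=[r.mass if r.mass else guess_mass(r.name) for r in recs],
            charges=[r.charge for r in recs],
        )

    @property
    def mol_slices(self) -> list[slice]:
        if self._mol_slices is None:
            slices: list[slice] = []
            start = 0
            for i in range(1, len(self) + 1):
                if (
                    i == len(self)
                    or self.resids[i] != self.resids[i - 1]
                    or self.resnames[i] != self.resnames[i - 1]
                ):
                    slices.append(slice(start, i))
                    start = i
            self._mol_slices = slices
        return self._mol_slices

    @property
    def n_molecules(self) -> int:
        return len(self.mol_slices)

    def mol_species(self) -> list[str]:
        return [str(self.resnames[s.start]) for s in self.mol_slices]

    def lipid_mask(self, lipid_species: set[str] | None = None) -> np.ndarray:
        """Boolean mask over atoms belonging to lipid molecules."""
        if lipid_species is None:
            return np.array(
                [str(r) not in NON_LIPID_SPECIES for r in self.resnames], dtype=bool
            )
        return np.array([str(r) in lipid_species for r in self.resnames], dtype=bool)


class SystemFrame:
    """One configuration: an atom table plus positions, box and time."""

    def __init__(
        self,
        table: AtomTable,
        positions: np.ndarray,
        box: Sequence[float],
        time: float = 0.0,
        velocities: np.ndarray | None = None,
    ) -> None:
        self.table = table
        self.positions = np.asarray(positions, dtype=float)
        if self.positions.shape != (len(table), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({len(table)}, 3)"
            )
        box = np.asarray(box, dtype=float)
        if box.shape != (3,):
            raise ValueError(
                "only orthorhombic boxes (Lx, Ly, Lz) are supported; "
                "triclinic input is rejected"
            )
        if np.any(box <= 0):
            raise ValueError(f"box components must be > 0, got {box}")
        self.box = box
        self.time = float(time)
        self.velocities = velocities

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def copy(self) -> "SystemFrame":
        return SystemFrame(
            self.table,
            self.positions.copy(),
            self.box.copy(),
            self.time,
            None if self.velocities is None else self.velocities.copy(),
        )

    def atom_records(self) -> list[AtomRecord]:
        t = self.table
        return [
            AtomRecord(
                index=i + 1,
                name=str(t.names[i]),
                residue_name=str(t.resnames[i]),
                residue_id=int(t.resids[i]),
                mass=float(t.masses[i]),
                charge=float(t.charges[i]),
                position=self.positions[i],
                velocity=None if self.velocities is None else self.velocities[i],
            )
            for i in range(len(t))
        ]


class Trajectory:
    """Ordered frame sequence over a fixed atom table.

    Times must be strictly increasing and every frame must share the same
    atom count.
    """

    def __init__(self, frames: Sequence[SystemFrame]) -> None:
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].n_atoms
        for f in frames[1:]:
            if f.n_atoms != n:
                raise ValueError("inconsistent atom count across frames")
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.frames = frames
        self.table = frames[0].table

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class LeafletAssignment:
    """Per-molecule leaflet labels plus the membrane COM z used to assign them."""

    labels: dict[int, str]  # molecule index -> "upper" | "lower"
    com_z: float

    def molecules(self, leaflet: str) -> list[int]:
        return [m for m, lab in self.labels.items() if lab == leaflet]


@dataclass
class MembraneComposition:
    """Species counts for one leaflet of a symmetric membrane."""

    counts: dict[str, int]
    leaflet_total: int

    def __post_init__(self) -> None:
        for sp, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {sp}: {n}")
        total = sum(self.counts.values())
        if total != self.leaflet_total:
            raise ValueError(
                f"composition sums to {total}, declared leaflet total is "
                f"{self.leaflet_total} (difference {total - self.leaflet_total})"
            )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def membrane_com(frame: SystemFrame, selection: np.ndarray | None = None) -> float:
    """Mass-weighted mean z (nm) of the selected atoms.

    ``selection`` is a boolean mask or integer index array; by default all
    lipid atoms (non-water, non-ion species) are used.
    """
    if selection is None:
        selection = frame.table.lipid_mask()
    sel = np.asarray(selection)
    masses = frame.table.masses[sel]
    z = frame.positions[sel, 2]
    if z.size == 0:
        raise ValueError("membrane_com: empty selection")
    total = masses.sum()
    if total <= 0:
        raise ValueError("membrane_com: zero total mass in selection")
    return float(np.dot(masses, z) / total)


#: default anchor atom per role: P for heads/whole lipids, C2 for split tails
DEFAULT_ANCHORS = {"head": "P", "tail": "C2"}


def assign_leaflets(
    frame: SystemFrame,
    anchor_atom_names: Mapping[str, str],
    lipid_species: set[str] | None = None,
) -> LeafletAssignment:
    """Label each lipid molecule upper/lower by its anchor atom's z versus
    the membrane COM.

    ``anchor_atom_names`` maps species name -> anchor atom name.  A molecule
    whose anchor sits exactly at the COM is assigned *upper* (tie-break,
    with a warning).
    """
    table = frame.table
    lipid_mask = table.lipid_mask(lipid_species)
    com_z = membrane_com(frame, lipid_mask)
    labels: dict[int, str] = {}
    for m, sl in enumerate(table.mol_slices):
        species = str(table.resnames[sl.start])
        if lipid_species is not None:
            if species not in lipid_species:
                continue
        elif species in NON_LIPID_SPECIES:
            continue
        if species not in anchor_atom_names:
            raise ConfigurationError(
                f"species {species!r} has no declared anchor atom"
            )
        anchor = anchor_atom_names[species]
        names = table.names[sl]
        hits = np.nonzero(names == anchor)[0]
        if hits.size == 0:
            raise ConfigurationError(
                f"molecule {m} ({species}): anchor atom {anchor!r} not found"
            )
        z = frame.positions[sl.start + hits[0], 2]
        if z == com_z:
            warnings.warn(
                f"molecule {m} anchor exactly at membrane COM; assigned 'upper'",
                stacklevel=2,
            )
            labels[m] = "upper"
        else:
            labels[m] = "upper" if z > com_z else "lower"
    return LeafletAssignment(labels=labels, com_z=com_z)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention component-wise."""
    return delta - box * np.round(delta / box)
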