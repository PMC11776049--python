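"""Deterministic synthetic systems: toy bilayers, Brownian walkers and ideal
all-trans chains, so every operation is testable without running MD.

Fixture lipids are simplified (a handful of pseudo-atoms) but preserve the
atom names and roles the toolkit touches: P/N headgroup atoms with in-plane
P->N vectors, the glycerol C1/C2 anchors joined by the cut bond, two acyl
chains of all-trans carbons, and water as an O plus two light dummy sites.
All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from splitmem.core import (
    AtomRecord,
    AtomTable,
    BondedTerm,
    MembraneComposition,
    MoleculeTopology,
    SystemFrame,
    Trajectory,
)

__all__ = [
    "FixtureConfig",
    "ChainFixture",
    "PM_COMPOSITIONS",
    "brownian_trajectory",
    "build_bilayer",
    "composition_from_counts",
    "default_chain_definitions",
    "ideal_chain",
    "lipid_template",
]

# all-trans tetrahedral zigzag geometry (nm / degrees)
CC_BOND = 0.153
CH_BOND = 0.109
TETRA_ANGLE = 109.47
_AXIAL = CC_BOND * math.sin(math.radians(TETRA_ANGLE / 2.0))
_LATERAL = CC_BOND * math.cos(math.radians(TETRA_ANGLE / 2.0))

#: plasma-membrane mimic compositions (species -> total phospholipid count,
#: both leaflets, symmetric systems of 600 lipids per leaflet)
PM_COMPOSITIONS: dict[str, dict[str, int]] = {
    "outer": {"PSM": 660, "POPC": 510, "POPS": 18, "POPA": 12},
    "inner": {"PSM": 30, "POPC": 336, "POPS": 480, "POPE": 342, "POPA": 12},
    "scrambled": {"PSM": 348, "POPC": 420, "POPS": 252, "POPE": 168, "POPA": 12},
    "scrambled_chl": {
        "PSM": 174, "POPC": 210, "POPS": 126, "POPE": 84, "POPA": 6, "CHL": 600,
    },
}

#: species with a -1 e net charge in the fixture force field
_ANIONIC = frozenset({"POPS", "POPA"})
#: species without a headgroup nitrogen
_NO_NITROGEN = frozenset({"POPA"})

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "H": 1.008}


@dataclass
class FixtureConfig:
    """Parameters of a toy bilayer; same seed means byte-identical output."""

    composition: MembraneComposition
    apl: float = 0.658  # target area per lipid, nm^2
    head_plane_offset: float = 1.9  # |z(P plane) - z(midplane)|, nm
    chain_length: int = 8
    seed: int = 0
    box_z: float = 8.0
    waters_per_lipid: int = 3
    xy_jitter: float = 0.02  # nm, lateral placement noise


def composition_from_counts(
    table: dict[str, int], declared_total: int
) -> MembraneComposition:
    """Validate species counts against a declared total lipid count."""
    return MembraneComposition(counts=dict(table), leaflet_total=declared_total)


def _zigzag(n: int, origin: np.ndarray, phase: int = 0) -> np.ndarray:
    """All-trans chain of ``n`` carbons descending along -z from ``origin``."""
    pts = np.empty((n, 3))
    for k in range(n):
        pts[k] = origin + np.array(
            [_LATERAL if (k + phase) % 2 else 0.0, 0.0, -_AXIAL * (k + 1)]
        )
    return pts


def lipid_template(
    species: str, chain_length: int = 8
) -> tuple[MoleculeTopology, np.ndarray]:
    """Simplified lipid topology plus template coordinates.

    Coordinates are for an upper-leaflet lipid with the P atom at the
    origin and the tails descending along -z; the head P->N vector lies in
    the xy plane.
    """
    if chain_length < 3:
        raise ValueError("chain_length must be >= 3")
    has_n = species not in _NO_NITROGEN
    names: list[str] = []
    coords: list[np.ndarray] = []

    if has_n:
        names.append("N")
        coords.append(np.array([0.25, 0.0, 0.0]))
    else:
        names.append("O1")
        coords.append(np.array([0.20, 0.0, 0.05]))
    names.append("P")
    coords.append(np.array([0.0, 0.0, 0.0]))
    names.append("C1")
    coords.append(np.array([0.0, 0.10, -0.15]))
    names.append("C2")
    coords.append(np.array([0.0, 0.10, -0.15 - CC_BOND]))
    names.append("C3")
    coords.append(np.array([0.13, 0.10, -0.38]))

    chain_a = _zigzag(chain_length, coords[3])
    chain_b = _zigzag(chain_length, coords[4])
    for k in range(chain_length):
        names.append(f"C{k + 1}A")
        coords.append(chain_a[k])
    for k in range(chain_length):
        names.append(f"C{k + 1}B")
        coords.append(chain_b[k])

    charges = {nm: 0.0 for nm in names}
    charges["C1"] = 0.1
    charges["C2"] = -0.1
    if has_n:
        charges["N"] = 0.4
        charges["P"] = -1.4 if species in _ANIONIC else -0.4
    else:
        charges["O1"] = 0.4
        charges["P"] = -1.4 if species in _ANIONIC else -0.4

    topo = MoleculeTopology(name=species)
    for i, nm in enumerate(names):
        element = nm.lstrip("0123456789")[0]
        topo.atoms.append(
            AtomRecord(
                index=i + 1,
                name=nm,
                residue_name=species,
                residue_id=1,
                mass=_MASS[element],
                charge=charges[nm],
                type=element,
            )
        )

    def bond(a: str, b: str, length: float = CC_BOND):
        topo.bonded.append(
            BondedTerm(
                kind="bond",
                atom_indices=(topo.atom_index(a), topo.atom_index(b)),
                parameters=(length, 250000.0),
            )
        )

    head_first = "N" if has_n else "O1"
    bond(head_first, "P", 0.25)
    bond("P", "C1", 0.22)
    bond("C1", "C2", CC_BOND)  # the cut bond
    bond("C2", "C3")
    bond("C2", "C1A")
    bond("C3", "C1B")
    for k in range(1, chain_length):
        bond(f"C{k}A", f"C{k + 1}A")
        bond(f"C{k}B", f"C{k + 1}B")

    def angle(a: str, b: str, c: str):
        topo.bonded.append(
            BondedTerm(
                kind="angle",
                atom_indices=(
                    topo.atom_index(a), topo.atom_index(b), topo.atom_index(c),
                ),
                parameters=(TETRA_ANGLE, 400.0),
            )
        )

    angle(head_first, "P", "C1")
    angle("P", "C1", "C2")       # spans the cut
    angle("C1", "C2", "C3")      # spans the cut
    angle("C1", "C2", "C1A")     # spans the cut
    angle("C2", "C3", "C1B")
    angle("C2", "C1A", "C2A")
    topo.bonded.append(
        BondedTerm(
            kind="dihedral",
            atom_indices=(
                topo.atom_index(head_first), topo.atom_index("P"),
                topo.atom_index("C1"), topo.atom_index("C2"),
            ),
            parameters=(180.0, 2.0, 1.0),
        )
    )
    # one cross-cut pair to exercise the drop rule
    topo.bonded.append(
        BondedTerm(kind="pair", atom_indices=(topo.atom_index("P"),
                                              topo.atom_index("C3")))
    )
    topo.validate()
    return topo, np.array(coords)


def water_template() -> tuple[MoleculeTopology, np.ndarray]:
    topo = MoleculeTopology(name="SOL")
    data = [("OW", "O", 15.999, -0.8), ("HW1", "H", 1.008, 0.4),
            ("HW2", "H", 1.008, 0.4)]
    for i, (nm, typ, mass, q) in enumerate(data):
        topo.atoms.append(
            AtomRecord(index=i + 1, name=nm, residue_name="SOL", residue_id=1,
                       mass=mass, charge=q, type=typ)
        )
    topo.bonded.append(BondedTerm(kind="bond", atom_indices=(1, 2),
                                  parameters=(0.09572, 500000.0)))
    topo.bonded.append(BondedTerm(kind="bond", atom_indices=(1, 3),
                                  parameters=(0.09572, 500000.0)))
    coords = np.array(
        [[0.0, 0.0, 0.0], [0.0957, 0.0, 0.0], [-0.024, 0.0927, 0.0]]
    )
    return topo, coords


def default_chain_definitions(
    species: list[str], chain_length: int = 8
) -> dict[str, dict[str, list[str]]]:
    """Chain-carbon name lists (SN1/SN2) for fixture lipids."""
    sn1 = [f"C{k + 1}A" for k in range(chain_length)]
    sn2 = [f"C{k + 1}B" for k in range(chain_length)]
    return {sp: {"SN1": sn1, "SN2": sn2} for sp in species}


def build_bilayer(
    config: FixtureConfig,
) -> tuple[SystemFrame, dict[str, MoleculeTopology]]:
    """Deterministic toy bilayer on a square lattice.

    Lipids sit at the target area per lipid with all-trans tails pointing to
    the midplane; the lower leaflet is the upper one rotated by 180 degrees
    about x (a proper rotation, so per-species virtual-site constructions
    transfer exactly).  A thin water slab is placed above and below.
    Molecule order: upper-leaflet lipids, lower-leaflet lipids, water.
    """
    comp = config.composition
    n_leaflet = comp.total
    if n_leaflet <= 0:
        raise ValueError("composition must contain at least one lipid")
    box_xy = math.sqrt(n_leaflet * config.apl)
    n_side = math.ceil(math.sqrt(n_leaflet))
    spacing = box_xy / n_side
    if spacing <= 0.2:
        raise ValueError(
            f"lattice cannot host {n_leaflet} lipids in a {box_xy:.2f} nm box"
        )
    rng = np.random.default_rng(config.seed)
    z_mid = config.box_z / 2.0

    species_list: list[str] = []
    for sp in sorted(comp.counts):
        species_list.extend([sp] * comp.counts[sp])
    order = rng.permutation(len(species_list))
    species_list = [species_list[i] for i in order]

    templates = {
        sp: lipid_template(sp, config.chain_length)
        for sp in sorted(set(species_list))
    }

    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    masses: list[float] = []
    charges: list[float] = []
    positions: list[np.ndarray] = []
    resid = 0

    def emit(topo: MoleculeTopology, coords: np.ndarray) -> None:
        nonlocal resid
        resid += 1
        for a, xyz in zip(topo.atoms, coords):
            names.append(a.name)
            resnames.append(topo.name)
            resids.append(resid)
            masses.append(a.mass)
            charges.append(a.charge)
            positions.append(xyz)

    flip = np.diag([1.0, -1.0, -1.0])  # 180 degree rotation about x
    for leaflet_sign in (+1.0, -1.0):
        for k, sp in enumerate(species_list):
            topo, template = templates[sp]
            row, col = divmod(k, n_side)
            jitter = rng.uniform(-config.xy_jitter, config.xy_jitter, size=2)
            cx = (col + 0.5) * spacing + jitter[0]
            cy = (row + 0.5) * spacing + jitter[1]
            coords = template if leaflet_sign > 0 else template @ flip.T
            offset = np.array(
                [cx, cy, z_mid + leaflet_sign * config.head_plane_offset]
            )
            emit(topo, coords + offset)

    wat_topo, wat_coords = water_template()
    n_waters = config.waters_per_lipid * n_leaflet * 2
    membrane_top = config.head_plane_offset + 0.45
    slab = (config.box_z / 2.0) - membrane_top - 0.3
    if n_waters > 0 and slab <= 0.2:
        raise ValueError("box_z too small to host the water slabs")
    if n_waters > 0:
        per_slab = (n_waters + 1) // 2
        n_wside = math.ceil(per_slab ** (1.0 / 3.0))
        placed = 0
        for sign in (+1.0, -1.0):
            for idx in range(per_slab if sign > 0 else n_waters - per_slab):
                a, rem = divmod(idx, n_wside * n_wside)
                b, c = divmod(rem, n_wside)
                frac = (np.array([b, c, a]) + 0.5) / n_wside
                base = np.array(
                    [
                        frac[0] * box_xy,
                        frac[1] * box_xy,
                        z_mid + sign * (membrane_top + 0.15 + frac[2] * slab),
                    ]
                )
                base[:2] += rng.uniform(-0.03, 0.03, size=2)
                emit(wat_topo, wat_coords + base)
                placed += 1

    table = AtomTable(
        names=names, resnames=resnames, resids=resids, masses=masses,
        charges=charges,
    )
    frame = SystemFrame(
        table,
        np.asarray(positions),
        box=(box_xy, box_xy, config.box_z),
        time=0.0,
    )
    topologies = {sp: t for sp, (t, _) in templates.items()}
    topologies["SOL"] = wat_topo
    return frame, topologies


def brownian_trajectory(
    n_particles: int,
    d_target: float,
    dt: float,
    n_frames: int,
    box: tuple[float, float, float],
    seed: int,
) -> Trajectory:
    """Lateral Brownian walkers: per-step xy displacements are independent
    Gaussians of variance 2 * D * dt per axis; z is fixed at mid-box.
    Positions are wrapped into the box (the unwrapping in the MSD machinery
    undoes this as long as steps stay below half a box length)."""
    if n_particles <= 0 or dt <= 0 or n_frames <= 0:
        raise ValueError("n_particles, dt and n_frames must be positive")
    if d_target < 0:
        raise ValueError("d_target must be >= 0")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    table = AtomTable(
        names=["C"] * n_particles,
        resnames=["BRW"] * n_particles,
        resids=list(range(1, n_particles + 1)),
        masses=[12.011] * n_particles,
    )
    start = np.empty((n_particles, 3))
    start[:, 0] = rng.uniform(0, box[0], n_particles)
    start[:, 1] = rng.uniform(0, box[1], n_particles)
    start[:, 2] = box[2] / 2.0
    sigma = math.sqrt(2.0 * d_target * dt)
    frames = []
    pos = start.copy()
    for i in range(n_frames):
        if i > 0:
            steps = rng.normal(0.0, sigma, size=(n_particles, 2))
            pos = pos.copy()
            pos[:, :2] += steps
        wrapped = pos.copy()
        wrapped[:, :2] -= np.floor(wrapped[:, :2] / box[:2]) * box[:2]
        frames.append(SystemFrame(table, wrapped, box, time=i * dt))
    return Trajectory(frames)


@dataclass
class ChainFixture:
    """All-trans chain with ideal tetrahedral hydrogens."""

    carbons: np.ndarray  # (n, 3)
    hydrogens: np.ndarray  # (n-2, 2, 3) on interior carbons
    bond_length: float = CC_BOND

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.carbons[-1] - self.carbons[0]))


def ideal_chain(
    n_carbons: int,
    orientation: np.ndarray | None = None,
    geometry: str = "tetrahedral",
) -> ChainFixture:
    """All-trans zigzag with 109.47 degree angles and 0.153 nm C-C bonds,
    long axis along +z, optionally rigidly rotated by ``orientation``."""
    if n_carbons < 3:
        raise ValueError("n_carbons must be >= 3")
    if geometry != "tetrahedral":
        raise ValueError(f"unknown geometry {geometry!r}")
    carbons = np.empty((n_carbons, 3))
    for k in range(n_carbons):
        carbons[k] = [_LATERAL if k % 2 else 0.0, 0.0, _AXIAL * k]

    half = math.radians(TETRA_ANGLE / 2.0)
    hydrogens = np.empty((n_carbons - 2, 2, 3))
    for i in range(1, n_carbons - 1):
        b1 = carbons[i - 1] - carbons[i]
        b2 = carbons[i + 1] - carbons[i]
        b1 /= np.linalg.norm(b1)
        b2 /= np.linalg.norm(b2)
        bis = -(b1 + b2)
        bis /= np.linalg.norm(bis)
        w = np.cross(b1, b2)
        w /= np.linalg.norm(w)
        for j, s in enumerate((+1.0, -1.0)):
            direction = math.cos(half) * bis + s * math.sin(half) * w
            hydrogens[i - 1, j] = carbons[i] + CH_BOND * direction

    if orientation is not None:
        rot = np.asarray(orientation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        carbons = carbons @ rot.T
        hydrogens = hydrogens @ rot.T
    return ChainFixture(carbons=carbons, hydrogens=hydrogens)
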