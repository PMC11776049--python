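"""Split transformation: cut each phospholipid into an independent head and
tail molecule at the glycerol backbone, cap both cut ends with massless
virtual sites, and partition charges and bonded terms.

The cut removes the glycerol C1-C2 carbon-carbon bond.  Each moiety gains
one virtual site (V1 on the head, V2 on the tail) with zero mass, zero
charge and a non-interacting atom type, bonded to the cut-side atom at the
original equilibrium bond length so the cut valence is preserved.  Bonded
terms spanning the cut (angles, dihedrals, pairs, exclusions) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from splitmem.core import (
    AtomRecord,
    AtomTable,
    BondedTerm,
    ConfigurationError,
    MoleculeTopology,
    NON_LIPID_SPECIES,
    SystemFrame,
    VirtualSiteDef,
)

__all__ = [
    "SplitSpec",
    "SplitResult",
    "default_split_spec",
    "fit_vsite_params",
    "place_virtual_site",
    "split_lipid",
    "split_system",
]

#: atom type used for virtual sites: no LJ, no charge, no mass
VSITE_TYPE = "VS"
DEFAULT_SKIP_SPECIES = frozenset(NON_LIPID_SPECIES | {"CHL", "CHOL", "CHL1"})


@dataclass
class SplitSpec:
    """Per-species declaration of how to cut one lipid type.

    ``cut_bond`` is (head-side atom name, tail-side atom name) at the
    glycerol backbone; ``head_atoms``/``tail_atoms`` must partition the full
    atom-name set.  For sphingolipids (PSM) the analogous backbone bond is
    declared the same way.
    """

    species: str
    cut_bond: tuple[str, str]
    head_atoms: frozenset[str]
    tail_atoms: frozenset[str]
    head_anchor: str = "C1"
    tail_anchor: str = "C2"
    vsite_head_name: str = "V1"
    vsite_tail_name: str = "V2"

    def __post_init__(self) -> None:
        self.head_atoms = frozenset(self.head_atoms)
        self.tail_atoms = frozenset(self.tail_atoms)
        overlap = self.head_atoms & self.tail_atoms
        if overlap:
            raise ValueError(f"{self.species}: atoms in both moieties: {sorted(overlap)}")
        if self.cut_bond[0] not in self.head_atoms:
            raise ValueError(
                f"{self.species}: cut-bond head atom {self.cut_bond[0]!r} "
                "not in head_atoms"
            )
        if self.cut_bond[1] not in self.tail_atoms:
            raise ValueError(
                f"{self.species}: cut-bond tail atom {self.cut_bond[1]!r} "
                "not in tail_atoms"
            )

    @property
    def head_species(self) -> str:
        return f"{self.species}H"[:5]

    @property
    def tail_species(self) -> str:
        return f"{self.species}T"[:5]


def default_split_spec(topology: MoleculeTopology, species: str | None = None) -> SplitSpec:
    """Derive a SplitSpec for a topology that uses the C1/C2 glycerol naming
    convention: the cut is the C1-C2 bond, the head is everything bonded to
    C1's side, the tail everything on C2's side."""
    species = species or topology.name
    names = topology.atom_names
    if "C1" not in names or "C2" not in names:
        raise ConfigurationError(
            f"{species}: cannot derive split spec, needs atoms named C1 and C2"
        )
    # flood-fill moieties over the bond graph with the cut bond removed
    idx_by_name = {a.name: a.index for a in topology.atoms}
    c1, c2 = idx_by_name["C1"], idx_by_name["C2"]
    adj: dict[int, set[int]] = {a.index: set() for a in topology.atoms}
    for t in topology.bonds():
        i, j = t.atom_indices
        if {i, j} == {c1, c2}:
            continue
        adj[i].add(j)
        adj[j].add(i)
    def reachable(start: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen
    head_idx = reachable(c1)
    tail_idx = reachable(c2)
    if head_idx & tail_idx:
        raise ConfigurationError(
            f"{species}: C1 and C2 remain connected after removing the cut bond"
        )
    by_index = {a.index: a.name for a in topology.atoms}
    return SplitSpec(
        species=species,
        cut_bond=("C1", "C2"),
        head_atoms=frozenset(by_index[i] for i in head_idx),
        tail_atoms=frozenset(by_index[i] for i in tail_idx),
    )


def place_virtual_site(coords: np.ndarray, vsdef: VirtualSiteDef) -> np.ndarray:
    """Construct the site position from the moiety's real-atom coordinates.

    ``coords`` is an (n, 3) array indexed by the moiety's 1-based atom
    indices.  vsite2: ``r = r_i + a (r_j - r_i)``.  vsite3 (out-of-plane):
    ``r = r_i + a r_ij + b r_ik + c (r_ij x r_ik)``.
    """
    coords = np.asarray(coords, dtype=float)
    idx = [i - 1 for i in vsdef.constructing_atoms]
    p = vsdef.geometric_parameters
    if vsdef.construction_type == "vsite2":
        ri, rj = coords[idx[0]], coords[idx[1]]
        return ri + p[0] * (rj - ri)
    ri, rj, rk = coords[idx[0]], coords[idx[1]], coords[idx[2]]
    rij, rik = rj - ri, rk - ri
    cross = np.cross(rij, rik)
    if np.linalg.norm(cross) < 1e-10 * max(np.linalg.norm(rij), np.linalg.norm(rik), 1e-30):
        raise ValueError(
            "collinear constructing atoms: out-of-plane construction undefined"
        )
    return ri + p[0] * rij + p[1] * rik + p[2] * cross


def fit_vsite_params(
    constructing_atoms: tuple[int, ...],
    construction_type: str,
    coords: np.ndarray,
    target: np.ndarray,
    site_index: int,
) -> VirtualSiteDef:
    """Fit geometric parameters so the constructed site lands on ``target``."""
    coords = np.asarray(coords, dtype=float)
    target = np.asarray(target, dtype=float)
    idx = [i - 1 for i in constructing_atoms]
    if construction_type == "vsite2":
        ri, rj = coords[idx[0]], coords[idx[1]]
        d = rj - ri
        a = float(np.dot(target - ri, d) / np.dot(d, d))
        params = (a,)
    else:
        ri, rj, rk = coords[idx[0]], coords[idx[1]], coords[idx[2]]
        rij, rik = rj - ri, rk - ri
        cross = np.cross(rij, rik)
        if np.linalg.norm(cross) < 1e-10:
            raise ValueError("collinear constructing atoms; cannot fit vsite3")
        basis = np.stack([rij, rik, cross], axis=1)
        params = tuple(float(x) for x in np.linalg.solve(basis, target - ri))
    return VirtualSiteDef(
        site_index=site_index,
        constructing_atoms=constructing_atoms,
        construction_type=construction_type,
        geometric_parameters=params,
    )


def _bonded_neighbors(topology: MoleculeTopology, index: int) -> list[int]:
    out = []
    for t in topology.bonds():
        i, j = t.atom_indices
        if i == index:
            out.append(j)
        elif j == index:
            out.append(i)
    return out


def _extract_moiety(
    topology: MoleculeTopology,
    spec: SplitSpec,
    keep_names: frozenset[str],
    cut_atom_name: str,
    vsite_name: str,
    new_species: str,
) -> tuple[MoleculeTopology, dict[int, int]]:
    """Build one moiety topology; returns it plus old->new local index map."""
    keep = [a for a in topology.atoms if a.name in keep_names]
    old_to_new = {a.index: i + 1 for i, a in enumerate(keep)}

    moiety = MoleculeTopology(name=new_species)
    for a in keep:
        moiety.atoms.append(
            AtomRecord(
                index=old_to_new[a.index],
                name=a.name,
                residue_name=new_species,
                residue_id=1,
                mass=a.mass,
                charge=a.charge,
                type=a.type,
            )
        )
    cut_old = topology.atom_index(cut_atom_name)
    cut_partner_name = (
        spec.cut_bond[1] if cut_atom_name == spec.cut_bond[0] else spec.cut_bond[0]
    )
    cut_partner_old = topology.atom_index(cut_partner_name)
    cut_params: tuple[float, ...] = ()
    cut_funct = 1
    for t in topology.bonds():
        if set(t.atom_indices) == {cut_old, cut_partner_old}:
            cut_params = t.parameters
            cut_funct = t.function_type
            break
    kept_old = set(old_to_new)
    for t in topology.bonded:
        if {cut_old, cut_partner_old} <= set(t.atom_indices) and t.kind == "bond":
            continue  # the cut bond itself
        if all(i in kept_old for i in t.atom_indices):
            moiety.bonded.append(
                BondedTerm(
                    kind=t.kind,
                    atom_indices=tuple(old_to_new[i] for i in t.atom_indices),
                    function_type=t.function_type,
                    parameters=t.parameters,
                )
            )
        # terms spanning the cut are dropped

    vsite_index = len(moiety.atoms) + 1
    moiety.atoms.append(
        AtomRecord(
            index=vsite_index,
            name=vsite_name,
            residue_name=new_species,
            residue_id=1,
            mass=0.0,
            charge=0.0,
            type=VSITE_TYPE,
        )
    )
    # bond the site to the cut-side atom at the original equilibrium length
    moiety.bonded.append(
        BondedTerm(
            kind="bond",
            atom_indices=(old_to_new[cut_old], vsite_index),
            function_type=cut_funct,
            parameters=cut_params,
        )
    )
    # construct the site from the cut atom and its two nearest bonded
    # neighbours inside the moiety; fall back to vsite2 for terminal cuts
    neighbors = [n for n in _bonded_neighbors(topology, cut_old) if n in kept_old]
    others = [a.index for a in topology.atoms
              if a.index in kept_old and a.index != cut_old]
    constructors = [old_to_new[cut_old]] + [old_to_new[n] for n in neighbors[:2]]
    for o in others:
        if len(constructors) >= 3:
            break
        if old_to_new[o] not in constructors:
            constructors.append(old_to_new[o])
    if len(constructors) >= 3:
        ctype = "vsite3"
        constructors = tuple(constructors[:3])
    else:
        ctype = "vsite2"
        constructors = tuple(constructors[:2])
    moiety.virtual_sites.append(
        VirtualSiteDef(
            site_index=vsite_index,
            constructing_atoms=constructors,
            construction_type=ctype,
            geometric_parameters=(0.0,) * (1 if ctype == "vsite2" else 3),
        )
    )
    return moiety, old_to_new


def split_lipid(
    topology: MoleculeTopology, spec: SplitSpec
) -> tuple[MoleculeTopology, MoleculeTopology]:
    """Cut one lipid topology into head and tail moiety topologies.

    Every original atom lands in exactly one moiety with unchanged
    name/mass/charge/type; the cut bond is removed and each moiety gains one
    capping virtual site.  Cross-cut bonded terms are dropped.
    """
    names = set(topology.atom_names)
    missing = (spec.head_atoms | spec.tail_atoms) - names
    if missing:
        raise ConfigurationError(
            f"{spec.species}: spec names not in topology: {sorted(missing)}"
        )
    uncovered = names - (spec.head_atoms | spec.tail_atoms)
    if uncovered:
        raise ConfigurationError(
            f"{spec.species}: atoms not assigned to a moiety: {sorted(uncovered)}"
        )
    c1 = topology.atom_index(spec.cut_bond[0])
    c2 = topology.atom_index(spec.cut_bond[1])
    if not any(set(t.atom_indices) == {c1, c2} for t in topology.bonds()):
        raise ConfigurationError(
            f"{spec.species}: cut bond {spec.cut_bond[0]}-{spec.cut_bond[1]} "
            "absent from topology"
        )
    head, _ = _extract_moiety(
        topology, spec, spec.head_atoms, spec.cut_bond[0],
        spec.vsite_head_name, spec.head_species,
    )
    tail, _ = _extract_moiety(
        topology, spec, spec.tail_atoms, spec.cut_bond[1],
        spec.vsite_tail_name, spec.tail_species,
    )
    return head, tail


@dataclass
class SplitResult:
    """Split system plus the bookkeeping needed to reunite it."""

    frame: SystemFrame
    topologies: dict[str, MoleculeTopology]
    original_topologies: dict[str, MoleculeTopology]
    specs: dict[str, "SplitSpec"]
    #: old 1-based global atom index -> new 1-based global atom index
    index_map: dict[int, int]
    moiety_charges: dict[str, float] = field(default_factory=dict)


def split_system(
    frame: SystemFrame,
    topologies: dict[str, MoleculeTopology],
    specs: dict[str, SplitSpec],
    skip_species: set[str] | None = None,
) -> SplitResult:
    """Split every phospholipid molecule of a system frame.

    Output molecule order: all heads (in original lipid order), then all
    tails (same order), then untouched species in original order.  Real-atom
    coordinates are copied unchanged; virtual-site coordinates are
    initialised at the position of the removed bonded neighbour, which is
    what the fitted construction rule reproduces.
    """
    if skip_species is None:
        skip_species = set(DEFAULT_SKIP_SPECIES)
    table = frame.table
    species_seen = set(table.mol_species())
    for sp in sorted(species_seen):
        topo = topologies.get(sp)
        if topo is not None and topo.virtual_sites:
            raise ConfigurationError(f"species {sp!r} already split")
        if sp in specs or sp in skip_species:
            continue
        raise ConfigurationError(
            f"lipid species {sp!r} has no SplitSpec and is not in skip_species"
        )

    moieties: dict[str, tuple[MoleculeTopology, MoleculeTopology]] = {}
    for sp, spec in specs.items():
        if sp not in species_seen:
            continue
        if sp not in topologies:
            raise ConfigurationError(f"no topology provided for species {sp!r}")
        moieties[sp] = split_lipid(topologies[sp], spec)

    head_entries = []  # (positions, table rows) per head molecule
    tail_entries = []
    other_entries = []
    index_map: dict[int, int] = {}
    head_old_indices: list[list[int | None]] = []
    tail_old_indices: list[list[int | None]] = []
    other_old_indices: list[list[int]] = []

    for sl in table.mol_slices:
        sp = str(table.resnames[sl.start])
        global_first = sl.start + 1  # 1-based
        if sp in moieties:
            topo = topologies[sp]
            spec = specs[sp]
            name_to_local = {a.name: a.index for a in topo.atoms}
            mol_names = [str(n) for n in table.names[sl]]
            if mol_names != topo.atom_names:
                raise ConfigurationError(
                    f"molecule at atom {global_first}: atom order differs from "
                    f"{sp} topology"
                )
            pos = frame.positions[sl]
            head_topo, tail_topo = moieties[sp]
            for which, moiety_topo, old_lists, entries in (
                ("head", head_topo, head_old_indices, head_entries),
                ("tail", tail_topo, tail_old_indices, tail_entries),
            ):
                cut_self, cut_other = (
                    (spec.cut_bond[0], spec.cut_bond[1])
                    if which == "head"
                    else (spec.cut_bond[1], spec.cut_bond[0])
                )
                coords = np.empty((moiety_topo.n_atoms, 3))
                olds: list[int | None] = []
                for a in moiety_topo.atoms:
                    if a.type == VSITE_TYPE:
                        coords[a.index - 1] = pos[name_to_local[cut_other] - 1]
                        olds.append(None)
                    else:
                        coords[a.index - 1] = pos[name_to_local[a.name] - 1]
                        olds.append(global_first + name_to_local[a.name] - 1)
                entries.append((sp, moiety_topo, coords))
                old_lists.append(olds)
        else:
            other_entries.append((sp, None, frame.positions[sl].copy()))
            other_old_indices.append(
                [global_first + k for k in range(sl.stop - sl.start)]
            )

    # fit per-species vsite construction parameters from the first instance
    fitted: set[str] = set()
    for sp, moiety_topo, coords in head_entries + tail_entries:
        if moiety_topo.name in fitted:
            continue
        vs = moiety_topo.virtual_sites[0]
        target = coords[vs.site_index - 1]
        moiety_topo.virtual_sites[0] = fit_vsite_params(
            vs.constructing_atoms, vs.construction_type, coords, target, vs.site_index
        )
        fitted.add(moiety_topo.name)

    names, resnames, resids, masses, charges = [], [], [], [], []
    positions = []
    new_index = 1
    resid = 0

    def emit(species_name, atom_names, atom_masses, atom_charges, coords, olds):
        nonlocal new_index, resid
        resid += 1
        for k, nm in enumerate(atom_names):
            names.append(nm)
            resnames.append(species_name)
            resids.append(resid)
            masses.append(atom_masses[k])
            charges.append(atom_charges[k])
            positions.append(coords[k])
            if olds[k] is not None:
                index_map[olds[k]] = new_index
            new_index += 1

    for (sp, moiety_topo, coords), olds in zip(
        head_entries, head_old_indices
    ):
        emit(
            moiety_topo.name,
            moiety_topo.atom_names,
            [a.mass for a in moiety_topo.atoms],
            [a.charge for a in moiety_topo.atoms],
            coords,
            olds,
        )
    for (sp, moiety_topo, coords), olds in zip(tail_entries, tail_old_indices):
        emit(
            moiety_topo.name,
            moiety_topo.atom_names,
            [a.mass for a in moiety_topo.atoms],
            [a.charge for a in moiety_topo.atoms],
            coords,
            olds,
        )
    for (sp, _, coords), olds in zip(other_entries, other_old_indices):
        sl = slice(olds[0] - 1, olds[-1])
        emit(
            sp,
            [str(n) for n in table.names[sl]],
            list(table.masses[sl]),
            list(table.charges[sl]),
            coords,
            olds,
        )

    new_table = AtomTable(
        names=names, resnames=resnames, resids=resids, masses=masses, charges=charges
    )
    new_frame = SystemFrame(
        new_table, np.asarray(positions), frame.box.copy(), frame.time
    )

    new_topos: dict[str, MoleculeTopology] = {}
    for sp, (h, t) in moieties.items():
        new_topos[h.name] = h
        new_topos[t.name] = t
    for sp, topo in topologies.items():
        if sp not in moieties:
            new_topos[sp] = topo

    moiety_charges = {
        name: topo.total_charge
        for name, topo in new_topos.items()
        if name.endswith(("H", "T")) and name not in topologies
    }
    return SplitResult(
        frame=new_frame,
        topologies=new_topos,
        original_topologies=dict(topologies),
        specs=dict(specs),
        index_map=index_map,
        moiety_charges=moiety_charges,
    )
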