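"""Reunite split heads and tails into whole lipids.

Pairing is per (leaflet, lipid type) class: candidate head-tail anchor
distances (minimum image in xy, plain difference in z) are either consumed
greedily in ascending order (default, "select the closest head") or solved
as a minimum-total-distance assignment.  Cross-leaflet or cross-type pairs
are never produced.  After merging, junctions longer than a threshold are
flagged for minimisation/re-equilibration with xy-restrained headgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from splitmem.core import (
    AtomTable,
    LeafletAssignment,
    MoleculeTopology,
    SystemFrame,
    assign_leaflets,
)
from splitmem.split import SplitSpec, VSITE_TYPE

__all__ = [
    "MergePlan",
    "StrainReport",
    "apply_merge",
    "plan_merge",
    "strain_report",
]


@dataclass
class MergePlan:
    """One-to-one head-tail pairing with junction distances."""

    #: (head molecule id, tail molecule id, junction distance nm, leaflet)
    pairs: list[tuple[int, int, float, str]]
    unmatched_heads: list[int] = field(default_factory=list)
    unmatched_tails: list[int] = field(default_factory=list)
    strategy: str = "greedy"

    @property
    def max_junction_distance(self) -> float:
        return max((p[2] for p in self.pairs), default=0.0)

    @property
    def total_distance(self) -> float:
        return float(sum(p[2] for p in self.pairs))

    @property
    def complete(self) -> bool:
        return not self.unmatched_heads and not self.unmatched_tails


def _junction_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image in xy, plain difference in z."""
    d = a - b
    d[0] -= box[0] * round(d[0] / box[0])
    d[1] -= box[1] * round(d[1] / box[1])
    return float(np.sqrt(d @ d))


def _anchor_position(
    frame: SystemFrame, mol_id: int, anchor_name: str
) -> np.ndarray:
    sl = frame.table.mol_slices[mol_id]
    names = frame.table.names[sl]
    hits = np.nonzero(names == anchor_name)[0]
    if hits.size == 0:
        raise ValueError(
            f"molecule {mol_id}: anchor atom {anchor_name!r} not found"
        )
    return frame.positions[sl.start + hits[0]].copy()


def plan_merge(
    frame: SystemFrame,
    specs: dict[str, SplitSpec],
    leaflets: LeafletAssignment | None = None,
    strategy: str = "greedy",
) -> MergePlan:
    """Pair every split head with a tail of the same lipid type and leaflet.

    ``greedy`` consumes candidate pairs in ascending distance (ties broken
    by head id, then tail id); ``optimal`` minimises the total junction
    distance via the Hungarian algorithm.
    """
    if strategy not in ("greedy", "optimal"):
        raise ValueError(f"unknown strategy {strategy!r}")
    table = frame.table
    head_species = {spec.head_species: sp for sp, spec in specs.items()}
    tail_species = {spec.tail_species: sp for sp, spec in specs.items()}

    if leaflets is None:
        anchors: dict[str, str] = {}
        for sp, spec in specs.items():
            anchors[spec.head_species] = spec.head_anchor
            anchors[spec.tail_species] = spec.tail_anchor
        moiety_names = set(anchors)
        # prefer the phosphorus atom for head leaflet assignment when present
        for m, sl in enumerate(table.mol_slices):
            resname = str(table.resnames[sl.start])
            if resname in head_species and "P" in table.names[sl]:
                anchors[resname] = "P"
        leaflets = assign_leaflets(frame, anchors, lipid_species=moiety_names)

    classes: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for m, sl in enumerate(table.mol_slices):
        resname = str(table.resnames[sl.start])
        if resname in head_species:
            key = (leaflets.labels[m], head_species[resname])
            classes.setdefault(key, ([], []))[0].append(m)
        elif resname in tail_species:
            key = (leaflets.labels[m], tail_species[resname])
            classes.setdefault(key, ([], []))[1].append(m)

    pairs: list[tuple[int, int, float, str]] = []
    for (leaflet, sp), (heads, tails) in sorted(classes.items()):
        if len(heads) != len(tails):
            raise ValueError(
                f"class ({leaflet}, {sp}): {len(heads)} heads vs "
                f"{len(tails)} tails"
            )
        spec = specs[sp]
        hpos = np.array(
            [_anchor_position(frame, h, spec.head_anchor) for h in heads]
        )
        tpos = np.array(
            [_anchor_position(frame, t, spec.tail_anchor) for t in tails]
        )
        dist = np.empty((len(heads), len(tails)))
        for i in range(len(heads)):
            for j in range(len(tails)):
                dist[i, j] = _junction_distance(hpos[i], tpos[j], frame.box)
        if strategy == "optimal":
            rows, cols = linear_sum_assignment(dist)
            for i, j in zip(rows, cols):
                pairs.append((heads[i], tails[j], float(dist[i, j]), leaflet))
        else:
            candidates = sorted(
                (float(dist[i, j]), heads[i], tails[j], i, j)
                for i in range(len(heads))
                for j in range(len(tails))
            )
            used_h: set[int] = set()
            used_t: set[int] = set()
            for d, h, t, i, j in candidates:
                if i in used_h or j in used_t:
                    continue
                used_h.add(i)
                used_t.add(j)
                pairs.append((h, t, d, leaflet))
    pairs.sort(key=lambda p: p[0])
    return MergePlan(pairs=pairs, strategy=strategy)


def apply_merge(
    frame: SystemFrame,
    plan: MergePlan,
    original_topologies: dict[str, MoleculeTopology],
    specs: dict[str, SplitSpec],
) -> tuple[SystemFrame, dict[str, MoleculeTopology]]:
    """Rebuild whole lipids from a complete merge plan.

    Virtual sites are discarded; atoms are reordered to the original species
    atom order; real-atom coordinates are unchanged; the cut bond and all
    original intra-lipid bonded terms come back with the stored pre-split
    topology.  Merged lipids appear in head-molecule order, followed by the
    untouched species.
    """
    if not plan.complete:
        raise ValueError("merge plan has unmatched molecules")
    table = frame.table
    n_mols = table.n_molecules
    head_species = {spec.head_species: sp for sp, spec in specs.items()}
    tail_species = {spec.tail_species: sp for sp, spec in specs.items()}

    for h, t, _, _ in plan.pairs:
        if not (0 <= h < n_mols and 0 <= t < n_mols):
            raise ValueError(f"plan references unknown molecule id {max(h, t)}")

    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    masses: list[float] = []
    charges: list[float] = []
    positions: list[np.ndarray] = []
    resid = 0

    def positions_by_name(mol_id: int) -> dict[str, np.ndarray]:
        sl = table.mol_slices[mol_id]
        return {
            str(table.names[sl.start + k]): frame.positions[sl.start + k]
            for k in range(sl.stop - sl.start)
        }

    for h, t, _, _ in sorted(plan.pairs, key=lambda p: p[0]):
        sp = head_species[str(table.resnames[table.mol_slices[h].start])]
        topo = original_topologies[sp]
        spec = specs[sp]
        hpos = positions_by_name(h)
        tpos = positions_by_name(t)
        resid += 1
        for a in topo.atoms:
            if a.name in spec.head_atoms:
                pos = hpos[a.name]
            elif a.name in spec.tail_atoms:
                pos = tpos[a.name]
            else:  # pragma: no cover - split_lipid guarantees full coverage
                raise ValueError(f"{sp}: atom {a.name} not in either moiety")
            names.append(a.name)
            resnames.append(sp)
            resids.append(resid)
            masses.append(a.mass)
            charges.append(a.charge)
            positions.append(pos)

    for m, sl in enumerate(table.mol_slices):
        resname = str(table.resnames[sl.start])
        if resname in head_species or resname in tail_species:
            continue
        resid += 1
        for k in range(sl.stop - sl.start):
            names.append(str(table.names[sl.start + k]))
            resnames.append(resname)
            resids.append(resid)
            masses.append(float(table.masses[sl.start + k]))
            charges.append(float(table.charges[sl.start + k]))
            positions.append(frame.positions[sl.start + k])

    new_table = AtomTable(
        names=names, resnames=resnames, resids=resids, masses=masses, charges=charges
    )
    merged = SystemFrame(
        new_table, np.asarray(positions), frame.box.copy(), frame.time
    )
    topologies = {
        sp: topo
        for sp, topo in original_topologies.items()
    }
    return merged, topologies


@dataclass
class StrainReport:
    """Junctions too long for immediate production use."""

    threshold: float
    #: (head id, tail id, distance, leaflet), sorted descending by distance
    flagged: list[tuple[int, int, float, str]]
    recommendation: str
    headgroup_posres: str = ""

    @property
    def needs_reequilibration(self) -> bool:
        return bool(self.flagged)

    def to_dict(self) -> dict:
        return {
            "threshold_nm": self.threshold,
            "n_flagged": len(self.flagged),
            "flagged": [
                {"head": h, "tail": t, "distance_nm": d, "leaflet": lf}
                for h, t, d, lf in self.flagged
            ],
            "recommendation": self.recommendation,
        }


def strain_report(
    plan: MergePlan,
    threshold: float = 0.3,
    head_topologies: dict[str, MoleculeTopology] | None = None,
) -> StrainReport:
    """Flag merged pairs whose junction distance exceeds ``threshold`` (nm).

    When any pair is flagged, the report carries an xy position-restraint
    block for headgroup atoms so the tails can relax toward their heads
    during re-equilibration.
    """
    flagged = sorted(
        (p for p in plan.pairs if p[2] > threshold),
        key=lambda p: -p[2],
    )
    if flagged:
        recommendation = (
            f"{len(flagged)} junction(s) exceed {threshold} nm: minimise and "
            "re-equilibrate with headgroup positions restrained in xy so the "
            "acyl tails move toward their heads."
        )
    else:
        recommendation = "all junctions within threshold; no re-equilibration needed"

    posres = ""
    if flagged and head_topologies:
        blocks = []
        for sp, topo in sorted(head_topologies.items()):
            lines = [f"; xy headgroup restraints for {sp}",
                     "[ position_restraints ]", "; atom  funct  fx  fy  fz"]
            for a in topo.atoms:
                if a.type == VSITE_TYPE:
                    continue
                lines.append(f"{a.index:6d}  1  1000  1000  0")
            blocks.append("\n".join(lines))
        posres = "\n\n".join(blocks) + "\n"

    return StrainReport(
        threshold=threshold,
        flagged=flagged,
        recommendation=recommendation,
        headgroup_posres=posres,
    )
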