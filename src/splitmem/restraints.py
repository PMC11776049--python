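"""Flat-bottomed layer potentials that hold the split bilayer together.

A restraint acts on the |z| distance of each selected atom from a reference
z (by default the membrane COM of the input frame).  Non-inverted wells are
flat inside ``r0`` and harmonic outside; inverted wells (used for water
oxygens) are harmonic inside and flat outside:

    non-inverted:  U = 1/2 k (d - r0)^2   for d > r0, else 0
    inverted:      U = 1/2 k (r0 - d)^2   for d < r0, else 0

with d = |z - z_ref|.  ``k`` is in kJ mol^-1 nm^-2.  The default parameter
sets are: water oxygens k=2.5, r0=2.5 nm inverted; head anchors (C1) k=10,
r0=3.3 nm (2.8 nm for pure POPC); tail anchors (C2) k=50, r0=1.0 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from splitmem.core import MoleculeTopology, SystemFrame, membrane_com

__all__ = [
    "RestraintSpec",
    "RestraintEmission",
    "default_restraints",
    "flat_bottom_energy",
    "emit_restraint_files",
    "resolve_selection",
]

#: GROMACS flat-bottomed position-restraint geometry code: layer along z
_LAYER_Z_GEOMETRY = 8

#: atom names recognised as water oxygen
WATER_O_NAMES = frozenset({"OW", "O", "OH2"})
WATER_SPECIES = frozenset({"SOL", "WAT", "TIP3"})


@dataclass
class RestraintSpec:
    """One flat-bottomed layer potential."""

    selection: str  # C1_heads | C2_tails | water_O | custom group name
    k: float  # kJ mol^-1 nm^-2
    r0: float  # nm, offset from the reference z
    inverted: bool = False
    reference_mode: str = "initial_frame_COM"  # or "fixed_z"
    fixed_z: float | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"force constant must be >= 0, got {self.k}")
        if self.r0 <= 0:
            raise ValueError(f"offset distance must be > 0, got {self.r0}")
        if self.reference_mode not in ("initial_frame_COM", "fixed_z"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")


def default_restraints(system_kind: str) -> list[RestraintSpec]:
    """Default restraint set for a split bilayer.

    ``system_kind`` is ``"mixed"`` (any multi-component membrane) or
    ``"pure_POPC"``, which tightens the head-anchor offset to 2.8 nm.
    """
    if system_kind not in ("mixed", "pure_POPC"):
        raise ValueError(
            f"unknown system_kind {system_kind!r}; expected 'mixed' or 'pure_POPC'"
        )
    c1_r0 = 2.8 if system_kind == "pure_POPC" else 3.3
    return [
        RestraintSpec(selection="water_O", k=2.5, r0=2.5, inverted=True),
        RestraintSpec(selection="C1_heads", k=10.0, r0=c1_r0),
        RestraintSpec(selection="C2_tails", k=50.0, r0=1.0),
    ]


def flat_bottom_energy(
    z: float | np.ndarray, z_ref: float, spec: RestraintSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Energy (kJ/mol) and z-force (kJ mol^-1 nm^-1) of one restraint.

    The force is the exact negative gradient, continuous at d = r0.
    """
    z = np.asarray(z, dtype=float)
    dz = z - z_ref
    d = np.abs(dz)
    sign = np.sign(dz)
    if spec.inverted:
        excess = np.maximum(spec.r0 - d, 0.0)
        energy = 0.5 * spec.k * excess**2
        # dU/dz = -k (r0 - d) sign(z - z_ref); pushes outward inside the well
        force = spec.k * excess * sign
    else:
        excess = np.maximum(d - spec.r0, 0.0)
        energy = 0.5 * spec.k * excess**2
        force = -spec.k * excess * sign
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def resolve_selection(
    frame: SystemFrame,
    selection: str,
    topologies: dict[str, MoleculeTopology] | None = None,
    anchor_names: dict[str, str] | None = None,
) -> list[int]:
    """Resolve a named restraint group to 1-based global atom indices.

    ``C1_heads``/``C2_tails`` select the anchor atoms of head/tail moiety
    species (resname ending in H/T); ``water_O`` selects water oxygens.
    """
    table = frame.table
    indices: list[int] = []
    if selection == "water_O":
        for i in range(len(table)):
            if (
                str(table.resnames[i]) in WATER_SPECIES
                and str(table.names[i]) in WATER_O_NAMES
            ):
                indices.append(i + 1)
    elif selection in ("C1_heads", "C2_tails"):
        suffix = "H" if selection == "C1_heads" else "T"
        anchor = "C1" if selection == "C1_heads" else "C2"
        for i in range(len(table)):
            resname = str(table.resnames[i])
            if resname.endswith(suffix) and resname not in WATER_SPECIES:
                name = str(table.names[i])
                wanted = (anchor_names or {}).get(resname, anchor)
                if name == wanted:
                    indices.append(i + 1)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not indices:
        raise ValueError(f"selection {selection!r} resolved to no atoms")
    return indices


@dataclass
class RestraintEmission:
    """Engine-ready text artefacts for one restraint set."""

    itp_sections: dict[str, str]  # species -> [position_restraints] block
    ndx_groups: dict[str, list[int]]
    manifest: dict
    reference_z: float
    pull_block: str = ""


def _posres_section(local_indices: Iterable[int], spec: RestraintSpec) -> str:
    # funct 2 = flat-bottomed position restraint; negative r means inverted
    r = -spec.r0 if spec.inverted else spec.r0
    lines = ["[ position_restraints ]", "; atom  funct  g  r(nm)  k(kJ/mol/nm^2)"]
    for i in sorted(local_indices):
        lines.append(f"{i:6d}  2  {_LAYER_Z_GEOMETRY}  {r:.3f}  {spec.k:.3f}")
    return "\n".join(lines) + "\n"


def emit_restraint_files(
    specs: list[RestraintSpec],
    frame: SystemFrame,
    topologies: dict[str, MoleculeTopology] | None = None,
    mode: str = "posres",
) -> RestraintEmission:
    """Turn restraint specs into engine-format text blocks.

    ``posres`` emits per-species ``[position_restraints]`` sections with the
    layer-along-z flat-bottom geometry, with the reference z pinned to the
    membrane COM of the supplied frame (documented approximation of the
    instantaneous-COM reference).  ``pull`` emits a COM-pull style block for
    engines where a moving reference is preferred.
    """
    if mode not in ("posres", "pull"):
        raise ValueError(f"unknown mode {mode!r}")
    z_ref = membrane_com(frame)
    table = frame.table
    ndx_groups: dict[str, list[int]] = {}
    itp_sections: dict[str, str] = {}
    manifest: dict = {"mode": mode, "reference_z_nm": z_ref, "restraints": []}

    for spec in specs:
        global_idx = resolve_selection(frame, spec.selection, topologies)
        ndx_groups[spec.selection] = global_idx
        manifest["restraints"].append(
            {
                "selection": spec.selection,
                "k_kJ_per_mol_nm2": spec.k,
                "r0_nm": spec.r0,
                "inverted": spec.inverted,
                "n_atoms": len(global_idx),
            }
        )
        if mode != "posres":
            continue
        # group global indices by species and convert to molecule-local ones
        by_species: dict[str, set[int]] = {}
        for gi in global_idx:
            i = gi - 1
            resname = str(table.resnames[i])
            sl = next(s for s in table.mol_slices if s.start <= i < s.stop)
            by_species.setdefault(resname, set()).add(i - sl.start + 1)
        for resname, locals_ in by_species.items():
            itp_sections[resname] = _posres_section(locals_, spec)

    pull_block = ""
    if mode == "pull":
        chunks = ["; COM-pull realisation of the layer restraints",
                  "pull = yes", f"pull-ngroups = {len(specs) + 1}",
                  "pull-group1-name = membrane"]
        for n, spec in enumerate(specs, start=2):
            chunks += [
                f"pull-group{n}-name = {spec.selection}",
                f"; flat-bottom{'-high' if not spec.inverted else ''} "
                f"r0={spec.r0} nm k={spec.k} kJ/mol/nm^2 along z vs membrane COM",
            ]
        pull_block = "\n".join(chunks) + "\n"

    return RestraintEmission(
        itp_sections=itp_sections,
        ndx_groups=ndx_groups,
        manifest=manifest,
        reference_z=z_ref,
        pull_block=pull_block,
    )
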