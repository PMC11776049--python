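"""GROMACS TOP/ITP subset reader/writer.

Interpreted sections: [moleculetype], [atoms], [bonds], [pairs], [angles],
[dihedrals], [exclusions], [virtual_sites2], [virtual_sites3].  Everything
else ([defaults], [atomtypes], [position_restraints], preprocessor lines,
unknown force-field sections) is carried through verbatim, so a file can be
round-tripped without understanding every parameter line.  #include is
expanded at most one level when reading a master TOP; #ifdef logic is
recorded, not evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from splitmem.core import (
    AtomRecord,
    BondedTerm,
    MoleculeTopology,
    VirtualSiteDef,
    guess_mass,
)
from splitmem.io._util import ParseError, open_text

__all__ = [
    "Section",
    "SystemTopology",
    "TopologyFileModel",
    "read_itp",
    "read_top",
    "write_itp",
    "write_top",
]

_INTERPRETED = {
    "moleculetype",
    "atoms",
    "bonds",
    "pairs",
    "angles",
    "dihedrals",
    "exclusions",
    "virtual_sites2",
    "virtual_sites3",
}
_KNOWN_PASSTHROUGH = {
    "defaults",
    "atomtypes",
    "bondtypes",
    "angletypes",
    "dihedraltypes",
    "pairtypes",
    "nonbond_params",
    "position_restraints",
    "settles",
    "system",
    "molecules",
}

_KIND_BY_SECTION = {
    "bonds": ("bond", 2),
    "pairs": ("pair", 2),
    "angles": ("angle", 3),
    "dihedrals": ("dihedral", 4),
}


@dataclass
class Section:
    """One ``[ name ]`` block; ``name=None`` holds the pre-section preamble."""

    name: str | None
    lines: list[str] = field(default_factory=list)


@dataclass
class TopologyFileModel:
    """Ordered section view of a TOP/ITP file; renders back verbatim."""

    sections: list[Section] = field(default_factory=list)

    @classmethod
    def parse(cls, text: str) -> "TopologyFileModel":
        model = cls()
        current = Section(name=None)
        model.sections.append(current)
        for raw in text.splitlines():
            stripped = raw.split(";", 1)[0].strip()
            if stripped.startswith("[") and stripped.endswith("]"):
                current = Section(name=stripped[1:-1].strip().lower())
                model.sections.append(current)
            else:
                current.lines.append(raw)
        return model

    def render(self) -> str:
        out: list[str] = []
        for sec in self.sections:
            if sec.name is not None:
                out.append(f"[ {sec.name} ]")
            out.extend(sec.lines)
        return "\n".join(out) + "\n"

    def find(self, name: str) -> list[Section]:
        return [s for s in self.sections if s.name == name]


def _data_lines(section: Section):
    for raw in section.lines:
        content = raw.split(";", 1)[0].strip()
        if not content or content.startswith("#"):
            continue
        yield content


def _parse_molecule(model: TopologyFileModel, path) -> MoleculeTopology:
    mt = model.find("moleculetype")
    if not mt:
        raise ParseError(path, 1, "no [moleculetype] section")
    fields = next(_data_lines(mt[0]), None)
    if fields is None:
        raise ParseError(path, 1, "[moleculetype] has no data line")
    name = fields.split()[0]

    topo = MoleculeTopology(name=name)
    seen_indices: set[int] = set()
    for sec in model.find("atoms"):
        for content in _data_lines(sec):
            parts = content.split()
            if len(parts) < 5:
                raise ParseError(path, 1, f"short [atoms] line: {content!r}")
            idx = int(parts[0])
            if idx in seen_indices:
                raise ParseError(path, 1, f"duplicate atom index {idx}")
            seen_indices.add(idx)
            atom_name = parts[4]
            charge = float(parts[6]) if len(parts) > 6 else 0.0
            mass = float(parts[7]) if len(parts) > 7 else guess_mass(atom_name)
            topo.atoms.append(
                AtomRecord(
                    index=idx,
                    name=atom_name,
                    residue_name=parts[3],
                    residue_id=int(parts[2]),
                    mass=mass,
                    charge=charge,
                    type=parts[1],
                )
            )

    for sec_name, (kind, arity) in _KIND_BY_SECTION.items():
        for sec in model.find(sec_name):
            for content in _data_lines(sec):
                parts = content.split()
                idxs = tuple(int(x) for x in parts[:arity])
                funct = int(parts[arity]) if len(parts) > arity else 1
                params = tuple(float(x) for x in parts[arity + 1 :])
                topo.bonded.append(
                    BondedTerm(kind=kind, atom_indices=idxs, function_type=funct,
                               parameters=params)
                )

    for sec in model.find("exclusions"):
        for content in _data_lines(sec):
            parts = [int(x) for x in content.split()]
            for partner in parts[1:]:
                topo.bonded.append(
                    BondedTerm(kind="exclusion", atom_indices=(parts[0], partner))
                )

    for sec in model.find("virtual_sites2"):
        for content in _data_lines(sec):
            parts = content.split()
            topo.virtual_sites.append(
                VirtualSiteDef(
                    site_index=int(parts[0]),
                    constructing_atoms=(int(parts[1]), int(parts[2])),
                    construction_type="vsite2",
                    geometric_parameters=tuple(float(x) for x in parts[4:]),
                )
            )
    for sec in model.find("virtual_sites3"):
        for content in _data_lines(sec):
            parts = content.split()
            topo.virtual_sites.append(
                VirtualSiteDef(
                    site_index=int(parts[0]),
                    constructing_atoms=tuple(int(x) for x in parts[1:4]),
                    construction_type="vsite3",
                    geometric_parameters=tuple(float(x) for x in parts[5:]),
                )
            )

    for sec in model.sections:
        if sec.name is None or sec.name in _INTERPRETED:
            continue
        if sec.name not in _KNOWN_PASSTHROUGH:
            warnings.warn(
                f"{path}: unknown section [{sec.name}] passed through verbatim",
                stacklevel=3,
            )
        topo.extra_sections.append((sec.name, list(sec.lines)))

    try:
        topo.validate()
    except ValueError as exc:
        raise ParseError(path, 1, str(exc)) from None
    return topo


def read_itp(path) -> MoleculeTopology:
    """Read a single-molecule ITP file."""
    path = Path(path)
    with open_text(path) as fh:
        text = fh.read()
    return _parse_molecule(TopologyFileModel.parse(text), path)


def write_itp(topology: MoleculeTopology, path) -> None:
    """Write a molecule topology as an ITP file (deterministic layout)."""
    out: list[str] = []
    out.append("[ moleculetype ]")
    out.append("; name  nrexcl")
    out.append(f"{topology.name}  3")
    out.append("")
    out.append("[ atoms ]")
    out.append(";   nr  type  resnr  resname  atom  cgnr  charge  mass")
    for a in topology.atoms:
        out.append(
            f"{a.index:6d}  {a.type or a.name:<6s}{a.residue_id:5d}  "
            f"{a.residue_name:<6s}{a.name:<6s}{a.index:5d}"
            f"{a.charge:12.6f}{a.mass:12.5f}"
        )
    for sec_name, (kind, _) in _KIND_BY_SECTION.items():
        terms = [t for t in topology.bonded if t.kind == kind]
        if not terms:
            continue
        out.append("")
        out.append(f"[ {sec_name} ]")
        for t in terms:
            idxs = "".join(f"{i:6d}" for i in t.atom_indices)
            params = "".join(f"  {p:.6g}" for p in t.parameters)
            out.append(f"{idxs}{t.function_type:6d}{params}")
    excl = [t for t in topology.bonded if t.kind == "exclusion"]
    if excl:
        out.append("")
        out.append("[ exclusions ]")
        for t in excl:
            out.append(f"{t.atom_indices[0]:6d}{t.atom_indices[1]:6d}")
    for vtype in ("vsite2", "vsite3"):
        sites = [v for v in topology.virtual_sites if v.construction_type == vtype]
        if not sites:
            continue
        out.append("")
        out.append(f"[ virtual_sites{vtype[-1]} ]")
        for v in sites:
            idxs = "".join(f"{i:6d}" for i in (v.site_index, *v.constructing_atoms))
            funct = 1 if vtype == "vsite2" else 4  # 4 = 3-atom out-of-plane
            params = "".join(f"  {p:.9g}" for p in v.geometric_parameters)
            out.append(f"{idxs}{funct:6d}{params}")
    for name, lines in topology.extra_sections:
        out.append("")
        out.append(f"[ {name} ]")
        out.extend(lines)
    with open_text(path, "wt") as fh:
        fh.write("\n".join(out) + "\n")


@dataclass
class SystemTopology:
    """Master TOP: include lines, system name and molecule counts."""

    system_name: str = "system"
    includes: list[str] = field(default_factory=list)
    molecules: list[tuple[str, int]] = field(default_factory=list)


def write_top(system: SystemTopology, path) -> None:
    out = []
    for inc in system.includes:
        out.append(f'#include "{inc}"')
    out.append("")
    out.append("[ system ]")
    out.append(system.system_name)
    out.append("")
    out.append("[ molecules ]")
    for name, count in system.molecules:
        out.append(f"{name:<10s}{count:8d}")
    with open_text(path, "wt") as fh:
        fh.write("\n".join(out) + "\n")


def read_top(path) -> SystemTopology:
    """Read a master TOP ([system]/[molecules] plus #include lines)."""
    path = Path(path)
    with open_text(path) as fh:
        text = fh.read()
    model = TopologyFileModel.parse(text)
    system = SystemTopology()
    for sec in model.sections:
        if sec.name is None:
            for raw in sec.lines:
                content = raw.strip()
                if content.startswith("#include"):
                    system.includes.append(content.split('"')[1])
    sys_secs = model.find("system")
    if sys_secs:
        line = next(_data_lines(sys_secs[0]), None)
        if line:
            system.system_name = line
    for sec in model.find("molecules"):
        for content in _data_lines(sec):
            parts = content.split()
            system.molecules.append((parts[0], int(parts[1])))
    return system
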