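import numpy as np
import pytest

from splitmem.core import (
    AtomRecord,
    BondedTerm,
    ConfigurationError,
    MoleculeTopology,
    VirtualSiteDef,
)
from splitmem.split import (
    SplitSpec,
    VSITE_TYPE,
    default_split_spec,
    fit_vsite_params,
    place_virtual_site,
    split_lipid,
    split_system,
)


def toy_linear_molecule():
    """A-B-C-D chain, charges (+0.3, -0.3, +0.1, -0.1)."""
    topo = MoleculeTopology(name="TOY")
    for i, (name, q) in enumerate(
        zip("ABCD", (0.3, -0.3, 0.1, -0.1)), start=1
    ):
        topo.atoms.append(
            AtomRecord(index=i, name=name, residue_name="TOY", residue_id=1,
                       mass=12.011, charge=q, type="C")
        )
    for i in range(1, 4):
        topo.bonded.append(
            BondedTerm(kind="bond", atom_indices=(i, i + 1),
                       parameters=(0.153, 250000.0))
        )
    return topo


def toy_spec():
    return SplitSpec(
        species="TOY",
        cut_bond=("B", "C"),
        head_atoms=frozenset("AB"),
        tail_atoms=frozenset("CD"),
        head_anchor="B",
        tail_anchor="C",
    )


class TestSplitLipid:
    def test_toy_charge_partition(self):
        head, tail = split_lipid(toy_linear_molecule(), toy_spec())
        assert {a.name for a in head.atoms} == {"A", "B", "V1"}
        assert {a.name for a in tail.atoms} == {"C", "D", "V2"}
        assert head.total_charge == pytest.approx(0.0, abs=1e-9)
        assert tail.total_charge == pytest.approx(0.0, abs=1e-9)

    def test_fixture_popc_bookkeeping(self, popc_system, popc_specs):
        # oracle: brute-force atom/charge bookkeeping over the fixture topology
        _, topologies = popc_system
        topo = topologies["POPC"]
        spec = popc_specs["POPC"]
        expected_head = {a.name for a in topo.atoms if a.name in spec.head_atoms}
        expected_tail = {a.name for a in topo.atoms if a.name in spec.tail_atoms}
        assert expected_head == {"N", "P", "C1"}
        assert len(expected_tail) == topo.n_atoms - 3

        head, tail = split_lipid(topo, spec)
        assert {a.name for a in head.atoms} == expected_head | {"V1"}
        assert {a.name for a in tail.atoms} == expected_tail | {"V2"}
        total = head.total_charge + tail.total_charge
        assert total == pytest.approx(topo.total_charge, abs=1e-6)
        # every original atom appears exactly once with unchanged properties
        by_name = {a.name: a for a in topo.atoms}
        for moiety in (head, tail):
            for a in moiety.atoms:
                if a.type == VSITE_TYPE:
                    assert a.mass == 0.0 and a.charge == 0.0
                    continue
                orig = by_name[a.name]
                assert (a.mass, a.charge, a.type) == (
                    orig.mass, orig.charge, orig.type
                )

    def test_bond_counting_identity(self, popc_system, popc_specs):
        _, topologies = popc_system
        topo = topologies["POPC"]
        head, tail = split_lipid(topo, popc_specs["POPC"])
        assert (
            len(head.bonds()) + len(tail.bonds())
            == len(topo.bonds()) - 1 + 2
        )

    def test_cross_cut_terms_dropped(self, popc_system, popc_specs):
        _, topologies = popc_system
        head, tail = split_lipid(topologies["POPC"], popc_specs["POPC"])
        orig = topologies["POPC"]
        n_angles = len([t for t in orig.bonded if t.kind == "angle"])
        n_cross = 3  # P-C1-C2, C1-C2-C3, C1-C2-C1A span the cut
        kept = sum(
            len([t for t in m.bonded if t.kind == "angle"])
            for m in (head, tail)
        )
        assert kept == n_angles - n_cross
        # the cross-cut pair and dihedral disappear too
        assert not any(t.kind == "pair" for t in head.bonded)
        assert not any(t.kind == "pair" for t in tail.bonded)
        assert not any(t.kind == "dihedral" for t in head.bonded)

    def test_mass_conservation(self, popc_system, popc_specs):
        _, topologies = popc_system
        topo = topologies["POPC"]
        head, tail = split_lipid(topo, popc_specs["POPC"])
        assert head.total_mass + tail.total_mass == pytest.approx(
            topo.total_mass, abs=1e-9
        )

    def test_unknown_names_error(self):
        spec = SplitSpec(
            species="TOY", cut_bond=("B", "C"),
            head_atoms=frozenset(["A", "B", "Z9"]),
            tail_atoms=frozenset("CD"),
        )
        with pytest.raises(ConfigurationError, match="Z9"):
            split_lipid(toy_linear_molecule(), spec)

    def test_missing_cut_bond_error(self):
        spec = SplitSpec(
            species="TOY", cut_bond=("A", "C"),
            head_atoms=frozenset(["A"]),
            tail_atoms=frozenset(["B", "C", "D"]),
        )
        with pytest.raises(ConfigurationError, match="cut bond"):
            split_lipid(toy_linear_molecule(), spec)


class TestPlaceVirtualSite:
    def test_reproduces_removed_neighbor(self, popc_system, popc_specs):
        frame, topologies = popc_system
        topo = topologies["POPC"]
        spec = popc_specs["POPC"]
        head, _ = split_lipid(topo, spec)
        sl = frame.table.mol_slices[0]
        pos = frame.positions[sl]
        local = {a.name: a.index for a in topo.atoms}
        coords = np.array(
            [pos[local[a.name] - 1] for a in head.atoms if a.type != VSITE_TYPE]
        )
        target = pos[local["C2"] - 1]
        vs = head.virtual_sites[0]
        fitted = fit_vsite_params(
            vs.constructing_atoms, vs.construction_type, coords, target,
            vs.site_index,
        )
        placed = place_virtual_site(coords, fitted)
        assert np.linalg.norm(placed - target) < 1e-3

    def test_translation_equivariance(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0, 0.1, 0.05]])
        vs = fit_vsite_params((1, 2, 3), "vsite3", coords,
                              np.array([0.05, 0.05, 0.1]), 4)
        base = place_virtual_site(coords, vs)
        shifted = place_virtual_site(coords + np.array([1.0, 1.0, 1.0]), vs)
        np.testing.assert_allclose(shifted, base + 1.0, atol=1e-12)

    def test_rotation_equivariance(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0, 0.1, 0.05]])
        vs = fit_vsite_params((1, 2, 3), "vsite3", coords,
                              np.array([0.05, 0.05, 0.1]), 4)
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        base = place_virtual_site(coords, vs)
        rotated = place_virtual_site(coords @ rot.T, vs)
        np.testing.assert_allclose(rotated, rot @ base, atol=1e-12)

    def test_collinear_constructors_error(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        vs = VirtualSiteDef(site_index=4, constructing_atoms=(1, 2, 3),
                            construction_type="vsite3",
                            geometric_parameters=(0.1, 0.1, 0.1))
        with pytest.raises(ValueError, match="collinear"):
            place_virtual_site(coords, vs)


class TestSplitSystem:
    def test_counts(self, popc_system, popc_split):
        frame, _ = popc_system
        species = popc_split.frame.table.mol_species()
        assert species.count("POPCH") == 32
        assert species.count("POPCT") == 32
        assert species.count("SOL") == frame.table.mol_species().count("SOL")

    def test_real_coordinates_bit_identical(self, popc_system, popc_split):
        frame, _ = popc_system
        inv = popc_split.index_map
        for old, new in inv.items():
            assert np.array_equal(
                frame.positions[old - 1], popc_split.frame.positions[new - 1]
            )

    def test_total_mass_and_charge_conserved(self, popc_system, popc_split):
        frame, _ = popc_system
        assert popc_split.frame.table.masses.sum() == pytest.approx(
            frame.table.masses.sum(), abs=1e-6
        )
        assert popc_split.frame.table.charges.sum() == pytest.approx(
            frame.table.charges.sum(), abs=1e-6
        )

    def test_chl_untouched(self, mixed_system):
        frame, topologies = mixed_system
        specs = {
            sp: default_split_spec(topologies[sp])
            for sp in ("POPC", "POPS", "POPA")
        }
        result = split_system(frame, topologies, specs)
        species = result.frame.table.mol_species()
        assert species.count("CHL") == frame.table.mol_species().count("CHL")
        chl_slices_old = [
            sl for sl in frame.table.mol_slices
            if frame.table.resnames[sl.start] == "CHL"
        ]
        chl_slices_new = [
            sl for sl in result.frame.table.mol_slices
            if result.frame.table.resnames[sl.start] == "CHL"
        ]
        for old_sl, new_sl in zip(chl_slices_old, chl_slices_new):
            assert np.array_equal(
                frame.positions[old_sl], result.frame.positions[new_sl]
            )

    def test_molecule_ordering(self, popc_split):
        species = popc_split.frame.table.mol_species()
        kinds = []
        for sp in species:
            kind = ("head" if sp.endswith("H") else
                    "tail" if sp.endswith("T") else "other")
            if not kinds or kinds[-1] != kind:
                kinds.append(kind)
        assert kinds == ["head", "tail", "other"]

    def test_already_split_error(self, popc_split):
        with pytest.raises(ConfigurationError, match="already split"):
            split_system(
                popc_split.frame, popc_split.topologies,
                {"POPCH": SplitSpec(
                    species="POPCH", cut_bond=("P", "C1"),
                    head_atoms=frozenset(["N", "P"]),
                    tail_atoms=frozenset(["C1", "V1"]),
                )},
            )

    def test_missing_spec_error(self, popc_system):
        frame, topologies = popc_system
        with pytest.raises(ConfigurationError, match="POPC"):
            split_system(frame, topologies, {}, skip_species={"SOL"})

    def test_moiety_charge_report(self, mixed_system):
        frame, topologies = mixed_system
        specs = {sp: default_split_spec(topologies[sp])
                 for sp in ("POPC", "POPS", "POPA")}
        result = split_system(frame, topologies, specs)
        assert result.moiety_charges["POPCH"] == pytest.approx(0.1, abs=1e-9)
        assert result.moiety_charges["POPST"] == pytest.approx(-0.1, abs=1e-9)
        assert result.moiety_charges["POPSH"] == pytest.approx(-0.9, abs=1e-9)


class TestDefaultSplitSpec:
    def test_flood_fill_partition(self, popc_system):
        _, topologies = popc_system
        spec = default_split_spec(topologies["POPC"])
        assert spec.cut_bond == ("C1", "C2")
        assert spec.head_atoms == frozenset({"N", "P", "C1"})
        assert "C8A" in spec.tail_atoms and "C8B" in spec.tail_atoms

    def test_requires_c1_c2(self):
        topo = toy_linear_molecule()
        with pytest.raises(ConfigurationError, match="C1 and C2"):
            default_split_spec(topo)
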