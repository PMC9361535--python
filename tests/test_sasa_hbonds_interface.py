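"""Surface accessibility, polar contacts and interface zones."""

import numpy as np
import pytest

from meninscope.structure.hbonds import hydrogen_bonds
from meninscope.structure.interface import InterfaceDefinition, interface_residues
from meninscope.structure.model import StructureModel, read_structure
from meninscope.structure.sasa import relative_sasa, shrake_rupley_sasa


def _single_residue_model(extra_cage=False):
    """One leucine, optionally enclosed in a 4-Å cage of carbons."""
    from meninscope.simulate.structure import StructureSpec, make_toy_structure

    pdb, _ = make_toy_structure(StructureSpec(n_residues=2), seed=0)
    model = read_structure(pdb)
    if not extra_cage:
        return model
    # surround residue 1's CA with a dense spherical shell of atoms
    center = model.atom_coord(("A", 1, ""), "CA")
    phi = np.pi * (3 - np.sqrt(5)) * np.arange(200)
    z = 1 - 2 * (np.arange(200) + 0.5) / 200
    r = np.sqrt(1 - z * z)
    shell = center + 4.0 * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    names = list(model.atom_names) + ["CA"] * 200
    elements = list(model.elements) + ["C"] * 200
    res_names = list(model.res_names) + ["ALA"] * 200
    chains = list(model.chains) + ["Z"] * 200
    keys = list(model.res_keys) + [("Z", 900 + i, "") for i in range(200)]
    coords = np.vstack([model.coords, shell])
    return StructureModel(
        "caged", names, elements, res_names, chains, keys, coords,
        np.ones(len(names)), [""] * len(names),
    )


def test_isolated_terminal_residue_is_fully_exposed(toy_structure):
    model = toy_structure["model"]
    rel = relative_sasa(model)
    # chain ends stick out into solvent
    assert rel[("A", 1, "")] >= 0.5
    assert all(0 <= v <= 1.2 for v in rel.values() if not np.isnan(v))


def test_caged_residue_is_buried():
    model = _single_residue_model(extra_cage=True)
    # oracle at 10× the default point density agrees the residue is buried
    for n_points in (196, 1960):
        rel = relative_sasa(model, n_points=n_points)
        assert rel[("A", 1, "")] < 0.05


def test_sasa_matches_biopython_shrake_rupley(toy_structure):
    """Independent oracle: Bio.PDB's Shrake–Rupley on the same structure."""
    import io
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    model = toy_structure["model"]
    ours = shrake_rupley_sasa(model, n_points=960)

    structure = PDBParser(QUIET=True).get_structure("t", io.StringIO(model.to_pdb()))
    ShrakeRupley(n_points=960).compute(structure, level="R")
    theirs = {}
    for res in structure.get_residues():
        chain = res.get_parent().id
        theirs[(chain, res.id[1], res.id[2].strip())] = res.sasa
    for key, ids in model.residue_index.items():
        assert float(np.sum(ours[ids])) == pytest.approx(theirs[key], rel=0.05, abs=2.0)


def test_glycine_makes_no_sidechain_polar_contacts(toy_structure):
    model = toy_structure["model"]
    # leucine side chains are apolar too — same expectation
    assert hydrogen_bonds(model, ("A", 2, "")) == []


def test_planted_ser_asp_hbond_found_exactly_once(toy_structure):
    model = toy_structure["model"]
    truth = toy_structure["truth"]
    (pos,) = truth.hbond_positions
    contacts = hydrogen_bonds(model, ("A", pos, ""))
    assert len(contacts) == 1
    c = contacts[0]
    assert c.kind == "hbond" and c.partner_atom == "OD1"
    assert c.distance == pytest.approx(2.8, abs=0.05)


def _two_atom_complex(gap):
    """Chain A glycine vs chain B glycine separated by ``gap`` Å CA-to-CA."""
    rows = []
    for i, (chain, x) in enumerate([("A", 0.0), ("B", gap)]):
        rows.append((chain, i + 1, "GLY", "CA", np.array([x, 0.0, 0.0])))
    return StructureModel(
        "pair",
        [r[3] for r in rows],
        ["C", "C"],
        [r[2] for r in rows],
        [r[0] for r in rows],
        [(r[0], r[1], "") for r in rows],
        np.array([r[4] for r in rows]),
        np.ones(2),
        ["", ""],
    )


@pytest.mark.parametrize("gap,included", [(4.9, True), (5.1, False)])
def test_interface_boundary_at_contact_radius(gap, included):
    model = _two_atom_complex(gap)
    idef = InterfaceDefinition("x", "pair", ("A",), ("B",), radius=5.0)
    zone = interface_residues(model, idef)
    assert (("A", 1, "") in zone) is included


def test_zero_radius_gives_empty_zone():
    model = _two_atom_complex(3.0)
    idef = InterfaceDefinition("x", "pair", ("A",), ("B",), radius=0.0)
    assert interface_residues(model, idef) == set()


def test_interface_zone_monotone_in_radius(toy_structure):
    model = toy_structure["model"]
    zones = []
    for r in (2.0, 4.0, 5.0, 8.0):
        idef = InterfaceDefinition("p", "toy", ("A",), ("B",), radius=r)
        zones.append(interface_residues(model, idef))
    for small, big in zip(zones, zones[1:]):
        assert small <= big


def test_planted_interface_position_in_zone(toy_structure):
    zone = interface_residues(toy_structure["model"], toy_structure["interface"])
    (pos,) = toy_structure["truth"].interface_positions
    assert ("A", pos, "") in zone


def test_missing_partner_chain_is_an_error():
    model = _two_atom_complex(3.0)
    idef = InterfaceDefinition("x", "pair", ("A",), ("Q",), radius=5.0)
    with pytest.raises(ValueError, match="partner"):
        interface_residues(model, idef)
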