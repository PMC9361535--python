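"""Rotamer construction and steric clash detection."""

import numpy as np
import pytest

from meninscope.structure.clashes import clash_fraction, rotamer_clashes
from meninscope.structure.geometry import dihedral
from meninscope.structure.rotamers import (
    CHI_ATOMS,
    AA1_TO_3,
    default_rotamer_library,
    enumerate_rotamers,
)
from meninscope.structure.sasa import VDW_RADII, _DEFAULT_RADIUS


def test_glycine_gives_single_trivial_placement(toy_structure):
    placements = enumerate_rotamers(toy_structure["model"], ("A", 5, ""), "G")
    assert len(placements) == 1
    assert placements[0].coords.shape == (0, 3)


def test_library_cardinality_is_preserved(toy_structure):
    lib = default_rotamer_library()
    for aa in ("K", "S", "F", "W"):
        placements = enumerate_rotamers(toy_structure["model"], ("A", 5, ""), aa, lib)
        assert len(placements) == len(lib[aa])


def test_gly_ala_have_no_chi_angles():
    lib = default_rotamer_library()
    assert lib["G"] == [] and lib["A"] == []
    assert all(lib[aa] for aa in lib if aa not in ("G", "A"))


@pytest.mark.parametrize("aa", ["K", "R", "E", "N", "I", "T", "Y", "M"])
def test_built_chi_angles_match_library_within_one_degree(toy_structure, aa):
    """Re-measuring χ from the built coordinates returns the library value."""
    model = toy_structure["model"]
    key = ("A", 6, "")
    backbone = {name: model.atom_coord(key, name) for name in ("N", "CA", "C")}
    res3 = AA1_TO_3[aa]
    quads = CHI_ATOMS[res3]
    for placement in enumerate_rotamers(model, key, aa)[:12]:
        pos = dict(zip(placement.atom_names, placement.coords))
        pos.update(backbone)
        for k, (a, b, c, d) in enumerate(quads):
            measured = dihedral(pos[a], pos[b], pos[c], pos[d])
            expected = placement.chis[k]
            delta = (measured - expected + 180.0) % 360.0 - 180.0
            assert abs(delta) < 1.0


def test_missing_backbone_atom_is_named(toy_structure):
    model = toy_structure["model"]
    # strip the CA of residue 5
    import copy

    m = copy.deepcopy(model)
    i = m.atom_index(("A", 5, ""), "CA")
    for attr in ("atom_names", "elements", "res_names", "chains", "res_keys", "altlocs"):
        getattr(m, attr).pop(i)
    m.coords = np.delete(m.coords, i, axis=0)
    m.occupancies = np.delete(m.occupancies, i)
    m.residue_index = {}
    m.__post_init__()
    with pytest.raises(ValueError, match="CA"):
        enumerate_rotamers(m, ("A", 5, ""), "K")


def _brute_force_clash(placement, model, tol, excluded_keys, excluded_names):
    """Exhaustive O(n²) pairwise check."""
    for k, xyz in enumerate(placement.coords):
        r1 = VDW_RADII.get(placement.elements[k], _DEFAULT_RADIUS)
        for j in range(model.n_atoms):
            key = model.res_keys[j]
            if key == placement.residue_key:
                continue
            if (key, model.atom_names[j]) in excluded_names:
                continue
            r2 = VDW_RADII.get(model.elements[j], _DEFAULT_RADIUS)
            if np.linalg.norm(xyz - model.coords[j]) < r1 + r2 - tol:
                return True
    return False


@pytest.mark.parametrize("aa", ["K", "W", "D"])
def test_clash_detection_equals_brute_force_oracle(toy_structure, aa):
    model = toy_structure["model"]
    for pos in (2, 3, 8, 12):
        key = ("A", pos, "")
        placements = enumerate_rotamers(model, key, aa)
        fast = rotamer_clashes(placements, model, 0.4)
        chain, num, _ = key
        skip = {
            ((chain, num - 1, ""), "C"), ((chain, num - 1, ""), "O"),
            ((chain, num + 1, ""), "N"),
        }
        slow = [
            _brute_force_clash(p, model, 0.4, {key}, skip) for p in placements
        ]
        assert fast == slow


def test_planted_blocker_forces_all_rotamers_to_clash(toy_structure):
    model = toy_structure["model"]
    truth = toy_structure["truth"]
    for pos in truth.clash_positions:
        for aa in ("K", "S", "W"):
            placements = enumerate_rotamers(model, ("A", pos, ""), aa)
            frac, cls = clash_fraction(placements, model)
            assert frac == 1.0 and cls == "unstable"


def test_placements_in_empty_space_are_stable(toy_structure):
    model = toy_structure["model"]
    # position 14 is the free C-terminal end of the chain
    placements = enumerate_rotamers(model, ("A", 14, ""), "S")
    frac, cls = clash_fraction(placements, model)
    assert frac == 0.0 and cls == "stable"


def test_clash_fraction_monotone_in_tolerance(toy_structure):
    model = toy_structure["model"]
    placements = enumerate_rotamers(model, ("A", 8, ""), "W")
    fracs = [clash_fraction(placements, model, tol)[0]
             for tol in (0.0, 0.2, 0.4, 0.8, 1.5)]
    assert fracs == sorted(fracs, reverse=True)


def test_empty_placements_rejected(toy_structure):
    with pytest.raises(ValueError):
        clash_fraction([], toy_structure["model"])
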