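"""Geometry, torsion and file-format unit tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anomerthermo.chem_core import (
    DihedralSpec,
    Geometry,
    bond_graph,
    measure_dihedral,
    molecular_formula,
    place_atom,
    read_xyz,
    read_xyz_frames,
    read_zmatrix,
    rigid_transform,
    set_dihedral,
    write_xyz,
)
from anomerthermo.errors import DegenerateTorsionError, ParseError, RingTorsionError
from anomerthermo.synthetic import toy_molecule


def _chain(torsion_deg: float) -> Geometry:
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([1.5, 0.0, 0.0])
    p2 = p1 + np.array([0.5, 1.4, 0.0])
    p3 = place_atom(p2, p1, p0, 1.5, 112.0, torsion_deg)
    return Geometry(("C", "C", "C", "C"), np.array([p3, p2, p1, p0]))


CHAIN_SPEC = DihedralSpec(0, 1, 2, 3)


@pytest.mark.parametrize(
    "angle, expected",
    [(0.0, 0.0), (180.0, 180.0), (60.0, 60.0), (-60.0, -60.0), (170.0, 170.0)],
)
def test_measure_dihedral_constructed_angles(angle, expected):
    """Torsions of analytically constructed chains: cis 0, trans 180, gauche ±60."""
    geom = _chain(angle)
    assert measure_dihedral(geom, CHAIN_SPEC) == pytest.approx(expected, abs=1e-6)


def test_measure_dihedral_collinear_raises():
    geom = Geometry(
        ("C", "C", "C", "C"),
        np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float),
    )
    with pytest.raises(DegenerateTorsionError):
        measure_dihedral(geom, CHAIN_SPEC)


def test_measure_dihedral_index_errors():
    geom = _chain(60.0)
    with pytest.raises(IndexError):
        measure_dihedral(geom, DihedralSpec(0, 1, 2, 9))
    with pytest.raises(IndexError):
        measure_dihedral(geom, DihedralSpec(0, 1, 2, 2))


@given(st.floats(min_value=-179.9, max_value=180.0))
def test_measure_dihedral_rigid_motion_invariant(angle):
    """Torsion angles are invariant under global rotation + translation."""
    geom = _chain(angle)
    ref = measure_dihedral(geom, CHAIN_SPEC)
    rng = np.random.default_rng(7)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    t = rng.uniform(0, 2 * math.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) * math.cos(t) + math.sin(t) * K + (1 - math.cos(t)) * np.outer(axis, axis)
    moved = rigid_transform(geom, rotation=R, translation=rng.normal(size=3) * 10)
    assert measure_dihedral(moved, CHAIN_SPEC) == pytest.approx(ref, abs=1e-9)


@pytest.mark.parametrize("target", [-170.0, -60.0, 0.0, 60.0, 170.0])
def test_set_measure_round_trip(target):
    geom = _chain(42.0)
    driven = set_dihedral(geom, CHAIN_SPEC, target)
    assert measure_dihedral(driven, CHAIN_SPEC) == pytest.approx(target, abs=1e-9)


def test_set_dihedral_identity_leaves_coordinates():
    geom = _chain(42.0)
    current = measure_dihedral(geom, CHAIN_SPEC)
    same = set_dihedral(geom, CHAIN_SPEC, current)
    assert np.allclose(same.coords, geom.coords, atol=1e-9)


def test_set_dihedral_preserves_internal_distances():
    """Distances within the moved side and within the anchored side are conserved."""
    geom, dihedrals = toy_molecule("toy-furanose")
    spec = dihedrals[0]
    graph = bond_graph(geom)
    comps = graph.components_without(spec.j, spec.k)
    driven = set_dihedral(geom, spec, 77.0)
    for comp in comps:
        idx = sorted(comp)
        before = np.linalg.norm(
            geom.coords[idx][:, None, :] - geom.coords[idx][None, :, :], axis=-1
        )
        after = np.linalg.norm(
            driven.coords[idx][:, None, :] - driven.coords[idx][None, :, :], axis=-1
        )
        assert np.allclose(before, after, atol=1e-9)
    assert molecular_formula(driven) == molecular_formula(geom)


def test_set_dihedral_ring_bond_raises():
    geom, _ = toy_molecule("toy-furanose")
    lab = {n: i for i, n in enumerate(geom.atom_labels)}
    ring_spec = DihedralSpec(lab["O4'"], lab["C1'"], lab["C2'"], lab["C3'"])
    with pytest.raises(RingTorsionError):
        set_dihedral(geom, ring_spec, 10.0)


@pytest.mark.parametrize(
    "kind, formula",
    [("water", "H2O"), ("methanol", "CH4O"), ("toy-furanose", "C5H10O5"),
     ("toy-deoxyfuranose", "C5H10O4"), ("toy-phosphate", "H2O4P")],
)
def test_molecular_formula(kind, formula):
    geom, _ = toy_molecule(kind)
    assert molecular_formula(geom) == formula


def test_molecular_formula_empty():
    assert molecular_formula(Geometry((), np.zeros((0, 3)))) == ""


def test_xyz_round_trip_all_toys():
    for kind in ("water", "methanol", "peroxide-chain", "toy-furanose", "toy-base"):
        geom, _ = toy_molecule(kind)
        back = read_xyz(write_xyz(geom))
        assert back.elements == geom.elements
        assert np.allclose(back.coords, geom.coords, atol=1e-6)
        assert molecular_formula(back) == molecular_formula(geom)


def test_xyz_count_mismatch_raises():
    with pytest.raises(ParseError):
        read_xyz("3\ncomment\nO 0.0 0.0 0.0\nH 1.0 0.0 0.0\n")


def test_xyz_malformed_row_names_line():
    with pytest.raises(ParseError) as err:
        read_xyz("2\ncomment\nO 0.0 0.0 0.0\nH 1.0 zero 0.0\n")
    assert err.value.line == 4


def test_multi_frame_xyz():
    g1, _ = toy_molecule("water")
    g2, _ = toy_molecule("methanol")
    frames = read_xyz_frames(write_xyz(g1) + write_xyz(g2))
    assert [molecular_formula(f) for f in frames] == ["H2O", "CH4O"]


def test_zmatrix_reconstruction_matches_declared_torsions():
    """Z-matrix → Cartesian: re-measured torsions equal the declared values."""
    text = """
C
C 1 1.53
C 2 1.53 1 111.0
C 3 1.53 2 111.0 1 -65.0
O 4 1.43 3 109.0 2 175.0
H 5 0.96 4 107.0 3 60.0
"""
    geom = read_zmatrix(text)
    assert measure_dihedral(geom, DihedralSpec(3, 2, 1, 0)) == pytest.approx(-65.0, abs=1e-6)
    assert measure_dihedral(geom, DihedralSpec(4, 3, 2, 1)) == pytest.approx(175.0, abs=1e-6)
    assert measure_dihedral(geom, DihedralSpec(5, 4, 3, 2)) == pytest.approx(60.0, abs=1e-6)
    assert molecular_formula(geom) == "C4HO"  # heavy-atom skeleton toy


def test_zmatrix_bad_reference_raises():
    with pytest.raises(ParseError):
        read_zmatrix("C\nC 2 1.5\n")


def test_bond_graph_furanose_connectivity(furanose):
    geom, _ = furanose
    graph = bond_graph(geom)
    # a connected single molecule: removing any hydroxyl H-O bond gives 2 parts
    lab = {n: i for i, n in enumerate(geom.atom_labels)}
    comps = graph.components_without(lab["O5'"], lab["HO5'"])
    assert len(comps) == 2
    assert {len(c) for c in comps} == {1, geom.n_atoms - 1}
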