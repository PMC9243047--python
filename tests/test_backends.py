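"""Surrogate potential, optimizer, frequencies, and QC deck/log adapters."""

import math

import numpy as np
import pytest

from anomerthermo.backends import (
    EnergyRecord,
    SurrogateBackend,
    SurrogateParams,
    extract_geometry_from_input,
    parse_qc_output,
    write_qc_input,
)
from anomerthermo.chem_core import DihedralSpec, Geometry, measure_dihedral, rigid_transform, set_dihedral
from anomerthermo.errors import ParseError, SingularPairError
from anomerthermo.synthetic import toy_molecule


def test_constructed_minimum_energy_zero(butane_like, torsion_toy_backend):
    """At reference bond lengths and a torsion minimum all terms vanish."""
    geom, spec = butane_like
    at_min = set_dihedral(geom, spec, 60.0)
    assert torsion_toy_backend.evaluate(at_min) == pytest.approx(0.0, abs=1e-9)


def test_energy_rigid_motion_invariant(furanose, furanose_backend):
    geom, _ = furanose
    ref = furanose_backend.evaluate(geom)
    t = math.radians(77.0)
    R = np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )
    moved = rigid_transform(geom, rotation=R, translation=np.array([5.0, -3.0, 11.0]))
    assert furanose_backend.evaluate(moved) == pytest.approx(ref, abs=1e-9)


def test_torsion_profile_matches_dense_grid_oracle(butane_like, torsion_toy_backend):
    """3-fold torsion, barrier 2, phase 0: minima at ±60°/180°, maxima at 0°/±120°."""
    geom, spec = butane_like
    angles = np.arange(-180, 180, 1)  # 360 points on the circle
    energies = np.array(
        [torsion_toy_backend.evaluate(set_dihedral(geom, spec, float(a))) for a in angles]
    )
    minima = set()
    maxima = set()
    n = len(angles)
    for i, a in enumerate(angles):
        lo, hi = energies[(i - 1) % n], energies[(i + 1) % n]
        if energies[i] < lo and energies[i] < hi:
            minima.add(int(a))
        if energies[i] > lo and energies[i] > hi:
            maxima.add(int(a))
    assert minima == {-60, 60, -180}
    assert maxima == {-120, 0, 120}


def test_singular_pair_raises():
    geom = Geometry(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.05, 0.0, 0.0]]))
    backend = SurrogateBackend(SurrogateParams(bonds=((0, 1, 100.0, 0.7),)))
    with pytest.raises(SingularPairError):
        backend.evaluate(geom)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SurrogateParams(bonds=((0, 1, -5.0, 1.0),))
    with pytest.raises(ValueError):
        SurrogateParams(nonbonded=((0, 1, 0.1, -1.0),))


def test_diatomic_optimizes_to_reference_length():
    geom = Geometry(("O", "O"), np.array([[0.0, 0.0, 0.0], [2.1, 0.0, 0.0]]))
    backend = SurrogateBackend(SurrogateParams(bonds=((0, 1, 150.0, 1.21),)))
    res = backend.optimize(geom)
    assert res.converged
    length = np.linalg.norm(res.geometry.coords[1] - res.geometry.coords[0])
    assert length == pytest.approx(1.21, abs=1e-6)


def test_optimize_from_minimum_is_stationary(butane_like, torsion_toy_backend):
    geom, spec = butane_like
    at_min = set_dihedral(geom, spec, 60.0)
    res = torsion_toy_backend.optimize(at_min)
    assert res.converged
    assert np.allclose(res.geometry.coords, at_min.coords, atol=1e-5)


def test_optimizer_always_descends(furanose, furanose_backend, rng):
    """Random perturbed starts: final energy never exceeds the initial one."""
    geom, _ = furanose
    for _ in range(100):
        start = geom.with_coords(geom.coords + rng.normal(0, 0.06, geom.coords.shape))
        try:
            e0 = furanose_backend.evaluate(start)
        except SingularPairError:
            continue
        res = furanose_backend.optimize(start, max_iterations=120)
        assert res.energy <= e0 + 1e-9


def test_frozen_torsion_held_during_optimization(butane_like, torsion_toy_backend):
    """Constrained relaxation keeps the torsion frozen at 40.000000° while
    relaxing everything else, matching an unconstrained-oracle energy bound."""
    geom, spec = butane_like
    start = set_dihedral(geom, spec, 40.0)
    stretched = start.with_coords(start.coords * 1.05)  # perturb bond lengths
    stretched = set_dihedral(stretched, spec, 40.0)
    res = torsion_toy_backend.optimize(stretched, constraints=[(spec, 40.0)])
    assert res.converged
    assert measure_dihedral(res.geometry, spec) == pytest.approx(40.0, abs=1e-6)
    # bare torsion term value at 40°: V/2(1+cos(120)) = 0.5; bonds relaxed to 0
    assert res.energy == pytest.approx(0.5, abs=1e-5)
    # oracle: unconstrained optimization must reach a strictly lower basin (60°)
    free = torsion_toy_backend.optimize(stretched)
    assert free.energy < res.energy


def test_frequencies_positive_at_minimum(furanose, furanose_backend):
    geom, _ = furanose
    res = furanose_backend.optimize(geom)
    freqs = furanose_backend.frequencies(res.geometry)
    assert len(freqs) == 3 * geom.n_atoms - 6
    assert np.all(freqs > 0)


# ---- QC output parsing ----------------------------------------------------

MOPAC_FIXTURE = """\
 SOME PREAMBLE
          FINAL HEAT OF FORMATION = -123.45678 KCAL/MOL
          FREQ.   101.100000   250.000000
"""

GAUSSIAN_FIXTURE = """\
 SCF Done:  E(RB3LYP) =  -0.200000
 Frequencies --   120.000000  340.000000
 Sum of electronic and thermal Free Energies=  -0.100000
"""


def test_mopac_energy_echo():
    rec = parse_qc_output(MOPAC_FIXTURE, "mopac_out")
    assert rec.electronic_energy == -123.45678
    assert rec.frequencies == (101.1, 250.0)
    assert rec.is_minimum


def test_gaussian_free_energy_unit_conversion():
    """−0.1 hartree → −62.75095 kcal/mol with the fixed conversion factor."""
    rec = parse_qc_output(GAUSSIAN_FIXTURE, "gaussian_log")
    assert rec.gibbs == pytest.approx(-62.75095, abs=1e-9)
    assert rec.electronic_energy == pytest.approx(-125.5019, abs=1e-4)


def test_imaginary_mode_flags_not_a_minimum():
    text = MOPAC_FIXTURE.replace("101.100000", "-101.100000")
    rec = parse_qc_output(text, "mopac_out")
    assert rec.imaginary_count == 1
    assert not rec.is_minimum


def test_missing_energy_marker_raises():
    with pytest.raises(ParseError):
        parse_qc_output("no markers here\n", "mopac_out")
    with pytest.raises(ParseError):
        parse_qc_output("nothing\n", "gaussian_log")


def test_parser_totality_over_corpus(rng):
    """Every corpus fixture parses to a record or a typed ParseError."""
    from anomerthermo.synthetic import make_fixture_qc_output, random_energy_record

    corpus = []
    for dialect in ("mopac_out", "gaussian_log"):
        for _ in range(10):
            corpus.append((make_fixture_qc_output(random_energy_record(rng, dialect), dialect), dialect))
    corpus.append(("garbage\n", "mopac_out"))
    corpus.append(("", "gaussian_log"))
    for text, dialect in corpus:
        try:
            rec = parse_qc_output(text, dialect)
            assert isinstance(rec, EnergyRecord)
            assert rec.electronic_energy is not None
        except ParseError:
            pass  # typed failure is acceptable totality


# ---- QC input decks -------------------------------------------------------

@pytest.mark.parametrize("dialect", ["mop", "gjf"])
def test_deck_geometry_round_trip(dialect, furanose):
    geom, _ = furanose
    deck = write_qc_input(geom, dialect)
    back = extract_geometry_from_input(deck, dialect)
    assert back.elements == geom.elements
    assert np.allclose(back.coords, geom.coords, atol=1e-6)


@pytest.mark.parametrize("dialect", ["mop", "gjf"])
def test_deck_carries_anion_charge(dialect):
    """The dihydrogen-phosphate stand-in writes its −1 charge into the deck."""
    geom, _ = toy_molecule("toy-phosphate")
    deck = write_qc_input(geom, dialect)
    assert extract_geometry_from_input(deck, dialect).charge == -1


def test_empty_geometry_rejected_at_write():
    with pytest.raises(ValueError):
        write_qc_input(Geometry((), np.zeros((0, 3))), "mop")
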