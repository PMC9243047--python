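"""Synthetic-data generators: planted structure must be recoverable."""

import numpy as np
import pytest

from anomerthermo.backends import parse_qc_output
from anomerthermo.boltzmann import boltzmann_weights
from anomerthermo.chem_core import bond_graph, read_xyz, write_xyz
from anomerthermo.errors import ConstructionError
from anomerthermo.synthetic import (
    TOY_KINDS,
    PlantedEnsembleSpec,
    PlantedRegistrySpec,
    make_fixture_qc_output,
    random_energy_record,
    synth_ensemble,
    synth_registry,
    toy_molecule,
    toy_nucleoside,
)


def test_planted_weight_is_exact():
    for w_star in (0.2, 0.51, 0.95):
        e = synth_ensemble(PlantedEnsembleSpec(n=40, w_star=w_star, seed=9))
        assert boltzmann_weights(e)[0] == pytest.approx(w_star, abs=1e-9)
        assert e[0] == 0.0
        assert np.all(e[1:] > 0)


def test_two_level_equal_levels_uniform_weights():
    e = synth_ensemble(PlantedEnsembleSpec(n=8, distribution="two-level", scale=0.0))
    assert np.allclose(boltzmann_weights(e), 1.0 / 8.0, atol=1e-12)


def test_ensemble_deterministic_under_seed():
    spec = PlantedEnsembleSpec(n=30, w_star=0.6, seed=123)
    assert np.array_equal(synth_ensemble(spec), synth_ensemble(spec))


def test_infeasible_w_star_raises():
    with pytest.raises(ConstructionError):
        synth_ensemble(PlantedEnsembleSpec(n=1, w_star=0.5))
    # w* below the uniform weight needs a negative shift that would push
    # competitors below the planted minimum
    with pytest.raises(ConstructionError):
        synth_ensemble(
            PlantedEnsembleSpec(n=100, distribution="two-level", scale=0.0, w_star=0.001)
        )


def test_unknown_toy_kind_raises():
    with pytest.raises(KeyError):
        toy_molecule("caffeine")


@pytest.mark.parametrize("kind", TOY_KINDS)
def test_catalogue_round_trips_and_is_bonded(kind):
    geom, declared = toy_molecule(kind)
    back = read_xyz(write_xyz(geom))
    assert back.elements == geom.elements
    assert np.allclose(back.coords, geom.coords, atol=1e-6)
    graph = bond_graph(geom)
    for spec in declared:
        spec.validate(geom, graph)  # consecutive atoms bonded


def test_toy_nucleoside_is_single_molecule():
    geom, glyco = toy_nucleoside("beta")
    graph = bond_graph(geom)
    assert len(graph.components_without(glyco.j, glyco.k)) == 2


def test_registry_byte_identical_for_fixed_seed():
    spec = PlantedRegistrySpec(seed=77)
    csv1 = synth_registry(spec)[0].to_csv()
    csv2 = synth_registry(spec)[0].to_csv()
    assert csv1 == csv2


def test_registry_zero_offset_zero_ddg():
    from anomerthermo.ledger import compare_pathway

    reg, _ = synth_registry(PlantedRegistrySpec(anomer_offset=0.0))
    for pw in ("a+b", "c+d"):
        assert compare_pathway(reg, "ribose", "A", "vacuum", pw).ddg == pytest.approx(
            0.0, abs=1e-9
        )


def test_registry_noise_breaks_exactness_but_not_structure():
    from anomerthermo.ledger import SpeciesKey, anomer_delta

    reg, _ = synth_registry(PlantedRegistrySpec(anomer_offset=-2.5, noise_scale=0.3, seed=5))
    b = reg.get(SpeciesKey("sugar", sugar="ribose", anomer="beta", phase="vacuum"))
    a = reg.get(SpeciesKey("sugar", sugar="ribose", anomer="alpha", phase="vacuum"))
    value = anomer_delta(b, a, "G").value
    assert value == pytest.approx(-2.5, abs=2.0)  # noisy but centred
    assert value != -2.5


def test_mopac_fixture_round_trip_exact(rng):
    for _ in range(50):
        rec = random_energy_record(rng, "mopac_out")
        back = parse_qc_output(make_fixture_qc_output(rec, "mopac_out"), "mopac_out")
        assert back.electronic_energy == rec.electronic_energy
        assert back.frequencies == rec.frequencies


def test_gaussian_fixture_round_trip_within_conversion_precision(rng):
    for _ in range(20):
        rec = random_energy_record(rng, "gaussian_log")
        back = parse_qc_output(make_fixture_qc_output(rec, "gaussian_log"), "gaussian_log")
        assert back.electronic_energy == pytest.approx(rec.electronic_energy, abs=1e-6)
        assert back.gibbs == pytest.approx(rec.gibbs, abs=1e-6)
        assert back.frequencies == rec.frequencies


def test_not_a_minimum_fixture_carries_negative_wavenumber(rng):
    rec = random_energy_record(rng, "mopac_out", not_a_minimum=True)
    text = make_fixture_qc_output(rec, "mopac_out")
    back = parse_qc_output(text, "mopac_out")
    assert back.imaginary_count == 1
    assert not back.is_minimum
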