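"""Species registry, anomer deltas, pathway bookkeeping, exchange, reports."""

import numpy as np
import pytest

from anomerthermo.errors import PairingError, RegistryLookupError, StoichiometryError
from anomerthermo.ledger import (
    ANOMERS,
    PATHWAYS,
    PHASES,
    ReactionStep,
    SpeciesKey,
    SpeciesRegistry,
    SpeciesThermoRecord,
    all_reaction_steps,
    anomer_delta,
    build_pathway_steps,
    build_report,
    compare_pathway,
    ddg_compare,
    enumerate_study,
    pathway_total,
    round_half_away,
    species_formula,
    step_delta_g,
    sugar_exchange_delta,
)
from anomerthermo.synthetic import PlantedRegistrySpec, synth_registry


def _record(role="sugar", sugar="ribose", base=None, anomer="beta", phase="vacuum",
            pathway=None, g=-100.0):
    key = SpeciesKey(role, sugar=sugar, base=base, anomer=anomer, phase=phase, pathway=pathway)
    return SpeciesThermoRecord(key=key, energy=g + 10, energy_zpe=g + 5, gibbs=g)


def test_anomer_delta_example_and_antisymmetry():
    beta = _record(anomer="beta", g=-100.0)
    alpha = _record(anomer="alpha", g=-99.0)
    d = anomer_delta(beta, alpha, "G")
    assert d.value == pytest.approx(-1.0)
    with pytest.raises(PairingError):
        anomer_delta(alpha, beta, "G")  # arguments must be (beta, alpha)
    # swapping the underlying values negates the result exactly
    beta2 = _record(anomer="beta", g=-99.0)
    alpha2 = _record(anomer="alpha", g=-100.0)
    assert anomer_delta(beta2, alpha2, "G").value == -d.value


def test_anomer_delta_mismatched_phase_raises():
    beta = _record(anomer="beta", phase="vacuum")
    alpha = _record(anomer="alpha", phase="aqueous")
    with pytest.raises(PairingError):
        anomer_delta(beta, alpha, "G")


def test_species_formulas_compose_with_water_loss():
    ns, q = species_formula(SpeciesKey("nucleoside", sugar="ribose", base="A", anomer="beta"))
    assert ns == "C10H13N5O4"  # adenosine
    assert q == 0
    nt, q = species_formula(
        SpeciesKey("nucleotide", sugar="deoxyribose", base="T", anomer="beta", pathway="a+b")
    )
    assert nt == "C10H14N2O8P"  # dTMP mono-anion composition
    assert q == -1


def test_step_delta_g_hand_sum():
    reg = SpeciesRegistry()
    for role, sugar, base, anomer, g in [
        ("sugar", "ribose", None, "beta", -10.0),
        ("base", None, "A", None, -5.0),
        ("nucleoside", "ribose", "A", "beta", -12.0),
        ("water", None, None, None, -4.0),
    ]:
        key = SpeciesKey(role, sugar=sugar, base=base, anomer=anomer, phase="vacuum")
        reg.add(SpeciesThermoRecord(key=key, energy=g, energy_zpe=g, gibbs=g))
    step = build_pathway_steps("ribose", "A", "beta", "vacuum", "a+b")[0]
    assert step_delta_g(step, reg) == pytest.approx((-12.0 - 4.0) - (-10.0 - 5.0))


def test_identity_reaction_is_zero():
    reg, _ = synth_registry(PlantedRegistrySpec())
    k = SpeciesKey("water", phase="vacuum")
    step = ReactionStep((k,), (k,), label="identity")
    assert step_delta_g(step, reg) == 0.0


def test_omitted_water_raises_stoichiometry_error():
    k_s = SpeciesKey("sugar", sugar="ribose", anomer="beta")
    k_b = SpeciesKey("base", base="A")
    k_n = SpeciesKey("nucleoside", sugar="ribose", base="A", anomer="beta")
    bad = ReactionStep((k_s, k_b), (k_n,), label="a-without-water")
    with pytest.raises(StoichiometryError):
        bad.check_balance()


def test_missing_species_raises_lookup_error():
    reg = SpeciesRegistry()
    step = build_pathway_steps("ribose", "A", "beta", "vacuum", "a+b")[0]
    with pytest.raises(RegistryLookupError):
        step_delta_g(step, reg)


def test_pathway_consistency_error_on_mixed_steps():
    reg, _ = synth_registry(PlantedRegistrySpec())
    a_step = build_pathway_steps("ribose", "A", "beta", "vacuum", "a+b")[0]
    d_step = build_pathway_steps("ribose", "A", "beta", "vacuum", "c+d")[1]
    with pytest.raises(PairingError):
        pathway_total((a_step, d_step), reg)


def test_two_zero_steps_total_zero():
    reg = SpeciesRegistry()
    for pw in PATHWAYS:
        for key in {
            k
            for step in build_pathway_steps("ribose", "A", "beta", "vacuum", pw)
            for k in step.reactants + step.products
        }:
            reg.add(SpeciesThermoRecord(key=key, energy=0.0, energy_zpe=0.0, gibbs=0.0))
    steps = build_pathway_steps("ribose", "A", "beta", "vacuum", "a+b")
    assert pathway_total(steps, reg).total == 0.0


def test_ddg_pairing_checks():
    reg, _ = synth_registry(PlantedRegistrySpec())
    beta = pathway_total(build_pathway_steps("ribose", "A", "beta", "vacuum", "a+b"), reg)
    alpha_other = pathway_total(build_pathway_steps("ribose", "A", "alpha", "vacuum", "c+d"), reg)
    with pytest.raises(PairingError):
        ddg_compare(beta, alpha_other)


def test_hess_law_with_shared_nucleotide_record():
    """With identical nucleotide records for both provenances, ΔG(a+b) = ΔG(c+d)."""
    reg, _ = synth_registry(PlantedRegistrySpec(seed=4))
    shared = reg.get(
        SpeciesKey("nucleotide", sugar="ribose", base="A", anomer="beta",
                   phase="vacuum", pathway="a+b")
    )
    for pw in PATHWAYS:
        key = SpeciesKey("nucleotide", sugar="ribose", base="A", anomer="beta",
                         phase="vacuum", pathway=pw)
        reg.add(SpeciesThermoRecord(key=key, energy=shared.energy,
                                    energy_zpe=shared.energy_zpe, gibbs=shared.gibbs))
    tot = {
        pw: pathway_total(build_pathway_steps("ribose", "A", "beta", "vacuum", pw), reg).total
        for pw in PATHWAYS
    }
    assert tot["a+b"] == pytest.approx(tot["c+d"], abs=1e-9)


def test_planted_parameter_recovery_exact():
    """δ, pathway ΔΔG effects and the exchange advantage recover to 1e-9."""
    spec = PlantedRegistrySpec(
        anomer_offset=-2.5,
        pathway_effects={"a+b": -9.1, "c+d": 2.9},
        exchange_advantage=-10.0,
        seed=17,
    )
    reg, truth = synth_registry(spec)
    # anomer deltas on every non-nucleotide anomeric species
    for role in ("sugar", "sugar_5p_monophosphate", "nucleoside"):
        for sugar in ("ribose", "deoxyribose"):
            for phase in PHASES:
                bases = ("A", "C") if role == "nucleoside" else (None,)
                for base in bases:
                    b = reg.get(SpeciesKey(role, sugar=sugar, base=base, anomer="beta", phase=phase))
                    a = reg.get(SpeciesKey(role, sugar=sugar, base=base, anomer="alpha", phase=phase))
                    for kind in ("E", "E+ZPE", "G"):
                        assert anomer_delta(b, a, kind).value == pytest.approx(-2.5, abs=1e-9)
    # pathway ΔΔG per provenance
    for pw, expect in truth["expected"]["ddg"].items():
        for sugar, base, phase in (("ribose", "U", "vacuum"), ("deoxyribose", "G", "aqueous")):
            cmp_ = compare_pathway(reg, sugar, base, phase, pw)
            assert cmp_.ddg == pytest.approx(expect, abs=1e-9)
    # exchange advantage, both anomers and roles
    for anomer in ANOMERS:
        assert sugar_exchange_delta(reg, anomer) == pytest.approx(-10.0, abs=1e-9)
        for pw in PATHWAYS:
            assert sugar_exchange_delta(
                reg, anomer, role="nucleotide", pathway=pw
            ) == pytest.approx(-10.0, abs=1e-9)


def test_exchange_trivials():
    reg = SpeciesRegistry()
    for sugar in ("ribose", "deoxyribose"):
        for base in ("T", "U"):
            key = SpeciesKey("nucleoside", sugar=sugar, base=base, anomer="beta", phase="vacuum")
            reg.add(SpeciesThermoRecord(key=key, energy=-50.0, energy_zpe=-50.0, gibbs=-50.0))
    assert sugar_exchange_delta(reg, "beta") == 0.0
    with pytest.raises(RegistryLookupError):
        sugar_exchange_delta(reg, "alpha")


def test_enumeration_counts():
    counts = enumerate_study()
    assert counts == {
        "nucleosides": 20,
        "guess_geometries": 40,
        "final_structures": 80,
        "reactions": 80,
    }


def test_all_80_reactions_balance_with_one_water_each():
    steps = all_reaction_steps()
    assert len(steps) == 80
    water = SpeciesKey("water", phase="vacuum")
    for _pw, _s, _b, _a, phase, (first, second) in steps:
        first.check_balance()
        second.check_balance()
        for step in (first, second):
            waters = [k for k in step.products if k.role == "water"]
            assert len(waters) == 1  # exactly one condensation water per step
        # net charge −1 carried from phosphate to nucleotide
        nt = [k for k in second.products if k.role == "nucleotide"][0]
        assert species_formula(nt)[1] == -1


def test_round_half_away_from_zero():
    assert round_half_away(-12.76) == -12.8
    assert round_half_away(-12.75) == -12.8
    assert round_half_away(2.25) == 2.3
    assert round_half_away(0.04) == 0.0


def test_registry_csv_round_trip():
    reg, _ = synth_registry(PlantedRegistrySpec(seed=3))
    back = SpeciesRegistry.from_csv(reg.to_csv())
    assert len(back) == len(reg)
    for rec in reg:
        twin = back.get(rec.key)
        assert twin.gibbs == pytest.approx(rec.gibbs, abs=1e-9)
        assert twin.formula == rec.formula
        assert twin.charge == rec.charge


def test_report_on_empty_registry_headers_only():
    report = build_report(SpeciesRegistry())
    assert report.tables["pathways"].empty
    assert list(report.tables["anomer_deltas"].columns)[:3] == ["role", "sugar", "base"]
    assert len(report.missing) > 0


def test_report_cells_recompute_and_round(tmp_path):
    reg, _ = synth_registry(PlantedRegistrySpec(anomer_offset=-2.5, seed=8))
    report = build_report(reg)
    assert not report.missing
    df = report.tables["pathways"]
    for _, row in df.sample(6, random_state=0).iterrows():
        cmp_ = compare_pathway(
            reg,
            "deoxyribose" if row["nucleotide"].startswith("d") else "ribose",
            row["nucleotide"].lstrip("d").replace("MP", ""),
            row["phase"],
            row["pathway"],
        )
        assert row["ddg"] == pytest.approx(cmp_.ddg, abs=1e-12)
        assert row["printed_ddg"] == round_half_away(cmp_.ddg, 1)
    report.write(tmp_path / "report")
    assert (tmp_path / "report" / "pathways.csv").exists()
    assert (tmp_path / "report" / "pathways.json").exists()
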