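"""The Gibbs-energy ledger: anomer differences, pathway ΔΔG, sugar exchange.

A synthetic species registry is generated with planted ground truth — a
β-vs-α offset δ = −2.5 kcal/mol on every β species, pathway effects of
−9.1 (classic a+b) and +2.9 (alternative c+d) kcal/mol, and a −10 kcal/mol
canonical advantage in the sugar-exchange reaction — and each ledger
operation recovers its planted value. Negative ΔΔG favors the β anomer;
negative exchange values favor thymine-on-deoxyribose + uracil-on-ribose.
"""

from anomerthermo.ledger import (
    SpeciesKey,
    anomer_delta,
    compare_pathway,
    enumerate_study,
    sugar_exchange_delta,
)
from anomerthermo.synthetic import PlantedRegistrySpec, synth_registry

spec = PlantedRegistrySpec(
    anomer_offset=-2.5,
    pathway_effects={"a+b": -9.1, "c+d": 2.9},
    exchange_advantage=-10.0,
    seed=0,
)
registry, truth = synth_registry(spec)
print(f"registry: {len(registry)} species records "
      "(sugars, bases, phosphate, water, nucleosides, 5'-monophosphates, nucleotides)")

beta = registry.get(SpeciesKey("sugar", sugar="ribose", anomer="beta", phase="vacuum"))
alpha = registry.get(SpeciesKey("sugar", sugar="ribose", anomer="alpha", phase="vacuum"))
d = anomer_delta(beta, alpha, "G")
print(f"\nΔG°_βα(ribose, vacuum) = {d.value:+.2f} kcal/mol  "
      "(negative ⇒ β more stable; recovers planted δ)")

for pathway in ("a+b", "c+d"):
    cmp_ = compare_pathway(registry, "ribose", "U", "vacuum", pathway)
    print(f"pathway {pathway}: ΔG_β = {cmp_.beta.total:+7.2f}, ΔG_α = {cmp_.alpha.total:+7.2f}, "
          f"ΔΔG = {cmp_.ddg:+6.2f} kcal/mol")

for anomer in ("beta", "alpha"):
    x = sugar_exchange_delta(registry, anomer, role="nucleotide", pathway="a+b")
    print(f"sugar exchange (rT + dU → dT + rU), {anomer} nucleotides, a+b: "
          f"ΔG = {x:+.2f} kcal/mol")

print("\nstudy space:", enumerate_study())
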