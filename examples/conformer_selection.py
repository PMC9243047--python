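"""Random conformers → local optimization → unique minima → Boltzmann selection.

Mirrors the conformer-screening stage: n random torsion conformers of the
toy furanose are optimized with the surrogate potential, duplicates that
converged to the same minimum are merged (n unique), and the smallest set
of conformers holding at least 50% of the partition function Z is kept
(n′). The discarded tail contributes only minor Boltzmann weight.
"""

from anomerthermo.backends import SurrogateBackend, SurrogateParams
from anomerthermo.boltzmann import select_ensemble
from anomerthermo.pipeline import generate_and_optimize
from anomerthermo.sampling import SamplingPlan, deduplicate_minima
from anomerthermo.synthetic import toy_molecule

geom, dihedrals = toy_molecule("toy-furanose")
backend = SurrogateBackend(SurrogateParams.from_geometry(geom))

plan = SamplingPlan(tuple(dihedrals), n_samples=25, seed=42)
optimized = generate_and_optimize(geom, plan, backend)
unique = deduplicate_minima(optimized)
selection = select_ensemble([c.energy for c in unique], temperature=298.15, threshold=0.5)

print(f"sampled {plan.n_samples} conformers over {len(dihedrals)} torsions (seed {plan.seed})")
print(f"unique optimized minima: n = {len(unique)}")
print(f"kept for refinement:     n′ = {selection.n_selected}, "
      f"contributing {selection.percent_of_z:.1f}% of Z")
print("\nlowest minima (kcal/mol above global):")
e0 = unique[0].energy
for c in unique[: selection.n_selected + 2]:
    kept = "kept" if c.sample_index in {unique[i].sample_index for i in range(len(unique))
                                        if i in selection.selected_indices} else "discarded"
    print(f"  sample {c.sample_index:3d}  ΔE = {c.energy - e0:6.3f}  ({kept})")
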