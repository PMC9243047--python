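"""Measure and drive torsion angles on the toy furanose, with XYZ I/O.

The toy furanose is a ribofuranose-like 5-ring carrying the four hydroxyl
torsions plus the exocyclic O-C5'-C4'-C3' ("beta") torsion that the
conformer sampler randomizes.
"""

from anomerthermo import measure_dihedral, molecular_formula, read_xyz, set_dihedral, write_xyz
from anomerthermo.synthetic import toy_molecule

geom, dihedrals = toy_molecule("toy-furanose")
print(f"molecule: {geom.label}, formula {molecular_formula(geom)} "
      f"({geom.n_atoms} atoms, {len(dihedrals)} rotatable torsions)")

for spec in dihedrals:
    print(f"  {spec.label:<24s} atoms {spec.indices}  "
          f"θ = {measure_dihedral(geom, spec):8.2f}°")

# drive the 5'-hydroxyl torsion to 60° and confirm
spec = dihedrals[0]
driven = set_dihedral(geom, spec, 60.0)
print(f"\nafter driving {spec.label} to 60°: θ = {measure_dihedral(driven, spec):.6f}°")
print("formula unchanged:", molecular_formula(driven))

# round-trip through the XYZ text format (6-decimal printing)
back = read_xyz(write_xyz(driven))
print("XYZ round trip preserves geometry:", back.isclose(driven, tol=1e-6))
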