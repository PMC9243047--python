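"""Relaxed (soft) scan of the glycosidic torsion of the toy nucleoside.

The toy N-nucleoside is assembled by condensing the toy furanose with the
toy base: the anomeric hydroxyl and the base N-H leave as water, the C1'-N9
bond starts at 1.52 Å and the H-C1'-N9-Cx torsion at −161.9°. The torsion
is then stepped 6 × 60°, everything else relaxing at each point, and the
lowest point is refined to a frequency-vetted minimum.
"""

from anomerthermo.backends import SurrogateBackend, SurrogateParams
from anomerthermo.scan import GLYCOSIDIC_TORSION_INIT, ScanProtocol, refine_minimum, soft_scan
from anomerthermo.synthetic import toy_nucleoside

geom, glyco = toy_nucleoside("beta")
backend = SurrogateBackend(SurrogateParams.from_geometry(geom))

scan = soft_scan(geom, ScanProtocol(glyco, start_deg=GLYCOSIDIC_TORSION_INIT), backend)
print("relaxed scan profile (glycosidic torsion, β anomer):")
for angle, energy, ok in zip(scan.angles, scan.energies, scan.converged):
    marker = "  ← argmin" if angle == scan.angles[scan.argmin_index] else ""
    print(f"  θ = {angle:8.1f}°   E = {energy:8.3f} kcal/mol   converged={ok}{marker}")

refined = refine_minimum(scan, backend)
print(f"\nrefined (unconstrained) minimum: E = {refined.energy:.3f} kcal/mol")
print(f"frequency vetting: {refined.imaginary_count} imaginary modes "
      f"→ {'a true minimum' if refined.is_minimum else 'NOT a minimum'}")
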