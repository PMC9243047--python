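"""RRHO thermochemistry: ZPE, entropy components, G° = H − T·S, and kBT.

The same statistical-mechanics bookkeeping a quantum-chemistry package
prints after a frequency job: ideal-gas translation (Sackur–Tetrode),
classical rigid rotor, harmonic vibrations.
"""

import numpy as np

from anomerthermo import thermal_energy_kT
from anomerthermo.chem_core import Geometry
from anomerthermo.thermochem import ThermoConditions, rrho_thermo, zpe

water = Geometry(
    ("O", "H", "H"),
    np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
    label="water (experimental-like geometry)",
)
freqs = [1595.0, 3657.0, 3756.0]  # cm⁻¹, the three water fundamentals

tb = rrho_thermo(water, freqs, ThermoConditions(temperature=298.15, pressure_atm=1.0))
print(f"ZPE                 = {tb.zpe:8.3f} kcal/mol  (½·Σ h·c·ν̃)")
print(f"S translational     = {tb.entropy_translational:8.3f} cal/(mol·K)")
print(f"S rotational        = {tb.entropy_rotational:8.3f} cal/(mol·K)")
print(f"S vibrational       = {tb.entropy_vibrational:8.3f} cal/(mol·K)")
print(f"H (incl. E_el, pV)  = {tb.enthalpy:8.3f} kcal/mol")
print(f"G° = H − T·S        = {tb.gibbs:8.3f} kcal/mol")
print(f"identity check      : {abs(tb.gibbs - (tb.enthalpy - 298.15*tb.entropy/1000)):.1e}")

print(f"\nzpe([1000 cm⁻¹])    = {zpe([1000.0]):.4f} kcal/mol")
print(f"kB·T at 298.15 K    = {thermal_energy_kT(298.15):.4f} kcal/mol")
print(f"kB·T at 343 K       = {thermal_energy_kT(343.0):.4f} kcal/mol "
      "(≈0.7; the warm-Archean comparison point)")
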