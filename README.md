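# anomerthermo

Conformer-ensemble thermodynamics of nucleoside/nucleotide anomers: a
self-contained Python pipeline for asking whether the β-configuration at
the sugar's anomeric carbon (C1′) — the form dominating present-day DNA
and RNA — holds a thermodynamic edge over the α-configuration when a
nucleotide is assembled from its parts (sugar + base + dihydrogen
phosphate), and whether thymine-on-deoxyribose / uracil-on-ribose is
favored over the swapped pairing.

The package is aimed at computational/prebiotic chemists who want the
*analysis machinery* of such a study — conformer screening, Boltzmann
bookkeeping, torsion scans, and reaction Gibbs-energy ledgers — as tested,
reusable code. The quantum-chemistry energies themselves are out of scope:
a surrogate molecular-mechanics backend and a synthetic-data generator
with planted ground truth stand in for external programs, and adapters
parse MOPAC-style/Gaussian-style output text when real energies are
available.

## The model

For a β/α pair of species the anomer difference is

    ΔX_βα ≡ X_β − X_α,   X ∈ {E, E+ZPE, G°}

(negative ⇒ β more stable). A nucleotide is assembled along one of two
two-step condensation pathways, each step releasing one water:

    classic (a+b):      sugar + base → nucleoside + H₂O
                        nucleoside + H₂PO₄⁻ → nucleotide⁻ + H₂O
    alternative (c+d):  sugar + H₂PO₄⁻ → 5′-sugar-monophosphate⁻ + H₂O
                        5′-SMP⁻ + base → nucleotide⁻ + H₂O

with ΔG°_reaction = Σ G°(products) − Σ G°(reactants) per step,
ΔG°_(i+j) = ΔG°_i + ΔG°_j, and the pathway comparison

    ΔΔG°_(i+j) = (ΔG°_(i+j))_β − (ΔG°_(i+j))_α ,  i = a,c; j = b,d.

Because each condensation re-optimizes the product geometry, the two
pathways end in *different* local minima; nucleotide records therefore
carry their pathway provenance, and Hess-law consistency is enforced only
within one provenance. Conformer screening keeps, per ensemble, the
minimal set of n′ conformers that together contribute at least 50% of the
partition function Z (Boltzmann weights at 298.15 K). Thermochemistry is
rigid-rotor/harmonic-oscillator: ZPE = ½Σhcν̃, Sackur–Tetrode translation,
classical rigid rotor, harmonic vibrations, G° = H − T·S. Sugar-exchange
reactions (rT + dU → dT + rU, per anomer) gauge the canonical-pairing
advantage.

## Worked example

```sh
python examples/conformer_selection.py
```

prints (seed 42, 25 random conformers of the toy furanose):

```
sampled 25 conformers over 5 torsions (seed 42)
unique optimized minima: n = 23
kept for refinement:     n′ = 4, contributing 52.6% of Z
```

25 random torsion conformers were optimized with the surrogate potential;
23 distinct minima survived deduplication, and the 4 lowest together hold
just over half the Boltzmann population, so only they would advance to the
expensive refinement stage. Similarly,

```sh
python examples/reaction_ledger.py
```

builds a synthetic species registry with a planted β-offset of
−2.5 kcal/mol and pathway effects −9.1/+2.9 kcal/mol and prints

```
ΔG°_βα(ribose, vacuum) = -2.50 kcal/mol  (negative ⇒ β more stable; recovers planted δ)
pathway a+b: ΔG_β =  -38.46, ΔG_α =  -29.36, ΔΔG =  -9.10 kcal/mol
pathway c+d: ΔG_β =  -27.30, ΔG_α =  -30.20, ΔΔG =  +2.90 kcal/mol
```

— every planted parameter is recovered exactly by the corresponding ledger
operation, which is how the bookkeeping is validated end to end. The other
examples cover torsion geometry (`torsions_and_geometry.py`), RRHO
thermochemistry (`thermochemistry.py`), the relaxed glycosidic scan
(`glycosidic_scan.py`) and the full orchestrated run
(`full_pipeline.py`). A thin CLI wraps the same operations
(`anomerthermo --help`).

## Layout

```
src/anomerthermo/
  chem_core.py    geometries, bond perception, torsions, XYZ/Z-matrix I/O
  sampling.py     rotatable-dihedral selection, random conformers, dedup
  backends.py     backend contract, surrogate potential, QC deck/log adapters
  thermochem.py   RRHO thermochemistry (ZPE, S, H, G°), kB·T helper
  boltzmann.py    Boltzmann weights, ≥50%-of-Z minimal selection
  scan.py         relaxed torsion scans + refinement and frequency vetting
  ledger.py       species registry, pathways, ΔΔG, exchange, reports
  datasets.py     reference condensation step energies (the 80-reaction grid)
  synthetic.py    toy molecules, planted ensembles/registries, QC fixtures
  pipeline.py     end-to-end orchestration with reproducible manifests
  cli.py          thin click CLI over the above
```
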