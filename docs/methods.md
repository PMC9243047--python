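# Methods

## Scope and model

The package implements the analysis layer of a conformational-ensemble
thermodynamics study of nucleoside/nucleotide anomers: randomized torsion
sampling of furanose sugars, partition-function-based conformer selection,
rigid-rotor/harmonic-oscillator (RRHO) thermochemistry, relaxed
(glycosidic and 5′-phosphate) torsion scans, and a reaction Gibbs-energy
ledger over two condensation pathways and sugar-exchange reactions.
Electronic-structure methods (semiempirical Hamiltonians, DFT functionals,
continuum solvation physics) are deliberately not implemented: energies
enter through a pluggable backend contract, served either by the built-in
surrogate potential or by parsing quantum-chemistry output text. The
"aqueous" phase is a pass-through tag selecting which records or keyword
sets a backend uses; no solvation model is simulated.

## Geometry and torsions

Geometries are ordered lists of (element, Cartesian Å) with integer net
charge and optional per-atom labels (C1′, O5′, …). Bonds are perceived
when an interatomic distance is at most 1.15 × the sum of covalent radii;
the factor is fixed and documented rather than tunable per call, so the
bond graph is deterministic for a geometry. Torsions follow the IUPAC sign
convention with range (−180°, +180°]. Driving a torsion rotates the
component containing the third atom rigidly about the central bond; a
central bond inside a ring (removal does not split the graph in two) is a
typed error. Atom indexing is 0-based throughout the API; the Z-matrix
reader keeps its native 1-based references internally. XYZ output prints
6 decimals, and read(write(g)) round-trips exactly at that precision.

## Conformer sampling and deduplication

The rotatable set under the `hydroxyl_plus_beta` rule is every
H-O-X-Y torsion whose oxygen carries exactly one hydrogen and one heavy
neighbor, plus the exocyclic O-C5′-C4′-C3′ ("beta") torsion when those
atom labels exist. The reference carbon Y is chosen deterministically
(carbons first, then heavy atoms, then hydrogens, lowest index), which
lets a molecule like methanol — whose hydroxyl carbon has only hydrogen
neighbors — still expose its single torsion. For the toy ribofuranose
this yields 5 torsions (4 hydroxyl + beta) and for the 2′-deoxy form 4
(3 hydroxyl + beta): the beta torsion is kept in the deoxy plan, reading
the protocol's "only 3 angles of the H-O-C-C type" as a statement about
hydroxyls, not about the total.

Sampling draws each torsion independently and uniformly on [−180°, 180°)
from one seedable generator per plan; the seed is recorded in each
conformer's provenance and identical plans reproduce identical output
bit-for-bit. The exact sampling distribution of the original
torsion-randomizing generators is not documented publicly; independent
uniform sampling is the simplest faithful reading of "randomly varying"
and is declared as this package's choice.

Optimized conformers merge into one minimum iff their energies differ by
≤ 0.1 kcal/mol *and* every wrapped dihedral difference is ≤ 15°
(single-linkage transitive closure; both tolerances configurable, since no
published values exist for this step). Cluster representatives are the
lowest-energy members, ties broken by sample index; output is sorted by
energy.

## Surrogate potential and optimizer

The surrogate is a minimal molecular-mechanics form:

* harmonic pair terms k(r−r₀)² over bonds **and** 1-3 pairs (the latter act
  as angle springs; defaults k = 300 and 60 kcal/mol/Å²),
* one 3-fold cosine per rotatable bond, E = V/2·(1+cos(nθ−γ)) with
  V = 1.5 kcal/mol and the phase chosen so the input geometry is a torsion
  minimum,
* 12-6 terms ε((r₀/r)¹² − 2(r₀/r)⁶) for pairs ≥ 4 bonds apart
  (ε = 0.05 kcal/mol, r₀ = 3.2 Å),
* a hard-core error below 0.1 Å.

`SurrogateParams.from_geometry` auto-parameterizes around any input
structure. Gradients are analytic (pair terms and the standard torsion
derivative formulas); Hessians are central finite differences of the
gradient (step 10⁻⁴ Å), mass-weighted, with the 3/5/6 smallest-magnitude
eigenvalues removed as rigid modes before conversion to wavenumbers.
Negative eigenvalues map to negative wavenumbers ("imaginary modes") and
veto minimum status.

Unconstrained optimization is L-BFGS with analytic gradients, restarted
until the RMS gradient is ≤ 10⁻⁴ kcal/mol/Å (the declared convergence
criterion) or 500 iterations are spent; the reported energy never exceeds
the input energy. Frozen-torsion optimization uses a stiff harmonic
restraint (starting at 2000 kcal/mol/rad², stiffened fivefold per cycle)
followed by exact re-imposition of the target angle via the torsion-driving
primitive; convergence is judged on the gradient component orthogonal to
the frozen-torsion directions. The restraint-plus-projection scheme was
chosen over Lagrange multipliers for testability: the frozen angle is
satisfied to machine precision at every return. Hard-core overlaps hit
during a line search report a huge energy so the search backtracks.

## Thermochemistry

RRHO with CODATA/SI defining constants pinned in one table
(`constants.py`); all conversions flow through it, including the
conventional 627.5095 kcal/mol per hartree for parsed logs and the
thermochemical calorie (4.184 J). Translation uses Sackur–Tetrode at
T, P (defaults 298.15 K, 1 atm); rotation the classical rigid rotor with
symmetry number 1 by default (the studied species are asymmetric;
configurable); vibrations the harmonic oscillator with no frequency
scaling factor. G° = H − T·S holds as an internal identity to 10⁻⁹. The
ideal-gas 1 atm standard state is used for both phase tags; the
solution-phase standard-state correction is deliberately not applied, and
reports inherit that convention. One recorded numerical point: kB·T is
0.59 kcal/mol at 298 K and 0.68 (≈0.7) at 343 K; a literature shorthand
of "≈0.5 kcal/mol at 298 K" is not reproduced by the constants and is not
used anywhere in the code.

## Boltzmann selection

Weights are exp(−(Eᵢ−Emin)/kBT)/Σ (minimum-shifted; Σw = 1 ± 10⁻¹²),
computed from the energies of whichever stage produced the ensemble — raw
minima energies, not degeneracy-corrected ones. Selection sorts by weight
descending (ties: original index ascending, for deterministic reports) and
keeps the shortest prefix reaching the threshold (default 0.5 at
298.15 K, both configurable; the selection temperature is this package's
choice since none is stated for the screening stage). The selected set is
minimal by construction: dropping its weakest member falls below the
threshold.

## Torsion scans

A soft scan freezes one torsion at each grid angle (default 6 steps of
60°, starting at the initial angle; a 0°-anchored grid is available via
configuration) and relaxes everything else. Grid points are visited
sequentially, each started from the previous relaxed structure — chain
continuation, mirroring common relaxed-scan practice. Unconverged points
are flagged and excluded from argmin selection, never silently dropped;
ties at the argmin resolve toward the smaller wrapped angle. The lowest
point is refined by a final unconstrained optimization and vetted by a
frequency calculation; an imaginary mode flags the result rather than
raising. Assembly constants for nucleoside/nucleotide construction:
glycosidic C1′-N bond 1.52 Å, H-C1′-N1/N9-Cx torsion −161.9°, 5′-phosphate
O-C5′-C4′-C3′ torsion 30.9°. In the toy base, C8 (the ring carbon adjacent
to N9) serves as the Cx reference atom of the glycosidic torsion; the
catalogue documents this choice explicitly since the reference carbon for
real purines/pyrimidines is not uniquely fixed by the N1/N9 naming alone.

## Reaction ledger

Species records carry role, sugar, base, anomer, phase and — for
nucleotides — pathway provenance, plus E, E+ZPE and G° and the real
molecular formula/charge (C5H10O5 for ribose, H2PO4⁻, adenosine
C10H13N5O4, …) even where geometries are toys, so stoichiometry checks
are exact chemistry. Every reaction step is balance-checked in elements
and charge before any energy is summed; each condensation must release
exactly one water, and the phosphate's −1 charge is conserved into the
products (the product's protonation state is an assumption recorded here,
not modelled). Pathway totals check that step 1's intermediate feeds
step 2. ΔΔG = total_β − total_α. Printed report tables round to one
decimal, half away from zero — a stated convention, since rounding rules
are rarely published — while unrounded values are always retained in the
JSON outputs. Missing registry cells produce listed gaps and partial
tables, not failures.

The embedded reference dataset (`datasets.py`) carries the published
B3LYP/6-31G(d,p) condensation step energies for all 80 pathway/anomer/
phase combinations together with their printed totals and ΔΔG cells. A
few printed rows are internally inconsistent at the last decimal (the
steps were rounded from unrounded intermediates before printing);
`row_is_self_consistent` exposes the check, and the acceptance suite uses
only self-consistent rows.

## Synthetic data and what it does (not) show

The generator plants ground truth that every downstream stage must
recover exactly in the zero-noise limit:

* **Ensembles** — the lowest conformer's Boltzmann weight is back-solved in
  closed form to equal w* at the spec temperature (shift
  Δ = kBT·ln(S/R), R = (1−w*)/w*); infeasible requests raise.
* **Registries** — species G° values are built compositionally (fragment
  terms plus separable condensation bond terms) so that the anomer offset
  δ (default −2.5 kcal/mol, a magnitude typical of sugar-monophosphate
  anomer gaps), per-pathway ΔΔG effects, and the sugar-exchange advantage
  are each recovered to 10⁻⁹ by exactly one ledger operation without
  interfering with the others: δ rides on every β record, pathway effects
  on β nucleotides of one provenance, and the exchange advantage is split
  over the canonical dT/rU species of *both* anomers (so anomer deltas are
  untouched). E and E+ZPE are rigid offsets from G° (+18.7 and +9.3
  kcal/mol), preserving planted structure across all three energy kinds.
  Optional normal noise (default 0) deliberately breaks exactness.
* **Toy molecules** — a planar-ring furanose stand-in with labelled
  C1′…C5′/O5′ atoms and realistic bond lengths, its 2′-deoxy variant, an
  imidazole-like base, a tetrahedral H₂PO₄⁻-like anion, plus water,
  methanol and hydrogen peroxide. Real furanose pucker, anomeric
  electronics and base aromaticity are *not* represented; passing tests
  demonstrate the correctness of the pipeline's bookkeeping and search
  machinery, not chemical accuracy for real nucleosides.
* **QC fixtures** — synthetic MOPAC-style/Gaussian-style log text (labelled
  as such in every fixture header) that round-trips through the parsers;
  kcal-denominated fields exactly, hartree-denominated fields to the
  conversion precision (~10⁻⁹ kcal/mol).

## Problem sizes

Default configuration mirrors the study protocol (1,000 conformers per
sugar; 6 × 60° scans). The test suite and the acceptance script run the
same code at desk scale — tens of conformers per ensemble, the full
6-point scans, 200-ensemble selection oracles — chosen so the whole suite
completes in a couple of minutes while still exercising every stage; all
counts are parameters of the public API, not separate code paths.

## Known limitations

No ring-pucker (pseudorotation) sampling — ring torsions are never
rotatable; no hindered-rotor or quasi-RRHO corrections; no kinetics,
transition states, pKa handling, or solvent-specific standard-state
corrections; the surrogate potential is not intended to approximate any
real Hamiltonian, only to provide a deterministic, differentiable
landscape with the right structural features (multiple torsional minima,
steric clashes, vettable Hessians).
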