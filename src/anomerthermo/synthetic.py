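"""Synthetic inputs with controlled ground truth.

Everything the pipeline consumes can be generated here: toy molecules with
declared rotatable-torsion sets (stand-ins for the sugars, bases and the
phosphate — real furanose and nucleobase geometries are out of scope, but
registry-level stoichiometry always uses the real molecular formulas),
conformer-energy ensembles with a planted dominant Boltzmann weight,
species-thermochemistry registries with a planted β-vs-α Gibbs offset and
pathway/exchange effects, and quantum-chemistry output text fixtures that
round-trip through the log parsers. All generators are pure functions of
their spec, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .backends import EnergyRecord
from .chem_core import DihedralSpec, Geometry, bond_graph, place_atom, set_dihedral
from .constants import KB_KCAL_PER_MOL_K
from .errors import ConstructionError
from .ledger import (
    ANOMERS,
    BASES,
    PATHWAYS,
    PHASES,
    SUGARS,
    SpeciesKey,
    SpeciesRegistry,
    SpeciesThermoRecord,
)

__all__ = [
    "PlantedEnsembleSpec",
    "PlantedRegistrySpec",
    "synth_ensemble",
    "synth_registry",
    "toy_molecule",
    "toy_nucleoside",
    "make_fixture_qc_output",
    "random_energy_record",
    "TOY_KINDS",
]


# --------------------------------------------------------------------------
# planted conformer ensembles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Energy-ensemble spec; energies in kcal/mol relative to the minimum.

    ``distribution`` ∈ {exponential-gap, normal, two-level} shapes the
    energies above the minimum with characteristic ``scale``. When
    ``w_star`` is set, the gap structure is back-solved so the lowest
    conformer's Boltzmann weight at ``temperature`` equals w* exactly.
    """

    n: int
    distribution: str = "exponential-gap"
    scale: float = 1.0
    w_star: float | None = None
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("ensemble size must be ≥ 1")
        if self.distribution not in ("exponential-gap", "normal", "two-level"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scale < 0:
            raise ValueError("scale must be ≥ 0")
        if self.w_star is not None and not (0.0 < self.w_star < 1.0):
            raise ValueError("w_star must lie in (0, 1)")


def _raw_gaps(spec: PlantedEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n - 1
    if spec.distribution == "exponential-gap":
        return rng.exponential(spec.scale, size=n)
    if spec.distribution == "normal":
        return np.abs(rng.normal(0.0, max(spec.scale, 1e-12), size=n))
    # two-level: half at 0, half at scale
    levels = np.full(n, spec.scale)
    levels[: n // 2] = 0.0
    return levels


def synth_ensemble(spec: PlantedEnsembleSpec) -> np.ndarray:
    """Energies (kcal/mol) of a synthetic conformer ensemble.

    The first entry is the minimum at 0. With ``w_star`` set, the remaining
    energies are shifted by the closed-form amount Δ = kBT·ln(S/R) with
    R = (1−w*)/w*, so that the minimum's normalized Boltzmann weight equals
    w* to machine precision; infeasible requests (n = 1 with w* < 1, or a
    shift that would push a competitor below the minimum) raise.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n == 1:
        if spec.w_star is not None:
            raise ConstructionError("a single conformer always holds weight 1, not w*")
        return np.zeros(1)
    gaps = _raw_gaps(spec, rng)
    if spec.w_star is None:
        return np.concatenate([[0.0], gaps])
    kt = KB_KCAL_PER_MOL_K * spec.temperature
    target_ratio = (1.0 - spec.w_star) / spec.w_star
    s = float(np.sum(np.exp(-gaps / kt)))
    shift = kt * math.log(s / target_ratio)
    shifted = gaps + shift
    if np.any(shifted <= 0):
        raise ConstructionError(
            f"w*={spec.w_star} infeasible with n={spec.n} and the drawn gap structure: "
            "a competitor would fall below the planted minimum"
        )
    return np.concatenate([[0.0], shifted])


# --------------------------------------------------------------------------
# toy molecule catalogue
# --------------------------------------------------------------------------

TOY_KINDS = (
    "water",
    "methanol",
    "peroxide-chain",
    "toy-furanose",
    "toy-deoxyfuranose",
    "toy-base",
    "toy-phosphate",
)

_CC = 1.53
_CO = 1.43
_OH = 0.96
_CH = 1.09


def _furanose(deoxy: bool, anomer: str = "beta") -> tuple[Geometry, list[DihedralSpec]]:
    """Furanose-like toy sugar: planar 5-ring O4′-C1′-C2′-C3′-C4′ with
    hydroxyls at C1′/C3′/C5′ (and C2′ unless deoxy) and the exocyclic
    C5′ arm. The anomeric C1′ substituents flip sides between anomers.
    The anomeric hydrogen is labelled H1′ (glycosidic torsion reference)."""
    side = 1.48
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    ring_names = ["O4'", "C1'", "C2'", "C3'", "C4'"]
    ring_elems = ["O", "C", "C", "C", "C"]
    coords: list[np.ndarray] = []
    elements: list[str] = []
    labels: list[str] = []
    ring_pos = {}
    for k, (name, el) in enumerate(zip(ring_names, ring_elems)):
        ang = math.radians(90.0 + 72.0 * k)
        p = np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        ring_pos[name] = p
        elements.append(el)
        labels.append(name)
        coords.append(p)

    z = np.array([0.0, 0.0, 1.0])

    def outward(name: str) -> np.ndarray:
        p = ring_pos[name]
        return p / np.linalg.norm(p)

    def sub_dir(name: str, up: bool) -> np.ndarray:
        d = 0.55 * outward(name) + (0.835 if up else -0.835) * z
        return d / np.linalg.norm(d)

    def add(el: str, name: str, pos: np.ndarray) -> int:
        elements.append(el)
        labels.append(name)
        coords.append(np.asarray(pos, dtype=float))
        return len(coords) - 1

    flip = anomer == "alpha"  # anomeric substituents swap faces in the α form

    # C1': anomeric OH + H
    add("O", "O1'", ring_pos["C1'"] + _CO * sub_dir("C1'", up=not flip))
    add("H", "H1'", ring_pos["C1'"] + _CH * sub_dir("C1'", up=flip))
    # C2': OH + H (ribo) or H + H (deoxy)
    if deoxy:
        add("H", "H2'1", ring_pos["C2'"] + _CH * sub_dir("C2'", up=False))
        add("H", "H2'2", ring_pos["C2'"] + _CH * sub_dir("C2'", up=True))
    else:
        add("O", "O2'", ring_pos["C2'"] + _CO * sub_dir("C2'", up=False))
        add("H", "H2'", ring_pos["C2'"] + _CH * sub_dir("C2'", up=True))
    # C3': OH + H
    add("O", "O3'", ring_pos["C3'"] + _CO * sub_dir("C3'", up=True))
    add("H", "H3'", ring_pos["C3'"] + _CH * sub_dir("C3'", up=False))
    # C4': exocyclic C5' arm + H
    c5_idx = add("C", "C5'", ring_pos["C4'"] + _CC * sub_dir("C4'", up=True))
    add("H", "H4'", ring_pos["C4'"] + _CH * sub_dir("C4'", up=False))
    # C5' substituents by internal-coordinate placement off C4'-C3'
    c5 = coords[c5_idx]
    o5_idx = add(
        "O", "O5'", place_atom(c5, ring_pos["C4'"], ring_pos["C3'"], _CO, 109.5, 60.0)
    )
    add("H", "H5'1", place_atom(c5, ring_pos["C4'"], ring_pos["C3'"], _CH, 109.5, -60.0))
    add("H", "H5'2", place_atom(c5, ring_pos["C4'"], ring_pos["C3'"], _CH, 109.5, 180.0))
    add("H", "HO5'", place_atom(coords[o5_idx], c5, ring_pos["C4'"], _OH, 107.0, 180.0))
    # hydroxyl hydrogens (anti to a ring neighbor)
    lab = {name: i for i, name in enumerate(labels)}
    add("H", "HO1'", place_atom(coords[lab["O1'"]], ring_pos["C1'"], ring_pos["C2'"], _OH, 107.0, 180.0))
    if not deoxy:
        add("H", "HO2'", place_atom(coords[lab["O2'"]], ring_pos["C2'"], ring_pos["C3'"], _OH, 107.0, 180.0))
    add("H", "HO3'", place_atom(coords[lab["O3'"]], ring_pos["C3'"], ring_pos["C4'"], _OH, 107.0, 180.0))

    geom = Geometry(
        tuple(elements),
        np.array(coords),
        label=f"toy-{'deoxy' if deoxy else ''}furanose ({anomer})",
        atom_labels=tuple(labels),
    )
    lab = {name: i for i, name in enumerate(labels)}
    declared = []
    # reference carbon = lowest-index carbon neighbor, as the selector picks
    hydroxyls = [("HO1'", "O1'", "C1'", "C2'"), ("HO3'", "O3'", "C3'", "C2'"),
                 ("HO5'", "O5'", "C5'", "C4'")]
    if not deoxy:
        hydroxyls.insert(1, ("HO2'", "O2'", "C2'", "C1'"))
    for h, o, x, y in hydroxyls:
        declared.append(
            DihedralSpec(lab[h], lab[o], lab[x], lab[y], label=f"H-O-C-C ({o})")
        )
    declared.sort(key=lambda s: s.indices)
    declared.append(
        DihedralSpec(lab["O5'"], lab["C5'"], lab["C4'"], lab["C3'"], label="O-C5'-C4'-C3' (beta)")
    )
    return geom, declared


def _methanol() -> tuple[Geometry, list[DihedralSpec]]:
    c = np.zeros(3)
    o = np.array([_CO, 0.0, 0.0])
    h1 = place_atom(c, o, o + np.array([0.0, 1.0, 0.0]), _CH, 109.5, 0.0)
    h2 = place_atom(c, o, h1, _CH, 109.5, 120.0)
    h3 = place_atom(c, o, h1, _CH, 109.5, -120.0)
    ho = place_atom(o, c, h1, _OH, 107.0, 180.0)
    geom = Geometry(
        ("C", "O", "H", "H", "H", "H"),
        np.array([c, o, h1, h2, h3, ho]),
        label="methanol",
        atom_labels=("C", "O", "H1", "H2", "H3", "HO"),
    )
    return geom, [DihedralSpec(5, 1, 0, 2, label="H-O-C-H")]


def _peroxide() -> tuple[Geometry, list[DihedralSpec]]:
    o1 = np.zeros(3)
    o2 = np.array([1.45, 0.0, 0.0])
    t = math.radians(100.0)
    h1 = o1 + _OH * np.array([math.cos(t), math.sin(t), 0.0])
    h2 = place_atom(o2, o1, h1, _OH, 100.0, 90.0)
    geom = Geometry(
        ("O", "O", "H", "H"),
        np.array([o1, o2, h1, h2]),
        label="peroxide-chain",
        atom_labels=("O1", "O2", "H1", "H2"),
    )
    return geom, [DihedralSpec(2, 0, 1, 3, label="H-O-O-H"), DihedralSpec(3, 1, 0, 2, label="H-O-O-H")]


def _water() -> tuple[Geometry, list[DihedralSpec]]:
    t = math.radians(104.5)
    geom = Geometry(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [_OH, 0.0, 0.0], [_OH * math.cos(t), _OH * math.sin(t), 0.0]]),
        label="water",
        atom_labels=("O", "H1", "H2"),
    )
    return geom, []


def _toy_base() -> tuple[Geometry, list[DihedralSpec]]:
    """Planar imidazole-like 5-ring. N9 is the glycosylation nitrogen (its
    hydrogen leaves on condensation); C8 plays the Cx reference carbon of
    the glycosidic torsion — the toy's explicit stand-in for the
    purine-N9/pyrimidine-N1 attachment geometry."""
    side = 1.37
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    names = ["N9", "C8", "N7", "C5", "C4"]
    elems = ["N", "C", "N", "C", "C"]
    coords = []
    for k in range(5):
        ang = math.radians(90.0 + 72.0 * k)
        coords.append([radius * math.cos(ang), radius * math.sin(ang), 0.0])
    coords = [np.array(p) for p in coords]

    def out(i):
        return coords[i] / np.linalg.norm(coords[i])

    atoms = list(zip(elems, names, coords))
    atoms.append(("H", "H9", coords[0] + 1.01 * out(0)))
    atoms.append(("H", "H8", coords[1] + _CH * out(1)))
    atoms.append(("H", "H5", coords[3] + _CH * out(3)))
    atoms.append(("H", "H4", coords[4] + _CH * out(4)))
    geom = Geometry(
        tuple(a[0] for a in atoms),
        np.array([a[2] for a in atoms]),
        label="toy-base",
        atom_labels=tuple(a[1] for a in atoms),
    )
    return geom, []


def _toy_phosphate() -> tuple[Geometry, list[DihedralSpec]]:
    """Dihydrogen-phosphate-like anion: tetrahedral P with two protonated
    oxygens; net charge −1."""
    p = np.zeros(3)
    po = 1.57
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    dirs /= math.sqrt(3.0)
    o_pos = [p + po * d for d in dirs]
    h1 = place_atom(o_pos[0], p, o_pos[1], _OH, 110.0, 180.0)
    h2 = place_atom(o_pos[1], p, o_pos[0], _OH, 110.0, 180.0)
    geom = Geometry(
        ("P", "O", "O", "O", "O", "H", "H"),
        np.array([p, *o_pos, h1, h2]),
        charge=-1,
        label="toy-phosphate",
        atom_labels=("P", "O1", "O2", "O3", "O4", "HO1", "HO2"),
    )
    specs = [
        DihedralSpec(5, 1, 0, 2, label="H-O-P-O"),
        DihedralSpec(6, 2, 0, 1, label="H-O-P-O"),
    ]
    return geom, specs


def toy_molecule(kind: str) -> tuple[Geometry, list[DihedralSpec]]:
    """A catalogue toy geometry plus its declared rotatable-dihedral set.

    The declared set matches :func:`~anomerthermo.sampling.select_rotatable_dihedrals`
    under the ``hydroxyl_plus_beta`` rule on the same geometry.
    """
    builders = {
        "water": _water,
        "methanol": _methanol,
        "peroxide-chain": _peroxide,
        "toy-furanose": lambda: _furanose(deoxy=False),
        "toy-deoxyfuranose": lambda: _furanose(deoxy=True),
        "toy-base": _toy_base,
        "toy-phosphate": _toy_phosphate,
    }
    if kind not in builders:
        raise KeyError(f"unknown toy molecule kind {kind!r}; catalogue: {TOY_KINDS}")
    return builders[kind]()


def toy_nucleoside(anomer: str = "beta") -> tuple[Geometry, DihedralSpec]:
    """Toy N-nucleoside: toy-furanose condensed with toy-base at C1′.

    The anomeric hydroxyl and the base's N9-H leave (one water); the base
    nitrogen is bonded at C1′ along the former O1′ direction at 1.52 Å and
    the glycosidic torsion H1′-C1′-N9-C8 is set to −161.9°. Returns the
    assembled geometry and that glycosidic :class:`DihedralSpec`.
    """
    sugar, _ = _furanose(deoxy=False, anomer=anomer)
    base, _ = _toy_base()
    s_lab = {n: i for i, n in enumerate(sugar.atom_labels)}
    b_lab = {n: i for i, n in enumerate(base.atom_labels)}

    keep_sugar = [i for i, n in enumerate(sugar.atom_labels) if n not in ("O1'", "HO1'")]
    o1 = sugar.coords[s_lab["O1'"]]
    c1 = sugar.coords[s_lab["C1'"]]
    direction = (o1 - c1) / np.linalg.norm(o1 - c1)
    n_target = c1 + 1.52 * direction

    keep_base = [i for i, n in enumerate(base.atom_labels) if n != "H9"]
    n9 = base.coords[b_lab["N9"]]
    centroid = base.coords[[b_lab[n] for n in ("N9", "C8", "N7", "C5", "C4")]].mean(axis=0)
    # the ring must extend outward: map (centroid − N9) onto +direction
    toward_ring = (centroid - n9) / np.linalg.norm(centroid - n9)
    rot = _rotation_between(toward_ring, direction)
    base_coords = (base.coords[keep_base] - n9) @ rot.T + n_target

    elements = tuple(sugar.elements[i] for i in keep_sugar) + tuple(
        base.elements[i] for i in keep_base
    )
    labels = tuple(sugar.atom_labels[i] for i in keep_sugar) + tuple(
        base.atom_labels[i] for i in keep_base
    )
    coords = np.vstack([sugar.coords[keep_sugar], base_coords])
    geom = Geometry(
        elements, coords, label=f"toy-nucleoside ({anomer})", atom_labels=labels
    )
    lab = {n: i for i, n in enumerate(labels)}
    glyco = DihedralSpec(
        lab["H1'"], lab["C1'"], lab["N9"], lab["C8"], label="H-C1'-N9-Cx (glycosidic)"
    )
    geom = set_dihedral(geom, glyco, -161.9)
    return geom, glyco


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# --------------------------------------------------------------------------
# planted species registries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRegistrySpec:
    """Ground-truth structure of a synthetic species-thermochemistry table.

    ``anomer_offset`` δ (kcal/mol) is added to every β record's energies;
    ``pathway_effects`` are added to β nucleotide records of the given
    provenance (so each pathway's ΔΔG equals its planted effect);
    ``exchange_advantage`` is split over the canonical T/U species (dT and
    rU) of both anomers, so the sugar-exchange value recovers it while
    anomer differences stay untouched. ``noise_scale`` > 0 adds independent
    normal perturbations and deliberately breaks exact recovery.
    """

    anomer_offset: float = -2.5
    pathway_effects: dict = field(default_factory=lambda: {"a+b": 0.0, "c+d": 0.0})
    exchange_advantage: float = 0.0
    noise_scale: float = 0.0
    seed: int = 0


# rigid offsets relating the three energy kinds in synthetic registries
_E_OFFSET = 18.7
_EZPE_OFFSET = 9.3


def synth_registry(spec: PlantedRegistrySpec = PlantedRegistrySpec()) -> tuple[
    SpeciesRegistry, dict
]:
    """A full 80-reaction-capable registry with planted ground truth.

    Species G° values are built compositionally (fragment terms plus
    separable per-condensation bond terms) so that, at zero noise, every
    planted parameter is recovered exactly by the corresponding ledger
    operation. Returns (registry, ground-truth sheet).
    """
    rng = np.random.default_rng(spec.seed)
    frag: dict[tuple[str, str], float] = {}
    for name in list(SUGARS) + list(BASES) + ["phosphate", "water"]:
        for phase in PHASES:
            frag[(name, phase)] = -float(rng.uniform(100.0, 900.0))
    # separable condensation bond terms
    u_ns = {(s, ph): float(rng.normal(-5.0, 3.0)) for s in SUGARS for ph in PHASES}
    v_ns = {(b, ph): float(rng.normal(-5.0, 3.0)) for b in BASES for ph in PHASES}
    b_smp = {(s, ph): float(rng.normal(-8.0, 3.0)) for s in SUGARS for ph in PHASES}
    u_nt = {
        (s, ph, pw): float(rng.normal(-10.0, 4.0))
        for s in SUGARS
        for ph in PHASES
        for pw in PATHWAYS
    }
    v_nt = {
        (b, ph, pw): float(rng.normal(-10.0, 4.0))
        for b in BASES
        for ph in PHASES
        for pw in PATHWAYS
    }

    delta = spec.anomer_offset
    exch = spec.exchange_advantage

    def beta_term(anomer: str) -> float:
        return delta if anomer == "beta" else 0.0

    def canonical_term(sugar: str, base: str) -> float:
        if (sugar, base) in (("deoxyribose", "T"), ("ribose", "U")):
            return exch / 2.0
        return 0.0

    def noise() -> float:
        return float(rng.normal(0.0, spec.noise_scale)) if spec.noise_scale > 0 else 0.0

    registry = SpeciesRegistry()

    def put(key: SpeciesKey, gibbs: float) -> None:
        g = gibbs + noise()
        registry.add(
            SpeciesThermoRecord(
                key=key, energy=g + _E_OFFSET, energy_zpe=g + _EZPE_OFFSET, gibbs=g
            )
        )

    for phase in PHASES:
        put(SpeciesKey("water", phase=phase), frag[("water", phase)])
        put(SpeciesKey("phosphate", phase=phase), frag[("phosphate", phase)])
        for b in BASES:
            put(SpeciesKey("base", base=b, phase=phase), frag[(b, phase)])
        for s, a in product(SUGARS, ANOMERS):
            put(
                SpeciesKey("sugar", sugar=s, anomer=a, phase=phase),
                frag[(s, phase)] + beta_term(a),
            )
            put(
                SpeciesKey("sugar_5p_monophosphate", sugar=s, anomer=a, phase=phase),
                frag[(s, phase)] + frag[("phosphate", phase)] - frag[("water", phase)]
                + b_smp[(s, phase)] + beta_term(a),
            )
        for s, b, a in product(SUGARS, BASES, ANOMERS):
            put(
                SpeciesKey("nucleoside", sugar=s, base=b, anomer=a, phase=phase),
                frag[(s, phase)] + frag[(b, phase)] - frag[("water", phase)]
                + u_ns[(s, phase)] + v_ns[(b, phase)]
                + beta_term(a) + canonical_term(s, b),
            )
            for pw in PATHWAYS:
                put(
                    SpeciesKey(
                        "nucleotide", sugar=s, base=b, anomer=a, phase=phase, pathway=pw
                    ),
                    frag[(s, phase)] + frag[(b, phase)] + frag[("phosphate", phase)]
                    - 2.0 * frag[("water", phase)]
                    + u_nt[(s, phase, pw)] + v_nt[(b, phase, pw)]
                    + beta_term(a)
                    + (spec.pathway_effects.get(pw, 0.0) if a == "beta" else 0.0)
                    + canonical_term(s, b),
                )

    ground_truth = {
        "anomer_offset": delta,
        "pathway_effects": dict(spec.pathway_effects),
        "exchange_advantage": exch,
        "noise_scale": spec.noise_scale,
        "seed": spec.seed,
        "expected": {
            "anomer_delta_non_nucleotide": delta,
            "anomer_delta_nucleotide": {
                pw: delta + spec.pathway_effects.get(pw, 0.0) for pw in PATHWAYS
            },
            "ddg": dict(spec.pathway_effects),
            "sugar_exchange": exch,
        },
    }
    return registry, ground_truth


# --------------------------------------------------------------------------
# QC output fixtures
# --------------------------------------------------------------------------

def make_fixture_qc_output(record: EnergyRecord, dialect: str) -> str:
    """Synthetic quantum-chemistry log text carrying a record's fields.

    ``parse_qc_output`` recovers energy and frequencies from the result.
    Values are printed at 6 decimals; records produced by
    :func:`random_energy_record` are pre-quantized so the round trip is
    exact. A record with imaginary modes yields a fixture containing the
    corresponding negative wavenumbers.
    """
    freq_rows = []
    freqs = list(record.frequencies)
    if dialect == "mopac_out":
        for k in range(0, len(freqs), 3):
            chunk = "   ".join(f"{v:.6f}" for v in freqs[k : k + 3])
            freq_rows.append(f"          FREQ.   {chunk}")
        body = [
            " *  SYNTHETIC FIXTURE — MOPAC-STYLE OUTPUT (not produced by MOPAC)",
            f" *  PHASE TAG: {record.phase}",
            "",
            f"          FINAL HEAT OF FORMATION = {record.electronic_energy:.6f} KCAL/MOL",
            "",
            *freq_rows,
            "",
        ]
        return "\n".join(body) + "\n"
    if dialect == "gaussian_log":
        from .constants import HARTREE_TO_KCAL_PER_MOL as H2K

        for k in range(0, len(freqs), 3):
            chunk = "  ".join(f"{v:.6f}" for v in freqs[k : k + 3])
            freq_rows.append(f" Frequencies --   {chunk}")
        body = [
            " Synthetic fixture - Gaussian-style log (not produced by Gaussian)",
            f" Phase tag: {record.phase}",
            f" SCF Done:  E(RB3LYP) =  {record.electronic_energy / H2K:.12f}",
            *freq_rows,
        ]
        if record.zpe is not None:
            body.append(f" Zero-point correction=  {record.zpe / H2K:.12f}")
        if record.gibbs is not None:
            body.append(
                f" Sum of electronic and thermal Free Energies=  {record.gibbs / H2K:.12f}"
            )
        return "\n".join(body) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def random_energy_record(
    rng: np.random.Generator, dialect: str = "mopac_out", not_a_minimum: bool = False
) -> EnergyRecord:
    """A random record quantized to fixture print precision (6 decimals)."""
    n_modes = int(rng.integers(3, 10))
    freqs = np.round(np.sort(rng.uniform(80.0, 3600.0, size=n_modes)), 6)
    if not_a_minimum:
        freqs[0] = -abs(freqs[0])
        freqs = np.sort(freqs)
    energy = round(float(rng.uniform(-900.0, -50.0)), 6)
    zpe_val = None
    gibbs = None
    if dialect == "gaussian_log":
        zpe_val = round(float(rng.uniform(10.0, 80.0)), 6)
        gibbs = round(energy + float(rng.uniform(-30.0, 30.0)), 6)
    return EnergyRecord(
        electronic_energy=energy,
        frequencies=tuple(float(f) for f in freqs),
        zpe=zpe_val,
        gibbs=gibbs,
        backend_tag=dialect,
        phase="vacuum",
    )
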