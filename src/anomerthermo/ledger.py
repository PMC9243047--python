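"""Reaction Gibbs-energy bookkeeping for nucleotide assembly.

Species registry, β−α anomer differences (ΔX_βα ≡ X_β − X_α; negative
means the β-anomer is more stable), two-step condensation pathways —
"classic" a+b (sugar+base → nucleoside, then nucleoside+phosphate →
nucleotide) and "alternative" c+d (sugar+phosphate → 5′-sugar
monophosphate, then +base → nucleotide) — their ΔΔG comparison
(ΔΔG = ΔG_β − ΔG_α; negative favors the β pathway), sugar-exchange
reactions between T/U nucleosides(tides), study-space enumeration and
report tables.

Nucleotide records are keyed by pathway provenance: the two pathways trap
the product in different local minima, so Hess-law consistency is enforced
only within one provenance. Every condensation releases exactly one water;
the phosphate enters as the mono-anion H₂PO₄⁻ and the nucleotide product
carries its −1 charge.
"""

from __future__ import annotations

import io
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .errors import PairingError, RegistryLookupError, StoichiometryError

__all__ = [
    "SpeciesKey",
    "SpeciesThermoRecord",
    "SpeciesRegistry",
    "AnomerDelta",
    "ReactionStep",
    "PathwayResult",
    "PathwayComparison",
    "anomer_delta",
    "step_delta_g",
    "pathway_total",
    "ddg_compare",
    "compare_pathway",
    "sugar_exchange_delta",
    "enumerate_study",
    "all_reaction_steps",
    "StudySpace",
    "LedgerReport",
    "build_report",
    "build_pathway_steps",
    "round_half_away",
    "nucleotide_label",
    "SUGARS",
    "BASES",
    "ANOMERS",
    "PHASES",
    "PATHWAYS",
]

SUGARS = ("ribose", "deoxyribose")
BASES = ("A", "G", "C", "T", "U")
ANOMERS = ("alpha", "beta")
PHASES = ("vacuum", "aqueous")
PATHWAYS = ("a+b", "c+d")
ROLES = (
    "sugar",
    "base",
    "phosphate",
    "water",
    "nucleoside",
    "sugar_5p_monophosphate",
    "nucleotide",
)
KINDS = ("E", "E+ZPE", "G")

#: molecular formulas of the real chemical species the tags denote
FRAGMENT_FORMULAS = {
    ("sugar", "ribose"): "C5H10O5",
    ("sugar", "deoxyribose"): "C5H10O4",
    ("base", "A"): "C5H5N5",
    ("base", "G"): "C5H5N5O",
    ("base", "C"): "C4H5N3O",
    ("base", "T"): "C5H6N2O2",
    ("base", "U"): "C4H4N2O2",
    ("phosphate", None): "H2O4P",  # H2PO4⁻
    ("water", None): "H2O",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    counts: Counter = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] += int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def formula_to_hill(counts: Counter) -> str:
    counts = +Counter(counts)
    if not counts:
        return ""
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else []) + sorted(
            e for e in counts if e not in ("C", "H")
        )
    else:
        order = sorted(counts)
    return "".join(e + (str(counts[e]) if counts[e] > 1 else "") for e in order)


@dataclass(frozen=True, order=True)
class SpeciesKey:
    """Identity tags of one chemical species in the registry."""

    role: str
    sugar: str | None = None
    base: str | None = None
    anomer: str | None = None
    phase: str = "vacuum"
    pathway: str | None = None  # provenance, nucleotides only

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.sugar is not None and self.sugar not in SUGARS:
            raise ValueError(f"unknown sugar {self.sugar!r}")
        if self.base is not None and self.base not in BASES:
            raise ValueError(f"unknown base {self.base!r}")
        if self.anomer is not None and self.anomer not in ANOMERS:
            raise ValueError(f"unknown anomer {self.anomer!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.pathway is not None and self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.role == "nucleotide" and (
            self.anomer is None or self.sugar is None or self.base is None or self.pathway is None
        ):
            raise ValueError("nucleotide keys need sugar, base, anomer and pathway provenance")

    def same_species_except_anomer(self, other: "SpeciesKey") -> bool:
        return (
            self.role == other.role
            and self.sugar == other.sugar
            and self.base == other.base
            and self.phase == other.phase
            and self.pathway == other.pathway
        )


def species_formula(key: SpeciesKey) -> tuple[str, int]:
    """(Hill formula, net charge) for a species tag.

    Composite species are condensation products: each bond formed releases
    one water. The −1 charge of H₂PO₄⁻ is conserved into the phosphorylated
    products.
    """
    water = parse_formula(FRAGMENT_FORMULAS[("water", None)])
    if key.role in ("sugar",):
        return FRAGMENT_FORMULAS[("sugar", key.sugar)], 0
    if key.role == "base":
        return FRAGMENT_FORMULAS[("base", key.base)], 0
    if key.role == "phosphate":
        return FRAGMENT_FORMULAS[("phosphate", None)], -1
    if key.role == "water":
        return FRAGMENT_FORMULAS[("water", None)], 0
    sugar = parse_formula(FRAGMENT_FORMULAS[("sugar", key.sugar)])
    if key.role == "nucleoside":
        base = parse_formula(FRAGMENT_FORMULAS[("base", key.base)])
        return formula_to_hill(sugar + base - water), 0
    phosphate = parse_formula(FRAGMENT_FORMULAS[("phosphate", None)])
    if key.role == "sugar_5p_monophosphate":
        return formula_to_hill(sugar + phosphate - water), -1
    if key.role == "nucleotide":
        base = parse_formula(FRAGMENT_FORMULAS[("base", key.base)])
        return formula_to_hill(sugar + base + phosphate - water - water), -1
    raise ValueError(f"no formula rule for role {key.role!r}")


@dataclass(frozen=True)
class SpeciesThermoRecord:
    """E, E+ZPE and G° (kcal/mol) of one species, with identity tags."""

    key: SpeciesKey
    energy: float  # electronic E
    energy_zpe: float  # E + ZPE
    gibbs: float  # G° at stated conditions
    formula: str = ""
    charge: int = 0

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.energy, self.energy_zpe, self.gibbs)):
            raise ValueError("non-finite energy in species record")
        if not self.formula:
            formula, charge = species_formula(self.key)
            object.__setattr__(self, "formula", formula)
            object.__setattr__(self, "charge", charge)

    def quantity(self, kind: str) -> float:
        if kind == "E":
            return self.energy
        if kind == "E+ZPE":
            return self.energy_zpe
        if kind == "G":
            return self.gibbs
        raise ValueError(f"unknown quantity kind {kind!r} (expected one of {KINDS})")


class SpeciesRegistry:
    """Keyed store of species thermochemistry records with CSV/JSON I/O."""

    def __init__(self, records: list[SpeciesThermoRecord] | None = None):
        self._records: dict[SpeciesKey, SpeciesThermoRecord] = {}
        for r in records or []:
            self.add(r)

    def add(self, record: SpeciesThermoRecord) -> None:
        self._records[record.key] = record

    def get(self, key: SpeciesKey | None = None, **tags) -> SpeciesThermoRecord:
        if key is None:
            key = SpeciesKey(**tags)
        try:
            return self._records[key]
        except KeyError:
            raise RegistryLookupError(f"species {key} absent from registry")

    def __contains__(self, key: SpeciesKey) -> bool:
        return key in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(sorted(self._records.values(), key=lambda r: _key_sort(r.key)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self:
            rows.append(
                {
                    "role": r.key.role,
                    "sugar": r.key.sugar or "",
                    "base": r.key.base or "",
                    "anomer": r.key.anomer or "",
                    "phase": r.key.phase,
                    "pathway": r.key.pathway or "",
                    "E": r.energy,
                    "E_plus_ZPE": r.energy_zpe,
                    "G": r.gibbs,
                    "formula": r.formula,
                    "charge": r.charge,
                }
            )
        columns = [
            "role", "sugar", "base", "anomer", "phase", "pathway",
            "E", "E_plus_ZPE", "G", "formula", "charge",
        ]
        return pd.DataFrame(rows, columns=columns)

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index=False, float_format="%.9f")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpeciesRegistry":
        reg = cls()
        for _, row in df.iterrows():
            key = SpeciesKey(
                role=row["role"],
                sugar=row["sugar"] or None if isinstance(row["sugar"], str) else None,
                base=row["base"] or None if isinstance(row["base"], str) else None,
                anomer=row["anomer"] or None if isinstance(row["anomer"], str) else None,
                phase=row["phase"],
                pathway=row["pathway"] or None if isinstance(row["pathway"], str) else None,
            )
            reg.add(
                SpeciesThermoRecord(
                    key=key,
                    energy=float(row["E"]),
                    energy_zpe=float(row["E_plus_ZPE"]),
                    gibbs=float(row["G"]),
                    formula=str(row.get("formula", "")) or "",
                    charge=int(row.get("charge", 0)),
                )
            )
        return reg

    @classmethod
    def from_csv(cls, text: str) -> "SpeciesRegistry":
        df = pd.read_csv(io.StringIO(text), keep_default_na=False)
        return cls.from_dataframe(df)

    def to_json(self) -> str:
        return json.dumps(
            json.loads(self.to_dataframe().to_json(orient="records")), indent=1, sort_keys=True
        )


def _key_sort(key: SpeciesKey):
    return (
        ROLES.index(key.role),
        key.sugar or "",
        key.base or "",
        key.anomer or "",
        key.phase,
        key.pathway or "",
    )


# --------------------------------------------------------------------------
# anomer differences
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnomerDelta:
    """ΔX_βα = X_β − X_α for one species pair; negative ⇒ β more stable."""

    kind: str
    value: float
    beta_key: SpeciesKey
    alpha_key: SpeciesKey


def anomer_delta(
    beta: SpeciesThermoRecord, alpha: SpeciesThermoRecord, kind: str = "G"
) -> AnomerDelta:
    """ΔX_βα from matched β/α records of the same species and phase."""
    if beta.key.anomer != "beta" or alpha.key.anomer != "alpha":
        raise PairingError(
            f"expected a (beta, alpha) pair, got ({beta.key.anomer}, {alpha.key.anomer})"
        )
    if not beta.key.same_species_except_anomer(alpha.key):
        raise PairingError(f"records are not anomer twins: {beta.key} vs {alpha.key}")
    return AnomerDelta(
        kind=kind,
        value=beta.quantity(kind) - alpha.quantity(kind),
        beta_key=beta.key,
        alpha_key=alpha.key,
    )


# --------------------------------------------------------------------------
# reaction steps and pathways
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionStep:
    """One condensation step: reactant/product species multisets + label."""

    reactants: tuple[SpeciesKey, ...]
    products: tuple[SpeciesKey, ...]
    label: str = ""  # a, b, c, d, exchange

    def check_balance(self) -> None:
        """Element and charge balance; raises naming the mismatch."""
        lhs: Counter = Counter()
        rhs: Counter = Counter()
        q_lhs = q_rhs = 0
        for k in self.reactants:
            f, q = species_formula(k)
            lhs += parse_formula(f)
            q_lhs += q
        for k in self.products:
            f, q = species_formula(k)
            rhs += parse_formula(f)
            q_rhs += q
        if lhs != rhs:
            diff = +(lhs - rhs) | +(rhs - lhs)
            raise StoichiometryError(
                f"step {self.label!r} unbalanced in elements {sorted(diff)}: "
                f"{formula_to_hill(lhs)} vs {formula_to_hill(rhs)}"
            )
        if q_lhs != q_rhs:
            raise StoichiometryError(
                f"step {self.label!r} unbalanced in charge: {q_lhs} vs {q_rhs}"
            )


def step_delta_g(step: ReactionStep, registry: SpeciesRegistry, kind: str = "G") -> float:
    """ΔX° = Σ X(products) − Σ X(reactants); balance-checked first."""
    step.check_balance()
    total = 0.0
    for k in step.products:
        total += registry.get(k).quantity(kind)
    for k in step.reactants:
        total -= registry.get(k).quantity(kind)
    return total


def build_pathway_steps(
    sugar: str, base: str, anomer: str, phase: str, pathway: str
) -> tuple[ReactionStep, ReactionStep]:
    """The two condensation steps of one pathway, each releasing one water."""
    k_sugar = SpeciesKey("sugar", sugar=sugar, anomer=anomer, phase=phase)
    k_base = SpeciesKey("base", base=base, phase=phase)
    k_phos = SpeciesKey("phosphate", phase=phase)
    k_water = SpeciesKey("water", phase=phase)
    k_nt = SpeciesKey(
        "nucleotide", sugar=sugar, base=base, anomer=anomer, phase=phase, pathway=pathway
    )
    if pathway == "a+b":
        k_ns = SpeciesKey("nucleoside", sugar=sugar, base=base, anomer=anomer, phase=phase)
        step_a = ReactionStep((k_sugar, k_base), (k_ns, k_water), label="a")
        step_b = ReactionStep((k_ns, k_phos), (k_nt, k_water), label="b")
        return step_a, step_b
    if pathway == "c+d":
        k_smp = SpeciesKey(
            "sugar_5p_monophosphate", sugar=sugar, anomer=anomer, phase=phase
        )
        step_c = ReactionStep((k_sugar, k_phos), (k_smp, k_water), label="c")
        step_d = ReactionStep((k_smp, k_base), (k_nt, k_water), label="d")
        return step_c, step_d
    raise ValueError(f"unknown pathway {pathway!r}")


@dataclass(frozen=True)
class PathwayResult:
    """Per-step and total ΔX° of one two-step pathway for one anomer."""

    pathway: str
    sugar: str
    base: str
    anomer: str
    phase: str
    kind: str
    step_values: tuple[float, float]

    @property
    def total(self) -> float:
        return self.step_values[0] + self.step_values[1]


def pathway_total(
    steps: tuple[ReactionStep, ReactionStep],
    registry: SpeciesRegistry,
    kind: str = "G",
) -> PathwayResult:
    """Total ΔX° of an ordered two-step pathway, with consistency checks.

    The intermediate produced by step 1 must appear among step 2's
    reactants (nucleoside for a+b, 5′-sugar monophosphate for c+d).
    """
    if len(steps) != 2:
        raise ValueError("a pathway is exactly two steps")
    first, second = steps
    intermediates = [
        k for k in first.products if k.role in ("nucleoside", "sugar_5p_monophosphate")
    ]
    if not intermediates or not any(k in second.reactants for k in intermediates):
        raise PairingError(
            f"intermediate of step {first.label!r} absent from step {second.label!r} reactants"
        )
    nt = [k for k in second.products if k.role == "nucleotide"]
    if not nt:
        raise PairingError("second step does not produce a nucleotide")
    key = nt[0]
    values = (step_delta_g(first, registry, kind), step_delta_g(second, registry, kind))
    return PathwayResult(
        pathway=key.pathway,
        sugar=key.sugar,
        base=key.base,
        anomer=key.anomer,
        phase=key.phase,
        kind=kind,
        step_values=values,
    )


def ddg_compare(beta: PathwayResult, alpha: PathwayResult) -> float:
    """ΔΔG = total_β − total_α; negative ⇒ the β pathway is more exergonic."""
    if beta.anomer != "beta" or alpha.anomer != "alpha":
        raise PairingError("ddg_compare expects a (beta, alpha) pathway pair")
    for attr in ("pathway", "sugar", "base", "phase", "kind"):
        if getattr(beta, attr) != getattr(alpha, attr):
            raise PairingError(
                f"pathway pair mismatch in {attr}: "
                f"{getattr(beta, attr)!r} vs {getattr(alpha, attr)!r}"
            )
    return beta.total - alpha.total


@dataclass(frozen=True)
class PathwayComparison:
    """β-vs-α comparison of one pathway for one nucleotide and phase."""

    pathway: str
    sugar: str
    base: str
    phase: str
    kind: str
    beta: PathwayResult
    alpha: PathwayResult

    @property
    def ddg(self) -> float:
        return ddg_compare(self.beta, self.alpha)

    @property
    def nucleotide(self) -> str:
        return nucleotide_label(self.sugar, self.base)


def compare_pathway(
    registry: SpeciesRegistry,
    sugar: str,
    base: str,
    phase: str,
    pathway: str,
    kind: str = "G",
) -> PathwayComparison:
    results = {}
    for anomer in ANOMERS:
        steps = build_pathway_steps(sugar, base, anomer, phase, pathway)
        results[anomer] = pathway_total(steps, registry, kind)
    return PathwayComparison(
        pathway=pathway,
        sugar=sugar,
        base=base,
        phase=phase,
        kind=kind,
        beta=results["beta"],
        alpha=results["alpha"],
    )


def nucleotide_label(sugar: str, base: str) -> str:
    return ("d" if sugar == "deoxyribose" else "") + base + "MP"


# --------------------------------------------------------------------------
# sugar exchange reactions: rT + dU → dT + rU (per anomer)
# --------------------------------------------------------------------------

def sugar_exchange_delta(
    registry: SpeciesRegistry,
    anomer: str,
    kind: str = "G",
    role: str = "nucleoside",
    phase: str = "vacuum",
    pathway: str | None = None,
) -> float:
    """ΔX of the double sugar swap toward the canonical pairing.

    ΔX = [X(dT) + X(rU)] − [X(rT) + X(dU)] for the given anomer; negative
    means thymine-on-deoxyribose plus uracil-on-ribose (the canonical
    pairing) is favored. For nucleotides the pathway provenance selects
    which four records are compared.
    """
    if role == "nucleotide" and pathway is None:
        raise ValueError("nucleotide exchange needs a pathway provenance")

    def rec(sugar: str, base: str) -> SpeciesThermoRecord:
        return registry.get(
            SpeciesKey(
                role,
                sugar=sugar,
                base=base,
                anomer=anomer,
                phase=phase,
                pathway=pathway if role == "nucleotide" else None,
            )
        )

    canonical = rec("deoxyribose", "T").quantity(kind) + rec("ribose", "U").quantity(kind)
    minor = rec("ribose", "T").quantity(kind) + rec("deoxyribose", "U").quantity(kind)
    return canonical - minor


# --------------------------------------------------------------------------
# study-space enumeration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpace:
    """Factor counts of the full study cross-product."""

    n_pathways: int = 2
    n_sugars: int = 2
    n_bases: int = 5
    n_anomers: int = 2
    n_phases: int = 2
    n_classes: int = 2  # nucleoside, nucleotide


def enumerate_study(space: StudySpace = StudySpace()) -> dict[str, int]:
    """Counts of structures and reactions spanned by the study design.

    With the default factors: 20 nucleoside structures, 40 initial
    nucleoside guess geometries, 80 final optimized structures, and
    2×2×5×2×2 = 80 condensation "reactions".
    """
    return {
        "nucleosides": space.n_sugars * space.n_bases * space.n_anomers,
        "guess_geometries": space.n_bases * space.n_sugars * space.n_anomers * space.n_phases,
        "final_structures": (
            space.n_classes * space.n_sugars * space.n_bases * space.n_anomers * space.n_phases
        ),
        "reactions": (
            space.n_pathways * space.n_sugars * space.n_bases * space.n_anomers * space.n_phases
        ),
    }


def all_reaction_steps() -> list[tuple[str, str, str, str, str, tuple[ReactionStep, ReactionStep]]]:
    """All 80 enumerated (pathway, sugar, base, anomer, phase) step pairs."""
    out = []
    for pathway, sugar, base, anomer, phase in product(PATHWAYS, SUGARS, BASES, ANOMERS, PHASES):
        out.append(
            (pathway, sugar, base, anomer, phase, build_pathway_steps(sugar, base, anomer, phase, pathway))
        )
    return out


# --------------------------------------------------------------------------
# report tables
# --------------------------------------------------------------------------

def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the print convention for report tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass
class LedgerReport:
    """Tabular report set: unrounded values plus 1-decimal printed columns."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.9f")
            (out / f"{name}.json").write_text(
                json.dumps(json.loads(df.to_json(orient="records")), indent=1, sort_keys=True)
                + "\n"
            )
        if self.missing:
            (out / "missing_cells.json").write_text(json.dumps(self.missing, indent=1) + "\n")


def build_report(registry: SpeciesRegistry) -> LedgerReport:
    """Anomer-difference, pathway and exchange tables from a registry.

    Printed columns are rounded to one decimal, half away from zero;
    unrounded values are retained. Missing species produce listed gaps,
    not failures.
    """
    report = LedgerReport()

    # anomer differences for each anomeric role
    rows = []
    role_pathways: dict[str, tuple[str | None, ...]] = {
        "sugar": (None,),
        "sugar_5p_monophosphate": (None,),
        "nucleoside": (None,),
        "nucleotide": PATHWAYS,
    }
    for role, pathways in role_pathways.items():
        bases = BASES if role in ("nucleoside", "nucleotide") else (None,)
        for sugar, base, phase, pathway in product(SUGARS, bases, PHASES, pathways):
            keys = {
                a: SpeciesKey(role, sugar=sugar, base=base, anomer=a, phase=phase, pathway=pathway)
                for a in ANOMERS
            }
            try:
                recs = {a: registry.get(k) for a, k in keys.items()}
            except RegistryLookupError:
                report.missing.append(str(keys["beta"]))
                continue
            for kind in KINDS:
                d = anomer_delta(recs["beta"], recs["alpha"], kind)
                rows.append(
                    {
                        "role": role,
                        "sugar": sugar,
                        "base": base or "",
                        "phase": phase,
                        "pathway": pathway or "",
                        "kind": kind,
                        "delta_beta_alpha": d.value,
                        "printed": round_half_away(d.value, 1),
                    }
                )
    report.tables["anomer_deltas"] = pd.DataFrame(
        rows,
        columns=[
            "role", "sugar", "base", "phase", "pathway", "kind",
            "delta_beta_alpha", "printed",
        ],
    )

    # pathway totals and ΔΔG
    rows = []
    for pathway, sugar, base, phase in product(PATHWAYS, SUGARS, BASES, PHASES):
        try:
            cmp_ = compare_pathway(registry, sugar, base, phase, pathway)
        except RegistryLookupError:
            report.missing.append(f"pathway {pathway} {sugar} {base} {phase}")
            continue
        rows.append(
            {
                "nucleotide": cmp_.nucleotide,
                "pathway": pathway,
                "phase": phase,
                "dg_step_i_alpha": cmp_.alpha.step_values[0],
                "dg_step_i_beta": cmp_.beta.step_values[0],
                "dg_step_j_alpha": cmp_.alpha.step_values[1],
                "dg_step_j_beta": cmp_.beta.step_values[1],
                "dg_total_alpha": cmp_.alpha.total,
                "dg_total_beta": cmp_.beta.total,
                "ddg": cmp_.ddg,
                "printed_total_alpha": round_half_away(cmp_.alpha.total, 1),
                "printed_total_beta": round_half_away(cmp_.beta.total, 1),
                "printed_ddg": round_half_away(cmp_.ddg, 1),
            }
        )
    report.tables["pathways"] = pd.DataFrame(
        rows,
        columns=[
            "nucleotide", "pathway", "phase",
            "dg_step_i_alpha", "dg_step_i_beta", "dg_step_j_alpha", "dg_step_j_beta",
            "dg_total_alpha", "dg_total_beta", "ddg",
            "printed_total_alpha", "printed_total_beta", "printed_ddg",
        ],
    )

    # sugar-exchange reactions
    rows = []
    exchange_roles: list[tuple[str, str | None]] = [
        ("nucleoside", None), ("nucleotide", "a+b"), ("nucleotide", "c+d"),
    ]
    for (role, pathway), anomer, phase, kind in product(exchange_roles, ANOMERS, PHASES, KINDS):
        try:
            value = sugar_exchange_delta(
                registry, anomer, kind=kind, role=role, phase=phase, pathway=pathway
            )
        except RegistryLookupError:
            report.missing.append(f"exchange {role} {pathway} {anomer} {phase}")
            continue
        rows.append(
            {
                "role": role,
                "pathway": pathway or "",
                "anomer": anomer,
                "phase": phase,
                "kind": kind,
                "delta_exchange": value,
                "printed": round_half_away(value, 1),
            }
        )
    report.tables["sugar_exchange"] = pd.DataFrame(
        rows,
        columns=["role", "pathway", "anomer", "phase", "kind", "delta_exchange", "printed"],
    )

    counts = enumerate_study()
    report.tables["study_space"] = pd.DataFrame(
        [{"quantity": k, "count": v} for k, v in counts.items()], columns=["quantity", "count"]
    )
    return report
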