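"""Randomized conformer generation over declared dihedrals, and deduplication.

The sampling emulates the random-torsion conformer generators used for
furanose sugars: every rotatable hydroxyl torsion (H-O-C-C type) plus the
exocyclic O-C5′-C4′-C3′ ("beta") torsion is varied independently and
uniformly over [−180°, 180°). Optimized conformers that collapse onto the
same minimum are merged into unique minima by a periodic-distance criterion.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace

import numpy as np

from .chem_core import (
    BondGraph,
    DihedralSpec,
    Geometry,
    bond_graph,
    measure_dihedral,
    set_dihedral,
    write_xyz,
    _wrap_deg,
)
from .errors import DegeneratePlanError

logger = logging.getLogger(__name__)

__all__ = [
    "Conformer",
    "SamplingPlan",
    "select_rotatable_dihedrals",
    "generate_conformers",
    "deduplicate_minima",
    "conformers_to_csv",
]

BETA_TORSION_LABELS = ("O5'", "C5'", "C4'", "C3'")

DEFAULT_ENERGY_TOL = 0.1  # kcal/mol
DEFAULT_DIHEDRAL_TOL = 15.0  # degrees


@dataclass(frozen=True)
class Conformer:
    """One sampled (and possibly optimized) conformer with provenance."""

    geometry: Geometry
    dihedrals: tuple[float, ...]  # degrees, one per DihedralSpec of the plan
    energy: float | None = None  # kcal/mol, absent until evaluated
    seed: int | None = None
    sample_index: int = 0
    backend_tag: str = ""

    def with_energy(self, energy: float, backend_tag: str | None = None) -> "Conformer":
        return replace(
            self,
            energy=float(energy),
            backend_tag=self.backend_tag if backend_tag is None else backend_tag,
        )


@dataclass(frozen=True)
class SamplingPlan:
    """Dihedral set, sample count and RNG seed for one sampling run."""

    dihedrals: tuple[DihedralSpec, ...]
    n_samples: int
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "dihedrals", tuple(self.dihedrals))
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")


def _hydroxyl_like_torsions(geom: Geometry, graph: BondGraph) -> list[DihedralSpec]:
    """All H-O-X-Y torsions where O carries exactly one H and one heavy neighbor.

    Y is chosen deterministically among X's other neighbors: carbons first,
    then other heavy atoms, then hydrogens, lowest index within each class
    (methanol therefore still yields its single H-O-C-H torsion).
    """
    specs = []
    for o in range(geom.n_atoms):
        if geom.elements[o] != "O":
            continue
        nbrs = sorted(graph.neighbors(o))
        hydrogens = [a for a in nbrs if geom.elements[a] == "H"]
        heavies = [a for a in nbrs if geom.elements[a] != "H"]
        if len(hydrogens) != 1 or len(heavies) != 1:
            continue
        h, x = hydrogens[0], heavies[0]
        candidates = sorted(
            (a for a in graph.neighbors(x) if a != o),
            key=lambda a: (
                0 if geom.elements[a] == "C" else (1 if geom.elements[a] != "H" else 2),
                a,
            ),
        )
        if not candidates:
            continue
        y = candidates[0]
        label = f"{geom.elements[h]}-{geom.elements[o]}-{geom.elements[x]}-{geom.elements[y]}"
        specs.append(DihedralSpec(h, o, x, y, label=label))
    specs.sort(key=lambda s: s.indices)
    return specs


def select_rotatable_dihedrals(
    geom: Geometry,
    rule: str = "hydroxyl_plus_beta",
    graph: BondGraph | None = None,
) -> list[DihedralSpec]:
    """The rotatable torsion set under a named rule.

    ``hydroxyl_plus_beta``: every hydroxyl H-O-C-C-type torsion, plus the
    exocyclic O-C5′-C4′-C3′ torsion when the geometry carries those atom
    labels. For a ribofuranose this yields 5 torsions, for a
    2′-deoxyribofuranose 4. Missing labelled atoms are logged, not fatal.
    Ordering is deterministic (by atom index tuple; the beta torsion last).
    """
    if rule != "hydroxyl_plus_beta":
        raise ValueError(f"unknown rotatable-dihedral rule {rule!r}")
    if graph is None:
        graph = bond_graph(geom)
    specs = _hydroxyl_like_torsions(geom, graph)
    try:
        idx = tuple(geom.index_of_label(name) for name in BETA_TORSION_LABELS)
        beta = DihedralSpec(*idx, label="O-C5'-C4'-C3' (beta)")
        beta.validate(geom, graph)
        specs.append(beta)
    except KeyError:
        logger.warning(
            "geometry '%s' lacks the labelled O5'/C5'/C4'/C3' atoms; beta torsion skipped",
            geom.label,
        )
    if not specs:
        logger.warning("no rotatable dihedrals found for geometry '%s'", geom.label)
    return specs


def generate_conformers(geom: Geometry, plan: SamplingPlan) -> list[Conformer]:
    """Draw ``plan.n_samples`` conformers, each torsion uniform on [−180, 180).

    Bit-for-bit reproducible for an identical plan (seed included); the
    input geometry is never mutated.
    """
    if len(plan.dihedrals) == 0 and plan.n_samples > 1:
        raise DegeneratePlanError(
            "no rotatable dihedrals: cannot generate more than one conformer"
        )
    graph = bond_graph(geom)
    for spec in plan.dihedrals:
        spec.validate(geom, graph)
    rng = np.random.default_rng(plan.seed)
    out = []
    for i in range(plan.n_samples):
        angles = rng.uniform(-180.0, 180.0, size=len(plan.dihedrals))
        g = geom
        for spec, angle in zip(plan.dihedrals, angles):
            g = set_dihedral(g, spec, float(angle), graph=graph)
        out.append(
            Conformer(
                geometry=g,
                dihedrals=tuple(float(a) for a in angles),
                seed=plan.seed,
                sample_index=i,
            )
        )
    return out


def _same_minimum(a: Conformer, b: Conformer, energy_tol: float, dihedral_tol: float) -> bool:
    if abs(a.energy - b.energy) > energy_tol:
        return False
    return all(
        abs(_wrap_deg(da - db)) <= dihedral_tol for da, db in zip(a.dihedrals, b.dihedrals)
    )


def deduplicate_minima(
    conformers: list[Conformer],
    energy_tol: float = DEFAULT_ENERGY_TOL,
    dihedral_tol: float = DEFAULT_DIHEDRAL_TOL,
) -> list[Conformer]:
    """Merge optimized conformers that converged to one and the same minimum.

    Two conformers merge iff their energies differ by ≤ *energy_tol* AND
    every periodic (wrapped) dihedral difference is ≤ *dihedral_tol*;
    merging is transitive (single-linkage). Each cluster is represented by
    its lowest-energy member (ties: lowest sample index); output sorted by
    energy ascending. All conformers must carry energies and share the
    dihedral-spec list length.
    """
    if not conformers:
        return []
    n_dih = len(conformers[0].dihedrals)
    for c in conformers:
        if c.energy is None:
            raise ValueError("deduplicate_minima requires energies on every conformer")
        if len(c.dihedrals) != n_dih:
            raise ValueError("conformers do not share a dihedral spec list")
    n = len(conformers)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _same_minimum(conformers[i], conformers[j], energy_tol, dihedral_tol):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    reps = []
    for members in clusters.values():
        rep = min(members, key=lambda i: (conformers[i].energy, conformers[i].sample_index))
        reps.append(conformers[rep])
    reps.sort(key=lambda c: (c.energy, c.sample_index))
    return reps


def conformers_to_csv(conformers: list[Conformer]) -> str:
    """CSV sidecar: sample index, seed, backend tag, energy, dihedral vector."""
    buf = io.StringIO()
    n_dih = len(conformers[0].dihedrals) if conformers else 0
    header = ["sample_index", "seed", "backend_tag", "energy_kcal_mol"] + [
        f"dihedral_{k}" for k in range(n_dih)
    ]
    buf.write(",".join(header) + "\n")
    for c in conformers:
        row = [
            str(c.sample_index),
            "" if c.seed is None else str(c.seed),
            c.backend_tag,
            "" if c.energy is None else f"{c.energy:.9f}",
        ] + [f"{d:.6f}" for d in c.dihedrals]
        buf.write(",".join(row) + "\n")
    return buf.getvalue()


def conformers_to_xyz(conformers: list[Conformer]) -> str:
    """Multi-record XYZ of the conformer geometries."""
    return "".join(
        write_xyz(
            c.geometry,
            comment=f"conformer {c.sample_index} seed={c.seed} E={c.energy}",
        )
        for c in conformers
    )
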