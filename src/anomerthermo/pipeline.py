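"""End-to-end orchestration: sample → optimize → dedup → select → scan →
registry → ledger → report.

The pipeline mirrors the study workflow on the toy catalogue with the
surrogate backend: randomized torsion conformers of the two toy sugars are
optimized and deduplicated into unique minima, the minimal ≥50%-of-Z
conformer sets are selected, the toy nucleoside's glycosidic torsion is
soft-scanned (6 × 60° from −161.9°) and refined, a planted synthetic
species registry supplies the thermochemistry for the 80-reaction Gibbs
ledger, and report tables are written. Two runs with the same configuration
are byte-identical (no timestamps; fixed float formats; sorted JSON keys).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .backends import SurrogateBackend, SurrogateParams
from .boltzmann import select_ensemble
from .chem_core import measure_dihedral, write_xyz
from .errors import PipelineStageError
from .ledger import build_report
from .sampling import (
    Conformer,
    SamplingPlan,
    conformers_to_csv,
    conformers_to_xyz,
    deduplicate_minima,
)
from .scan import ScanProtocol, refine_minimum, soft_scan
from .synthetic import PlantedRegistrySpec, synth_registry, toy_molecule, toy_nucleoside

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration; defaults are the study protocol constants.

    The conformer count default mirrors the study protocol (1,000 random
    conformers per sugar); desk-scale runs and the test suite pass smaller
    counts through this same field.
    """

    sugars: tuple[str, ...] = ("toy-furanose", "toy-deoxyfuranose")
    n_conformers: int = 1000
    seed: int = 0
    backend: str = "surrogate"
    selection_threshold: float = 0.5
    temperature: float = 298.15
    scan_step_deg: float = 60.0
    scan_n_steps: int = 6
    glycosidic_bond_length: float = 1.52
    glycosidic_torsion_init: float = -161.9
    phosphate_torsion_init: float = 30.9
    pathway: str = "both"  # "ab", "cd" or "both"
    dedup_energy_tol: float = 0.1
    dedup_dihedral_tol: float = 15.0
    registry_anomer_offset: float = -2.5
    registry_pathway_effect_ab: float = 0.0
    registry_pathway_effect_cd: float = 0.0
    registry_exchange_advantage: float = 0.0
    registry_noise_scale: float = 0.0
    outdir: str = "pipeline_out"

    def __post_init__(self):
        object.__setattr__(self, "sugars", tuple(self.sugars))
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be ≥ 1")
        if not (0.0 < self.selection_threshold <= 1.0):
            raise ValueError("selection_threshold must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.scan_n_steps < 1 or self.scan_step_deg == 0:
            raise ValueError("scan grid must have ≥ 1 nonzero steps")
        if self.pathway not in ("ab", "cd", "both"):
            raise ValueError("pathway must be 'ab', 'cd' or 'both'")
        if self.backend != "surrogate":
            raise ValueError("only the surrogate backend runs the full pipeline")

    def registry_spec(self) -> PlantedRegistrySpec:
        return PlantedRegistrySpec(
            anomer_offset=self.registry_anomer_offset,
            pathway_effects={
                "a+b": self.registry_pathway_effect_ab,
                "c+d": self.registry_pathway_effect_cd,
            },
            exchange_advantage=self.registry_exchange_advantage,
            noise_scale=self.registry_noise_scale,
            seed=self.seed,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if "sugars" in data:
            data["sugars"] = tuple(data["sugars"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write artifacts + manifest under ``config.outdir``.

    Returns the output directory. A failing stage raises
    :class:`PipelineStageError` naming the stage; artifacts of completed
    stages are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stages": [],
        "counts": {},
    }

    # ---- sample / optimize / dedup / select per sugar -------------------
    selection_rows = ["molecule,n_sampled,n_unique,n_selected,percent_of_z"]
    try:
        for mol_index, kind in enumerate(config.sugars):
            geom, dihedrals = toy_molecule(kind)
            backend = SurrogateBackend(SurrogateParams.from_geometry(geom))
            plan = SamplingPlan(
                tuple(dihedrals), config.n_conformers, seed=config.seed + 1000 * mol_index
            )
            conformers = generate_and_optimize(geom, plan, backend)
            unique = deduplicate_minima(
                conformers, config.dedup_energy_tol, config.dedup_dihedral_tol
            )
            (out / f"conformers_{kind}.csv").write_text(conformers_to_csv(unique))
            (out / f"conformers_{kind}.xyz").write_text(conformers_to_xyz(unique))
            sel = select_ensemble(
                [c.energy for c in unique],
                temperature=config.temperature,
                threshold=config.selection_threshold,
            )
            selection_rows.append(
                f"{kind},{plan.n_samples},{len(unique)},{sel.n_selected},{sel.percent_of_z:.4f}"
            )
            manifest["counts"][kind] = {
                "n_sampled": plan.n_samples,
                "n_unique": len(unique),
                "n_selected": sel.n_selected,
                "percent_of_z": round(sel.percent_of_z, 4),
            }
        (out / "selection_summary.csv").write_text("\n".join(selection_rows) + "\n")
        manifest["stages"] += ["sample", "optimize", "dedup", "select"]
    except Exception as exc:  # noqa: BLE001 — re-typed with stage context
        raise PipelineStageError("sample/optimize/dedup/select", str(exc)) from exc

    # ---- glycosidic scan on the toy nucleosides -------------------------
    try:
        for anomer in ("beta", "alpha"):
            geom, glyco = toy_nucleoside(anomer)
            backend = SurrogateBackend(SurrogateParams.from_geometry(geom))
            protocol = ScanProtocol(
                glyco,
                start_deg=config.glycosidic_torsion_init,
                step_deg=config.scan_step_deg,
                n_steps=config.scan_n_steps,
            )
            scan = soft_scan(geom, protocol, backend)
            refined = refine_minimum(scan, backend)
            (out / f"scan_glycosidic_{anomer}.csv").write_text(scan.to_csv())
            (out / f"refined_{anomer}.xyz").write_text(
                write_xyz(refined.geometry, comment=f"refined glycosidic minimum ({anomer})")
            )
            manifest["counts"][f"scan_{anomer}"] = {
                "argmin_angle": round(scan.angles[scan.argmin_index], 4),
                "refined_energy": round(refined.energy, 9),
                "vetted_minimum": refined.is_minimum,
                "all_points_converged": not scan.any_unconverged,
            }
        manifest["stages"].append("scan")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("scan", str(exc)) from exc

    # ---- registry + ledger + report -------------------------------------
    try:
        registry, ground_truth = synth_registry(config.registry_spec())
        (out / "registry.csv").write_text(registry.to_csv())
        (out / "registry_ground_truth.json").write_text(
            json.dumps(ground_truth, indent=1, sort_keys=True) + "\n"
        )
        manifest["stages"].append("registry")
        report = build_report(registry)
        if config.pathway != "both":
            wanted = {"ab": "a+b", "cd": "c+d"}[config.pathway]
            report.tables["pathways"] = report.tables["pathways"][
                report.tables["pathways"]["pathway"] == wanted
            ].reset_index(drop=True)
        report.write(out / "report")
        manifest["stages"] += ["ledger", "report"]
        manifest["counts"]["pathway_rows"] = int(len(report.tables["pathways"]))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("ledger/report", str(exc)) from exc

    # ---- manifest with artifact checksums -------------------------------
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["artifacts"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out


def generate_and_optimize(geom, plan: SamplingPlan, backend) -> list[Conformer]:
    """Sample the plan and locally optimize every conformer with the backend."""
    from .sampling import generate_conformers

    conformers = generate_conformers(geom, plan)
    optimized = []
    for c in conformers:
        res = backend.optimize(c.geometry)
        dihedrals = tuple(
            measure_dihedral(res.geometry, spec) for spec in plan.dihedrals
        )
        optimized.append(
            replace(
                c,
                geometry=res.geometry,
                dihedrals=dihedrals,
                energy=res.energy,
                backend_tag=backend.tag,
            )
        )
    return optimized
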