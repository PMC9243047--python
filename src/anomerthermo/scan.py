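"""Soft (relaxed) torsion scans and refinement of the lowest grid point.

A soft scan steps one dihedral through a grid — by default 6 steps of 60°
starting from the initial angle — freezing only that torsion at each point
while all remaining coordinates relax. Grid points are visited sequentially,
each started from the previous relaxed structure (chain continuation). The
lowest converged point is refined by a final unconstrained optimization and
vetted by a harmonic frequency calculation (no imaginary modes ⇒ minimum).

Protocol constants for nucleoside/nucleotide assembly: glycosidic C1′-N
bond started at 1.52 Å with the H-C1′-N1/N9-Cx torsion at −161.9°, and the
5′-phosphate O-C5′-C4′-C3′ torsion started at 30.9°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_core import DihedralSpec, Geometry, _wrap_deg, set_dihedral
from .errors import AnomerThermoError

__all__ = [
    "ScanProtocol",
    "ScanResult",
    "RefinedMinimum",
    "soft_scan",
    "refine_minimum",
    "GLYCOSIDIC_BOND_LENGTH",
    "GLYCOSIDIC_TORSION_INIT",
    "PHOSPHATE_TORSION_INIT",
]

GLYCOSIDIC_BOND_LENGTH = 1.52  # Å, initial C1'-N bond length
GLYCOSIDIC_TORSION_INIT = -161.9  # degrees, initial H-C1'-N1/N9-Cx torsion
PHOSPHATE_TORSION_INIT = 30.9  # degrees, initial O-C5'-C4'-C3' torsion


@dataclass(frozen=True)
class ScanProtocol:
    """Grid definition for one relaxed torsion scan."""

    dihedral: DihedralSpec
    start_deg: float
    step_deg: float = 60.0
    n_steps: int = 6
    start_at_initial: bool = True  # False: grid anchored at 0° instead

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be ≥ 1")
        if self.step_deg == 0:
            raise ValueError("step_deg must be nonzero")

    def grid(self) -> np.ndarray:
        """Raw (unwrapped) grid angles θ0 + k·step, k = 0..n_steps−1."""
        anchor = self.start_deg if self.start_at_initial else 0.0
        return anchor + self.step_deg * np.arange(self.n_steps)


@dataclass(frozen=True)
class ScanResult:
    """Relaxed-scan profile; angles reported wrapped into (−180, +180]."""

    protocol: ScanProtocol
    angles: tuple[float, ...]  # wrapped grid angles
    energies: tuple[float, ...]  # kcal/mol, NaN where unconverged
    converged: tuple[bool, ...]
    geometries: tuple[Geometry, ...]

    @property
    def argmin_index(self) -> int:
        """Lowest converged grid point; ties resolved toward the smaller angle."""
        candidates = [
            (self.energies[i], self.angles[i], i)
            for i in range(len(self.angles))
            if self.converged[i]
        ]
        if not candidates:
            raise AnomerThermoError("no converged grid point in scan")
        return min(candidates)[2]

    @property
    def min_energy(self) -> float:
        return self.energies[self.argmin_index]

    @property
    def any_unconverged(self) -> bool:
        return not all(self.converged)

    def to_csv(self) -> str:
        lines = ["angle_deg,energy_kcal_mol,converged"]
        for a, e, c in zip(self.angles, self.energies, self.converged):
            lines.append(f"{a:.4f},{e:.9f},{int(c)}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RefinedMinimum:
    """Result of the final unconstrained refinement + frequency vetting."""

    geometry: Geometry
    energy: float
    frequencies: tuple[float, ...]
    is_minimum: bool  # True iff zero imaginary modes
    converged: bool

    @property
    def imaginary_count(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)


def soft_scan(geom: Geometry, protocol: ScanProtocol, backend) -> ScanResult:
    """Run the relaxed scan; unconverged points are flagged, not fatal."""
    protocol.dihedral.validate(geom)
    angles_raw = protocol.grid()
    current = geom
    wrapped, energies, flags, geoms = [], [], [], []
    for angle in angles_raw:
        current = set_dihedral(current, protocol.dihedral, float(angle))
        res = backend.optimize(current, constraints=[(protocol.dihedral, float(angle))])
        wrapped.append(_wrap_deg(float(angle)))
        energies.append(float(res.energy) if res.converged else float("nan"))
        flags.append(bool(res.converged))
        geoms.append(res.geometry)
        current = res.geometry  # chain continuation
    return ScanResult(
        protocol=protocol,
        angles=tuple(wrapped),
        energies=tuple(energies),
        converged=tuple(flags),
        geometries=tuple(geoms),
    )


def refine_minimum(scan: ScanResult, backend) -> RefinedMinimum:
    """Unconstrained optimization from the scan argmin, with frequency vetting.

    The refined energy never exceeds the grid minimum. An imaginary mode
    does not raise — the result is returned flagged not-a-minimum.
    """
    start = scan.geometries[scan.argmin_index]
    res = backend.optimize(start)
    freqs = tuple(float(f) for f in backend.frequencies(res.geometry))
    return RefinedMinimum(
        geometry=res.geometry,
        energy=float(res.energy),
        frequencies=freqs,
        is_minimum=all(f > 0 for f in freqs),
        converged=bool(res.converged),
    )
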