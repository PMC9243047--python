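"""Pluggable energy backends and quantum-chemistry deck/log adapters.

The pipeline treats energies as backend-supplied. The built-in
:class:`SurrogateBackend` is a small molecular-mechanics potential
(harmonic bonds/1-3 pairs, cosine torsions, 12-6 nonbonded) with a local
optimizer and finite-difference harmonic frequencies, so the whole workflow
runs with no external program. Adapters write MOPAC-style/.gjf input decks
and parse the contractual markers of output logs (final heat of formation,
SCF energy, free-energy sums, harmonic frequencies).

The "aqueous" phase tag is a pass-through label selecting which keyword
set or fixture a backend uses; no continuum solvation is simulated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .chem_core import (
    BondGraph,
    DihedralSpec,
    Geometry,
    bond_graph,
    measure_dihedral,
    set_dihedral,
)
from .constants import AMU_TO_KG, AVOGADRO, CAL_TO_J, HARTREE_TO_KCAL_PER_MOL, SPEED_OF_LIGHT_M_S
from .errors import ParseError, SingularPairError
from .thermochem import n_rigid_modes

__all__ = [
    "SurrogateParams",
    "SurrogateBackend",
    "OptimizationResult",
    "EnergyRecord",
    "parse_qc_output",
    "write_qc_input",
    "extract_geometry_from_input",
]

GRADIENT_TOL = 1e-4  # kcal/mol/Å, RMS
MAX_ITERATIONS = 500
HARD_CORE_RADIUS = 0.1  # Å


@dataclass(frozen=True)
class EnergyRecord:
    """Energy/frequency summary for one structure, kcal/mol and cm⁻¹.

    Negative wavenumbers denote imaginary modes; a record with any is
    flagged not-a-minimum. ``gibbs`` is present only when a free energy was
    actually available (parsed or computed alongside frequencies).
    """

    electronic_energy: float
    frequencies: tuple[float, ...] = ()
    zpe: float | None = None
    gibbs: float | None = None
    backend_tag: str = ""
    phase: str = "vacuum"

    @property
    def imaginary_count(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)

    @property
    def is_minimum(self) -> bool:
        return len(self.frequencies) > 0 and self.imaginary_count == 0

    @property
    def e_plus_zpe(self) -> float | None:
        if self.zpe is None:
            return None
        return self.electronic_energy + self.zpe


@dataclass(frozen=True)
class OptimizationResult:
    geometry: Geometry
    energy: float
    converged: bool
    gradient_norm: float  # RMS, projected for constrained runs
    n_iterations: int = 0


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate potential.

    bonds: (i, j, k_force kcal/mol/Å², r0 Å) — harmonic pairs, including
      optional 1-3 "angle-spring" pairs.
    torsions: (i, j, k, l, barrier kcal/mol, multiplicity, phase °) with
      E = (V/2)·(1 + cos(n·θ − γ)).
    nonbonded: (i, j, well depth ε kcal/mol, rmin Å) 12-6 pairs with the
      minimum −ε at rmin.
    """

    bonds: tuple[tuple[int, int, float, float], ...] = ()
    torsions: tuple[tuple[int, int, int, int, float, int, float], ...] = ()
    nonbonded: tuple[tuple[int, int, float, float], ...] = ()

    def __post_init__(self):
        for *_ij, k, r0 in self.bonds:
            if k < 0 or r0 <= 0:
                raise ValueError("bond force constants must be ≥ 0 and lengths > 0")
        for *_ijkl, v, n, _g in self.torsions:
            if v < 0 or n < 1:
                raise ValueError("torsion barriers must be ≥ 0, multiplicities ≥ 1")
        for *_ij, eps, rmin in self.nonbonded:
            if eps < 0 or rmin <= 0:
                raise ValueError("well depths must be ≥ 0 and radii > 0")

    @classmethod
    def from_geometry(
        cls,
        geom: Geometry,
        graph: BondGraph | None = None,
        bond_k: float = 300.0,
        angle_k: float = 60.0,
        torsion_barrier: float = 1.5,
        nb_epsilon: float = 0.05,
        nb_rmin: float = 3.2,
    ) -> "SurrogateParams":
        """Auto-parameterize around the current geometry.

        The input structure becomes a (near-)minimum: harmonic terms use the
        current bond and 1-3 distances as reference values, every rotatable
        bond gets one 3-fold cosine torsion, and atom pairs 4+ bonds apart
        get a soft 12-6 term.
        """
        if graph is None:
            graph = bond_graph(geom)
        dist = np.linalg.norm(geom.coords[:, None, :] - geom.coords[None, :, :], axis=-1)
        bonds = []
        for e in sorted(graph.edges, key=sorted):
            a, b = sorted(e)
            bonds.append((a, b, bond_k, float(dist[a, b])))
        # 1-3 pairs act as angle springs
        pairs13 = set()
        for j in range(geom.n_atoms):
            nbrs = sorted(graph.neighbors(j))
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    a, b = nbrs[x], nbrs[y]
                    if not graph.has_bond(a, b):
                        pairs13.add((min(a, b), max(a, b)))
        for a, b in sorted(pairs13):
            bonds.append((a, b, angle_k, float(dist[a, b])))
        # one cosine term per rotatable (non-terminal, non-ring) bond
        torsions = []
        for e in sorted(graph.edges, key=sorted):
            j, k = sorted(e)
            if len(graph.components_without(j, k)) != 2:
                continue  # ring bond
            nj = sorted(a for a in graph.neighbors(j) if a != k)
            nk = sorted(a for a in graph.neighbors(k) if a != j)
            if not nj or not nk:
                continue
            theta0 = measure_dihedral(geom, DihedralSpec(nj[0], j, k, nk[0]))
            # phase chosen so the current torsion sits at a cosine minimum
            gamma = (3.0 * theta0 - 180.0) % 360.0
            torsions.append((nj[0], j, k, nk[0], torsion_barrier, 3, float(gamma)))
        # topological distances for 1-4+ detection
        nb = []
        sep = _bond_separation(graph)
        for a in range(geom.n_atoms):
            for b in range(a + 1, geom.n_atoms):
                if sep[a][b] >= 4:
                    nb.append((a, b, nb_epsilon, nb_rmin))
        return cls(bonds=tuple(bonds), torsions=tuple(torsions), nonbonded=tuple(nb))


def _bond_separation(graph: BondGraph) -> list[list[int]]:
    """All-pairs shortest path lengths over the bond graph (BFS; ∞ → big)."""
    n = graph.n_atoms
    big = 10**6
    out = []
    for src in range(n):
        d = [big] * n
        d[src] = 0
        queue = [src]
        while queue:
            nxt = []
            for a in queue:
                for b in graph.neighbors(a):
                    if d[b] > d[a] + 1:
                        d[b] = d[a] + 1
                        nxt.append(b)
            queue = nxt
        out.append(d)
    return out


class SurrogateBackend:
    """Deterministic surrogate potential with optimizer and frequencies.

    Implements the backend contract: ``evaluate``, ``optimize`` (with
    frozen-dihedral constraints, imposed by projection) and
    ``frequencies``. Energies in kcal/mol, coordinates in Å.
    """

    tag = "surrogate"

    def __init__(self, params: SurrogateParams, phase: str = "vacuum"):
        self.params = params
        self.phase = phase
        # vectorized term tables
        b = params.bonds
        self._b_idx = np.array([(t[0], t[1]) for t in b], dtype=int).reshape(-1, 2)
        self._b_k = np.array([t[2] for t in b])
        self._b_r0 = np.array([t[3] for t in b])
        nb = params.nonbonded
        self._nb_idx = np.array([(t[0], t[1]) for t in nb], dtype=int).reshape(-1, 2)
        self._nb_eps = np.array([t[2] for t in nb])
        self._nb_rmin = np.array([t[3] for t in nb])
        tor = params.torsions
        self._t_idx = np.array([t[:4] for t in tor], dtype=int).reshape(-1, 4)
        self._t_v = np.array([t[4] for t in tor])
        self._t_n = np.array([t[5] for t in tor], dtype=float)
        self._t_gamma = np.array([t[6] for t in tor])

    # ---- energy ---------------------------------------------------------

    def evaluate(self, geom: Geometry) -> float:
        return self._energy(geom.coords)

    def _pair_vectors(self, c: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if idx.size == 0:
            return np.zeros((0, 3)), np.zeros(0)
        d = c[idx[:, 0]] - c[idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < HARD_CORE_RADIUS):
            bad = int(np.argmin(r))
            raise SingularPairError(
                f"atoms {idx[bad, 0]},{idx[bad, 1]} overlap (r={r[bad]:.3f} Å)"
            )
        return d, r

    def _torsion_angles(self, c: np.ndarray) -> np.ndarray:
        if self._t_idx.size == 0:
            return np.zeros(0)
        p0, p1, p2, p3 = (c[self._t_idx[:, k]] for k in range(4))
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
        x = np.einsum("ij,ij->i", n1, n2)
        return np.degrees(np.arctan2(y, x))

    def _energy(self, coords: np.ndarray) -> float:
        c = coords.reshape(-1, 3)
        e = 0.0
        _, rb = self._pair_vectors(c, self._b_idx)
        e += float(np.sum(self._b_k * (rb - self._b_r0) ** 2))
        _, rn = self._pair_vectors(c, self._nb_idx)
        if rn.size:
            x6 = (self._nb_rmin / rn) ** 6
            e += float(np.sum(self._nb_eps * (x6 * x6 - 2.0 * x6)))
        theta = self._torsion_angles(c)
        if theta.size:
            e += float(
                np.sum(0.5 * self._t_v * (1.0 + np.cos(np.radians(self._t_n * theta - self._t_gamma))))
            )
        return e

    def _energy_flat(self, x: np.ndarray) -> float:
        return self._energy(x.reshape(-1, 3))

    def _gradient_cart(self, coords: np.ndarray) -> np.ndarray:
        """Analytic pair-term gradient + per-term finite-difference torsion
        gradient (each torsion touches only its own 12 coordinates)."""
        c = coords.reshape(-1, 3)
        g = np.zeros_like(c)
        d, r = self._pair_vectors(c, self._b_idx)
        if r.size:
            dEdr = 2.0 * self._b_k * (r - self._b_r0)
            f = (dEdr / r)[:, None] * d
            np.add.at(g, self._b_idx[:, 0], f)
            np.add.at(g, self._b_idx[:, 1], -f)
        d, r = self._pair_vectors(c, self._nb_idx)
        if r.size:
            x6 = (self._nb_rmin / r) ** 6
            dEdr = -12.0 * self._nb_eps / r * (x6 * x6 - x6)
            f = (dEdr / r)[:, None] * d
            np.add.at(g, self._nb_idx[:, 0], f)
            np.add.at(g, self._nb_idx[:, 1], -f)
        if self._t_idx.size:
            theta = self._torsion_angles(c)
            # dE/dθ in rad⁻¹: E = V/2·(1 + cos(nθ − γ)) with θ, γ in degrees
            dEdtheta = -0.5 * self._t_v * self._t_n * np.sin(
                np.radians(self._t_n * theta - self._t_gamma)
            )
            di, dj, dk, dl = _torsion_gradients(c, self._t_idx)
            np.add.at(g, self._t_idx[:, 0], dEdtheta[:, None] * di)
            np.add.at(g, self._t_idx[:, 1], dEdtheta[:, None] * dj)
            np.add.at(g, self._t_idx[:, 2], dEdtheta[:, None] * dk)
            np.add.at(g, self._t_idx[:, 3], dEdtheta[:, None] * dl)
        return g.ravel()

    # ---- optimization ---------------------------------------------------

    def optimize(
        self,
        geom: Geometry,
        constraints: list[tuple[DihedralSpec, float]] | None = None,
        gtol: float = GRADIENT_TOL,
        max_iterations: int = MAX_ITERATIONS,
    ) -> OptimizationResult:
        """Gradient minimization; frozen dihedrals re-imposed by projection.

        Converged means the RMS gradient (projected orthogonal to the frozen
        torsion directions, when constrained) is ≤ *gtol* and every frozen
        dihedral sits at its target within 1e-6°. The reported energy never
        exceeds the input energy.
        """
        constraints = list(constraints or [])
        graph = bond_graph(geom)
        current = geom
        for spec, target in constraints:
            current = set_dihedral(current, spec, target, graph=graph)
        e_in = self.evaluate(current)

        if constraints:
            # stiff harmonic restraints hold the frozen torsions during the
            # minimization; the exact target is re-imposed (projection) after
            # each cycle, so the constraint is satisfied to machine precision
            restraint_k = 2000.0  # kcal/mol/rad², stiffened per cycle
            c_idx = np.array([spec.indices for spec, _t in constraints], dtype=int)
            c_target = np.array([t for _s, t in constraints])

            def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
                c = x.reshape(-1, 3)
                try:
                    e = self._energy(c)
                    g = self._gradient_cart(x).reshape(-1, 3)
                except SingularPairError:
                    # hard-core overlap during a line-search trial step:
                    # report a huge energy so the search backtracks
                    return 1e9, np.zeros_like(x)
                theta = np.array([_torsion(c, *row) for row in c_idx])
                dev = np.radians((theta - c_target + 180.0) % 360.0 - 180.0)
                e += float(0.5 * restraint_k * np.sum(dev**2))
                di, dj, dk, dl = _torsion_gradients(c, c_idx)
                w = restraint_k * dev
                np.add.at(g, c_idx[:, 0], w[:, None] * di)
                np.add.at(g, c_idx[:, 1], w[:, None] * dj)
                np.add.at(g, c_idx[:, 2], w[:, None] * dk)
                np.add.at(g, c_idx[:, 3], w[:, None] * dl)
                return e, g.ravel()

            best, e_best = current, e_in
            n_iter = 0
            converged = False
            grad_rms = math.inf
            for _cycle in range(12):
                res = minimize(
                    objective,
                    best.coords.ravel(),
                    method="L-BFGS-B",
                    jac=True,
                    options={"maxiter": max_iterations, "gtol": 1e-8, "ftol": 1e-16},
                )
                n_iter += int(res.nit)
                cand = best.with_coords(res.x.reshape(-1, 3))
                for spec, target in constraints:
                    cand = set_dihedral(cand, spec, target, graph=graph)
                e_cand = self.evaluate(cand)
                if e_cand <= e_best:
                    best, e_best = cand, e_cand
                grad_rms = self._projected_gradient_rms(best, constraints)
                if grad_rms <= gtol:
                    converged = True
                    break
                restraint_k = min(restraint_k * 5.0, 1e8)
            if e_best > e_in:
                best, e_best = current, e_in
            return OptimizationResult(
                geometry=best,
                energy=e_best,
                converged=converged,
                gradient_norm=grad_rms,
                n_iterations=n_iter,
            )

        def safe_objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            try:
                return self._energy_flat(x), self._gradient_cart(x)
            except SingularPairError:
                return 1e9, np.zeros_like(x)

        best, e_best = current, e_in
        n_iter = 0
        grad_rms = math.inf
        for _restart in range(8):  # L-BFGS may quit early on ftol; restart
            res = minimize(
                safe_objective,
                best.coords.ravel(),
                method="L-BFGS-B",
                jac=True,
                options={"maxiter": max_iterations, "gtol": 1e-8, "ftol": 1e-16},
            )
            n_iter += int(res.nit)
            cand = current.with_coords(res.x.reshape(-1, 3))
            e_cand = self.evaluate(cand)
            if e_cand <= e_best:
                best, e_best = cand, e_cand
            grad_rms = float(np.sqrt(np.mean(self.gradient(best) ** 2)))
            if grad_rms <= gtol or n_iter >= max_iterations:
                break
        if e_best > e_in:
            best, e_best = current, e_in
        return OptimizationResult(
            geometry=best,
            energy=e_best,
            converged=grad_rms <= gtol,
            gradient_norm=grad_rms,
            n_iterations=n_iter,
        )

    def gradient(self, geom: Geometry) -> np.ndarray:
        """Cartesian gradient in kcal/mol/Å."""
        return self._gradient_cart(geom.coords.ravel().copy())

    def _projected_gradient_rms(
        self, geom: Geometry, constraints: list[tuple[DihedralSpec, float]]
    ) -> float:
        g = self.gradient(geom)
        if constraints:
            basis = []
            for spec, _t in constraints:
                t = _dihedral_direction(geom, spec)
                for b in basis:
                    t = t - np.dot(t, b) * b
                nrm = np.linalg.norm(t)
                if nrm > 1e-12:
                    basis.append(t / nrm)
            for b in basis:
                g = g - np.dot(g, b) * b
        return float(np.sqrt(np.mean(g**2)))

    # ---- frequencies ----------------------------------------------------

    def hessian(self, geom: Geometry, step: float = 1e-4) -> np.ndarray:
        """Central finite-difference Cartesian Hessian, kcal/mol/Å²."""
        x0 = geom.coords.ravel().copy()
        n = x0.size
        H = np.zeros((n, n))
        for i in range(n):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += step
            xm[i] -= step
            H[i] = (self._gradient_cart(xp) - self._gradient_cart(xm)) / (2 * step)
        return 0.5 * (H + H.T)

    def frequencies(self, geom: Geometry) -> np.ndarray:
        """Harmonic wavenumbers in cm⁻¹, ascending; imaginary modes negative.

        Mass-weighted Cartesian Hessian eigenvalues with the rigid-body
        modes (the 3/5/6 smallest in magnitude) removed.
        """
        H = self.hessian(geom)
        m = np.repeat(geom.masses(), 3)
        F = H / np.sqrt(np.outer(m, m))
        evals = np.linalg.eigvalsh(F)
        # kcal/mol/Å²/amu → s⁻²
        to_si = (CAL_TO_J * 1000.0 / AVOGADRO) / (1e-20 * AMU_TO_KG)
        omega_sq = evals * to_si
        keep = np.argsort(np.abs(omega_sq))[n_rigid_modes(geom):]
        omega_sq = omega_sq[np.sort(keep)]
        wavenumbers = np.sign(omega_sq) * np.sqrt(np.abs(omega_sq)) / (
            2.0 * math.pi * SPEED_OF_LIGHT_M_S * 100.0
        )
        return np.sort(wavenumbers)

    def energy_record(self, geom: Geometry, with_frequencies: bool = True) -> EnergyRecord:
        e = self.evaluate(geom)
        if not with_frequencies:
            return EnergyRecord(electronic_energy=e, backend_tag=self.tag, phase=self.phase)
        freqs = tuple(float(f) for f in self.frequencies(geom))
        zpe_val = None
        if all(f > 0 for f in freqs):
            from .thermochem import zpe as _zpe

            zpe_val = _zpe(freqs)
        return EnergyRecord(
            electronic_energy=e,
            frequencies=freqs,
            zpe=zpe_val,
            backend_tag=self.tag,
            phase=self.phase,
        )


def _torsion_gradients(
    c: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """∂θ/∂r (radians per Å) for each torsion row of *idx*, per end atom.

    Standard rigid-geometry formulas: with b1 = rj−ri, b2 = rk−rj,
    b3 = rl−rk, n1 = b1×b2, n2 = b2×b3:
      ∂θ/∂ri = −|b2|·n1/|n1|², ∂θ/∂rl = +|b2|·n2/|n2|²,
    and the j/k derivatives follow from translation/rotation invariance.
    """
    p0, p1, p2, p3 = (c[idx[:, k]] for k in range(4))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-24)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-24)
    di = (-b2n / n1sq)[:, None] * n1
    dl = (b2n / n2sq)[:, None] * n2
    t = (np.einsum("ij,ij->i", b1, b2) / b2n**2)[:, None]
    s = (np.einsum("ij,ij->i", b3, b2) / b2n**2)[:, None]
    dj = -(1.0 + t) * di + s * dl
    dk = t * di - (1.0 + s) * dl
    return di, dj, dk, dl


def _torsion(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    y = float(np.dot(np.cross(n1, n2), b2) / max(b2n, 1e-12))
    x = float(np.dot(n1, n2))
    return math.degrees(math.atan2(y, x))


def _dihedral_direction(geom: Geometry, spec: DihedralSpec) -> np.ndarray:
    """Cartesian direction of the torsion coordinate (analytic ∂θ/∂r)."""
    idx = np.array([spec.indices], dtype=int)
    di, dj, dk, dl = _torsion_gradients(geom.coords, idx)
    d = np.zeros_like(geom.coords)
    d[spec.i] += di[0]
    d[spec.j] += dj[0]
    d[spec.k] += dk[0]
    d[spec.l] += dl[0]
    return d.ravel()


# --------------------------------------------------------------------------
# QC output parsing (contractual markers only)
# --------------------------------------------------------------------------

_MOPAC_HOF = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL", re.IGNORECASE
)
_MOPAC_FREQ_LINE = re.compile(r"^\s*FREQ\.\s+(.*)$")
_G16_SCF = re.compile(r"SCF Done:\s*E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_G16_FREE = re.compile(r"Sum of electronic and thermal Free Energies\s*=\s*(-?\d+\.\d+)")
_G16_ZPE = re.compile(r"Zero-point correction\s*=\s*(-?\d+\.\d+)")
_G16_FREQ = re.compile(r"Frequencies\s*--\s*(.*)$")


def parse_qc_output(text: str, dialect: str, phase: str = "vacuum") -> EnergyRecord:
    """Extract an :class:`EnergyRecord` from a quantum-chemistry output log.

    ``mopac_out``: final heat of formation (kcal/mol) plus ``FREQ.`` rows.
    ``gaussian_log``: SCF energy and free-energy/ZPE sums (hartree, converted
    at 627.5095 kcal/mol per hartree) plus ``Frequencies --`` rows.
    Imaginary modes (negative wavenumbers) flag the record not-a-minimum.
    """
    if dialect == "mopac_out":
        m = list(_MOPAC_HOF.finditer(text))
        if not m:
            raise ParseError("no FINAL HEAT OF FORMATION marker in mopac output")
        energy = float(m[-1].group(1))
        freqs: list[float] = []
        for line in text.splitlines():
            fm = _MOPAC_FREQ_LINE.match(line)
            if fm:
                freqs.extend(float(v) for v in fm.group(1).split())
        zpe_val = None
        if freqs and all(f > 0 for f in freqs):
            from .thermochem import zpe as _zpe

            zpe_val = _zpe(freqs)
        return EnergyRecord(
            electronic_energy=energy,
            frequencies=tuple(freqs),
            zpe=zpe_val,
            backend_tag="mopac_out",
            phase=phase,
        )
    if dialect == "gaussian_log":
        scf = list(_G16_SCF.finditer(text))
        if not scf:
            raise ParseError("no 'SCF Done' energy marker in gaussian log")
        energy = float(scf[-1].group(1)) * HARTREE_TO_KCAL_PER_MOL
        freqs = []
        for line in text.splitlines():
            fm = _G16_FREQ.search(line)
            if fm:
                freqs.extend(float(v) for v in fm.group(1).split())
        zm = _G16_ZPE.search(text)
        gm = _G16_FREE.search(text)
        return EnergyRecord(
            electronic_energy=energy,
            frequencies=tuple(freqs),
            zpe=None if zm is None else float(zm.group(1)) * HARTREE_TO_KCAL_PER_MOL,
            gibbs=None if gm is None else float(gm.group(1)) * HARTREE_TO_KCAL_PER_MOL,
            backend_tag="gaussian_log",
            phase=phase,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_qc_input(geom: Geometry, dialect: str, keywords: str = "") -> str:
    """Emit a .mop / .gjf input deck embedding the geometry at 6 decimals."""
    if geom.n_atoms == 0:
        raise ValueError("refusing to write a deck for an empty geometry")
    if dialect == "mop":
        kw = keywords or "PM7 PRECISE"
        lines = [f"{kw} CHARGE={geom.charge}", geom.label or "generated deck", ""]
        for e, (x, y, z) in zip(geom.elements, geom.coords):
            lines.append(f"{e:<2s} {x:12.6f} 1 {y:12.6f} 1 {z:12.6f} 1")
        return "\n".join(lines) + "\n"
    if dialect == "gjf":
        kw = keywords or "# B3LYP/6-31G(d,p) Opt Freq"
        lines = [kw, "", geom.label or "generated deck", "", f"{geom.charge} 1"]
        for e, (x, y, z) in zip(geom.elements, geom.coords):
            lines.append(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
        lines.append("")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


_DECK_ATOM_MOP = re.compile(
    r"^\s*([A-Z][a-z]?)\s+(-?\d+\.\d+)\s+1\s+(-?\d+\.\d+)\s+1\s+(-?\d+\.\d+)\s+1\s*$"
)
_DECK_ATOM_GJF = re.compile(
    r"^\s*([A-Z][a-z]?)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)
_DECK_CHARGE_MOP = re.compile(r"CHARGE=(-?\d+)", re.IGNORECASE)


def extract_geometry_from_input(text: str, dialect: str) -> Geometry:
    """Parse the geometry (and charge) back out of a deck written by this module."""
    if dialect == "mop":
        pattern, charge_re = _DECK_ATOM_MOP, _DECK_CHARGE_MOP
    elif dialect == "gjf":
        pattern, charge_re = _DECK_ATOM_GJF, None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    elements, coords = [], []
    charge = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if charge_re is not None:
            cm = charge_re.search(line)
            if cm:
                charge = int(cm.group(1))
        m = pattern.match(line)
        if m:
            elements.append(m.group(1))
            coords.append([float(m.group(2)), float(m.group(3)), float(m.group(4))])
    if dialect == "gjf":
        for line in text.splitlines():
            parts = line.split()
            if len(parts) == 2 and re.fullmatch(r"-?\d+", parts[0]) and re.fullmatch(
                r"\d+", parts[1]
            ):
                charge = int(parts[0])
                break
    if not elements:
        raise ParseError("no atom rows found in input deck")
    return Geometry(tuple(elements), np.array(coords), charge=charge)
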